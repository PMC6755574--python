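"""Accumulation (hit-enrichment) curves.

An accumulation curve plots the cumulative response over the first m
"tests" when observations are tested in decreasing order of predicted
score.  For a binary response this counts actives found after m tests;
the binary curve is a special case of the continuous definition.  Two
reference curves accompany every plot: the *ideal* curve of a ranker
that finds all p positives in the first p tests (min(m, p) for binary
y; descending-sorted cumulative sums in general), and the *random*
curve — the expected accumulation under a uniformly random testing
order, a straight line through m * sum(y) / n.  The random curve is the
deterministic expectation, not one sampled ordering.

Ties in the predicted score are broken by original row order (stable
descending sort), matching the top-m rule used by initial enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import _top_m_order, combo_label

__all__ = [
    "AccumulationCurve",
    "PlotGroup",
    "default_max_select",
    "accumulation_curve",
    "ideal_curve",
    "random_curve",
    "curve_series",
]


def default_max_select(n: int) -> int:
    """floor(min(300, n/4)) — prioritises finding actives in few tests."""
    if n < 4:
        raise ValueError("need at least 4 observations")
    return int(np.floor(min(300.0, n / 4.0)))


@dataclass(frozen=True)
class AccumulationCurve:
    tests: np.ndarray  # 1..max_select
    accumulated: np.ndarray
    label: tuple  # (split, descriptor_set, method) or a reference name
    kind: str  # "model" | "ideal" | "random"


def _check_max_select(n: int, max_select: int) -> None:
    if not 1 <= max_select <= n:
        raise ValueError(f"need 1 <= max_select <= n, got {max_select} (n={n})")


def accumulation_curve(y, scores, max_select: int,
                       label: tuple = ()) -> AccumulationCurve:
    """Cumulative response in decreasing-score testing order."""
    y = np.asarray(y, float)
    _check_max_select(len(y), max_select)
    order = _top_m_order(np.asarray(scores, float))
    acc = np.cumsum(y[order[:max_select]])
    return AccumulationCurve(
        tests=np.arange(1, max_select + 1), accumulated=acc,
        label=label, kind="model",
    )


def ideal_curve(y, max_select: int) -> AccumulationCurve:
    """Best achievable accumulation: y sorted in decreasing order.

    For binary y this equals min(m, p) at m tests.
    """
    y = np.asarray(y, float)
    _check_max_select(len(y), max_select)
    acc = np.cumsum(np.sort(y)[::-1][:max_select])
    return AccumulationCurve(
        tests=np.arange(1, max_select + 1), accumulated=acc,
        label=("ideal",), kind="ideal",
    )


def random_curve(y, max_select: int) -> AccumulationCurve:
    """Expected accumulation under random testing order: m * sum(y) / n."""
    y = np.asarray(y, float)
    _check_max_select(len(y), max_select)
    m = np.arange(1, max_select + 1)
    return AccumulationCurve(
        tests=m, accumulated=m * y.sum() / len(y),
        label=("random",), kind="random",
    )


@dataclass(frozen=True)
class PlotGroup:
    """One panel: model curves plus the ideal and random references."""

    key: tuple  # (split, descriptor_set) or (split, method)
    series: str  # "descriptors" | "methods"
    curves: tuple  # model curves
    ideal: AccumulationCurve
    random: AccumulationCurve


def curve_series(
    store,
    series: str = "descriptors",
    splits=None,
    meths=None,
    max_select: int | None = None,
) -> list:
    """Group accumulation curves into plot panels.

    ``series="descriptors"``: one panel per (split, descriptor set),
    overlaying the curves of every method.  ``series="methods"``: one
    panel per (split, method), overlaying descriptor sets.  ``"both"``
    concatenates the two.  ``splits``/``meths`` subset the panels.
    """
    if series == "both":
        return curve_series(store, "descriptors", splits, meths, max_select) + \
            curve_series(store, "methods", splits, meths, max_select)
    if series not in ("descriptors", "methods"):
        raise ValueError("series must be 'descriptors', 'methods' or 'both'")
    if not store.entries:
        raise ValueError("empty prediction store")
    if max_select is None:
        max_select = default_max_select(store.n)

    keys = list(store.entries)
    if splits is not None:
        keys = [k for k in keys if k[0] in set(splits)]
    if meths is not None:
        keys = [k for k in keys if k[2] in set(meths)]
    if not keys:
        raise ValueError("no (split, descriptor set, method) entries match the filter")

    y = store.observed
    ideal = ideal_curve(y, max_select)
    rand = random_curve(y, max_select)
    group_of = (lambda k: (k[0], k[1])) if series == "descriptors" else \
        (lambda k: (k[0], k[2]))
    groups: dict[tuple, list] = {}
    for k in keys:
        groups.setdefault(group_of(k), []).append(k)
    out = []
    for gk, members in groups.items():
        curves = tuple(
            accumulation_curve(y, store.entries[k], max_select, label=k)
            for k in members
        )
        out.append(PlotGroup(key=gk, series=series, curves=curves,
                             ideal=ideal, random=rand))
    return out


def curves_to_frame(groups):
    """Flatten plot groups to a tidy table of curve coordinates."""
    import pandas as pd

    rows = []
    for g in groups:
        for curve in (*g.curves, g.ideal, g.random):
            if curve.kind == "model":
                split, dset, meth = curve.label
                name = combo_label(dset, meth)
            else:
                split, name = g.key[0], curve.kind
            for t, a in zip(curve.tests, curve.accumulated):
                rows.append(
                    {"series": g.series, "panel": "|".join(map(str, g.key)),
                     "split": split, "curve": name, "kind": curve.kind,
                     "tests": int(t), "accumulated": float(a)}
                )
    return pd.DataFrame(rows)
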