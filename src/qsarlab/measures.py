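"""Performance measures on pooled out-of-fold predictions.

Binary-response measures: error rate, sensitivity, specificity, PPV
(precision), F1, AUC, and initial enhancement (IE) — the hit rate among
the top-m ranked observations divided by the dataset's base rate of
positives, i.e. the fold improvement over random selection a model
delivers in the first m "tests".  Continuous-response measures: RMSE,
R² and Spearman's ρ.

One value is computed per (split, D-M combination) on that split's
pooled n out-of-fold predictions; the resulting table (splits as rows,
combinations as columns) is the input to the blocked ANOVA.  Undefined
values (0/0 ratios, zero-variance response) are encoded as NaN, not
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "PerformanceTable",
    "BINARY_MEASURES",
    "CONTINUOUS_MEASURES",
    "DEFAULT_M",
    "DEFAULT_THRESHOLD",
    "threshold_scores",
    "confusion",
    "binary_measures",
    "auc",
    "initial_enhancement",
    "continuous_measures",
    "build_performance_table",
    "larger_is_better",
]

DEFAULT_M = 300
DEFAULT_THRESHOLD = 0.5

BINARY_MEASURES = ("error_rate", "sensitivity", "specificity", "auc", "ppv", "f1", "ie")
CONTINUOUS_MEASURES = ("rmse", "r2", "spearman")

#: orientation of each measure; the MCS ordering is descending for
#: larger-is-better measures and ascending otherwise.
_LARGER_BETTER = {
    "error_rate": False, "rmse": False,
    "sensitivity": True, "specificity": True, "auc": True, "ppv": True,
    "f1": True, "ie": True, "r2": True, "spearman": True,
}


def larger_is_better(measure: str) -> bool:
    if measure not in _LARGER_BETTER:
        raise KeyError(f"unknown measure {measure!r}")
    return _LARGER_BETTER[measure]


def threshold_scores(scores, threshold: float) -> np.ndarray:
    """Binarize scores: 1 where score >= threshold, else 0."""
    return (np.asarray(scores, float) >= threshold).astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y, yhat) -> ConfusionCounts:
    y = np.asarray(y, int)
    yhat = np.asarray(yhat, int)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def binary_measures(c: ConfusionCounts) -> dict:
    """Confusion-matrix measures; 0/0 ratios come back as NaN markers."""
    sens = _ratio(c.tp, c.tp + c.fn)
    ppv = _ratio(c.tp, c.tp + c.fp)
    if np.isnan(sens) or np.isnan(ppv) or sens + ppv == 0:
        f1 = float("nan")
    else:
        f1 = 2 * sens * ppv / (sens + ppv)
    return {
        "error_rate": _ratio(c.fp + c.fn, c.n),
        "sensitivity": sens,
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": ppv,
        "f1": f1,
    }


def auc(y, scores) -> float:
    """Area under the ROC curve, the Mann-Whitney probability that a
    random positive outscores a random negative (ties count half)."""
    y = np.asarray(y, float)
    if len(set(np.unique(y))) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def _top_m_order(scores: np.ndarray) -> np.ndarray:
    # stable sort by descending score; original row order breaks ties
    return np.argsort(-np.asarray(scores, float), kind="stable")


def initial_enhancement(y, scores, m: int = DEFAULT_M) -> float:
    """IE = (h/m) / (p/n): hit rate at m tests over the base positive rate.

    h is the number of positives among the m highest-scored observations
    (ties broken by original row order).  A perfect ranking at m = p
    gives n/p; random scoring has expectation 1.
    """
    y = np.asarray(y, float)
    n = len(y)
    p = int(y.sum())
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
    if p < 1:
        raise ValueError("initial enhancement needs at least one positive")
    h = float(y[_top_m_order(scores)[:m]].sum())
    return (h / m) / (p / n)


def continuous_measures(y, yhat) -> dict:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or len(y) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return {"rmse": rmse, "r2": float("nan"), "spearman": float("nan")}
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    if np.std(yhat) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(y, yhat).statistic)
    return {"rmse": rmse, "r2": r2, "spearman": rho}


@dataclass
class PerformanceTable:
    """Split x D-M matrix of one measure, ready for the blocked ANOVA.

    Rows are splits (identical fold assignments across columns — the
    blocking structure); columns are "set/method" combination labels.
    """

    values: pd.DataFrame
    measure: str
    larger_is_better: bool
    m: int | None = None
    threshold: float | None = None

    @property
    def n_splits(self) -> int:
        return self.values.shape[0]

    @property
    def n_combos(self) -> int:
        return self.values.shape[1]

    def combo_means(self) -> pd.Series:
        return self.values.mean(axis=0)

    def drop_incomplete(self) -> "PerformanceTable":
        """Drop columns containing any undefined (NaN) cell, with a warning."""
        bad = self.values.columns[self.values.isna().any(axis=0)]
        if len(bad):
            warnings.warn(
                f"dropping combination(s) with undefined {self.measure}: "
                f"{list(bad)}"
            )
        return PerformanceTable(
            values=self.values.drop(columns=bad),
            measure=self.measure,
            larger_is_better=self.larger_is_better,
            m=self.m,
            threshold=self.threshold,
        )


def combo_label(descriptor_set: str, method: str) -> str:
    return f"{descriptor_set}/{method}"


def _one_measure(measure, y, scores, m, threshold):
    if measure == "auc":
        return auc(y, scores)
    if measure == "ie":
        return initial_enhancement(y, scores, m)
    if measure in BINARY_MEASURES:
        return binary_measures(confusion(y, threshold_scores(scores, threshold)))[measure]
    return continuous_measures(y, scores)[measure]


def build_performance_table(
    store,
    measure: str,
    m: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> PerformanceTable:
    """Evaluate one measure for every (split, D-M combination) in a store.

    Binary measures other than AUC/IE first binarize the scores at
    ``threshold`` (applied identically to probabilities and to the
    unbounded scores of the least-squares methods).  ``m`` defaults to
    min(300, n) for IE.
    """
    if measure not in BINARY_MEASURES + CONTINUOUS_MEASURES:
        raise KeyError(
            f"unknown measure {measure!r}; valid: "
            f"{BINARY_MEASURES + CONTINUOUS_MEASURES}"
        )
    if store.response_type == "binary" and measure in CONTINUOUS_MEASURES:
        raise ValueError(
            f"{measure} requires a continuous response; valid binary "
            f"measures: {BINARY_MEASURES}"
        )
    if store.response_type == "continuous" and measure in BINARY_MEASURES:
        raise ValueError(
            f"{measure} requires a binary response; valid continuous "
            f"measures: {CONTINUOUS_MEASURES}"
        )
    if measure == "ie" and m is None:
        m = min(DEFAULT_M, store.n)

    combos = store.combinations
    failed = set()
    rows = {}
    for split in store.splits:
        row = {}
        for d, meth in combos:
            key = (split, d, meth)
            if key not in store.entries:
                failed.add(combo_label(d, meth))
                row[combo_label(d, meth)] = float("nan")
                continue
            row[combo_label(d, meth)] = _one_measure(
                measure, store.observed, store.entries[key], m, threshold
            )
        rows[split] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "split"
    if failed:
        warnings.warn(f"dropping combination(s) with no predictions: {sorted(failed)}")
        df = df.drop(columns=sorted(failed))
    return PerformanceTable(
        values=df,
        measure=measure,
        larger_is_better=larger_is_better(measure),
        m=m if measure == "ie" else None,
        threshold=threshold if measure not in ("auc", "ie") else None,
    )
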