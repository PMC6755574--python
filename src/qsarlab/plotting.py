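"""Static renderings of the assessment outputs (matplotlib, Agg-safe).

Thin layer over the data structures in :mod:`accumulation`, :mod:`mcs`
and :mod:`applicability` so everything stays testable headlessly.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_mcs", "plot_curve_group", "plot_control_chart"]

_CATEGORY_COLORS = {
    0: "#2166ac",  # not significantly different from each other
    1: "#fddbc7",  # significant between the two band edges
    2: "#b2182b",  # significant at the strictest level
    -1: "#f0f0f0",  # diagonal
}


def _category_rank(cat: str, bands) -> int:
    lo, hi = bands
    if cat == "self":
        return -1
    if cat.startswith("p <="):
        return 2
    if cat.startswith("p >"):
        return 0
    return 1


def plot_mcs(matrix, bands, path, measure: str = "") -> None:
    """Heatmap of pairwise significance categories, best -> worst axes."""
    ranks = matrix.map(lambda c: _category_rank(c, bands))
    img = np.vectorize(lambda r: list(_CATEGORY_COLORS).index(r))(ranks.to_numpy())
    colors = [_CATEGORY_COLORS[k] for k in _CATEGORY_COLORS]
    cmap = matplotlib.colors.ListedColormap(colors)
    c = matrix.shape[0]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * c), max(5, 0.45 * c)))
    ax.imshow(img, cmap=cmap, vmin=0, vmax=len(colors) - 1)
    ax.set_xticks(range(c), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(c), matrix.index, fontsize=7)
    title = "Multiple comparisons similarity"
    if measure:
        title += f" — {measure}"
    ax.set_title(title)
    lo, hi = bands
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=_CATEGORY_COLORS[2]),
        plt.Rectangle((0, 0), 1, 1, color=_CATEGORY_COLORS[1]),
        plt.Rectangle((0, 0), 1, 1, color=_CATEGORY_COLORS[0]),
    ]
    ax.legend(handles, [f"p <= {lo:g}", f"{lo:g} < p <= {hi:g}", f"p > {hi:g}"],
              loc="upper left", bbox_to_anchor=(1.02, 1), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_curve_group(group, path) -> None:
    """One accumulation-curve panel: model curves + ideal and random."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve in group.curves:
        _, dset, meth = curve.label
        label = meth if group.series == "descriptors" else dset
        ax.plot(curve.tests, curve.accumulated, lw=1.2, label=label)
    ax.plot(group.ideal.tests, group.ideal.accumulated, "k--", lw=1.5,
            label="ideal")
    ax.plot(group.random.tests, group.random.accumulated, "k:", lw=1.5,
            label="random")
    ax.set_xlabel("tests")
    ax.set_ylabel("accumulated response")
    ax.set_title(" / ".join(map(str, group.key)))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_control_chart(result, path, ids=None) -> None:
    """T² per external observation with the UCL as a horizontal line."""
    m = len(result.t2)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(np.arange(1, m + 1), result.t2, "o-", ms=3, lw=0.8)
    ax.axhline(result.ucl, color="red", ls="--",
               label=f"UCL (alpha={result.alpha:g})")
    for i in result.outlier_indices:
        ax.plot(i + 1, result.t2[i], "rs", ms=6)
    ax.set_xlabel("external observation")
    ax.set_ylabel("Hotelling $T^2$")
    ax.set_title("Applicability domain control chart")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
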