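"""Blocked ANOVA and Tukey-Kramer multiple comparisons (the MCS plot).

The performance table from repeated cross-validation is a randomized
complete block design: splits are blocks (every D-M combination within
a split shares the fold assignment) and D-M combinations are the
treatments.  The additive fixed-effects model

    Y_ij = mu + alpha_i + beta_j + eps_ij

is fitted by the closed-form balanced two-way decomposition, with no
interaction term (one observation per cell leaves it inestimable).
All pairwise differences between combination means are then tested with
the Tukey-Kramer procedure: q = |diff| / sqrt(MS_error / s) referred to
the studentized range distribution on (c, df_error), which controls the
familywise error rate over all c(c-1)/2 comparisons.

The multiple-comparisons-similarity (MCS) matrix arranges combinations
best-to-worst by mean measure on both axes and colors each cell by the
pair's significance category (p <= 0.01, 0.01 < p <= 0.05, p > 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .measures import PerformanceTable

__all__ = [
    "AnovaResult",
    "ComparisonResult",
    "n_pairs",
    "blocked_anova",
    "tukey_kramer",
    "mcs_matrix",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS = (0.01, 0.05)
CATEGORIES = ("p <= 0.01", "0.01 < p <= 0.05", "p > 0.05")


def n_pairs(c: int) -> int:
    """Number of unordered pairs among c combinations: c(c-1)/2."""
    if c < 2:
        raise ValueError("need at least 2 combinations")
    return c * (c - 1) // 2


@dataclass(frozen=True)
class AnovaResult:
    grand_mean: float
    split_effects: pd.Series  # alpha_i
    combo_effects: pd.Series  # beta_j
    ss_split: float
    ss_combo: float
    ss_error: float
    ss_total: float
    df_split: int
    df_combo: int
    df_error: int
    ms_split: float
    ms_combo: float
    ms_error: float
    f_split: float
    f_combo: float
    p_split: float
    p_combo: float

    def table(self) -> pd.DataFrame:
        """Classical ANOVA table (rows: split, combination, error)."""
        return pd.DataFrame(
            {
                "df": [self.df_split, self.df_combo, self.df_error],
                "sum_sq": [self.ss_split, self.ss_combo, self.ss_error],
                "mean_sq": [self.ms_split, self.ms_combo, self.ms_error],
                "F": [self.f_split, self.f_combo, np.nan],
                "p": [self.p_split, self.p_combo, np.nan],
            },
            index=["split", "combination", "error"],
        )


def _values(table) -> pd.DataFrame:
    return table.values if isinstance(table, PerformanceTable) else pd.DataFrame(table)


def blocked_anova(table) -> AnovaResult:
    """Two-way additive ANOVA of a complete splits x combinations table.

    SS_split = c * sum_i (rowmean_i - grand)^2,
    SS_combo = s * sum_j (colmean_j - grand)^2, SS_error by subtraction;
    F statistics on (df, (s-1)(c-1)) degrees of freedom.
    """
    df = _values(table)
    s, c = df.shape
    if s < 2 or c < 2:
        raise ValueError("need at least 2 splits and 2 combinations (df_error >= 1)")
    if df.isna().any().any():
        bad = list(df.columns[df.isna().any(axis=0)])
        raise ValueError(
            f"table has undefined cells in columns {bad}; drop incomplete "
            "columns first (PerformanceTable.drop_incomplete)"
        )
    Y = df.to_numpy(float)
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_split = c * float(np.sum((row_means - grand) ** 2))
    ss_combo = s * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_error = max(ss_total - ss_split - ss_combo, 0.0)
    df_split, df_combo = s - 1, c - 1
    df_error = df_split * df_combo
    ms_split = ss_split / df_split
    ms_combo = ss_combo / df_combo
    ms_error = ss_error / df_error
    if ms_error > 0:
        f_split = ms_split / ms_error
        f_combo = ms_combo / ms_error
        p_split = float(stats.f.sf(f_split, df_split, df_error))
        p_combo = float(stats.f.sf(f_combo, df_combo, df_error))
    else:  # degenerate: perfectly additive table
        f_split = np.inf if ss_split > 0 else 0.0
        f_combo = np.inf if ss_combo > 0 else 0.0
        p_split = 0.0 if ss_split > 0 else 1.0
        p_combo = 0.0 if ss_combo > 0 else 1.0
    return AnovaResult(
        grand_mean=float(grand),
        split_effects=pd.Series(row_means - grand, index=df.index),
        combo_effects=pd.Series(col_means - grand, index=df.columns),
        ss_split=ss_split, ss_combo=ss_combo, ss_error=ss_error,
        ss_total=ss_total,
        df_split=df_split, df_combo=df_combo, df_error=df_error,
        ms_split=ms_split, ms_combo=ms_combo, ms_error=ms_error,
        f_split=f_split, f_combo=f_combo, p_split=p_split, p_combo=p_combo,
    )


@dataclass(frozen=True)
class ComparisonResult:
    ordered_combos: list  # best -> worst by mean measure, orientation-aware
    pairs: pd.DataFrame  # combo_a, combo_b, mean_a, mean_b, diff, se, q, p_adjusted, category
    anova: AnovaResult
    bands: tuple
    larger_is_better: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _category(p: float, bands: tuple) -> str:
    lo, hi = bands
    if p <= lo:
        return f"p <= {lo:g}"
    if p <= hi:
        return f"{lo:g} < p <= {hi:g}"
    return f"p > {hi:g}"


def tukey_kramer(
    table,
    anova: AnovaResult | None = None,
    bands: tuple = DEFAULT_BANDS,
    larger_is_better: bool | None = None,
) -> ComparisonResult:
    """All-pairs comparison of combination means, Tukey-Kramer adjusted.

    For each unordered pair: difference of combination means, standard
    error sqrt(MS_error / s) (balanced design, s blocks per mean), the
    studentized-range statistic q = |diff| / SE, and the adjusted
    p-value P(Q_{c, df_error} >= q).  With MS_error = 0 every nonzero
    difference gets p = 0 and zero differences p = 1 (degenerate case,
    logged).
    """
    df = _values(table)
    if anova is None:
        anova = blocked_anova(table)
    if larger_is_better is None:
        larger_is_better = (
            table.larger_is_better if isinstance(table, PerformanceTable) else True
        )
    s, c = df.shape
    means = df.mean(axis=0)
    se = float(np.sqrt(anova.ms_error / s))
    degenerate = anova.ms_error == 0
    if degenerate:
        warnings.warn("MS_error is 0; pairwise p-values are degenerate (0 or 1)")
    pair_list = list(combinations(df.columns, 2))
    diffs = np.array([means[a] - means[b] for a, b in pair_list])
    if degenerate:
        qs = np.where(diffs != 0, np.inf, 0.0)
        ps = np.where(diffs != 0, 0.0, 1.0)
    else:
        qs = np.abs(diffs) / se
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ps = np.clip(stats.studentized_range.sf(qs, c, anova.df_error), 0, 1)
    rows = [
        {"combo_a": a, "combo_b": b,
         "mean_a": float(means[a]), "mean_b": float(means[b]),
         "diff": float(d), "se": se, "q": float(q), "p_adjusted": float(p),
         "category": _category(float(p), bands)}
        for (a, b), d, q, p in zip(pair_list, diffs, qs, ps)
    ]
    order = means.sort_values(ascending=not larger_is_better).index.tolist()
    return ComparisonResult(
        ordered_combos=order,
        pairs=pd.DataFrame(rows),
        anova=anova,
        bands=bands,
        larger_is_better=larger_is_better,
    )


def mcs_matrix(comp: ComparisonResult) -> pd.DataFrame:
    """Symmetric matrix of significance categories, ordered best -> worst.

    Cell (j, j') holds the pair's category; the diagonal is "self".
    """
    order = comp.ordered_combos
    mat = pd.DataFrame("self", index=order, columns=order)
    for _, row in comp.pairs.iterrows():
        mat.loc[row.combo_a, row.combo_b] = row.category
        mat.loc[row.combo_b, row.combo_a] = row.category
    return mat
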