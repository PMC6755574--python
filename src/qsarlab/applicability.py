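"""Hotelling T² applicability-domain control chart.

For each external compound x, T² = (x - x̄)ᵀ S⁻¹ (x - x̄) — the squared
Mahalanobis distance from the training descriptor mean x̄ under the
training sample covariance S (divisor n-1).  Unlike Euclidean distance,
T² accounts for the correlation structure of the descriptors: a point
that is Euclidean-close but violates strong descriptor correlations is
still flagged.  The statistic is invariant under invertible affine maps
of the descriptor space, so standardization is irrelevant.

Observations with T² above the phase-II upper control limit

    UCL = p(n+1)(n-1) / (n(n-p)) * F_{1-α}(p, n-p)

(the individual-future-observation limit from multivariate quality
control) are treated as extrapolations outside the applicability
domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ControlChartResult", "hotelling_t2", "ucl", "control_chart"]


def _train_summary(train_X: np.ndarray, shrinkage: float = 0.0):
    train_X = np.asarray(train_X, float)
    n, p = train_X.shape
    if n <= p:
        raise ValueError(
            f"training covariance is singular with n={n} <= p={p}; reduce "
            "descriptor dimension (or enable ridge shrinkage)"
        )
    mean = train_X.mean(axis=0)
    cov = np.cov(train_X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if shrinkage > 0:
        cov = cov + shrinkage * np.eye(p) * np.trace(cov) / p
    return mean, cov


def hotelling_t2(train_X, new_X, shrinkage: float = 0.0) -> np.ndarray:
    """T² of each external row relative to the training mean/covariance.

    ``shrinkage`` (default off) adds a ridge term lambda * mean-variance
    to the covariance diagonal for near-singular training sets.
    """
    train_X = np.asarray(train_X, float)
    new_X = np.atleast_2d(np.asarray(new_X, float))
    if train_X.shape[1] != new_X.shape[1]:
        raise ValueError("train and external descriptor widths differ")
    mean, cov = _train_summary(train_X, shrinkage)
    centered = new_X - mean
    try:
        sol = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "training covariance is singular; reduce descriptor dimension"
        ) from exc
    return np.einsum("ij,ji->i", centered, sol)


def ucl(n: int, p: int, alpha: float = 0.05) -> float:
    """Phase-II Hotelling T² upper control limit for new individual
    observations; monotone decreasing in alpha."""
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    factor = p * (n + 1) * (n - 1) / (n * (n - p))
    return float(factor * stats.f.ppf(1 - alpha, p, n - p))


@dataclass
class ControlChartResult:
    t2: np.ndarray
    ucl: float
    alpha: float
    outlier_indices: np.ndarray
    train_mean: np.ndarray
    train_cov: np.ndarray

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)


def control_chart(train_X, new_X, alpha: float = 0.05,
                  shrinkage: float = 0.0) -> ControlChartResult:
    """T² per external observation plus the UCL and flagged outliers."""
    train_X = np.asarray(train_X, float)
    t2 = hotelling_t2(train_X, new_X, shrinkage)
    limit = ucl(train_X.shape[0], train_X.shape[1], alpha)
    mean, cov = _train_summary(train_X, shrinkage)
    return ControlChartResult(
        t2=t2,
        ucl=limit,
        alpha=alpha,
        outlier_indices=np.flatnonzero(t2 > limit),
        train_mean=mean,
        train_cov=cov,
    )
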