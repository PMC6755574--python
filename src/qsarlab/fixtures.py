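"""Synthetic dataset generators with controllable signal.

Every downstream module is testable without any download.  The default
binary fixture emulates the shape of a small cytotoxicity-screening
subset: 500 compounds of which exactly 50 are active, characterised by
a 24-column continuous descriptor set ("ContinuousSet", standard-normal
columns, e.g. Burden-number-like) and a 147-column binary descriptor
set ("BinarySet", Bernoulli presence/absence fingerprints).

Signal mechanism: a fraction of descriptor columns is "informative";
for actives, informative continuous columns get a mean shift of
``effect`` standard deviations and informative binary columns get an
increased success probability.  ``effect = 0`` gives an exact null
(descriptors independent of the response), which makes
chance-performance checks exact.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ModelingDataset
from .measures import PerformanceTable

__all__ = [
    "FixtureSpec",
    "make_binary_dataset",
    "make_continuous_dataset",
    "make_performance_table",
    "dataset_to_frame",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and signal of a synthetic binary screening dataset."""

    n: int = 500
    n_active: int = 50
    n_continuous_desc: int = 24
    n_binary_desc: int = 147
    effect: float = 1.0
    informative_fraction: float = 0.25
    base_rate: float = 0.2  # background success probability of binary descriptors
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_active < self.n:
            raise ValueError("need 0 < n_active < n")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.n_continuous_desc < 1 or self.n_binary_desc < 1:
            raise ValueError("descriptor-set widths must be >= 1")
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in [0, 1]")


def make_binary_dataset(spec: FixtureSpec = FixtureSpec()) -> ModelingDataset:
    """Generate a binary-response dataset with two descriptor sets."""
    rng = np.random.default_rng(spec.seed)
    y = np.zeros(spec.n)
    y[rng.choice(spec.n, size=spec.n_active, replace=False)] = 1.0
    active = y == 1

    n_inf_c = max(1, int(round(spec.informative_fraction * spec.n_continuous_desc)))
    cont = rng.standard_normal((spec.n, spec.n_continuous_desc))
    cont[np.ix_(active, np.arange(n_inf_c))] += spec.effect

    n_inf_b = max(1, int(round(spec.informative_fraction * spec.n_binary_desc)))
    prob = np.full((spec.n, spec.n_binary_desc), spec.base_rate)
    # success-probability shift scaled by effect, capped away from 1
    shift = min(0.2 * spec.effect, 0.95 - spec.base_rate)
    prob[np.ix_(active, np.arange(n_inf_b))] += shift
    binary = (rng.random((spec.n, spec.n_binary_desc)) < prob).astype(float)

    return ModelingDataset(
        ids=[f"CMPD{i + 1:05d}" for i in range(spec.n)],
        response=y,
        descriptor_sets={"ContinuousSet": cont, "BinarySet": binary},
        response_type="binary",
    )


def make_continuous_dataset(
    n: int = 277,
    n_desc: int = 10,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    informative_fraction: float = 0.3,
    seed: int = 0,
) -> ModelingDataset:
    """Continuous-response dataset: y is an ``effect``-weighted linear
    combination of informative descriptors plus Gaussian noise.

    The default n mirrors a small physical-property modeling set (e.g. a
    boiling-point series); no chemistry is generated.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_desc))
    n_inf = max(1, int(round(informative_fraction * n_desc)))
    w = np.zeros(n_desc)
    w[:n_inf] = effect
    y = X @ w + (rng.standard_normal(n) * noise_sd if noise_sd > 0 else 0.0)
    return ModelingDataset(
        ids=[f"CMPD{i + 1:05d}" for i in range(n)],
        response=y,
        descriptor_sets={"descriptors": X},
        response_type="continuous",
    )


def make_performance_table(
    s: int = 3,
    c: int = 18,
    sigma: float = 0.1,
    elevated: tuple | None = None,
    mu: float = 1.0,
    split_effect_sd: float = 0.1,
    seed: int = 0,
    measure: str = "synthetic",
    larger_is_better: bool = True,
) -> PerformanceTable:
    """Synthetic splits x combinations table following the additive model
    Y_ij = mu + alpha_i + delta * 1[j = elevated] + N(0, sigma²).

    ``elevated=(index, delta)`` raises one combination's mean by delta.
    Fixed split effects alpha_i are drawn once from N(0, split_effect_sd²).
    """
    if s < 2 or c < 2:
        raise ValueError("need s >= 2 and c >= 2")
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, split_effect_sd, size=s)
    Y = mu + alpha[:, None] + rng.normal(0.0, sigma, size=(s, c))
    if elevated is not None:
        j, delta = elevated
        Y[:, j] += delta
    df = pd.DataFrame(
        Y,
        index=pd.RangeIndex(1, s + 1, name="split"),
        columns=[f"combo{j + 1}" for j in range(c)],
    )
    return PerformanceTable(values=df, measure=measure,
                            larger_is_better=larger_is_better)


def dataset_to_frame(data: ModelingDataset, id_column: str = "ID",
                     response_column: str = "y") -> pd.DataFrame:
    """Flatten a dataset to the CSV layout `load_dataset` reads back."""
    cols = {id_column: data.ids, response_column: data.response}
    for name, X in data.descriptor_sets.items():
        for j in range(X.shape[1]):
            cols[f"{name}_{j + 1}"] = X[:, j]
    return pd.DataFrame(cols)
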