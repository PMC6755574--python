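"""Seeded repeated k-fold cross-validation with shared fold assignments.

Every descriptor-set/method (D-M) combination within a split is trained
and scored on the *identical* fold assignment, so the split acts as a
blocking factor in the downstream ANOVA: split-to-split variability is
separated from genuine differences between combinations.

Seeds follow the convention that, unspecified, split 1 uses 11111,
split 2 uses 22222, and so on.  Fold assignment is a seeded uniform
permutation of the observations dealt round-robin into k folds, which
guarantees fold sizes differ by at most one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import ModelingDataset
from .model_suite import (
    IncompatibleMethodError,
    fit_predict,
    method_descriptor,
    validate_params,
)

__all__ = [
    "CvPlan",
    "PredictionStore",
    "default_seeds",
    "assign_folds",
    "build_plan",
    "run_repeated_cv",
]

log = logging.getLogger(__name__)

DEFAULT_NSPLITS = 3
DEFAULT_NFOLDS = 10


def default_seeds(nsplits: int) -> list:
    """Seed for split i is 11111 * i: [11111, 22222, 33333, ...]."""
    if nsplits < 1:
        raise ValueError("nsplits must be >= 1")
    return [11111 * i for i in range(1, nsplits + 1)]


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Randomly assign n observations to k folds of near-equal size.

    Returns a length-n vector of fold labels in 1..k.  A seeded uniform
    permutation is dealt round-robin, so every fold has floor(n/k) or
    ceil(n/k) members and the same seed always reproduces the same
    assignment.
    """
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % k + 1
    return labels


@dataclass(frozen=True)
class CvPlan:
    """Per-split fold assignments shared by all D-M combinations."""

    nsplits: int
    nfolds: int
    seeds: tuple
    assignments: tuple  # one length-n label vector per split

    @property
    def n(self) -> int:
        return len(self.assignments[0])


def build_plan(
    n: int,
    nsplits: int = DEFAULT_NSPLITS,
    nfolds: int = DEFAULT_NFOLDS,
    seeds: list | None = None,
) -> CvPlan:
    """Construct the fold assignments for every split."""
    if seeds is None:
        seeds = default_seeds(nsplits)
    if len(seeds) != nsplits:
        raise ValueError(f"expected {nsplits} seeds, got {len(seeds)}")
    assignments = tuple(assign_folds(n, nfolds, s) for s in seeds)
    return CvPlan(nsplits=nsplits, nfolds=nfolds, seeds=tuple(seeds),
                  assignments=assignments)


@dataclass
class PredictionStore:
    """Out-of-fold predicted scores indexed by (split, descriptor set, method).

    Each entry is a length-n vector aligned to observation order; the
    prediction for an observation was made by a model trained without
    that observation's fold.
    """

    ids: list
    observed: np.ndarray
    response_type: str
    entries: dict = field(default_factory=dict)
    fold_assignments: dict = field(default_factory=dict)  # split -> labels
    skipped: list = field(default_factory=list)  # (split, set, method, reason)

    def add(self, split: int, descriptor_set: str, method: str,
            scores: np.ndarray) -> None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != self.observed.shape:
            raise ValueError("score vector length does not match observations")
        self.entries[(split, descriptor_set, method)] = scores

    @property
    def splits(self) -> list:
        return sorted({k[0] for k in self.entries})

    @property
    def combinations(self) -> list:
        """(descriptor_set, method) pairs present, in insertion order."""
        seen = []
        for _, d, m in self.entries:
            if (d, m) not in seen:
                seen.append((d, m))
        return seen

    @property
    def n(self) -> int:
        return len(self.observed)


def run_repeated_cv(
    data: ModelingDataset,
    methods: list,
    plan: CvPlan | None = None,
    params: dict | None = None,
) -> PredictionStore:
    """Train/predict over splits x folds x descriptor sets x methods.

    All D-M combinations within a split share the split's fold
    assignment (the blocking structure).  Preprocessing is fitted inside
    each training fold.  Model-internal randomness is seeded from one
    deterministic per-split stream, so the whole run is reproducible
    from the plan's seeds.

    A method incompatible with the response type is skipped with a
    warning (recorded in ``store.skipped``) rather than aborting the run.
    """
    for m in methods:
        method_descriptor(m)  # raises early on unknown names
    if params:
        validate_params(params)
    if plan is None:
        plan = build_plan(data.n)
    if plan.n != data.n:
        raise ValueError("CV plan was built for a different number of observations")

    store = PredictionStore(
        ids=list(data.ids),
        observed=data.response.copy(),
        response_type=data.response_type,
    )
    y = data.response
    for split_idx, (seed, folds) in enumerate(zip(plan.seeds, plan.assignments), 1):
        store.fold_assignments[split_idx] = folds
        seed_stream = np.random.default_rng(seed)
        for set_name, X in data.descriptor_sets.items():
            for method in methods:
                fit_seeds = seed_stream.integers(0, 2**31, size=plan.nfolds)
                desc = method_descriptor(method)
                if data.response_type == "continuous" and not desc.supports_continuous:
                    reason = f"{method} does not support continuous responses"
                    warnings.warn(f"skipping ({set_name}, {method}): {reason}")
                    store.skipped.append((split_idx, set_name, method, reason))
                    continue
                preds = np.empty(data.n)
                try:
                    for f in range(1, plan.nfolds + 1):
                        test = folds == f
                        train = ~test
                        preds[test] = fit_predict(
                            method, X[train], y[train], X[test],
                            params=params.get(method) if params else None,
                            response_type=data.response_type,
                            seed=int(fit_seeds[f - 1]),
                        )
                except IncompatibleMethodError as exc:
                    warnings.warn(f"skipping ({set_name}, {method}): {exc}")
                    store.skipped.append((split_idx, set_name, method, str(exc)))
                    continue
                store.add(split_idx, set_name, method, preds)
                log.info("split %d: %s/%s done", split_idx, set_name, method)
    return store
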