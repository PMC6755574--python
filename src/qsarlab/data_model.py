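"""Core dataset container and tabular I/O.

A :class:`ModelingDataset` holds observation IDs, a response vector
(binary 0/1 or continuous, larger = better) and one or more named
descriptor sets — blocks of numeric feature columns characterising each
compound.  Everything downstream (cross-validation, model fitting, the
performance measures) consumes this container, so validation is strict:
no missing values, descriptor matrices row-aligned with the response,
unique non-empty set names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelingDataset",
    "DescriptorSetSpec",
    "ValidationError",
    "ConfigurationError",
    "load_dataset",
    "write_predictions",
    "read_predictions",
]


class ValidationError(ValueError):
    """Raised when input data violate a dataset invariant."""


class ConfigurationError(ValueError):
    """Raised when a column specification does not match the file."""


@dataclass(frozen=True)
class DescriptorSetSpec:
    """Names a descriptor set and says which file columns belong to it.

    ``columns`` is either an explicit list of column names, or a
    ``(start, stop)`` tuple of 1-based *inclusive* positions among the
    descriptor columns (the columns left after removing the ID and
    response columns, in file order).  1-based inclusive ranges match
    the column-count narrative users of descriptor tables are used to.
    """

    name: str
    columns: tuple | list

    def __post_init__(self):
        if not self.name:
            raise ConfigurationError("descriptor set name must be non-empty")


@dataclass
class ModelingDataset:
    """IDs, response and named descriptor sets in one validated container."""

    ids: list
    response: np.ndarray
    descriptor_sets: dict  # name -> (n, p_d) float array, insertion-ordered
    response_type: str  # "binary" | "continuous"
    descriptor_names: dict = field(default_factory=dict)  # name -> column labels

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        n = self.response.shape[0]
        if n < 2:
            raise ValidationError("need at least 2 observations")
        if len(self.ids) != n:
            raise ValidationError("ids and response lengths differ")
        if not np.all(np.isfinite(self.response)):
            raise ValidationError("response contains missing/non-finite values")
        if self.response_type not in ("binary", "continuous"):
            raise ValidationError(f"unknown response_type {self.response_type!r}")
        if self.response_type == "binary":
            vals = set(np.unique(self.response))
            if not vals <= {0.0, 1.0}:
                raise ValidationError("binary response must contain only 0 and 1")
            if len(vals) < 2:
                raise ValidationError("binary response needs at least one 0 and one 1")
        if not self.descriptor_sets:
            raise ValidationError("at least one descriptor set required")
        seen = set()
        for name, X in self.descriptor_sets.items():
            if not name:
                raise ValidationError("descriptor set names must be non-empty")
            if name in seen:
                raise ValidationError(f"duplicate descriptor set name {name!r}")
            seen.add(name)
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != n:
                raise ValidationError(
                    f"descriptor set {name!r} must have {n} rows, got shape {X.shape}"
                )
            if not np.all(np.isfinite(X)):
                bad = np.argwhere(~np.isfinite(X))[0]
                raise ValidationError(
                    f"missing value in descriptor set {name!r} at row {bad[0]}, column {bad[1]}"
                )
            self.descriptor_sets[name] = X

    @property
    def n(self) -> int:
        """Number of observations."""
        return self.response.shape[0]

    @property
    def n_positive(self) -> int:
        """Number of positives (binary response only)."""
        if self.response_type != "binary":
            raise ValidationError("n_positive is defined for binary responses only")
        return int(self.response.sum())

    def set_widths(self) -> dict:
        return {name: X.shape[1] for name, X in self.descriptor_sets.items()}


def _infer_response_type(y: np.ndarray) -> str:
    return "binary" if set(np.unique(y)) <= {0.0, 1.0} else "continuous"


def load_dataset(
    path,
    response_column: str,
    id_column: str | None = None,
    set_specs: list | None = None,
    response_type: str | None = None,
) -> ModelingDataset:
    """Read a CSV with a header row into a :class:`ModelingDataset`.

    If ``set_specs`` is omitted all non-ID, non-response columns form a
    single descriptor set named ``"descriptors"``.  The response type is
    inferred as binary iff the response takes only values {0, 1};
    ``response_type`` overrides the inference.

    Raises :class:`ConfigurationError` for missing columns and
    :class:`ValidationError` for missing or non-numeric cells.
    """
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise ConfigurationError(f"response column {response_column!r} not in file")
    if id_column is not None and id_column not in df.columns:
        raise ConfigurationError(f"id column {id_column!r} not in file")

    ids = (
        df[id_column].astype(str).tolist()
        if id_column is not None
        else [str(i) for i in range(len(df))]
    )
    y = pd.to_numeric(df[response_column], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        row = int(np.argwhere(~np.isfinite(y))[0][0])
        raise ValidationError(
            f"missing or non-numeric response at row {row} (column {response_column!r})"
        )

    drop = {response_column} | ({id_column} if id_column else set())
    desc_cols = [c for c in df.columns if c not in drop]

    sets: dict[str, np.ndarray] = {}
    names: dict[str, list] = {}
    if set_specs is None:
        sets_cols = {"descriptors": desc_cols}
    else:
        sets_cols = {}
        used: set[str] = set()
        for spec in set_specs:
            if isinstance(spec.columns, tuple) and len(spec.columns) == 2 and all(
                isinstance(v, int) for v in spec.columns
            ):
                start, stop = spec.columns
                if not (1 <= start <= stop <= len(desc_cols)):
                    raise ConfigurationError(
                        f"set {spec.name!r}: range {start}-{stop} outside "
                        f"1-{len(desc_cols)} descriptor columns"
                    )
                cols = desc_cols[start - 1 : stop]
            else:
                cols = list(spec.columns)
                missing = [c for c in cols if c not in desc_cols]
                if missing:
                    raise ConfigurationError(
                        f"set {spec.name!r}: columns {missing} not in file"
                    )
            overlap = used & set(cols)
            if overlap:
                raise ConfigurationError(
                    f"set {spec.name!r} overlaps previous sets on {sorted(overlap)}"
                )
            used |= set(cols)
            if spec.name in sets_cols:
                raise ConfigurationError(f"duplicate set name {spec.name!r}")
            sets_cols[spec.name] = cols

    for name, cols in sets_cols.items():
        block = df[cols].apply(pd.to_numeric, errors="coerce")
        arr = block.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"missing or non-numeric value at row {int(r)}, column {cols[int(c)]!r}"
            )
        sets[name] = arr
        names[name] = cols

    rtype = response_type or _infer_response_type(y)
    return ModelingDataset(
        ids=ids,
        response=y,
        descriptor_sets=sets,
        response_type=rtype,
        descriptor_names=names,
    )


PREDICTION_COLUMNS = ["split", "descriptor_set", "method", "id", "observed", "predicted"]


def write_predictions(store, path) -> None:
    """Serialize a PredictionStore to a long-format CSV.

    One row per (split, descriptor set, method, observation) with the
    observed response and out-of-fold predicted score.  Round-trips
    losslessly up to float formatting via :func:`read_predictions`.
    """
    if not store.entries:
        raise ValidationError("refusing to write an empty prediction store")
    frames = []
    for (split, dset, method), scores in store.entries.items():
        frames.append(
            pd.DataFrame(
                {
                    "split": split,
                    "descriptor_set": dset,
                    "method": method,
                    "id": store.ids,
                    "observed": store.observed,
                    "predicted": scores,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_predictions(path):
    """Read a predictions CSV back into a PredictionStore."""
    from .cv_engine import PredictionStore  # local import avoids a cycle

    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"predictions file lacks columns {missing}")
    first = df[(df.split == df.split.iloc[0])]
    key0 = (df.split.iloc[0], df.descriptor_set.iloc[0], df.method.iloc[0])
    base = first[(first.descriptor_set == key0[1]) & (first.method == key0[2])]
    ids = base["id"].tolist()
    observed = base["observed"].to_numpy(dtype=float)
    rtype = _infer_response_type(observed)
    store = PredictionStore(ids=ids, observed=observed, response_type=rtype)
    for (split, dset, method), grp in df.groupby(
        ["split", "descriptor_set", "method"], sort=False
    ):
        if grp["id"].tolist() != ids:
            grp = grp.set_index("id").loc[ids].reset_index()
        store.add(int(split), str(dset), str(method), grp["predicted"].to_numpy(float))
    return store
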