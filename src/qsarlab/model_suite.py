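"""Registry of the 13 modeling methods with a uniform fit/predict contract.

Methods fall into three response-handling groups:

* ``Tree, RPart, RF, KNN, NNet, SVM`` — support binary and continuous
  responses natively; for a binary response they return predicted
  probabilities of class 1 in [0, 1].
* ``Lasso, LAR, Ridge, ENet, PCR, PLS`` — least-squares methods that
  treat a binary response as continuous; their scores are unbounded
  reals and are deliberately *not* clipped to [0, 1].  Thresholding, if
  wanted, happens later in the measures layer.
* ``PLSLDA`` — binary only (a continuous response must be dichotomized
  by the caller first).

Methods that are sensitive to variable scale (everything except the
tree-based learners) get their inputs centered and scaled using
training-fold statistics only; see :func:`preprocess_for`.

Default hyperparameters are this package's own documented choices
(overridable per method through the parameter registry); the shrinkage
methods pick their penalty by a small internal cross-validated grid on
the training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import (
    ElasticNetCV,
    LarsCV,
    LassoCV,
    LinearRegression,
    RidgeCV,
)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = [
    "METHOD_NAMES",
    "MethodDescriptor",
    "method_descriptor",
    "make_model_defaults",
    "validate_params",
    "preprocess_for",
    "fit_predict",
    "IncompatibleMethodError",
]


class IncompatibleMethodError(ValueError):
    """Method cannot be applied to the given response type."""


@dataclass(frozen=True)
class MethodDescriptor:
    name: str
    supports_binary: bool
    supports_continuous: bool
    treats_binary_as_continuous: bool
    needs_standardization: bool


_NATIVE_BOTH = ("Tree", "RPart", "RF", "KNN", "NNet", "SVM")
_AS_CONTINUOUS = ("Lasso", "LAR", "Ridge", "ENet", "PCR", "PLS")

_REGISTRY: dict[str, MethodDescriptor] = {}
for _m in _NATIVE_BOTH:
    _REGISTRY[_m] = MethodDescriptor(
        _m,
        supports_binary=True,
        supports_continuous=True,
        treats_binary_as_continuous=False,
        needs_standardization=_m in ("KNN", "NNet", "SVM"),
    )
for _m in _AS_CONTINUOUS:
    _REGISTRY[_m] = MethodDescriptor(
        _m,
        supports_binary=True,
        supports_continuous=True,
        treats_binary_as_continuous=True,
        needs_standardization=True,
    )
_REGISTRY["PLSLDA"] = MethodDescriptor(
    "PLSLDA",
    supports_binary=True,
    supports_continuous=False,
    treats_binary_as_continuous=False,
    needs_standardization=True,
)

METHOD_NAMES = (
    "ENet", "KNN", "Lasso", "LAR", "NNet", "PLSLDA", "PLS",
    "PCR", "Ridge", "RF", "Tree", "RPart", "SVM",
)
assert set(METHOD_NAMES) == set(_REGISTRY)


def method_descriptor(name: str) -> MethodDescriptor:
    if name not in _REGISTRY:
        raise KeyError(f"unknown method {name!r}; choose from {sorted(_REGISTRY)}")
    return _REGISTRY[name]


_DEFAULTS = {
    "ENet": {"l1_ratio": 0.5, "n_alphas": 20, "cv": 3},
    "KNN": {"k": 10},
    "Lasso": {"n_alphas": 20, "cv": 3},
    "LAR": {"cv": 3, "max_iter": 50},
    "NNet": {"size": 2, "decay": 1e-3, "max_iter": 500},
    "PLSLDA": {"ncomp": 5},
    "PLS": {"ncomp": 10},
    "PCR": {"ncomp": 10},
    "Ridge": {"alphas": (0.01, 0.1, 1.0, 10.0, 100.0)},
    "RF": {"n_trees": 100, "max_features": "sqrt"},
    "Tree": {"min_samples_split": 2, "min_samples_leaf": 1},
    "RPart": {"min_samples_split": 20, "min_samples_leaf": 7, "ccp_alpha": 0.01},
    "SVM": {"kernel": "rbf", "cost": 1.0, "gamma": "scale"},
}


def make_model_defaults() -> dict:
    """Return the default parameter registry: method name -> {param: value}.

    Mutating the returned mapping (e.g. ``defaults["KNN"]["k"] = 5``) and
    passing it to the CV engine changes only that method's behaviour.
    """
    return {m: dict(p) for m, p in _DEFAULTS.items()}


def validate_params(params: dict) -> None:
    """Check that every key is a registered method with recognized parameters."""
    for method, overrides in params.items():
        if method not in _REGISTRY:
            raise KeyError(f"unknown method {method!r} in parameter registry")
        unknown = set(overrides) - set(_DEFAULTS[method])
        if unknown:
            raise KeyError(
                f"unrecognized parameter(s) {sorted(unknown)} for {method}; "
                f"valid: {sorted(_DEFAULTS[method])}"
            )


def preprocess_for(method: str, train_X: np.ndarray, test_X: np.ndarray):
    """Center/scale columns by training-fold statistics for methods needing it.

    Scale is the sample standard deviation (ddof=1); zero-variance
    training columns are centered but left unscaled (scale factor 1).
    Tree-based methods pass through unchanged.
    """
    desc = method_descriptor(method)
    if not desc.needs_standardization:
        return train_X, test_X
    mean = train_X.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = train_X.std(axis=0, ddof=1)
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    return (train_X - mean) / sd, (test_X - mean) / sd


def _merged(method: str, params: dict | None) -> dict:
    p = dict(_DEFAULTS[method])
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise KeyError(f"unrecognized parameter(s) {sorted(unknown)} for {method}")
        p.update(params)
    return p


def _max_components(requested: int, X: np.ndarray) -> int:
    return max(1, min(requested, X.shape[0] - 1, X.shape[1]))


def _fit_predict_raw(method, X, y, Xt, p, classify, seed):
    """Dispatch to the underlying learner. `classify` means y is 0/1 and the
    method handles classes natively (returns P(class 1))."""
    if method == "KNN":
        k = min(int(p["k"]), X.shape[0])
        est = (KNeighborsClassifier if classify else KNeighborsRegressor)(n_neighbors=k)
        est.fit(X, y.astype(int) if classify else y)
        return est.predict_proba(Xt)[:, 1] if classify else est.predict(Xt)

    if method == "RF":
        cls = RandomForestClassifier if classify else RandomForestRegressor
        est = cls(
            n_estimators=int(p["n_trees"]),
            max_features=p["max_features"],
            random_state=seed,
        )
        est.fit(X, y.astype(int) if classify else y)
        return est.predict_proba(Xt)[:, 1] if classify else est.predict(Xt)

    if method in ("Tree", "RPart"):
        kw = dict(
            min_samples_split=int(p["min_samples_split"]),
            min_samples_leaf=int(p["min_samples_leaf"]),
            random_state=seed,
        )
        if method == "RPart":
            kw["ccp_alpha"] = float(p["ccp_alpha"])
        est = (DecisionTreeClassifier if classify else DecisionTreeRegressor)(**kw)
        est.fit(X, y.astype(int) if classify else y)
        return est.predict_proba(Xt)[:, 1] if classify else est.predict(Xt)

    if method == "SVM":
        if classify:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                est = SVC(
                    kernel=p["kernel"], C=float(p["cost"]), gamma=p["gamma"],
                    probability=True, random_state=seed,
                )
                est.fit(X, y.astype(int))
            return est.predict_proba(Xt)[:, 1]
        est = SVR(kernel=p["kernel"], C=float(p["cost"]), gamma=p["gamma"])
        est.fit(X, y)
        return est.predict(Xt)

    if method == "NNet":
        cls = MLPClassifier if classify else MLPRegressor
        est = cls(
            hidden_layer_sizes=(int(p["size"]),),
            alpha=float(p["decay"]),
            max_iter=int(p["max_iter"]),
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y.astype(int) if classify else y)
        return est.predict_proba(Xt)[:, 1] if classify else est.predict(Xt)

    if method == "PLSLDA":
        ncomp = _max_components(int(p["ncomp"]), X)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X, y)
        lda = LinearDiscriminantAnalysis()
        lda.fit(pls.transform(X), y.astype(int))
        return lda.predict_proba(pls.transform(Xt))[:, 1]

    # least-squares family: y treated as continuous
    if method == "Lasso":
        est = LassoCV(alphas=int(p["n_alphas"]), cv=int(p["cv"]), random_state=seed)
    elif method == "ENet":
        est = ElasticNetCV(
            l1_ratio=float(p["l1_ratio"]), alphas=int(p["n_alphas"]),
            cv=int(p["cv"]), random_state=seed,
        )
    elif method == "Ridge":
        est = RidgeCV(alphas=list(p["alphas"]))
    elif method == "LAR":
        est = LarsCV(cv=int(p["cv"]), max_iter=int(p["max_iter"]))
    elif method == "PCR":
        ncomp = _max_components(int(p["ncomp"]), X)
        pca = PCA(n_components=ncomp, random_state=seed)
        Z = pca.fit_transform(X)
        ols = LinearRegression().fit(Z, y)
        return ols.predict(pca.transform(Xt))
    elif method == "PLS":
        ncomp = _max_components(int(p["ncomp"]), X)
        est = PLSRegression(n_components=ncomp, scale=False)
        est.fit(X, y)
        return np.asarray(est.predict(Xt)).ravel()
    else:  # pragma: no cover
        raise KeyError(method)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est.predict(Xt)


def fit_predict(
    method: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    params: dict | None = None,
    response_type: str = "binary",
    seed: int | None = 0,
) -> np.ndarray:
    """Fit one method on a training fold and score the held-out rows.

    Returns a score vector with the convention *higher = predicted more
    active*: probabilities of class 1 for native classifiers on binary
    responses, unbounded reals for the least-squares family, real-valued
    predictions for continuous responses.  Preprocessing is applied
    internally using training statistics only.

    Degenerate fits (constant response, numerical failure) fall back to
    predicting the training mean, with a warning — never a crash.
    """
    desc = method_descriptor(method)
    train_y = np.asarray(train_y, dtype=float)
    if response_type == "continuous" and not desc.supports_continuous:
        raise IncompatibleMethodError(
            f"{method} supports binary responses only; dichotomize the "
            "response with a threshold first"
        )
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test descriptor matrices differ in width")

    X, Xt = preprocess_for(method, np.asarray(train_X, float), np.asarray(test_X, float))
    classify = response_type == "binary" and not desc.treats_binary_as_continuous

    if np.all(train_y == train_y[0]):
        return np.full(test_X.shape[0], float(train_y[0]))
    try:
        scores = _fit_predict_raw(method, X, train_y, Xt, _merged(method, params),
                                  classify, seed)
    except KeyError:
        raise
    except Exception as exc:  # noqa: BLE001 — fallback keeps long runs alive
        warnings.warn(f"{method} fit failed ({exc!r}); predicting the mean response")
        return np.full(test_X.shape[0], float(train_y.mean()))
    return np.asarray(scores, dtype=float)
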