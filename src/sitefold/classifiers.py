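"""Regularized classifiers with per-fold standardization and nested tuning.

Three families are supported, all scored by AUC and all wrapped the same
way: features are z-scored using statistics of the training rows only, then
hyperparameters are chosen by an internal stratified CV before a final refit
on all supplied rows.

- ``ridge_logistic``: L2-penalized logistic regression; the regularization
  strength is chosen over a log-spaced grid (an efficient warm-started
  regularization path under the hood).
- ``elasticnet_logistic``: logistic regression with an elastic-net penalty;
  the mixing weight and the strength are drawn from a random search
  (l1_ratio ~ U(0,1), strength log-uniform).  The contract is the penalized
  objective, not a particular optimizer.
- ``svm_rbf``: RBF-kernel SVM with random search over C and gamma.

Ties in the inner-CV criterion are broken toward stronger regularization.
Scores follow one package-wide convention: higher = more case-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

FAMILIES = ("ridge_logistic", "elasticnet_logistic", "svm_rbf")


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of one classifier family and its search.

    ``fixed_params`` short-circuits the nested search entirely (used by the
    evolutionary search, where a fixed-strength ridge keeps fitness
    evaluation cheap).
    """

    family: str = "ridge_logistic"
    n_search: int = 100
    inner_folds: int = 3
    seed: int = 0
    fixed_params: dict | None = None
    ridge_grid_size: int = 13
    strength_range: tuple[float, float] = (1e-4, 1e4)  # C bounds (inverse strength)
    gamma_range: tuple[float, float] = (1e-6, 1e1)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_search < 1:
            raise ValueError("n_search must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        d = dict(d)
        for key in ("strength_range", "gamma_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FittedModel:
    """A trained classifier plus the standardization learned with it."""

    family: str
    params: dict
    feature_indices: np.ndarray  # columns (in the full canonical order) used
    n_features_in: int  # width of the matrices fit/predict expect
    mean_: np.ndarray
    scale_: np.ndarray
    estimator: object = field(repr=False, default=None)

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "params": {k: float(v) if isinstance(v, (int, float, np.floating)) else v
                       for k, v in self.params.items()},
            "feature_indices": [int(i) for i in self.feature_indices],
            "standardization": {
                "mean": [float(m) for m in self.mean_],
                "scale": [float(s) for s in self.scale_],
            },
        }
        coef = getattr(self.estimator, "coef_", None)
        if coef is not None:
            out["coef"] = [float(c) for c in np.ravel(coef)]
            out["intercept"] = float(np.ravel(self.estimator.intercept_)[0])
        return out


def _mask_to_indices(feature_mask, p: int) -> np.ndarray:
    if feature_mask is None:
        return np.arange(p)
    mask = np.asarray(feature_mask)
    idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if idx.size == 0:
        raise ValueError("feature mask selects no features")
    if idx.min() < 0 or idx.max() >= p:
        raise ValueError("feature mask index out of range")
    return idx


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    flat = scale == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance feature(s) standardized to zeros",
            RuntimeWarning,
            stacklevel=3,
        )
        scale = np.where(flat, 1.0, scale)
    return mean, scale


def _make_estimator(family: str, params: dict, seed: int):
    if family == "ridge_logistic":
        return LogisticRegression(penalty="l2", C=params["C"], solver="lbfgs", max_iter=2000)
    if family == "elasticnet_logistic":
        return LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            C=params["C"],
            l1_ratio=params["l1_ratio"],
            max_iter=3000,
            tol=1e-4,
            random_state=seed,
        )
    if family == "svm_rbf":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
    raise ValueError(family)


def _draw_candidates(spec: ClassifierSpec, rng: np.random.Generator) -> list[dict]:
    lo, hi = spec.strength_range
    if spec.family == "ridge_logistic":
        grid = np.logspace(np.log10(lo), np.log10(hi), spec.ridge_grid_size)
        return [{"C": float(c)} for c in grid]
    if spec.family == "elasticnet_logistic":
        return [
            {
                "C": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                "l1_ratio": float(rng.uniform(0.0, 1.0)),
            }
            for _ in range(spec.n_search)
        ]
    glo, ghi = spec.gamma_range
    return [
        {
            "C": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "gamma": float(np.exp(rng.uniform(np.log(glo), np.log(ghi)))),
        }
        for _ in range(spec.n_search)
    ]


def _inner_cv_auc(family, params, Z, y, folds, seed) -> float:
    aucs = []
    for tr, va in folds:
        est = _make_estimator(family, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saga convergence chatter at extreme C
            est.fit(Z[tr], y[tr])
        aucs.append(roc_auc_score(y[va], est.decision_function(Z[va])))
    return float(np.mean(aucs))


def fit(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_mask=None,
) -> FittedModel:
    """Standardize, tune by nested CV, and refit on all supplied rows.

    Standardization statistics come exclusively from the rows passed here;
    the nested search operates on the standardized training matrix.
    Deterministic for a given ``spec.seed``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    idx = _mask_to_indices(feature_mask, X.shape[1])
    Xs = X[:, idx]
    mean, scale = _standardize_stats(Xs)
    Z = (Xs - mean) / scale

    seed = int(spec.seed) % (2**31)
    skf = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=seed)

    if spec.fixed_params is not None:
        params = dict(spec.fixed_params)
    elif spec.family == "ridge_logistic":
        # Warm-started regularization path; argmax over ascending C takes the
        # smallest (most regularized) C on ties.
        grid = np.logspace(
            np.log10(spec.strength_range[0]),
            np.log10(spec.strength_range[1]),
            spec.ridge_grid_size,
        )
        lrcv = LogisticRegressionCV(
            Cs=grid, cv=skf, scoring="roc_auc", penalty="l2",
            solver="lbfgs", max_iter=300, refit=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lrcv.fit(Z, y)
        params = {"C": float(lrcv.C_[0])}
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1F]))
        candidates = _draw_candidates(spec, rng)
        folds = list(skf.split(Z, y))
        best = None
        for params_c in candidates:
            score = _inner_cv_auc(spec.family, params_c, Z, y, folds, seed)
            # tie-break: smaller C = stronger regularization
            key = (-score, params_c["C"])
            if best is None or key < best[0]:
                best = (key, params_c)
        params = best[1]

    est = _make_estimator(spec.family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Z, y)
    return FittedModel(
        family=spec.family,
        params=params,
        feature_indices=idx,
        n_features_in=X.shape[1],
        mean_=mean,
        scale_=scale,
        estimator=est,
    )


def predict_scores(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Decision scores (higher = more case-like) for new rows."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} columns, got {X.shape[1] if X.ndim == 2 else 'non-2d'}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    Z = (X[:, model.feature_indices] - model.mean_) / model.scale_
    return np.asarray(model.estimator.decision_function(Z), float)
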