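"""AUC computation, the two cross-validation schemes, and paired AUC tests.

Two schemes are compared throughout the package:

- *random repeated k-fold*, stratified on diagnosis only.  Site is
  deliberately ignored: when per-site class composition is confounded, this
  scheme lets a classifier exploit site fingerprints and overstates
  generalization.
- *leave-one-site-out* (LOSO): each balanced site is held out in turn and
  everything else (including any case-only / control-only sites present in
  the supplied dataset) trains the model; the reported score is the
  unweighted mean over held-out sites.

Paired AUC comparison uses DeLong's covariance estimator for correlated
ROC curves, with a label-preserving permutation test available as a
small-sample alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classifiers
from .data_model import MultiSiteDataset


@dataclass
class CVResult:
    """Per-fold AUCs for one (dataset, classifier, scheme) cell.

    ``sd`` is the sample standard deviation across all fold scores — i.e.
    across the R*k folds for repeated k-fold, and across left-out sites for
    LOSO — matching how multi-site studies typically report +/- SD.
    """

    scheme: str  # random_repeated_kfold | leave_site_out
    fold_scores: list[float]
    n_repeats: int = 1
    n_folds: int | None = None
    left_out_sites: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd(self) -> float:
        if len(self.fold_scores) < 2:
            return 0.0
        return float(np.std(self.fold_scores, ddof=1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "fold_scores": [float(s) for s in self.fold_scores],
                "mean": self.mean,
                "sd": self.sd,
                "n_repeats": self.n_repeats,
                "n_folds": self.n_folds,
                "left_out_sites": list(self.left_out_sites),
                "seed": self.seed,
            }
        )


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney statistic: the fraction of (case, control)
    pairs where the case outscores the control, ties counted 1/2.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def repeated_stratified_kfold_cv(
    ds: MultiSiteDataset,
    clf: classifiers.ClassifierSpec,
    k: int = 3,
    n_repeats: int = 50,
    seed: int = 0,
) -> CVResult:
    """Random repeated k-fold CV stratified on diagnosis only.

    Returns all ``n_repeats * k`` fold AUCs.  Site plays no role in the
    partitioning — that blindness is exactly the scheme under scrutiny.
    """
    counts = np.bincount(ds.y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} subjects per class")
    scores: list[float] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + rep) % 2**31)
        for tr, va in skf.split(ds.X, ds.y):
            model = classifiers.fit(clf, ds.X[tr], ds.y[tr])
            scores.append(compute_auc(classifiers.predict_scores(model, ds.X[va]), ds.y[va]))
    return CVResult(
        scheme="random_repeated_kfold",
        fold_scores=scores,
        n_repeats=n_repeats,
        n_folds=k,
        seed=seed,
    )


def leave_site_out_cv(
    ds: MultiSiteDataset,
    clf: classifiers.ClassifierSpec,
    fold_sites: list[str],
    feature_mask=None,
) -> CVResult:
    """Leave-one-site-out CV over the given balanced sites.

    For each fold site the model trains on every other subject in ``ds``
    (imbalanced sites included whenever the supplied variant contains them)
    and is scored on the held-out site.  The result is the unweighted mean
    of the per-site AUCs.
    """
    if len(fold_sites) < 2:
        raise ValueError("leave-site-out CV needs at least 2 fold sites")
    site = np.asarray(ds.site)
    scores: list[float] = []
    for s in fold_sites:
        held = site == s
        if not held.any():
            raise ValueError(f"fold site {s!r} absent from dataset")
        y_held = ds.y[held]
        if len(np.unique(y_held)) < 2:
            raise ValueError(f"fold site {s!r} lacks one of the classes")
        model = classifiers.fit(clf, ds.X[~held], ds.y[~held], feature_mask=feature_mask)
        scores.append(compute_auc(classifiers.predict_scores(model, ds.X[held]), y_held))
    return CVResult(
        scheme="leave_site_out",
        fold_scores=scores,
        n_folds=len(fold_sites),
        left_out_sites=list(fold_sites),
    )


class AUCComparison(NamedTuple):
    auc_a: float
    auc_b: float
    p_value: float


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the DeLong structural components V10 (cases), V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_rank = _midrank(np.concatenate([pos, neg]))
    pos_rank = _midrank(pos)
    neg_rank = _midrank(neg)
    auc = (all_rank[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_rank[:m] - pos_rank) / n
    v01 = 1.0 - (all_rank[m:] - neg_rank) / m
    return auc, v10, v01


SMALL_SAMPLE_N = 30  # at or below this, the permutation test replaces the
# asymptotic DeLong p-value, whose normal approximation is unreliable


def delong_compare(
    scores_a,
    scores_b,
    labels,
    method: str = "auto",
    n_permutations: int = 50_000,
    seed: int = 0,
) -> AUCComparison:
    """Two-sided test for equality of two correlated AUCs.

    Both score vectors must refer to the same subjects (same labels), e.g.
    two models evaluated on one test set.  ``method="asymptotic"`` uses
    DeLong's covariance estimator for correlated ROC curves;
    ``method="permutation"`` swaps the two models' scores per subject;
    ``"auto"`` (default) uses the permutation test when the sample is small
    (n <= 30 subjects) and DeLong's asymptotics otherwise.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if method not in ("auto", "asymptotic", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if method == "permutation" or (method == "auto" and len(labels) <= SMALL_SAMPLE_N):
        return permutation_compare(
            scores_a, scores_b, labels, n_permutations=n_permutations, seed=seed
        )

    auc_a, v10_a, v01_a = _delong_structural(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= np.finfo(float).tiny:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return AUCComparison(float(auc_a), float(auc_b), p)


def permutation_compare(
    scores_a, scores_b, labels, n_permutations: int = 10_000, seed: int = 0
) -> AUCComparison:
    """Paired permutation test of AUC equality (small-sample alternative).

    Under the null the two models are exchangeable per subject, so the pair
    (score_a_i, score_b_i) is swapped with probability 1/2 and the absolute
    AUC difference is re-measured; the p-value includes the observed
    statistic in the reference set.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if not (len(a) == len(b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    obs = abs(compute_auc(a, labels) - compute_auc(b, labels))
    rng = np.random.default_rng(seed)
    pos = labels == 1
    neg = ~pos
    count = 0
    chunk = max(1, min(n_permutations, 4_000_000 // (int(pos.sum()) * int(neg.sum()) + 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        swap = rng.random((m, len(a))) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        # pair-count AUC per permutation via broadcasting (cases x controls)
        pa_pos = pa[:, pos][:, :, None]
        pa_neg = pa[:, neg][:, None, :]
        da = (pa_pos > pa_neg).mean(axis=(1, 2)) + 0.5 * (pa_pos == pa_neg).mean(axis=(1, 2))
        pb_pos = pb[:, pos][:, :, None]
        pb_neg = pb[:, neg][:, None, :]
        db = (pb_pos > pb_neg).mean(axis=(1, 2)) + 0.5 * (pb_pos == pb_neg).mean(axis=(1, 2))
        count += int((np.abs(da - db) >= obs - 1e-12).sum())
        done += m
    p = (1 + count) / (1 + n_permutations)
    return AUCComparison(compute_auc(a, labels), compute_auc(b, labels), float(p))


def result_to_table_row(
    dataset_name: str, classifier_name: str, random_cv: CVResult, loso: CVResult
) -> str:
    """One TSV row in the exploratory-report layout."""
    return (
        f"{dataset_name}\t{classifier_name}\t"
        f"{random_cv.mean:.3f} ± {random_cv.sd:.3f}\t"
        f"{loso.mean:.3f} ± {loso.sd:.3f}"
    )
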