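"""Orchestration: the exploratory CV grid and the final search-and-test run.

Two experiments are wired end to end:

1. :func:`run_exploratory_grid` — every dataset variant (balanced sites
   only / plus case-only sites / all sites) crossed with every classifier
   family, each scored under random repeated k-fold CV *and* leave-site-out
   CV.  The gap between the two schemes ("inflation") quantifies how much a
   site-blind CV overstates generalization when site composition is
   confounded with diagnosis.

2. :func:`run_final_pipeline` — GA search variants on the full training
   set, importance meta-analysis, threshold selection of a best feature
   subset, then a single nested-tuned ridge model on those features scored
   once on the pooled held-out test sites, with all-feature comparators,
   paired DeLong tests and a top-k sweep as posthoc checks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import classifiers, cv_engine, ga_search, importance as importance_mod
from .data_model import (
    MultiSiteDataset,
    VARIANTS,
    assemble_variant,
    site_composition,
)

logger = logging.getLogger(__name__)


def default_specs(seed: int = 0) -> list[classifiers.ClassifierSpec]:
    return [
        classifiers.ClassifierSpec(family="ridge_logistic", seed=seed),
        classifiers.ClassifierSpec(family="elasticnet_logistic", seed=seed),
        classifiers.ClassifierSpec(family="svm_rbf", seed=seed),
    ]


@dataclass
class ExploratoryReport:
    """One row per (dataset variant, classifier family) with both schemes."""

    table: pd.DataFrame

    def inflation(self, variant: str, family: str) -> float:
        """Random-CV mean minus LOSO mean: the over-optimism of site-blind CV."""
        row = self.table[(self.table["variant"] == variant) & (self.table["family"] == family)]
        if row.empty:
            raise KeyError((variant, family))
        return float(row["random_mean"].iloc[0] - row["loso_mean"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_exploratory_grid(
    train: MultiSiteDataset,
    specs: list[classifiers.ClassifierSpec] | None = None,
    seed: int = 0,
    k: int = 3,
    n_repeats: int = 50,
    min_per_class: int = 5,
    variants: tuple[str, ...] = VARIANTS,
) -> ExploratoryReport:
    """Cross dataset variants with classifier families under both CV schemes."""
    comp = site_composition(train, min_per_class=min_per_class)
    if len(comp.balanced_sites) < 2:
        raise ValueError("exploratory grid needs at least 2 balanced sites")
    specs = specs if specs is not None else default_specs(seed)
    fold_sites = comp.fold_sites
    rows = []
    for vi, variant in enumerate(variants):
        ds_v = assemble_variant(train, comp, variant)
        for ci, spec in enumerate(specs):
            cell_seed = (seed + 1_000 * vi + 97 * ci) % 2**31
            spec_seeded = classifiers.ClassifierSpec.from_dict(
                {**spec.to_dict(), "seed": cell_seed}
            )
            rand = cv_engine.repeated_stratified_kfold_cv(
                ds_v, spec_seeded, k=k, n_repeats=n_repeats, seed=cell_seed
            )
            loso = cv_engine.leave_site_out_cv(ds_v, spec_seeded, fold_sites)
            rows.append(
                {
                    "variant": variant,
                    "family": spec.family,
                    "random_mean": rand.mean,
                    "random_sd": rand.sd,
                    "loso_mean": loso.mean,
                    "loso_sd": loso.sd,
                }
            )
            logger.info(
                "grid %s/%s: random %.3f±%.3f loso %.3f±%.3f",
                variant, spec.family, rand.mean, rand.sd, loso.mean, loso.sd,
            )
    return ExploratoryReport(table=pd.DataFrame(rows))


@dataclass
class FinalReport:
    selected_features: list[str]
    selected_importance: dict[str, float]
    test_auc: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    posthoc_aucs: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    sweep: list[tuple[int, float]] = field(default_factory=list)
    importance_table: importance_mod.ImportanceTable | None = None
    threshold: float = 0.8
    fallback_used: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_features": self.selected_features,
                "selected_importance": self.selected_importance,
                "threshold": self.threshold,
                "fallback_used": self.fallback_used,
                "test_auc": self.test_auc,
                "posthoc_aucs": self.posthoc_aucs,
                "p_values": self.p_values,
                "sweep": [[int(k), float(a)] for k, a in self.sweep],
                "roc": {
                    "fpr": [float(v) for v in self.roc["fpr"]],
                    "tpr": [float(v) for v in self.roc["tpr"]],
                    "threshold": [float(v) for v in self.roc["threshold"]],
                },
            },
            indent=2,
        )


def _names_to_mask(names: list[str], universe: list[str]) -> np.ndarray:
    mask = np.zeros(len(universe), bool)
    pos = {f: i for i, f in enumerate(universe)}
    for f in names:
        mask[pos[f]] = True
    return mask


def _fit_and_score(
    train: MultiSiteDataset,
    test: MultiSiteDataset,
    spec: classifiers.ClassifierSpec,
    mask=None,
) -> tuple[float, np.ndarray]:
    model = classifiers.fit(spec, train.X, train.y, feature_mask=mask)
    scores = classifiers.predict_scores(model, test.X)
    return cv_engine.compute_auc(scores, test.y), scores


def posthoc_threshold_sweep(
    imp: pd.Series,
    train: MultiSiteDataset,
    test: MultiSiteDataset,
    k_range=range(2, 16),
    spec: classifiers.ClassifierSpec | None = None,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Pooled test AUC of the top-k importance features for each k."""
    spec = spec or classifiers.ClassifierSpec(family="ridge_logistic", seed=seed)
    p = train.n_features
    out = []
    for k in k_range:
        if k > p:
            warnings.warn(f"top-{k} exceeds {p} features; truncating sweep", RuntimeWarning)
            break
        names = importance_mod.top_k_features(imp, k)
        auc, _ = _fit_and_score(train, test, spec, _names_to_mask(names, list(imp.index)))
        out.append((k, auc))
    return out


def run_final_pipeline(
    train: MultiSiteDataset,
    test: MultiSiteDataset,
    ga_configs: list[ga_search.GAConfig] | None = None,
    threshold: float = 0.8,
    seed: int = 0,
    min_per_class: int = 5,
    run_posthoc: bool = True,
    sweep_range=range(2, 16),
) -> FinalReport:
    """GA search -> importance -> threshold selection -> held-out-site test."""
    overlap = set(train.sites) & set(test.sites)
    if overlap:
        raise ValueError(f"train/test site overlap: {sorted(overlap)}")
    if len(np.unique(test.y)) < 2:
        raise ValueError("test set must contain both classes")

    comp = site_composition(train, min_per_class=min_per_class)
    if ga_configs is None:
        ga_configs = ga_search.six_variant_preset(seed=seed)
    results = []
    for i, cfg in enumerate(ga_configs):
        results.append(
            ga_search.run_ga_variant(
                train, cfg, fold_sites=comp.fold_sites, variant_id=f"v{i + 1}"
            )
        )
        logger.info(
            "GA variant v%d: %d evaluations, best fitness %.3f",
            i + 1, results[-1].n_evaluations, results[-1].subsets[0].fitness,
        )

    table = importance_mod.ImportanceTable.from_variants(results, threshold=threshold)
    selected = importance_mod.select_by_threshold(table.mean, threshold)
    fallback = False
    if not selected:
        fallback = True
        selected = importance_mod.top_k_features(table.mean, 4)
        warnings.warn(
            f"no feature reached importance {threshold}; falling back to the top 4",
            RuntimeWarning,
        )
        logger.warning("empty selection at threshold %.2f; using top-4 fallback", threshold)

    final_spec = classifiers.ClassifierSpec(family="ridge_logistic", seed=seed)
    universe = list(train.feature_names)
    test_auc, final_scores = _fit_and_score(
        train, test, final_spec, _names_to_mask(selected, universe)
    )
    fpr, tpr, thr = roc_curve(test.y, final_scores)
    report = FinalReport(
        selected_features=selected,
        selected_importance={f: float(table.mean[f]) for f in selected},
        test_auc=test_auc,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        importance_table=table,
        threshold=threshold,
        fallback_used=fallback,
    )

    if run_posthoc:
        svm_spec = classifiers.ClassifierSpec(family="svm_rbf", seed=seed)
        datasets = {
            "full": train,
            "no_extra_controls": assemble_variant(train, comp, "base_plus_cases"),
            "balanced_only": assemble_variant(train, comp, "base"),
        }
        for dname, ds in datasets.items():
            for fname, spec in (("ridge", final_spec), ("svm", svm_spec)):
                auc, scores = _fit_and_score(ds, test, spec)
                report.posthoc_aucs[f"{fname}_all_features_{dname}"] = auc
                if fname == "ridge":
                    cmp = cv_engine.delong_compare(final_scores, scores, test.y)
                    report.p_values[f"final_vs_ridge_all_features_{dname}"] = cmp.p_value
        report.sweep = posthoc_threshold_sweep(
            table.mean, train, test, k_range=sweep_range, spec=final_spec, seed=seed
        )
    return report
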