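"""Weighted feature importance pooled over retained search subsets.

Within one search variant each retained subset ``S`` contributes
``fit(S) / |S|`` to every feature it contains (better subsets weigh more,
bigger subsets dilute their members), and the per-feature totals are
normalized by ``sum_S fit(S)/|S|``.  That is the unique linear normalization
with the natural endpoints: a feature in *every* retained subset scores 1, a
feature in *none* scores 0.  The final importance is the unweighted mean of
the per-variant scores, and the "best" subset is everything at or above a
threshold on that mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ga_search import SearchVariantResult


def variant_importance(result: SearchVariantResult) -> pd.Series:
    """Per-feature importance in [0, 1] for one search variant."""
    if not result.subsets:
        raise ValueError("search variant retained no subsets")
    p = result.subsets[0].mask.size
    raw = np.zeros(p)
    denom = 0.0
    for s in result.subsets:
        if s.fitness is None or s.fitness <= 0:
            raise ValueError("importance requires every retained subset to have fitness > 0")
        w = s.fitness / s.size
        raw[s.mask] += w
        denom += w
    names = result.feature_names or [f"feature_{j:03d}" for j in range(p)]
    return pd.Series(raw / denom, index=names, name=result.variant_id)


def aggregate_importance(tables: list[pd.Series]) -> pd.Series:
    """Unweighted mean of per-variant importances over a shared feature set."""
    if not tables:
        raise ValueError("no importance tables supplied")
    universe = list(tables[0].index)
    for t in tables[1:]:
        if list(t.index) != universe:
            raise ValueError("importance tables cover different feature universes")
    return pd.concat(tables, axis=1).mean(axis=1).rename("mean_importance")


@dataclass
class ImportanceTable:
    """Per-variant and averaged importances plus the selection threshold."""

    per_variant: pd.DataFrame  # features x variants
    mean: pd.Series
    threshold: float = 0.8

    @classmethod
    def from_variants(
        cls, results: list[SearchVariantResult], threshold: float = 0.8
    ) -> "ImportanceTable":
        tables = [variant_importance(r) for r in results]
        return cls(
            per_variant=pd.concat(tables, axis=1),
            mean=aggregate_importance(tables),
            threshold=threshold,
        )

    @property
    def n_variants(self) -> int:
        return self.per_variant.shape[1]

    def to_tsv(self, path, feature_kind: list[str] | None = None) -> None:
        out = self.per_variant.copy()
        if feature_kind is not None:
            out.insert(0, "kind", feature_kind)
        out["mean_importance"] = self.mean
        out.to_csv(path, sep="\t", index_label="feature")


def select_by_threshold(
    mean_importance: pd.Series, threshold: float = 0.8
) -> list[str]:
    """Features with mean importance >= threshold, best first.

    Ties are broken by canonical feature order (the order of the index).
    May be empty; the caller decides how to proceed.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = {f: i for i, f in enumerate(mean_importance.index)}
    picked = [f for f in mean_importance.index if mean_importance[f] >= threshold]
    return sorted(picked, key=lambda f: (-mean_importance[f], order[f]))


def top_k_features(mean_importance: pd.Series, k: int) -> list[str]:
    """The k highest-importance features (canonical order breaks ties)."""
    order = {f: i for i, f in enumerate(mean_importance.index)}
    ranked = sorted(mean_importance.index, key=lambda f: (-mean_importance[f], order[f]))
    return ranked[:k]
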