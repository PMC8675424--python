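"""Typed container and CSV I/O for multi-site case-control feature tables.

The central object is :class:`MultiSiteDataset`: a subjects x features matrix
of structural brain measures (cortical thickness, cortical surface area,
subcortical volume) together with a binary diagnosis and a site identifier
per subject.  Sites are bookkept by :class:`SiteComposition`, which classifies
each site as balanced, case-only, control-only, or mixed-small, and dataset
variants (balanced sites only / plus case-only sites / all sites) are
assembled with :func:`assemble_variant`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANTS = ("base", "base_plus_cases", "full")

CATEGORY_BALANCED = "balanced"
CATEGORY_CASE_ONLY = "case_only"
CATEGORY_CONTROL_ONLY = "control_only"
CATEGORY_MIXED_SMALL = "mixed_small"


class SchemaError(ValueError):
    """A mandatory column is absent or the schema is otherwise unusable."""


class EmptyDatasetError(ValueError):
    """No subjects remain after filtering."""


@dataclass(frozen=True)
class ColumnSchema:
    """Names of the mandatory columns in the CSV dialect.

    ``feature_columns=None`` means every column that is not subject id, site
    or diagnosis is a feature; the column order of the file defines the
    canonical feature order used by every downstream feature mask.
    """

    subject_id: str = "subject_id"
    site: str = "site_id"
    diagnosis: str = "dx"
    case_label: object = 1
    control_label: object = 0
    feature_columns: tuple[str, ...] | None = None


def infer_feature_kind(name: str) -> str:
    """Map a FreeSurfer/ENIGMA-style column name to its measurement kind."""
    if name.endswith("_thickavg"):
        return "thickness"
    if name.endswith("_surfarea"):
        return "area"
    if name.endswith("_vol"):
        return "volume"
    return "other"


@dataclass
class MultiSiteDataset:
    """Subjects x features table with per-subject diagnosis and site.

    Attributes
    ----------
    subject_id : array of str, one per row.
    X : float matrix, n_subjects x n_features; no missing values.
    y : int array in {0, 1}; 1 = case, 0 = control.
    site : array of str site identifiers, one per row.
    feature_names : canonical ordered feature names (columns of ``X``).
    feature_kind : per-feature tag (thickness / area / volume / other).
    n_excluded : rows dropped at load time for missing feature values.
    """

    subject_id: np.ndarray
    X: np.ndarray
    y: np.ndarray
    site: np.ndarray
    feature_names: list[str]
    feature_kind: list[str] = field(default_factory=list)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.site = np.asarray(self.site, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if not (len(self.subject_id) == len(self.y) == len(self.site) == n):
            raise ValueError("subject_id, y and site must have one entry per row of X")
        if len(self.feature_names) != p:
            raise ValueError("feature_names must match the number of columns of X")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; filter rows at load time")
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise ValueError(f"diagnosis values outside {{0,1}}: {sorted(bad)}")
        if not self.feature_kind:
            self.feature_kind = [infer_feature_kind(f) for f in self.feature_names]
        elif len(self.feature_kind) != p:
            raise ValueError("feature_kind must match the number of features")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def sites(self) -> list[str]:
        """Unique site ids in order of first appearance."""
        seen: dict = {}
        for s in self.site:
            seen.setdefault(s, None)
        return list(seen)

    def subset_rows(self, mask: np.ndarray) -> "MultiSiteDataset":
        mask = np.asarray(mask)
        return replace(
            self,
            subject_id=self.subject_id[mask],
            X=self.X[mask],
            y=self.y[mask],
            site=self.site[mask],
            n_excluded=0,
        )

    def fingerprint(self) -> str:
        """Stable content hash of (X, y, site); keys fitness memoization."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(np.ascontiguousarray(self.y).tobytes())
        h.update("\x00".join(str(s) for s in self.site).encode())
        return h.hexdigest()[:16]

    def to_frame(self, schema: ColumnSchema | None = None) -> pd.DataFrame:
        schema = schema or ColumnSchema()
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, schema.diagnosis, self.y)
        df.insert(0, schema.site, self.site)
        df.insert(0, schema.subject_id, self.subject_id)
        return df


@dataclass
class SiteComposition:
    """Per-site case/control counts and the derived site category.

    ``min_per_class`` is the minimum number of subjects of *each* class a
    site needs to count as balanced (and hence serve as a leave-site-out
    evaluation fold).  Sites with some of each class but fewer than that are
    flagged ``mixed_small``: they stay in the training pool but are not used
    as evaluation folds.
    """

    table: pd.DataFrame  # index: site; columns: n_cases, n_controls, category
    min_per_class: int

    def _sites_of(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    @property
    def balanced_sites(self) -> list[str]:
        return self._sites_of(CATEGORY_BALANCED)

    @property
    def case_only_sites(self) -> list[str]:
        return self._sites_of(CATEGORY_CASE_ONLY)

    @property
    def control_only_sites(self) -> list[str]:
        return self._sites_of(CATEGORY_CONTROL_ONLY)

    @property
    def mixed_small_sites(self) -> list[str]:
        return self._sites_of(CATEGORY_MIXED_SMALL)

    @property
    def fold_sites(self) -> list[str]:
        """Sites eligible as leave-site-out folds (balanced only)."""
        return self.balanced_sites

    def category(self, site: str) -> str:
        return str(self.table.loc[site, "category"])


def load_dataset(path, schema: ColumnSchema | None = None) -> MultiSiteDataset:
    """Read a subjects x features CSV, dropping rows with missing features.

    Rows missing any feature value are excluded (the count is logged and
    recorded on ``n_excluded``); values are never imputed.  Column order in
    the file defines the canonical feature order.
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (schema.subject_id, schema.site, schema.diagnosis):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    if schema.feature_columns is not None:
        missing = [c for c in schema.feature_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"feature columns missing from {path}: {missing}")
        feature_names = list(schema.feature_columns)
    else:
        reserved = {schema.subject_id, schema.site, schema.diagnosis}
        feature_names = [c for c in df.columns if c not in reserved]
    if not feature_names:
        raise SchemaError("no feature columns found")

    dx = df[schema.diagnosis]
    label_map = {schema.case_label: 1, schema.control_label: 0}
    bad = set(dx.unique()) - set(label_map)
    if bad:
        raise ValueError(
            f"diagnosis column contains values outside the configured labels: {sorted(map(str, bad))}"
        )
    y = dx.map(label_map).to_numpy()

    feats = df[feature_names].apply(pd.to_numeric, errors="coerce")
    keep = ~feats.isna().any(axis=1)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d subject(s) with missing feature values", n_excluded)
    if not keep.any():
        raise EmptyDatasetError("no subjects remain after removing rows with missing features")

    return MultiSiteDataset(
        subject_id=df.loc[keep, schema.subject_id].astype(str).to_numpy(dtype=object),
        X=feats.loc[keep].to_numpy(dtype=float),
        y=y[keep.to_numpy()],
        site=df.loc[keep, schema.site].astype(str).to_numpy(dtype=object),
        feature_names=feature_names,
        n_excluded=n_excluded,
    )


def write_dataset(ds: MultiSiteDataset, path, schema: ColumnSchema | None = None) -> None:
    """Write the CSV dialect read by :func:`load_dataset` (exact round-trip)."""
    # repr-faithful decimals so float64 values survive the round trip bit-exactly
    ds.to_frame(schema).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def site_composition(ds: MultiSiteDataset, min_per_class: int = 5) -> SiteComposition:
    """Count cases/controls per site and categorize every site."""
    if ds.n_subjects == 0:
        raise EmptyDatasetError("cannot compute site composition of an empty dataset")
    rows = []
    for s in ds.sites:
        at = ds.site == s
        n_cases = int(ds.y[at].sum())
        n_controls = int((~ds.y[at].astype(bool)).sum())
        if n_controls == 0 and n_cases > 0:
            cat = CATEGORY_CASE_ONLY
        elif n_cases == 0 and n_controls > 0:
            cat = CATEGORY_CONTROL_ONLY
        elif min(n_cases, n_controls) >= min_per_class:
            cat = CATEGORY_BALANCED
        else:
            cat = CATEGORY_MIXED_SMALL
        rows.append((s, n_cases, n_controls, cat))
    table = pd.DataFrame(
        rows, columns=["site", "n_cases", "n_controls", "category"]
    ).set_index("site")
    return SiteComposition(table=table, min_per_class=min_per_class)


def assemble_variant(
    ds: MultiSiteDataset, comp: SiteComposition, variant: str
) -> MultiSiteDataset:
    """Restrict the dataset to the site categories of a named variant.

    ``base`` keeps balanced (and mixed-small) sites, ``base_plus_cases``
    additionally keeps case-only sites, ``full`` keeps everything.  Subject
    order is preserved.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if not comp.balanced_sites:
        raise ValueError("variant assembly requires at least one balanced site")
    included = set(comp.balanced_sites) | set(comp.mixed_small_sites)
    if variant in ("base_plus_cases", "full"):
        included |= set(comp.case_only_sites)
    if variant == "full":
        included |= set(comp.control_only_sites)
    mask = np.array([s in included for s in ds.site])
    return ds.subset_rows(mask)
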