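"""Seeded generator of multi-site feature tables with planted signal and site effects.

The generative model for subject ``i`` at site ``s`` and feature ``j`` is

    x_ij = a_sj + c_s * (delta_j * y_i * [j in J] + eps_ij + (L u_i)_j)

with per-site additive offsets ``a_sj ~ N(0, site_offset_sd^2)`` (scanner and
sample shifts, the confound every downstream stage is about), a per-site
multiplicative gain ``log c_s ~ N(0, site_scale_sd^2)``, subject noise
``eps_ij ~ N(0, noise_sd^2)``, an optional rank-``r`` latent factor inducing
feature correlation, and a planted diagnosis effect ``delta_j`` (in
within-class SD units) on the signal feature set ``J``.  Labels are assigned
by construction from the site plan, so class-by-site confounding is under
direct experimental control.

Randomness is keyed per site from one integer seed, so adding or removing a
site never changes another site's draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .data_model import MultiSiteDataset

# 34 bilateral Desikan cortical parcels (thickness and surface area each)
# plus 7 bilateral subcortical structures: 68 + 68 + 14 = 150 columns.
DESIKAN_ROIS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)
SUBCORTICAL_ROIS = (
    "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens",
)


def desikan_feature_schema() -> tuple[list[str], list[str]]:
    """Canonical 150-column feature schema (names, kinds)."""
    names: list[str] = []
    kinds: list[str] = []
    for suffix, kind in (("thickavg", "thickness"), ("surfarea", "area")):
        for hemi in ("lh", "rh"):
            for roi in DESIKAN_ROIS:
                names.append(f"{hemi}_{roi}_{suffix}")
                kinds.append(kind)
    for side in ("Left", "Right"):
        for roi in SUBCORTICAL_ROIS:
            names.append(f"{side}-{roi}_vol")
            kinds.append("volume")
    return names, kinds


@dataclass(frozen=True)
class SitePlanEntry:
    site_id: str
    n_cases: int
    n_controls: int
    split: str = "train"  # train | test


@dataclass
class GeneratorConfig:
    """Everything needed to draw one reproducible multi-site dataset."""

    site_plan: tuple[SitePlanEntry, ...]
    n_features: int = 150
    feature_names: tuple[str, ...] | None = None
    signal_features: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    site_offset_sd: float = 1.0
    site_scale_sd: float = 0.1
    noise_sd: float = 1.0
    latent_rank: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_names is not None and len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length must equal n_features")
        if len(self.signal_features) != len(self.effect_sizes):
            raise ValueError("signal_features and effect_sizes must align")
        if any(j < 0 or j >= self.n_features for j in self.signal_features):
            raise ValueError("signal feature index out of range")
        if not all(np.isfinite(self.effect_sizes)):
            raise ValueError("effect sizes must be finite")
        for sd in (self.site_offset_sd, self.site_scale_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        if any(e.n_cases < 0 or e.n_controls < 0 for e in self.site_plan):
            raise ValueError("site plan counts must be nonnegative")

    def ground_truth(self) -> dict:
        """JSON-ready record of the planted signal (for recovery checks)."""
        names, _ = self._schema()
        return {
            "signal_features": [int(j) for j in self.signal_features],
            "signal_feature_names": [names[j] for j in self.signal_features],
            "effect_sizes": [float(d) for d in self.effect_sizes],
            "site_offset_sd": self.site_offset_sd,
            "site_scale_sd": self.site_scale_sd,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    def _schema(self) -> tuple[list[str], list[str]]:
        if self.feature_names is not None:
            names = list(self.feature_names)
            from .data_model import infer_feature_kind

            return names, [infer_feature_kind(n) for n in names]
        if self.n_features == 150:
            return desikan_feature_schema()
        return [f"feature_{j:03d}" for j in range(self.n_features)], ["other"] * self.n_features


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    # crc32 keys the substream by site id: independent of plan order.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(site_id.encode())])
    )


def generate(config: GeneratorConfig) -> tuple[MultiSiteDataset, MultiSiteDataset]:
    """Draw (train, test) datasets for a site plan; bit-reproducible per seed."""
    if not config.site_plan:
        raise ValueError("site plan is empty")
    names, kinds = config._schema()
    p = config.n_features
    r = config.latent_rank

    delta = np.zeros(p)
    for j, d in zip(config.signal_features, config.effect_sizes):
        delta[j] = d

    # Loadings are a global property of the feature set, not of any site.
    if r > 0:
        loading_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 0x10AD])
        )
        L = loading_rng.normal(size=(p, r)) / np.sqrt(r)
    else:
        L = None

    parts: dict[str, list] = {"train": [], "test": []}
    for entry in config.site_plan:
        if entry.split not in parts:
            raise ValueError(f"unknown split {entry.split!r} for site {entry.site_id}")
        n = entry.n_cases + entry.n_controls
        rng = _site_rng(config.seed, entry.site_id)
        a = rng.normal(0.0, config.site_offset_sd, size=p)
        c = float(np.exp(rng.normal(0.0, config.site_scale_sd))) if config.site_scale_sd > 0 else 1.0
        if n == 0:
            continue
        y = np.concatenate([np.ones(entry.n_cases, int), np.zeros(entry.n_controls, int)])
        eps = rng.normal(0.0, config.noise_sd, size=(n, p))
        within = eps + y[:, None] * delta[None, :]
        if L is not None:
            u = rng.normal(size=(n, r))
            within = within + u @ L.T
        X = a[None, :] + c * within
        ids = np.array([f"{entry.site_id}_{i:04d}" for i in range(n)], dtype=object)
        parts[entry.split].append(
            (ids, X, y, np.full(n, entry.site_id, dtype=object))
        )

    out = []
    for split in ("train", "test"):
        blocks = parts[split]
        if blocks:
            ds = MultiSiteDataset(
                subject_id=np.concatenate([b[0] for b in blocks]),
                X=np.vstack([b[1] for b in blocks]),
                y=np.concatenate([b[2] for b in blocks]),
                site=np.concatenate([b[3] for b in blocks]),
                feature_names=names,
                feature_kind=kinds,
            )
        else:
            ds = MultiSiteDataset(
                subject_id=np.empty(0, object),
                X=np.empty((0, p)),
                y=np.empty(0, int),
                site=np.empty(0, object),
                feature_names=names,
                feature_kind=kinds,
            )
        out.append(ds)
    return out[0], out[1]


# Default apportionment of the consortium-style margins across sites.
# Train: 5 balanced + 3 case-only + 16 control-only sites with 692 cases and
# 960 controls (1,652 subjects); test: 3 balanced sites with 146 cases and
# 236 controls (382 subjects).  Per-site sizes are a documented convention
# (balanced sites 60-260 subjects, control-only sites 14-120), chosen to
# resemble a large multi-site consortium; only the margins are calibrated.
TRAIN_BALANCED = (("S01", 120, 140), ("S02", 90, 80), ("S03", 70, 60),
                  ("S04", 50, 40), ("S05", 30, 30))
TRAIN_CASE_ONLY = (("S06", 150, 0), ("S07", 100, 0), ("S08", 82, 0))
TRAIN_CONTROL_ONLY = tuple(
    (f"S{i + 9:02d}", 0, n)
    for i, n in enumerate((120, 90, 60, 40, 36, 34, 32, 30, 28, 26, 24, 22, 20, 18, 16, 14))
)
TEST_SITES = (("T01", 60, 100), ("T02", 50, 80), ("T03", 36, 56))


def _scaled(count: int, scale: float) -> int:
    if count == 0:
        return 0
    return max(2, round(count * scale))


def enigma_like_config(scale: float = 1.0, seed: int = 0, **overrides) -> GeneratorConfig:
    """Config whose site plan mirrors a large addiction-consortium layout.

    At ``scale=1`` the margins are 24 training sites (5 balanced, 3
    case-only, 16 control-only; 692 cases / 960 controls) plus 3 balanced
    test sites (146 cases / 236 controls).  At ``scale<1`` every nonzero
    cell shrinks proportionally but keeps at least 2 subjects, so no site
    changes category.  Keyword overrides are forwarded to
    :class:`GeneratorConfig` (e.g. ``signal_features=...``).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    plan = []
    for site, nca, nco in TRAIN_BALANCED + TRAIN_CASE_ONLY + TRAIN_CONTROL_ONLY:
        plan.append(SitePlanEntry(site, _scaled(nca, scale), _scaled(nco, scale), "train"))
    for site, nca, nco in TEST_SITES:
        plan.append(SitePlanEntry(site, _scaled(nca, scale), _scaled(nco, scale), "test"))
    return GeneratorConfig(site_plan=tuple(plan), seed=seed, **overrides)


def plant_signal(
    config: GeneratorConfig, n_signal: int = 4, delta: float = 1.0, seed: int | None = None
) -> GeneratorConfig:
    """Return a copy of ``config`` with ``n_signal`` random diagnosis-signal
    features of effect size ``delta`` (within-class SD units)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 0x516])
    )
    idx = tuple(int(j) for j in sorted(rng.choice(config.n_features, n_signal, replace=False)))
    return replace(config, signal_features=idx, effect_sizes=(float(delta),) * n_signal)


def write_ground_truth(config: GeneratorConfig, path) -> None:
    """JSON sidecar recording the planted signal set and effect sizes."""
    with open(path, "w") as fh:
        json.dump(config.ground_truth(), fh, indent=2)
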