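import numpy as np
import pytest

import sitefold as sf


def build_dataset(blocks, n_features=4, seed=0, signal_feature=None):
    """Assemble a MultiSiteDataset from (site, n_cases, n_controls) blocks.

    If ``signal_feature`` is given, that column equals the diagnosis label
    exactly (a perfectly separating feature).
    """
    rng = np.random.default_rng(seed)
    ids, Xs, ys, sites = [], [], [], []
    for site, n_cases, n_controls in blocks:
        n = n_cases + n_controls
        ids.append(np.array([f"{site}_{i}" for i in range(n)], object))
        Xs.append(rng.normal(size=(n, n_features)))
        ys.append(np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)]))
        sites.append(np.full(n, site, object))
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    if signal_feature is not None:
        X[:, signal_feature] = y
    return sf.MultiSiteDataset(
        subject_id=np.concatenate(ids),
        X=X,
        y=y,
        site=np.concatenate(sites),
        feature_names=[f"f{i}" for i in range(n_features)],
    )


@pytest.fixture
def toy_dataset():
    """Four sites spanning every composition category (min_per_class=5):
    A balanced (10/12), B control-only (0/30), C case-only (8/0),
    D mixed-small (2/40)."""
    return build_dataset([("A", 10, 12), ("B", 0, 30), ("C", 8, 0), ("D", 2, 40)])


@pytest.fixture
def two_site_signal_dataset():
    """Two balanced sites with one perfectly separating feature (f0 = y)."""
    return build_dataset(
        [("E", 15, 15), ("F", 12, 18)], n_features=5, seed=1, signal_feature=0
    )


@pytest.fixture
def small_multisite():
    """A richer layout for LOSO/pipeline tests: 3 balanced + 1 case-only +
    2 control-only sites, 10 noise features."""
    return build_dataset(
        [("P", 12, 12), ("Q", 10, 14), ("R", 8, 8), ("CO", 15, 0),
         ("N1", 0, 20), ("N2", 0, 15)],
        n_features=10,
        seed=2,
    )


def small_generator_config(seed=0, n_signal=0, delta=1.0, n_features=20, **kw):
    """Compact generator plan (4 balanced + 2 case-only + 3 control-only
    train sites, 2 balanced test sites) used by pipeline-level tests."""
    plan = tuple(
        sf.SitePlanEntry(*args)
        for args in [
            ("B1", 15, 15, "train"), ("B2", 12, 10, "train"),
            ("B3", 10, 12, "train"), ("B4", 8, 8, "train"),
            ("C1", 15, 0, "train"), ("C2", 10, 0, "train"),
            ("K1", 0, 20, "train"), ("K2", 0, 15, "train"), ("K3", 0, 10, "train"),
            ("T1", 12, 14, "test"), ("T2", 10, 12, "test"),
        ]
    )
    cfg = sf.GeneratorConfig(site_plan=plan, n_features=n_features, seed=seed, **kw)
    if n_signal:
        cfg = sf.plant_signal(cfg, n_signal=n_signal, delta=delta)
    return cfg


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney oracle: all (case, control) pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
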