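import numpy as np
import pytest

import sitefold as sf
from sitefold.ga_search import ridge_logistic_newton

from conftest import pair_count_auc, small_generator_config


class TestSitePlanBookkeeping:
    def test_margins_match_plan_exactly(self):
        cfg = small_generator_config(seed=3)
        train, test = sf.generate(cfg)
        for entry in cfg.site_plan:
            ds = train if entry.split == "train" else test
            at = ds.site == entry.site_id
            assert int(ds.y[at].sum()) == entry.n_cases
            assert int(at.sum()) == entry.n_cases + entry.n_controls

    def test_full_scale_consortium_margins(self):
        train, test = sf.generate(sf.enigma_like_config(scale=1.0, seed=0))
        assert (train.n_subjects, int(train.y.sum())) == (1652, 692)
        assert (test.n_subjects, int(test.y.sum())) == (382, 146)
        assert train.n_features == 150
        kinds = np.array(train.feature_kind)
        assert [(kinds == k).sum() for k in ("thickness", "area", "volume")] == [68, 68, 14]
        comp = sf.site_composition(train)
        assert len(comp.balanced_sites) == 5
        assert len(comp.case_only_sites) == 3
        assert len(comp.control_only_sites) == 16

    def test_downscaling_preserves_site_categories(self):
        full = sf.site_composition(sf.generate(sf.enigma_like_config(scale=1.0))[0],
                                   min_per_class=2)
        small = sf.site_composition(sf.generate(sf.enigma_like_config(scale=0.1))[0],
                                    min_per_class=2)
        for site in full.table.index:
            assert small.category(site) == full.category(site)

    def test_same_seed_is_bit_identical(self):
        cfg = small_generator_config(seed=11, n_signal=2)
        a_train, a_test = sf.generate(cfg)
        b_train, b_test = sf.generate(cfg)
        np.testing.assert_array_equal(a_train.X, b_train.X)
        np.testing.assert_array_equal(a_test.X, b_test.X)
        np.testing.assert_array_equal(a_train.y, b_train.y)

    def test_site_substreams_independent_of_other_sites(self):
        # dropping one site leaves every other site's draws untouched
        cfg = small_generator_config(seed=7)
        full_train, _ = sf.generate(cfg)
        reduced = sf.GeneratorConfig(
            site_plan=tuple(e for e in cfg.site_plan if e.site_id != "B1"),
            n_features=cfg.n_features, seed=cfg.seed,
        )
        red_train, _ = sf.generate(reduced)
        keep = full_train.site != "B1"
        np.testing.assert_array_equal(full_train.X[keep], red_train.X)


class TestValidation:
    def test_empty_site_plan_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.generate(sf.GeneratorConfig(site_plan=()))

    def test_signal_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            small_generator_config(signal_features=(25,), effect_sizes=(1.0,))

    def test_scale_bounds(self):
        with pytest.raises(ValueError):
            sf.enigma_like_config(scale=0.0)


class TestStatisticalStructure:
    def test_pure_noise_has_no_class_signal(self):
        cfg = small_generator_config(
            seed=5, site_offset_sd=0.0, site_scale_sd=0.0, n_features=10
        )
        train, test = sf.generate(cfg)
        spec = sf.ClassifierSpec(family="ridge_logistic", fixed_params={"C": 1.0})
        model = sf.fit(spec, train.X, train.y)
        auc = sf.compute_auc(sf.predict_scores(model, test.X), test.y)
        assert 0.35 <= auc <= 0.65

    def test_huge_effect_separates_on_single_feature(self):
        plan = (sf.SitePlanEntry("solo", 100, 100, "train"),)
        cfg = sf.GeneratorConfig(
            site_plan=plan, n_features=5, signal_features=(2,), effect_sizes=(10.0,),
            site_offset_sd=0.0, site_scale_sd=0.0, seed=9,
        )
        train, _ = sf.generate(cfg)
        # the raw column as a score, checked against the pair-count oracle
        auc = pair_count_auc(train.X[:, 2], train.y)
        assert auc > 0.99
        assert auc == pytest.approx(sf.compute_auc(train.X[:, 2], train.y), abs=1e-12)

    def test_site_identity_predictable_iff_offsets_present(self):
        # with site offsets the features fingerprint the scanner; without, they don't
        for offset_sd, lo, hi in ((1.0, 0.9, 1.0), (0.0, 0.25, 0.75)):
            cfg = small_generator_config(
                seed=13, site_offset_sd=offset_sd, site_scale_sd=0.0, n_features=20
            )
            train, _ = sf.generate(cfg)
            is_b1 = (train.site == "B1").astype(int)
            rng = np.random.default_rng(0)
            half = rng.random(train.n_subjects) < 0.5
            Z = (train.X - train.X[half].mean(0)) / (train.X[half].std(0) + 1e-12)
            w, b = ridge_logistic_newton(Z[half], is_b1[half].astype(float), C=1.0)
            auc = sf.compute_auc(Z[~half] @ w + b, is_b1[~half])
            assert lo <= auc <= hi, f"offset_sd={offset_sd}: site AUC {auc}"

    def test_site_offset_moments(self):
        # noise_sd=0 makes each row the site offset vector itself
        plan = tuple(sf.SitePlanEntry(f"m{i}", 0, 1, "train") for i in range(200))
        cfg = sf.GeneratorConfig(
            site_plan=plan, n_features=50, site_offset_sd=1.0,
            site_scale_sd=0.0, noise_sd=0.0, seed=17,
        )
        train, _ = sf.generate(cfg)
        draws = train.X.ravel()  # 10,000 iid offset draws
        assert abs(draws.mean()) < 0.05
        assert abs(draws.std() - 1.0) < 0.05

    def test_latent_rank_induces_feature_correlation(self):
        base = small_generator_config(seed=19, n_features=10, site_offset_sd=0.0,
                                      site_scale_sd=0.0)
        corr_cfg = small_generator_config(seed=19, n_features=10, site_offset_sd=0.0,
                                          site_scale_sd=0.0, latent_rank=1)
        x0 = sf.generate(base)[0].X
        x1 = sf.generate(corr_cfg)[0].X
        off_diag = lambda m: np.abs(m - np.diag(np.diag(m)))[np.triu_indices(10, 1)]
        assert off_diag(np.corrcoef(x1.T)).mean() > off_diag(np.corrcoef(x0.T)).mean()


class TestPlantSignal:
    def test_plant_signal_is_reproducible_and_recorded(self, tmp_path):
        cfg = sf.plant_signal(small_generator_config(seed=23), n_signal=3, delta=0.7)
        cfg2 = sf.plant_signal(small_generator_config(seed=23), n_signal=3, delta=0.7)
        assert cfg.signal_features == cfg2.signal_features
        assert len(cfg.signal_features) == 3
        truth_path = tmp_path / "truth.json"
        sf.synthetic_data.write_ground_truth(cfg, truth_path)
        import json

        truth = json.loads(truth_path.read_text())
        assert truth["effect_sizes"] == [0.7, 0.7, 0.7]
        assert truth["signal_features"] == list(cfg.signal_features)
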