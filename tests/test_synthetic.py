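"""Generator contracts: determinism, marginal laws, calibration bands."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from igdscreen import (GeneratorConfig, generate_criteria, generate_dataset,
                       generate_item_responses, generate_latent)
from igdscreen.reference import FACTOR_MAP


def small_config(**kw):
    defaults = dict(n_persons=200, seed=11)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestLatent:
    def test_same_seed_is_bitwise_identical(self):
        cfg = small_config()
        a = generate_latent(cfg)
        b = generate_latent(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_high_gamma_factors_track_general_factor(self):
        gamma = {f: 0.99 for f in FACTOR_MAP}
        cfg = small_config(n_persons=20_000, second_order=gamma)
        fac = generate_latent(cfg)
        for f in FACTOR_MAP:
            assert np.corrcoef(fac[f], fac["G"])[0, 1] >= 0.97

    def test_vanishing_gamma_decouples_factors(self):
        gamma = {f: 1e-4 for f in FACTOR_MAP}
        cfg = small_config(n_persons=20_000, second_order=gamma)
        fac = generate_latent(cfg)
        for f in FACTOR_MAP:
            assert abs(np.corrcoef(fac[f], fac["G"])[0, 1]) < 0.03

    def test_factors_marginally_standard_normal(self):
        cfg = small_config(n_persons=50_000)
        fac = generate_latent(cfg)
        for col in fac.columns:
            assert abs(fac[col].mean()) < 0.02
            assert abs(fac[col].std() - 1.0) < 0.02

    @pytest.mark.parametrize("bad", [0, -5])
    def test_nonpositive_n_rejected(self, bad):
        with pytest.raises(ValueError, match="n_persons"):
            GeneratorConfig(n_persons=bad)

    def test_gamma_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="second-order"):
            small_config(second_order={**dict.fromkeys(FACTOR_MAP, 0.8),
                                       "F3": 1.2})


class TestItemResponses:
    def test_category_proportions_match_normal_cdf(self):
        cfg = small_config(
            n_persons=50_000,
            thresholds={i: (0.0, 0.8416) for f in FACTOR_MAP.values() for i in f})
        responses = generate_item_responses(generate_latent(cfg), cfg)
        expected = np.array([0.50, 0.30, 0.20])
        for item in responses.items:
            freq = np.bincount(responses.data[item], minlength=3) / cfg.n_persons
            assert np.allclose(freq, expected, atol=0.01)

    def test_marginal_law_within_sampling_error(self):
        cfg = small_config(n_persons=4000)
        responses = generate_item_responses(generate_latent(cfg), cfg)
        for item in responses.items:
            t1, t2 = cfg.thresholds[item]
            probs = np.diff([0.0, norm.cdf(t1), norm.cdf(t2), 1.0])
            freq = np.bincount(responses.data[item], minlength=3) / cfg.n_persons
            tol = 4.0 * np.sqrt(probs * (1 - probs) / cfg.n_persons)
            assert np.all(np.abs(freq - probs) <= tol), item

    def test_near_unit_loadings_give_near_unit_polychoric(self):
        from igdscreen.polychoric import polychoric_matrix
        lam = dict.fromkeys([i for f in FACTOR_MAP.values() for i in f], 0.7)
        lam["F3_1"] = lam["F3_2"] = 0.99
        cfg = small_config(n_persons=20_000, loadings=lam)
        responses = generate_item_responses(generate_latent(cfg), cfg)
        pm = polychoric_matrix(responses.data[["F3_1", "F3_2"]])
        assert pm.matrix.loc["F3_1", "F3_2"] >= 0.95

    def test_degenerate_thresholds_give_middle_category(self):
        cfg = small_config(
            thresholds={i: (-10.0, 10.0) for f in FACTOR_MAP.values() for i in f})
        responses = generate_item_responses(generate_latent(cfg), cfg)
        assert (responses.data.to_numpy() == 1).all()

    def test_item_without_mapped_factor_rejected(self):
        cfg = small_config()
        fac = generate_latent(cfg).drop(columns=["F4"])
        with pytest.raises(ValueError, match="F4"):
            generate_item_responses(fac, cfg)


class TestCriteria:
    def test_infinite_dsm_threshold_gives_zero_prevalence(self):
        cfg = small_config(dsm_threshold=(100.0,) * 9)
        crit = generate_criteria(generate_latent(cfg), cfg)
        assert crit["dsm_items"].to_numpy().sum() == 0

    def test_zero_target_decouples_depression(self):
        cfg = small_config(n_persons=20_000,
                           criterion_targets={"ia": 0.45, "frequency": 0.40,
                                              "depression": 0.0})
        fac = generate_latent(cfg)
        crit = generate_criteria(fac, cfg)
        from igdscreen import select_top_items, sum_score, MeasurementModel
        model = MeasurementModel(factor_map=cfg.factor_map,
                                 loadings=cfg.loadings,
                                 second_order=cfg.second_order)
        score = sum_score(generate_item_responses(fac, cfg),
                          select_top_items(model))
        r = np.corrcoef(score, crit["depression_score"])[0, 1]
        assert abs(r) < 0.04

    def test_default_prevalence_in_calibration_band(self):
        cfg = GeneratorConfig(n_persons=5000, seed=7)
        crit = generate_criteria(generate_latent(cfg), cfg)
        prev = (crit["dsm_items"].sum(axis=1) >= 5).mean()
        assert 0.109 <= prev <= 0.149

    def test_criterion_correlations_near_targets(self, large_dataset):
        from igdscreen import select_top_items, sum_score, MeasurementModel
        cfg = large_dataset.truth
        model = MeasurementModel(factor_map=cfg.factor_map,
                                 loadings=cfg.loadings,
                                 second_order=cfg.second_order)
        score = sum_score(large_dataset.responses, select_top_items(model))
        for target, series in [
                (cfg.criterion_targets["ia"], large_dataset.ia_score),
                (cfg.criterion_targets["frequency"],
                 large_dataset.gameplay_frequency),
                (cfg.criterion_targets["depression"],
                 large_dataset.depression_score)]:
            r = np.corrcoef(score, series)[0, 1]
            assert abs(r - target) <= 0.07

    def test_target_outside_open_interval_rejected(self):
        with pytest.raises(ValueError, match="criterion target"):
            small_config(criterion_targets={"ia": 1.0, "frequency": 0.4,
                                            "depression": 0.28})


class TestDataset:
    def test_shapes_and_codes(self, default_dataset):
        ds = default_dataset
        assert ds.responses.n_persons == 464
        assert len(ds.responses.items) == 34
        assert ds.dsm_items.shape == (464, 9)
        assert set(np.unique(ds.responses.data)) <= {0, 1, 2}
        assert set(np.unique(ds.dsm_items)) <= {0, 1}

    def test_different_seeds_differ(self):
        a = generate_dataset(small_config(seed=1))
        b = generate_dataset(small_config(seed=2))
        assert not a.responses.data.equals(b.responses.data)

    def test_reduced_sum_within_scale_bounds(self, default_dataset):
        from igdscreen import select_top_items, sum_score, MeasurementModel
        cfg = default_dataset.truth
        model = MeasurementModel(factor_map=cfg.factor_map,
                                 loadings=cfg.loadings,
                                 second_order=cfg.second_order)
        score = sum_score(default_dataset.responses, select_top_items(model))
        assert score.between(0, 54).all()

    def test_csv_round_trip(self, tmp_path, default_dataset):
        from igdscreen import read_responses
        path = tmp_path / "data.csv"
        default_dataset.write_csv(path)
        responses, criteria = read_responses(path)
        pd.testing.assert_frame_equal(
            responses.data, default_dataset.responses.data.astype(np.int8))
        assert list(criteria.columns[1:]) == [f"dsm_{k}" for k in range(1, 10)] \
            + ["ia", "dep", "freq", "spend", "device"]

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = GeneratorConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
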