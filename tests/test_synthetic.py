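"""Generator calibration: marginals, dependence, determinism, learnability."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from aquametal.specs import (
    FEATURES,
    METALS,
    POSITIVE_PAIRS,
    ResponseSpec,
    default_specs,
)
from aquametal.synthetic import (
    default_config,
    generate_targets,
    load_dataset,
    make_dataset,
    sample_features,
    save_dataset,
)


class TestDefaultSpecs:
    def test_dry_surface_ph_limits(self):
        spec = {s.name: s for s in default_specs("dry", "surface")}["ph"]
        assert (spec.vmin, spec.vmax, spec.mean) == (2.9, 9.4, 6.28)

    def test_wet_ground_lead(self):
        spec = {s.name: s for s in default_specs("wet", "ground")}["pb"]
        assert (spec.vmin, spec.vmax, spec.mean) == (0.05496, 0.12178, 0.11831)

    def test_twelve_variables_per_campaign(self):
        for season in ("dry", "wet"):
            for water in ("surface", "ground"):
                specs = default_specs(season, water)
                assert len(specs) == 12
                assert [s.name for s in specs[:4]] == list(FEATURES)
                assert all(s.vmin < s.mean < s.vmax for s in specs)

    def test_unknown_campaign_rejected(self):
        with pytest.raises(ValueError, match="unknown campaign"):
            default_specs("dry", "lake")


class TestSampleFeatures:
    def test_empty_draw_keeps_columns(self):
        f = sample_features(default_config("dry", "surface"), 0)
        assert f.shape == (0, 4)
        assert list(f.columns) == list(FEATURES)

    def test_bounds_respected(self):
        cfg = default_config("wet", "surface", seed=11)
        f = sample_features(cfg, 500)
        for s in cfg.feature_specs:
            assert f[s.name].between(s.vmin, s.vmax).all()

    def test_deterministic_under_seed(self):
        cfg = default_config("dry", "ground", seed=5)
        pd.testing.assert_frame_equal(
            sample_features(cfg, 50), sample_features(cfg, 50)
        )

    def test_marginal_mean_within_two_standard_errors(self):
        cfg = default_config("dry", "surface", seed=7)
        f = sample_features(cfg, 20000)
        for s in cfg.feature_specs:
            se = f[s.name].std() / np.sqrt(len(f))
            assert abs(f[s.name].mean() - s.mean) < 2 * se, s.name


class TestGenerateTargets:
    def test_noise_free_map_is_deterministic(self):
        cfg = default_config("dry", "surface", noise_rel_sd=0.0, seed=2)
        f = sample_features(cfg, 60)
        pd.testing.assert_frame_equal(
            generate_targets(f, cfg), generate_targets(f, cfg)
        )

    def test_targets_within_spec_ranges(self):
        cfg = default_config("wet", "ground", seed=9)
        f = sample_features(cfg, 300)
        t = generate_targets(f, cfg)
        for s in cfg.target_specs:
            assert t[s.name].between(s.vmin, s.vmax).all()

    def test_wrong_feature_count_rejected(self):
        cfg = default_config("dry", "surface")
        f = sample_features(cfg, 10)
        with pytest.raises(ValueError, match="4 feature"):
            generate_targets(f.iloc[:, :3], cfg)

    def test_negative_ph_response_gives_negative_spearman(self):
        cfg = default_config(
            "dry",
            "surface",
            seed=31,
            responses={"cu": ResponseSpec((0.0, -1.0, 0.0, 0.0), (0, 1), 0.0)},
        )
        f = sample_features(cfg, 5000)
        t = generate_targets(f, cfg)
        assert spearmanr(f["ph"], t["cu"]).statistic < -0.9

    @pytest.mark.parametrize("water_type", ["surface", "ground"])
    def test_configured_pairs_positively_associated(self, water_type):
        cfg = default_config("dry", water_type, seed=17)
        f = sample_features(cfg, 5000)
        t = generate_targets(f, cfg)
        both = pd.concat([f, t], axis=1)
        for a, b in POSITIVE_PAIRS[water_type]:
            rho = spearmanr(both[a], both[b]).statistic
            assert rho >= 0.3, f"{a}-{b}: {rho:.3f}"


class TestMakeDataset:
    def test_shape_and_repeatability(self):
        d1 = make_dataset("dry", "surface", 80, 7)
        d2 = make_dataset("dry", "surface", 80, 7)
        assert d1.features.shape == (80, 4)
        assert d1.targets.shape == (80, 8)
        pd.testing.assert_frame_equal(d1.frame(), d2.frame())

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            make_dataset("dry", "surface", 0, 7)

    def test_noise_free_dataset_is_learnable(self):
        """A flexible off-the-shelf regressor reaches validation R > 0.99."""
        from sklearn.neural_network import MLPRegressor

        from aquametal import metrics
        from aquametal.preprocessing import (
            fit_normalizer,
            normalize_frame,
            split_dataset,
        )

        ds = make_dataset("wet", "ground", 80, 7, noise_rel_sd=0.0)
        frame = ds.frame()
        norm = normalize_frame(frame, fit_normalizer(frame))
        split = split_dataset(80, seed=0)
        x = norm[list(FEATURES)].to_numpy()

        def oracle_r(metal):
            oracle = MLPRegressor(
                hidden_layer_sizes=(50, 50),
                activation="tanh",
                solver="lbfgs",
                max_iter=20000,
                random_state=1,
            ).fit(x[split.train], norm[metal].to_numpy()[split.train])
            pred = oracle.predict(x[split.validation])
            return metrics.pearson_r(norm[metal].to_numpy()[split.validation], pred)

        # well-covered metals are fit essentially perfectly; metals whose
        # sample extremes fall outside the training hull stay above 0.9
        assert oracle_r("cu") > 0.99
        assert min(oracle_r(m) for m in ("cr", "cd", "ni", "pb")) > 0.9

    def test_csv_round_trip(self, tmp_path):
        ds = make_dataset("wet", "surface", 25, 3)
        path = tmp_path / "campaign.csv"
        save_dataset(ds, path)
        assert (tmp_path / "campaign.csv.json").exists()
        back = load_dataset(path)
        for col in list(FEATURES) + list(METALS):
            np.testing.assert_allclose(
                back[col].to_numpy(), ds.frame()[col].to_numpy(), rtol=1e-12
            )
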