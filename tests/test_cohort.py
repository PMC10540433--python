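"""Generator contracts: calibration, determinism, marginal rates, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import expit, logit

from truealarms.cohort import (
    CohortValidationError,
    GeneratorConfig,
    calibrate_intercept,
    generate_cohort,
    impute_simple,
    inject_missingness,
    read_cohort,
    write_cohort,
)

from .conftest import toy_cohort


class TestCalibrateIntercept:
    def test_zero_slope_closed_form(self):
        assert calibrate_intercept(0.0, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert calibrate_intercept(0.0, 0.0843) == pytest.approx(
            logit(0.0843), abs=1e-9
        )

    def test_monte_carlo_oracle(self):
        """Marginal prevalence over 10^6 standard-normal draws hits the target."""
        alpha = calibrate_intercept(1.5, 0.0843)
        z = np.random.default_rng(99).standard_normal(1_000_000)
        assert expit(alpha + 1.5 * z).mean() == pytest.approx(0.0843, abs=1e-3)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept(1.0, 1.5)


class TestGenerateCohort:
    def test_same_seed_identical(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=500, seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert_frame_equal(a.data, b.data)
        assert_frame_equal(a.latent, b.latent)

    def test_marginal_prevalences_null_slopes(self):
        cfg = dataclasses.replace(
            GeneratorConfig(),
            n_subjects=50_000,
            beta1=0.0,
            beta2=0.0,
            missing_rate=0.0,
            seed=11,
        )
        c = generate_cohort(cfg)
        p1 = cfg.target_prev_t1
        se1 = np.sqrt(p1 * (1 - p1) / cfg.n_subjects)
        assert abs(c.data["y1"].mean() - p1) < 3 * se1
        eligible = (c.data["y1"] == 0) & (c.data["t2_responded"] == 1)
        prev2 = c.data.loc[eligible, "y2_first"].astype(float).mean()
        se2 = np.sqrt(0.021 * 0.979 / eligible.sum())
        assert abs(prev2 - 0.021) < 3 * se2

    def test_signal_scale_correlation_matches_loading(self):
        cfg = dataclasses.replace(
            GeneratorConfig(),
            n_subjects=50_000,
            n_signal_scales=1,
            n_noise_features=1,
            loadings=(0.8,),
            beta1=3.0,
            missing_rate=0.0,
            seed=13,
        )
        c = generate_cohort(cfg)
        r = np.corrcoef(c.data["scale_1"], c.latent["latent_z1"])[0, 1]
        assert r == pytest.approx(0.8, abs=0.02)

    def test_followup_rate_and_label_logic(self, small_cohort):
        c = small_cohort
        rate = c.data["t2_responded"].mean()
        assert abs(rate - 0.74) < 3 * np.sqrt(0.74 * 0.26 / c.n)
        defined = c.data["y2_first"].notna()
        assert not (defined & (c.data["y1"] == 1)).any()
        assert not (defined & (c.data["t2_responded"] == 0)).any()
        # defined exactly on eligible subjects
        assert (
            defined == ((c.data["y1"] == 0) & (c.data["t2_responded"] == 1))
        ).all()

    def test_null_structure_labels_independent_of_features(self):
        cfg = dataclasses.replace(
            GeneratorConfig(),
            n_subjects=50_000,
            beta1=0.0,
            beta2=0.0,
            missing_rate=0.0,
            seed=17,
        )
        c = generate_cohort(cfg)
        y1 = c.data["y1"].to_numpy(dtype=float)
        bound = 4 / np.sqrt(cfg.n_subjects)  # corr of independent vars is O(1/sqrt n)
        for col in c.feature_names:
            assert abs(np.corrcoef(y1, c.data[col])[0, 1]) < bound
        eligible = c.data["y2_first"].notna()
        y2 = c.data.loc[eligible, "y2_first"].astype(float).to_numpy()
        y1e = y1[eligible.to_numpy()]
        assert abs(np.corrcoef(y2, y1e * 0 + c.latent.loc[eligible.to_numpy(), "latent_z1"])[0, 1]) < bound * 3

    def test_signal_structure_latent_risk_elevated_in_attempters(self, small_cohort):
        c = small_cohort
        eligible = c.data["y2_first"].notna().to_numpy()
        z2 = c.latent["latent_z2"].to_numpy()[eligible]
        y2 = c.data["y2_first"][eligible].astype(float).to_numpy()
        assert z2[y2 == 1].mean() > z2[y2 == 0].mean()

    def test_invalid_config_lists_offending_field(self):
        cfg = dataclasses.replace(GeneratorConfig(), persistence=1.5, missing_rate=1.0)
        with pytest.raises(CohortValidationError, match="persistence"):
            cfg.validate()
        with pytest.raises(CohortValidationError, match="missing_rate"):
            cfg.validate()


class TestMissingness:
    def test_zero_rate_is_identity(self, small_cohort):
        out = inject_missingness(small_cohort, 0.0, seed=1)
        assert_frame_equal(out.data, small_cohort.data)

    def test_masked_fraction_within_binomial_band(self):
        cfg = dataclasses.replace(
            GeneratorConfig(),
            n_subjects=10_000,
            n_signal_scales=6,
            n_noise_features=14,
            missing_rate=0.0,
            seed=3,
        )
        c = inject_missingness(generate_cohort(cfg), 0.0752, seed=4)
        frac = c.mask.to_numpy().mean()
        assert 0.070 <= frac <= 0.081
        assert not c.data[["y1", "t2_responded"]].isna().any().any()

    def test_total_missingness_rejected(self, small_cohort):
        with pytest.raises(CohortValidationError):
            inject_missingness(small_cohort, 1.0, seed=0)


class TestImputeSimple:
    def test_no_missing_is_identity(self, small_cohort):
        assert_frame_equal(impute_simple(small_cohort).data, small_cohort.data)

    def test_mean_fill(self):
        c = toy_cohort(
            y1=[0, 0, 0, 1],
            t2=[1, 1, 1, 1],
            y2=[0, 0, 0, None],
            features={"scale_1": [1.0, 2.0, 3.0, np.nan]},
        )
        out = impute_simple(c)
        assert out.data["scale_1"].iloc[3] == pytest.approx(2.0)

    def test_statistics_come_from_training_split_only(self):
        # train column mean 1.0, pooled mean would be 2.0
        c = toy_cohort(
            y1=[0, 0, 1, 0, 0, 1],
            t2=[1] * 6,
            y2=[0, 0, None, 0, 0, None],
            features={"scale_1": [0.0, 2.0, 1.0, 5.0, np.nan, 4.0]},
        )
        out = impute_simple(c, train_ids=np.array([0, 1, 2]))
        assert out.data["scale_1"].iloc[4] == pytest.approx(1.0)  # train mean, not pooled

    def test_entirely_missing_feature_fails(self):
        c = toy_cohort(
            y1=[0, 0, 1],
            t2=[1, 1, 1],
            y2=[0, 0, None],
            features={"scale_1": [np.nan, np.nan, np.nan]},
        )
        with pytest.raises(CohortValidationError, match="scale_1"):
            impute_simple(c)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=300, seed=21)
        c = generate_cohort(cfg)
        path = write_cohort(c, tmp_path / "cohort.csv")
        back = read_cohort(path)
        assert_frame_equal(back.data, c.data, check_dtype=False)
        assert np.allclose(back.latent, c.latent)
        assert back.feature_names == c.feature_names
        assert back.config == c.config

    def test_invalid_label_logic_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "subject_id": [0, 1],
                "y1": [1, 0],
                "t2_responded": [1, 1],
                "y2_first": [1, 0],  # defined for a wave-1 positive
                "scale_1": [0.1, 0.2],
            }
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="y2_first"):
            read_cohort(path)

    def test_empty_file_fails_informatively(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(CohortValidationError):
            read_cohort(path)
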