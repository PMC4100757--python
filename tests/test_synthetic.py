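import numpy as np
import pandas as pd
import pytest

from paircause.assumptions import hoeffding_independence
from paircause.moments import ols_residual, sample_skew_kurt
from paircause.synthetic import (CohortConfig, LingamPairConfig, PanelDataset,
                                 fleishman_coefficients, generate_cohort,
                                 generate_lingam_pair)


class TestFleishman:
    def test_normal_identity(self):
        assert np.allclose(fleishman_coefficients(0.0, 3.0), (0, 1, 0, 0), atol=1e-8)

    @pytest.mark.parametrize("skew,kurt,tol_s,tol_k", [
        (1.05, 6.01, 0.05, 0.5),
        (2.02, 15.45, 0.08, 1.5),
        (1.26, 5.87, 0.05, 0.5),
    ])
    def test_moment_targets_reached(self, skew, kurt, tol_s, tol_k, rng):
        a, b, c, d = fleishman_coefficients(skew, kurt)
        z = rng.standard_normal(10**6)
        x = a + b * z + c * z**2 + d * z**3
        sk, ku = sample_skew_kurt(x)
        assert sk == pytest.approx(skew, abs=tol_s)
        assert ku == pytest.approx(kurt, abs=tol_k)
        assert abs(x.mean()) < 5e-3 and abs(x.std() - 1) < 5e-3

    def test_infeasible_region_rejected(self):
        with pytest.raises(ValueError):
            fleishman_coefficients(3.0, 5.0)   # kurtosis < skew^2 + 1


class TestLingamPair:
    def test_null_pair_uncorrelated(self):
        cfg = LingamPairConfig(n=2000, b=0.0, seed=3)
        p = generate_lingam_pair(cfg)
        assert p.truth == "independent"
        assert abs(np.corrcoef(p.x, p.y)[0, 1]) < 3 / np.sqrt(2000)

    def test_ols_slope_matches_variance_algebra(self):
        # y = 0.5 x + e with unit-variance x, e: after standardizing y the
        # slope on x is b / sqrt(1 + b^2) = 0.4472
        cfg = LingamPairConfig(n=10**5, b=0.5, standardize_output=True, seed=4)
        p = generate_lingam_pair(cfg)
        slope = (p.x @ p.y) / (p.x @ p.x)
        assert slope == pytest.approx(0.5 / np.sqrt(1.25), abs=0.02)

    def test_full_confounding_no_direct_link(self):
        cfg = LingamPairConfig(n=5000, b=1.0, confound_weight=1.0, seed=5)
        p = generate_lingam_pair(cfg)
        assert p.truth == "confounded"
        # partial correlation given the confounder vanishes
        rx = ols_residual(p.x, p.confounder)
        ry = ols_residual(p.y, p.confounder)
        assert abs(np.corrcoef(rx, ry)[0, 1]) < 3 / np.sqrt(5000)

    def test_gaussian_pair_flagged_unidentifiable(self):
        cfg = LingamPairConfig(n=100, b=1.0, cause_dist="gaussian",
                               noise_dist="gaussian", seed=1)
        with pytest.warns(UserWarning, match="unidentifiable"):
            p = generate_lingam_pair(cfg)
        assert p.unidentifiable

    def test_reproducible(self):
        cfg = LingamPairConfig(n=500, b=0.8, seed=11)
        a, b = generate_lingam_pair(cfg), generate_lingam_pair(cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LingamPairConfig(n=5)
        with pytest.raises(ValueError):
            LingamPairConfig(n=100, confound_weight=1.5)

    def test_residual_independence_at_nominal_rate(self):
        """Under the correctly specified direction the cause is independent
        of the OLS residual: the Hoeffding permutation test should reject
        at about the nominal 5% rate."""
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            p = generate_lingam_pair(LingamPairConfig(n=80, b=1.0, seed=seed))
            resid = ols_residual(p.y, p.x)
            _, pval = hoeffding_independence(p.x, resid, n_perm=99, seed=seed)
            rejections += pval <= 0.05
        rate = rejections / n_rep
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_rep) <= rate <= \
               0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep) + 1e-9


class TestCohort:
    def test_reproducible_bit_identical(self):
        cfg = CohortConfig(n_subjects=300, seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_tv_moments_and_nonnegativity(self):
        ds = generate_cohort(CohortConfig(n_subjects=10**5, seed=2,
                                          missing_rate=(0, 0, 0)))
        tv_h = ds.frame["tv1"].values / 60.0
        assert (tv_h >= 0).all()
        assert tv_h.mean() == pytest.approx(1.9, abs=0.03)
        assert tv_h.std() == pytest.approx(1.2, abs=0.03)
        sk, ku = sample_skew_kurt(tv_h)
        # moments are matched before flooring at 0; flooring the left tail
        # raises skewness/kurtosis somewhat (1.05 -> ~1.2 at these targets)
        assert sk == pytest.approx(1.05, abs=0.25)
        assert ku == pytest.approx(6.01, rel=0.25)
        assert ds.tv_floor_rate < 0.05

    def test_null_effect_gives_null_change_correlation(self):
        cfg = CohortConfig(n_subjects=10**4, seed=3, missing_rate=(0, 0, 0),
                           effect_tv_on_waist_change=0.0,
                           effect_tv_on_bmi_change=0.0)
        f = generate_cohort(cfg).frame
        r = np.corrcoef(f["tv1"], f["waist3"] - f["waist1"])[0, 1]
        assert abs(r) < 0.03

    def test_missingness_binomial(self):
        cfg = CohortConfig(n_subjects=4000, seed=4, missing_rate=(0.0, 0.1, 0.2))
        avail = generate_cohort(cfg).available_n()
        for wave, rate in ((1, 0.0), (2, 0.1), (3, 0.2)):
            for var in ("tv", "waist", "bmi"):
                expected = 4000 * (1 - rate)
                sd = np.sqrt(4000 * rate * (1 - rate))
                assert abs(avail[f"{var}{wave}"] - expected) <= 3 * sd + 1e-9

    def test_csv_roundtrip_with_sidecar(self, tmp_path):
        ds = generate_cohort(CohortConfig(n_subjects=100, seed=6))
        path = tmp_path / "panel.csv"
        ds.to_csv(path)
        assert (tmp_path / "panel.json").exists()
        back = PanelDataset.from_csv(path)
        assert len(back) == 100
        assert set(back.frame.columns) == set(ds.frame.columns)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(waist_moments=(84.0, -1.0, 0.7, 3.6))
        with pytest.raises(ValueError):
            CohortConfig(missing_rate=(0.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            CohortConfig(bmi_moments=(25.0, 4.0, 2.0, 4.0))  # kurt < skew^2+1
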