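import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from paircause.cohort import (TV_GROUPS, assign_tv_group, assign_tv_groups,
                              causality_power_sim, change_table, f_test_power,
                              obesity_risk_ratio, temporality_matrix)
from paircause.synthetic import CohortConfig, generate_cohort


class TestGroupAssignment:
    @pytest.mark.parametrize("tv,expected", [
        ((30, 40, 35), "constantly_low"),
        ((70, 120, 110), "constantly_moderate"),
        ((200, 190, 240), "constantly_high"),
        ((45, 100, 160), "increased"),
        ((170, 100, 40), "decreased"),
        ((50, 100, 90), "unclassified"),   # crosses bands, shift < 1 h
        ((60, 60, 60), "constantly_low"),      # 1 h boundary belongs to low
        ((180, 180, 180), "constantly_high"),  # 3 h boundary belongs to high
        ((np.nan, 100, 100), "unclassified"),
    ])
    def test_examples(self, tv, expected):
        assert assign_tv_group(*tv) == expected

    def test_precedence_flag(self):
        # all-low band but with a >= 1h rise inside it is impossible (band is
        # 60 wide); use a high-band trajectory rising by 60+
        tv = (180, 200, 260)
        assert assign_tv_group(*tv) == "constantly_high"
        assert assign_tv_group(*tv, constant_band_precedence=False) == "increased"

    def test_partition_property(self):
        ds = generate_cohort(CohortConfig(n_subjects=2000, seed=1))
        groups = assign_tv_groups(ds)
        counts = groups.value_counts()
        assert counts.sum() == 2000
        assert set(counts.index) <= set(TV_GROUPS)
        # every named group is populated under the calibrated conditions
        assert (counts[TV_GROUPS[:5]] > 0).all()


class TestChangeTable:
    def toy(self):
        # group A changes +5 everywhere, group B +3: adjusted difference 2.0
        n = 10
        w1 = np.array([80.0, 82, 84, 86, 88, 81, 83, 85, 87, 89])
        change = np.array([5.0] * 5 + [3.0] * 5)
        panel = make_panel(n, waist1=w1, waist2=w1 + change, waist3=w1 + change)
        groups = pd.Series(["A"] * 5 + ["B"] * 5)
        return panel, groups, w1, change

    def test_toy_exact_arithmetic(self):
        panel, groups, w1, change = self.toy()
        tab = change_table(panel, groups, outcome="waist", horizon="10y",
                           covariates=(), include_baseline=False)
        assert tab.means.loc["A", "waist1"] == pytest.approx(w1[:5].mean())
        assert tab.means.loc["A", "change"] == pytest.approx(5.0)
        assert tab.means.loc["B", "change"] == pytest.approx(3.0)
        row = tab.contrasts.iloc[0]
        assert abs(row["difference"]) == pytest.approx(2.0, abs=1e-10)

    def test_exchangeable_labels_not_significant(self):
        ds = generate_cohort(CohortConfig(n_subjects=1000, seed=21,
                                          missing_rate=(0, 0, 0)))
        rng = np.random.default_rng(0)
        fake = pd.Series(rng.choice(["A", "B", "C"], size=1000))
        tab = change_table(ds, fake, outcome="waist", horizon="10y")
        assert not tab.contrasts["significant"].any()

    def test_strong_effect_doubles_high_vs_low(self):
        # effect sized so the 10y waist change in the constantly-high group
        # is about twice the constantly-low group's
        cfg = CohortConfig(n_subjects=6000, seed=22, missing_rate=(0, 0, 0),
                           effect_tv_on_waist_change=1.81,
                           change_sd_waist=(5.0, 7.5))
        ds = generate_cohort(cfg)
        groups = assign_tv_groups(ds)
        tab = change_table(ds, groups, outcome="waist", horizon="10y")
        adj = tab.adjusted["adjusted_change"]
        ratio = adj["constantly_high"] / adj["constantly_low"]
        assert 1.5 < ratio < 2.6
        hl = tab.contrasts.query(
            "group_a == 'constantly_low' and group_b == 'constantly_high'")
        assert bool(hl.iloc[0]["significant"])

    def test_singular_design_reported(self):
        panel, groups, _, _ = self.toy()
        panel.frame["dup"] = panel.frame["age"]
        with pytest.raises(ValueError, match="collinear|singular"):
            change_table(panel, groups, covariates=("age", "dup"),
                         include_baseline=False)


class TestObesityRR:
    def two_by_two(self):
        n = 200
        bmi3 = np.full(n, 25.0)
        bmi3[:20] = 32.0            # group A: 20/100 obese
        bmi3[100:110] = 32.0        # reference: 10/100 obese
        panel = make_panel(n, bmi3=bmi3)
        groups = pd.Series(["constantly_moderate"] * 100 + ["constantly_low"] * 100)
        return panel, groups

    def test_closed_form_two_by_two(self):
        panel, groups = self.two_by_two()
        rr = obesity_risk_ratio(panel, groups, covariates=())
        row = rr[rr.group == "constantly_moderate"].iloc[0]
        assert row["rr"] == pytest.approx(2.0, rel=1e-6)

    def test_identical_groups_rr_one(self):
        rng = np.random.default_rng(7)
        n = 400
        bmi3 = np.where(rng.random(n) < 0.15, 32.0, 25.0)
        panel = make_panel(n, bmi3=bmi3)
        groups = pd.Series(rng.choice(["constantly_low", "constantly_high"], n))
        rr = obesity_risk_ratio(panel, groups, covariates=())
        row = rr[rr.group == "constantly_high"].iloc[0]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_monotone_risk_with_tv_effect(self):
        cfg = CohortConfig(n_subjects=8000, seed=23, missing_rate=(0, 0, 0),
                           effect_tv_on_bmi_change=1.2, change_sd_bmi=(2.5, 3.5))
        ds = generate_cohort(cfg)
        rr = obesity_risk_ratio(ds, assign_tv_groups(ds))
        vals = rr.set_index("group")["rr"]
        assert vals["constantly_low"] <= vals["constantly_moderate"] <= \
            vals["constantly_high"] + 0.1

    def test_zero_reference_cells_error(self):
        panel, groups = self.two_by_two()
        panel.frame.loc[groups.values == "constantly_low", "bmi3"] = 25.0
        with pytest.raises(ValueError, match="reference"):
            obesity_risk_ratio(panel, groups, covariates=())


class TestTemporality:
    def test_null_cohort_mostly_nonsignificant(self):
        cfg = CohortConfig(n_subjects=2000, seed=31, missing_rate=(0, 0, 0),
                           effect_tv_on_waist_change=0.0,
                           effect_tv_on_bmi_change=0.0)
        tm = temporality_matrix(generate_cohort(cfg))
        assert len(tm) == 8
        assert tm["significant"].sum() <= 2  # ~ nominal false-positive rate

    def test_forward_effect_recovered(self):
        tm = temporality_matrix(generate_cohort(
            CohortConfig(n_subjects=4000, seed=32, missing_rate=(0, 0, 0))))
        fwd = tm[tm.direction == "forward"]
        rev = tm[tm.direction == "reverse"]
        assert fwd["significant"].all()
        assert (fwd["r"] > 0).all()
        assert rev["significant"].sum() <= 1

    def test_insufficient_n_error(self):
        ds = generate_cohort(CohortConfig(n_subjects=25, seed=1,
                                          missing_rate=(0, 0, 0)))
        with pytest.raises(ValueError):
            temporality_matrix(ds)


class TestPower:
    def test_null_effect_power_is_alpha(self):
        assert f_test_power(100, 4, 0.0, 0.05) == pytest.approx(0.05)

    def test_small_effect_cohort_power(self):
        assert f_test_power(959, 5, 0.02, 0.05) == pytest.approx(0.956, abs=0.005)

    def test_large_effect_certain(self):
        assert f_test_power(959, 5, 0.35, 0.05) == pytest.approx(1.0, abs=5e-4)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            f_test_power(4, 5, 0.02)

    def test_power_sim_null_and_monotone(self):
        grid = [{"n": n, "b": b, "cause_dist": "exponential",
                 "noise_dist": "exponential"} for n, b in
                [(100, 0.0), (100, 0.5), (400, 0.5), (1600, 0.5)]]
        tab = causality_power_sim(grid, B_replicates=40, seed=0,
                                  statistic="skew", use_bootstrap=False)
        null_power = tab[tab.b == 0.0]["power"].iloc[0]
        assert abs(null_power - 0.5) < 0.25   # sign of a null statistic is a coin flip
        p = tab[tab.b == 0.5].sort_values("n")["power"].values
        assert p[-1] >= p[0] - 0.05           # nondecreasing within MC noise
        assert p[-1] > 0.9
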