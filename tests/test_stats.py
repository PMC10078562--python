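import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from posturo.core import DataError, DegenerateInputError
from posturo.stats import (
    aggregate_trials,
    bonferroni_pairwise,
    change_correlation,
    evans_band,
    greenhouse_geisser_epsilon,
    partial_eta_squared,
    rm_anova_2way,
    rm_anova_cells,
    screen_outliers,
    type_one_error_rates,
)


class TestScreenOutliers:
    def test_single_extreme_subject_removed(self):
        """Nine values of 70 and one of 150: mean 78, sd 25.3, |z| = 2.85."""
        values = {f"s{i}": 70.0 for i in range(9)} | {"s9": 150.0}
        retained, removed = screen_outliers(values, z_cut=2.5)
        assert removed == ["s9"]
        assert len(retained) == 9

    def test_equal_values_remove_nobody(self):
        retained, removed = screen_outliers({f"s{i}": 5.0 for i in range(6)})
        assert removed == [] and len(retained) == 6

    def test_boundary_value_at_exactly_z_cut_retained(self):
        # construct a sample where one value sits exactly at 2.5 sd
        base = np.array([-1.0, 1.0] * 8)
        x = np.concatenate([base - base.mean(), [0.0]])
        sd = np.std(np.append(x[:-1], 0.0), ddof=1)
        vals = dict(enumerate(np.append(x[:-1], 2.5 * sd)))
        sd_full = pd.Series(vals).std(ddof=1)
        z_max = (pd.Series(vals) - pd.Series(vals).mean()).abs().max() / sd_full
        retained, removed = screen_outliers(vals, z_cut=float(z_max))
        assert removed == []  # strict inequality


class TestAggregate:
    def _per_trial(self, values, reps=5):
        rows = []
        for subj in ("S01", "S02", "S03"):
            for rep in range(reps):
                rows.append({"subject": subj, "inhalation_type": "AIR",
                             "inhalation_time": "T5", "rep": rep,
                             "outcome": "total_path", "value": values[rep]})
        return pd.DataFrame(rows)

    def test_cell_mean_of_five_reps(self):
        out = aggregate_trials(self._per_trial([1, 2, 3, 4, 5]))
        assert np.allclose(out["value"], 3.0)
        assert np.all(out["n_reps"] == 5)

    def test_partial_reps_recorded_in_count(self):
        frame = self._per_trial([1, 2, 3, 4, 5])
        frame = frame[~((frame["subject"] == "S01") & (frame["rep"] == 4))]
        out = aggregate_trials(frame)
        s01 = out[out["subject"] == "S01"]
        assert s01["value"].iloc[0] == pytest.approx(2.5)
        assert s01["n_reps"].iloc[0] == 4

    def test_missing_cell_raises_with_cell_named(self):
        frame = self._per_trial([1, 2, 3, 4, 5])
        extra = frame.copy()
        extra["inhalation_time"] = "T10"
        frame = pd.concat([frame, extra[extra["subject"] != "S02"]])
        with pytest.raises(DataError, match="S02"):
            aggregate_trials(frame)


class TestRmAnova:
    def test_two_level_factor_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, (9, 2, 3)) + rng.normal(0, 1, (9, 1, 1))
        eff = rm_anova_cells(y)["type"]
        marg = y.mean(axis=2)
        t, _ = sst.ttest_rel(marg[:, 0], marg[:, 1])
        assert eff.F == pytest.approx(t**2, abs=1e-10)
        assert eff.epsilon_gg == 1.0

    def test_matches_pingouin_two_way_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n, a, b = 10, 2, 4
        y = (rng.normal(0, 1, (n, a, b)) + rng.normal(0, 1, (n, 1, 1))
             + 0.3 * np.arange(b) + 0.5 * np.arange(a)[:, None])
        ours = rm_anova_cells(y)
        df = pd.DataFrame(
            [{"subj": s, "A": f"a{i}", "B": f"b{j}", "y": y[s, i, j]}
             for s in range(n) for i in range(a) for j in range(b)]
        )
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj",
                          detailed=True, effsize="np2").set_index("Source")
        for name, source in (("type", "A"), ("time", "B"), ("type:time", "A * B")):
            assert ours[name].F == pytest.approx(ref.loc[source, "F"], rel=1e-9)
            assert ours[name].p == pytest.approx(ref.loc[source, "p_unc"], rel=1e-9)
            assert ours[name].eta_p2 == pytest.approx(ref.loc[source, "np2"], rel=1e-9)
            assert ours[name].epsilon_gg == pytest.approx(ref.loc[source, "eps"], rel=1e-9)
            assert ours[name].p_gg == pytest.approx(ref.loc[source, "p_GG_corr"], rel=1e-9)

    def test_zero_condition_differences_give_zero_f(self):
        subj = np.random.default_rng(0).normal(0, 1, (8, 1, 1))
        y = np.broadcast_to(subj, (8, 2, 4)).copy()
        eff = rm_anova_cells(y)
        assert eff["type"].F == 0.0
        assert eff["type"].eta_p2 == 0.0

    def test_sums_of_squares_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (10, 2, 4))
        a = rm_anova_cells(y)
        b = rm_anova_cells(y + 123.456)
        for k in a:
            assert a[k].ss_effect == pytest.approx(b[k].ss_effect, rel=1e-9, abs=1e-9)
            assert a[k].F == pytest.approx(b[k].F, rel=1e-9)

    def test_eta_p2_identity_holds_internally(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, (10, 2, 4)) + 0.4 * np.arange(4)
        for eff in rm_anova_cells(y).values():
            if eff.F > 0:
                identity = eff.F * eff.df1 / (eff.F * eff.df1 + eff.df2)
                assert abs(eff.eta_p2 - identity) < 1e-12

    def test_type_one_error_calibrated_at_alpha(self):
        rates = type_one_error_rates(2000, n_subjects=10, n_a=2, n_b=4, seed=0)
        half = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        for effect, rate in rates.items():
            assert 0.05 - half <= rate <= 0.05 + half, (effect, rate)

    def test_power_monotone_in_injected_type_effect(self):
        """Rejection rate for the condition effect grows with the injected shift."""
        rng = np.random.default_rng(21)
        rejections = []
        for shift in (0.0, 0.4, 0.8):
            count = 0
            for _ in range(300):
                y = rng.normal(0, 1, (10, 2, 4)) + rng.normal(0, 1, (10, 1, 1))
                y[:, 1, :] += shift
                count += rm_anova_cells(y)["type"].p < 0.05
            rejections.append(count / 300)
        assert rejections[0] <= rejections[1] <= rejections[2]


class TestGreenhouseGeisser:
    def test_two_levels_give_epsilon_one(self):
        y = np.random.default_rng(0).normal(size=(10, 2))
        assert greenhouse_geisser_epsilon(y) == 1.0

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, (4000, 4)) + rng.normal(0, 1, (4000, 1))
        assert greenhouse_geisser_epsilon(y) == pytest.approx(1.0, abs=0.01)

    def test_rank_one_covariance_attains_lower_bound(self):
        base = np.random.default_rng(2).normal(size=(12, 1))
        y = base @ np.array([[1.0, 2.0, -1.0, 0.5]])
        assert greenhouse_geisser_epsilon(y) == pytest.approx(1.0 / 3.0, abs=1e-12)


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,printed",
        [(18.90, 1, 9, 0.68), (33.98, 1, 8, 0.81), (17.19, 1, 9, 0.66),
         (7.04, 1, 9, 0.44), (23.10, 1, 9, 0.72), (6.069, 1, 9, 0.40),
         (8.23, 1, 9, 0.48), (23.82, 1, 9, 0.73)],
    )
    def test_reported_effect_sizes_recovered_from_f_and_dfs(self, F, df1, df2, printed):
        assert round(partial_eta_squared(F, df1, df2), 2) == pytest.approx(printed, abs=0.015)

    def test_zero_f_gives_zero(self):
        assert partial_eta_squared(0.0, 1, 9) == 0.0

    @given(F=st.floats(0, 1e4), df1=st.integers(1, 10), df2=st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_range_and_monotonicity(self, F, df1, df2):
        v = partial_eta_squared(F, df1, df2)
        assert 0.0 <= v <= 1.0
        assert partial_eta_squared(F + 1.0, df1, df2) >= v


class TestBonferroni:
    @pytest.fixture()
    def cells(self):
        rng = np.random.default_rng(4)
        return rng.normal(0, 1, (10, 2, 4)) + np.arange(4) * 0.5

    def test_time_family_has_six_pairs_and_min_capped_adjustment(self, cells):
        comps = bonferroni_pairwise(cells, ("AIR", "CO2"), ("T5", "T10", "T15", "POST"), "time")
        assert len(comps) == 6
        for c in comps:
            assert c.p_bonferroni == pytest.approx(min(1.0, 6 * c.p_raw))

    def test_interaction_family_is_per_time_type_contrasts(self, cells):
        comps = bonferroni_pairwise(cells, ("AIR", "CO2"), ("T5", "T10", "T15", "POST"), "type:time")
        assert len(comps) == 4
        assert comps[0].level_a == "AIR@T5" and comps[0].level_b == "CO2@T5"
        for c in comps:
            assert c.p_bonferroni == pytest.approx(min(1.0, 4 * c.p_raw))

    def test_single_pair_family_unadjusted(self, cells):
        comps = bonferroni_pairwise(cells, ("AIR", "CO2"), ("T5",) * 0 + ("T5", "T10", "T15", "POST"), "type")
        assert len(comps) == 1
        assert comps[0].p_bonferroni == pytest.approx(comps[0].p_raw)


class TestChangeCorrelation:
    def test_exact_linearity_is_very_strong(self):
        res = change_correlation(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        assert res.r == pytest.approx(1.0)
        assert res.band == "very strong"

    def test_moderate_band_for_r_near_minus_point_six(self):
        assert evans_band(-0.57) == "moderate"
        assert evans_band(0.02) == "very weak"
        assert evans_band(0.26) == "weak"
        assert evans_band(-0.62) == "strong"

    def test_one_tailed_p_is_half_the_two_tailed_p(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = change_correlation(x, y)
        _, p2 = sst.pearsonr(x, y)
        assert res.p == pytest.approx(p2 / 2.0)

    def test_zero_variance_deltas_rejected(self):
        with pytest.raises(DegenerateInputError):
            change_correlation(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


def test_rm_anova_2way_from_cohort_table_runs_pairwise_for_significant_effects():
    rng = np.random.default_rng(6)
    rows = []
    for s in range(10):
        subj_eff = rng.normal(0, 0.3)
        for itype in ("AIR", "CO2"):
            for tp in ("T5", "T10", "T15", "POST"):
                value = subj_eff + (1.0 if itype == "CO2" else 0.0) + rng.normal(0, 0.3)
                rows.append({"subject": f"S{s:02d}", "inhalation_type": itype,
                             "inhalation_time": tp, "outcome": "total_path",
                             "value": value})
    result = rm_anova_2way(pd.DataFrame(rows), "total_path")
    assert result.effects["type"].p < 0.05
    assert "type" in result.pairwise
    assert result.effects["time"].df1 == 3 and result.effects["time"].df2 == 27
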