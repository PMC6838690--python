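import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmflex import pm_cost, synthetic_cohort as sc


def make_probes(rts, level=3, block=1, pm_type="non_pm", correct=1):
    n = len(rts)
    return pd.DataFrame({
        "block": block, "trial": 1, "probe": np.arange(1, n + 1),
        "condition": "fixed", "pm_type": pm_type,
        "difficulty_level": level, "is_catch": False,
        "is_final_probe": [False] * (n - 1) + [True],
        "rt": rts, "og_correct": correct, "response": "og",
    })


class TestFilterResponses:
    def test_boundary_300ms_is_kept(self):
        probes = make_probes([0.25, 0.30, 0.80])
        out = pm_cost.filter_responses(probes)
        assert list(out["rt"]) == [0.30, 0.80]

    def test_identity_when_all_slow_enough(self):
        probes = make_probes([0.5, 0.9])
        assert len(pm_cost.filter_responses(probes)) == 2

    def test_empty_table_passes_through(self):
        probes = make_probes([0.5]).iloc[:0]
        assert pm_cost.filter_responses(probes).empty

    def test_missing_rt_column_is_schema_error(self):
        with pytest.raises(pm_cost.SchemaError):
            pm_cost.filter_responses(pd.DataFrame({"block": [1]}))

    def test_omissions_are_retained(self):
        probes = make_probes([0.5, np.nan, 0.7])
        assert len(pm_cost.filter_responses(probes)) == 3


class TestBaselines:
    def test_cell_mean_is_arithmetic_mean(self):
        probes = pd.concat([
            make_probes([0.7, 0.9], level=3, block=1),
            make_probes([0.8], level=3, block=2),
        ])
        bt = pm_cost.compute_baselines(probes,
                                       block_split={1: "early", 2: "late"})
        assert bt.lookup(3, "early") == pytest.approx(0.8)
        assert bt.lookup(3, "late") == pytest.approx(0.8)

    def test_constant_rt_fills_all_cells_with_it(self, small_cohort):
        probes, _, _ = small_cohort
        one = probes[probes["participant"] == 1].copy()
        one["rt"] = 0.8
        one["og_correct"] = 1
        bt = pm_cost.compute_baselines(one)
        assert np.allclose(bt.table["mean_rt"], 0.8)

    def test_full_session_populates_30_cells(self, small_cohort):
        probes, _, _ = small_cohort
        one = pm_cost.filter_responses(probes[probes["participant"] == 1])
        bt = pm_cost.compute_baselines(one)
        assert bt.n_cells == 30

    def test_default_split_matches_5_and_6_block_sessions(self):
        assert pm_cost.default_block_split([1, 2, 3, 4, 5]) == {
            1: "early", 2: "early", 3: "late", 4: "late", 5: "late"}
        split6 = pm_cost.default_block_split([1, 2, 3, 4, 5, 6])
        assert [split6[b] for b in range(1, 7)] == [
            "early"] * 3 + ["late"] * 3

    def test_only_correct_non_pm_used(self):
        probes = pd.concat([
            make_probes([0.5], level=2, pm_type="face"),
            make_probes([0.9], level=2, correct=0),
        ])
        with pytest.raises(pm_cost.BaselineError):
            pm_cost.compute_baselines(probes, block_split={1: "early"})

    def test_all_responses_variant_uses_incorrect_rts(self):
        probes = make_probes([0.9], level=2, correct=0)
        bt = pm_cost.compute_baselines(probes, block_split={1: "early"},
                                       correct_only=False)
        assert bt.lookup(2, "early") == pytest.approx(0.9)


class TestProbeCosts:
    def test_cost_is_rt_minus_matched_baseline(self):
        base = make_probes([0.8, 0.8], level=5)
        bt = pm_cost.compute_baselines(base, block_split={1: "early"})
        pm = make_probes([0.9, 0.8], level=5, pm_type="face")
        out = pm_cost.probe_costs(pm, bt)
        assert out["cost"].tolist() == pytest.approx([0.1, 0.0])

    def test_missing_cell_flags_not_crashes(self):
        base = make_probes([0.8], level=5)
        bt = pm_cost.compute_baselines(base, block_split={1: "early"})
        pm = make_probes([0.9], level=7, pm_type="face")
        out = pm_cost.probe_costs(pm, bt)
        assert out["cost"].isna().all()

    def test_generator_cost_recovery_without_decay(self):
        # with no difficulty attenuation, mean recovered cost at every level
        # approximates theta * cost_amplitude
        p = sc.SynthParams(n_participants=10, n_blocks=6, seed=17,
                           cost_amplitude=0.12, cost_difficulty_decay=0.0,
                           drift_inc=0.0, drift_dec=0.0, drift_fix=0.0,
                           drift_sd=0.0, theta0=1.0)
        probes, _ = sc.simulate_cohort(p)
        filtered = pm_cost.filter_responses(probes)
        _, profiles = pm_cost.summarize_trials(filtered)
        lc = profiles["level_cost"].groupby("difficulty_level")["mean_cost"].mean()
        assert np.nanmean(np.abs(lc - 0.12)) < 0.03


class TestCostSlope:
    def test_hand_computed_example(self):
        # 100 ms window difference on a 10-probe trial -> 5 ms/s
        costs = np.array([0.05] * 3 + [0.1] * 3 + [0.15] * 3)
        assert pm_cost.cost_slope(costs, 10) == pytest.approx(5.0)

    def test_constant_costs_give_zero_slope(self):
        assert pm_cost.cost_slope(np.full(9, 0.08), 10) == pytest.approx(0.0)

    def test_short_trials_undefined(self):
        assert np.isnan(pm_cost.cost_slope(np.full(5, 0.1), 6))

    def test_window_occupancy_requirement(self):
        costs = np.array([np.nan, np.nan, np.nan, 0.1, 0.1, 0.2, 0.2, 0.2, 0.2])
        assert np.isnan(pm_cost.cost_slope(costs, 10))
        costs[0] = 0.1
        assert np.isfinite(pm_cost.cost_slope(costs, 10))
        assert np.isnan(pm_cost.cost_slope(costs, 10, min_window_n=3))

    @given(st.floats(-0.2, 0.2), st.floats(0.5, 2.0))
    @settings(deadline=None, max_examples=25)
    def test_shift_invariance_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(0)
        costs = rng.normal(0.1, 0.05, 11)
        base = pm_cost.cost_slope(costs, 12)
        shifted = pm_cost.cost_slope(costs + shift, 12)
        scaled = pm_cost.cost_slope(costs * scale, 12)
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestSummarizeTrials:
    def test_below_chance_accuracy_excluded(self, trial_summary):
        summary, _ = trial_summary
        low = summary["og_accuracy"] < 0.5
        assert (summary.loc[low, "excluded"]).all()
        assert (~summary.loc[~low, "excluded"]).all()

    def test_exclusion_monotone_in_threshold(self, small_cohort):
        probes, _, _ = small_cohort
        filtered = pm_cost.filter_responses(probes)
        strict, _ = pm_cost.summarize_trials(filtered, accuracy_threshold=0.5)
        lax, _ = pm_cost.summarize_trials(filtered, accuracy_threshold=0.3)
        assert lax["excluded"].sum() <= strict["excluded"].sum()

    def test_non_pm_trials_have_no_slope(self, trial_summary):
        summary, _ = trial_summary
        nonpm = summary[summary["pm_type"] == "non_pm"]
        assert nonpm["cost_slope"].isna().all()

    def test_constant_rt_shift_moves_costs_not_slopes(self, small_cohort):
        probes, _, _ = small_cohort
        one = pm_cost.filter_responses(
            probes[probes["participant"] == 1]).copy()
        s0, _ = pm_cost.summarize_trials(one)
        shifted = one.copy()
        pm_mask = shifted["pm_type"] != "non_pm"
        shifted.loc[pm_mask, "rt"] = shifted.loc[pm_mask, "rt"] + 0.05
        s1, _ = pm_cost.summarize_trials(shifted)
        m = s0["pm_type"] != "non_pm"
        d_cost = (s1.loc[m, "mean_cost"] - s0.loc[m, "mean_cost"]).dropna()
        assert np.allclose(d_cost, 0.05, atol=1e-9)
        d_slope = (s1.loc[m, "cost_slope"] - s0.loc[m, "cost_slope"]).dropna()
        assert d_slope.abs().max() < 1e-6

    def test_null_drift_gives_near_zero_condition_slopes(self):
        # decay must also be off: with constant theta, the difficulty
        # attenuation of expressed cost alone yields nonzero slopes
        p = sc.SynthParams(n_participants=12, n_blocks=4, seed=55,
                           drift_inc=0.0, drift_dec=0.0, drift_fix=0.0,
                           drift_sd=0.0, pm_slope_gain=0.0,
                           pm_slope_gain_inc=0.0, cost_difficulty_decay=0.0)
        probes, _ = sc.simulate_cohort(p)
        _, profiles = pm_cost.summarize_trials(pm_cost.filter_responses(probes))
        slopes = profiles["condition_slopes"]["mean_slope"]
        assert slopes.abs().max() < 2.0
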