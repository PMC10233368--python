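import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotscreen import calling
from dotscreen.calling import (
    aggregate_replicates,
    apply_exclusions,
    call_pairs,
    call_preference,
    leave_one_out_z,
    normalize_dot,
    summarize_screen,
)


class TestNormalizeDot:
    @pytest.mark.parametrize(
        "signal,control,expected",
        [(200.0, 100.0, 2.0), (0.0, 100.0, 0.0), (3.0, 4.0, 0.75)],
    )
    def test_ratio(self, signal, control, expected):
        ratio, valid = normalize_dot(signal, control)
        assert valid and ratio == expected

    def test_zero_control_flags_invalid(self):
        ratio, valid = normalize_dot(200.0, 0.0)
        assert not valid and math.isnan(ratio)

    def test_control_at_floor_flags_invalid(self):
        _, valid = normalize_dot(200.0, 5.0, control_floor=5.0)
        assert not valid

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_dot(-1.0, 10.0)


class TestAggregateReplicates:
    def test_nine_identical_values(self):
        agg = aggregate_replicates([3.7] * 9)
        assert agg.aggregate == 3.7
        assert agg.replicate_sd == pytest.approx(0.0, abs=1e-12)
        assert agg.n_used == 9
        assert agg.ok

    def test_median_robust_to_one_outlier(self):
        agg = aggregate_replicates([1.0] * 8 + [10.0])
        assert agg.aggregate == 1.0

    def test_too_few_replicates_refused(self):
        agg = aggregate_replicates([2.0, 4.0], min_replicates=3)
        assert not agg.ok and agg.reason == "too_few_replicates"
        assert math.isnan(agg.aggregate)

    def test_empty_refused(self):
        assert not aggregate_replicates([]).ok

    def test_nan_ratios_dropped_before_count(self):
        agg = aggregate_replicates([1.0, 2.0, 3.0, float("nan")], min_replicates=3)
        assert agg.ok and agg.n_used == 3 and agg.aggregate == 2.0

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=9)
    )
    def test_aggregate_bounded_by_data(self, ratios):
        agg = aggregate_replicates(ratios)
        assert min(ratios) <= agg.aggregate <= max(ratios)
        assert agg.replicate_sd >= 0


def _sets_frame(bait, aggregates, prefix="p"):
    n = len(aggregates)
    return pd.DataFrame(
        {
            "bait_id": bait,
            "prey_id": [f"{prefix}{i:03d}" for i in range(n)],
            "aggregate": aggregates,
            "replicate_sd": 0.01,
            "n_used": 9,
            "n_total": 9,
            "agg_ok": True,
            "agg_reason": "",
        }
    )


def _od_for(sets, od=0.5):
    return pd.DataFrame(
        {
            "strain_id": sets["bait_id"] + ":" + sets["prey_id"],
            "od600": od,
        }
    )


class TestExclusions:
    def test_low_tail_z_excluded(self):
        """An aggregate ~12 SD below the rest of its membrane stack is
        excluded; the same deviation above is retained (one-sided rule)."""
        rng = np.random.default_rng(0)
        base = 1.0 + 0.05 * rng.standard_normal(40)
        sets = _sets_frame("baitA", np.r_[base, 0.4])
        out = apply_exclusions(sets, _od_for(sets))
        low = out.iloc[-1]
        assert low["membrane_z"] < -10
        assert low["excluded"] and low["exclusion_reason"] == "low_signal_z"
        assert not out.iloc[:-1]["excluded"].any()

    def test_high_outlier_not_excluded(self):
        rng = np.random.default_rng(0)
        base = 1.0 + 0.05 * rng.standard_normal(40)
        sets = _sets_frame("baitA", np.r_[base, 2.0])
        out = apply_exclusions(sets, _od_for(sets))
        hi = out.iloc[-1]
        assert hi["membrane_z"] > 10
        assert not hi["excluded"]

    def test_leave_one_out_matches_brute_force(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 0.2, 1.02, 0.98])
        z = leave_one_out_z(vals)
        for i, v in enumerate(vals):
            rest = np.delete(vals, i)
            expected = (v - rest.mean()) / rest.std(ddof=1)
            assert z[i] == pytest.approx(expected, rel=1e-12)

    def test_missing_strain_excluded_by_od(self):
        sets = _sets_frame("baitA", np.ones(12))
        od = _od_for(sets)
        od.loc[3, "od600"] = 0.01
        out = apply_exclusions(sets, od, od_floor=0.05)
        assert out.loc[3, "excluded"]
        assert out.loc[3, "exclusion_reason"] == "missing_strain"

    def test_strain_without_od_record_flagged(self):
        sets = _sets_frame("baitA", np.ones(12))
        od = _od_for(sets).iloc[1:]
        out = apply_exclusions(sets, od)
        assert out.loc[0, "exclusion_reason"] == "no_od"

    def test_high_replicate_sd_flagged_not_excluded(self):
        sets = _sets_frame("baitA", np.ones(12))
        sets.loc[5, "replicate_sd"] = 4.0
        out = apply_exclusions(sets, _od_for(sets), sd_flag_threshold=3.0)
        assert out.loc[5, "sd_flagged"] and not out.loc[5, "excluded"]

    def test_small_population_rejected(self):
        sets = _sets_frame("baitA", np.ones(5))
        with pytest.raises(ValueError, match="at least 10"):
            apply_exclusions(sets, _od_for(sets))


class TestCallPreference:
    @pytest.mark.parametrize(
        "a,b,floor,expected_cat,expected_fc",
        [
            (2.1, 1.0, 0.1, "prefers_A", 2.1),
            (1.0, 2.1, 0.1, "prefers_B", 2.1),
            (2.0, 1.0, 0.1, "both", 2.0),  # strictly-greater-than rule
            (0.01, 0.02, 0.1, "no_interaction", None),
            (1.0, 1.0, 0.1, "both", 1.0),
            (0.5, 0.01, 0.1, "prefers_A", 5.0),  # one side below floor
        ],
    )
    def test_examples(self, a, b, floor, expected_cat, expected_fc):
        cat, fc = call_preference(a, b, detection_floor=floor)
        assert cat == expected_cat
        if expected_fc is None:
            assert math.isnan(fc)
        else:
            assert fc == pytest.approx(expected_fc)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            call_preference(-0.1, 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(0, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    def test_swapping_signals_swaps_preference(self, a, b):
        cat1, _ = call_preference(a, b, detection_floor=0.1)
        cat2, _ = call_preference(b, a, detection_floor=0.1)
        swap = {"prefers_A": "prefers_B", "prefers_B": "prefers_A"}
        assert cat2 == swap.get(cat1, cat1)


class TestSummarize:
    def test_counts_partition_preys(self, full_screen_analysis):
        pairs = full_screen_analysis["pairs"]
        summary = summarize_screen(pairs)
        assert summary["count"].sum() == len(pairs) == 512

    def test_empty_input_gives_zero_table(self):
        empty = pd.DataFrame({"prey_id": [], "category": []})
        summary = summarize_screen(empty)
        assert (summary["count"] == 0).all()

    def test_duplicate_prey_rejected(self):
        pairs = pd.DataFrame(
            {"prey_id": ["x", "x"], "category": ["both", "both"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            summarize_screen(pairs)


class TestScreenLevelInvariants:
    def test_bait_swap_antisymmetry(self, full_screen_analysis):
        """Relabeling the baits A<->B swaps the preference labels and
        leaves every other category untouched, prey by prey."""
        sets = full_screen_analysis["sets"]
        floors = full_screen_analysis["floors"]
        cfg = full_screen_analysis["screen"].config
        fwd = call_pairs(sets, cfg.baits, detection_floor=max(floors.values()))
        rev = call_pairs(
            sets, (cfg.baits[1], cfg.baits[0]),
            detection_floor=max(floors.values()),
        )
        swap = {"prefers_A": "prefers_B", "prefers_B": "prefers_A"}
        m = fwd.merge(rev, on="prey_id", suffixes=("_f", "_r"))
        assert (
            m["category_r"]
            == m["category_f"].map(lambda c: swap.get(c, c))
        ).all()

    def test_preference_recovery_at_planted_fold_change(
        self, full_screen_analysis
    ):
        merged = full_screen_analysis["merged"]
        pref = merged[merged["category_true"].isin(["prefers_A", "prefers_B"])]
        correct = (pref["category_called"] == pref["category_true"]).mean()
        assert correct >= 0.95
        non = merged[merged["category_true"].isin(["null", "equal"])]
        false_rate = non["category_called"].isin(
            ["prefers_A", "prefers_B"]
        ).mean()
        assert false_rate <= 0.05

    def test_no_preference_calls_when_fold_change_is_one(self):
        from conftest import analyze_screen
        from dotscreen.simulate import ScreenConfig, generate_screen

        cfg = ScreenConfig(
            n_preys=96, grid_rows=16, grid_cols=24, seed=13,
            category_fractions=(0.3, 0.7, 0.0, 0.0),
            missing_strain_fraction=0.0,
        )
        _, _, pairs, _ = analyze_screen(generate_screen(cfg))
        false_rate = pairs["category"].isin(["prefers_A", "prefers_B"]).mean()
        assert false_rate <= 0.05

    def test_replicate_sd_stays_below_three_at_low_noise(
        self, full_screen_analysis
    ):
        sd = full_screen_analysis["sets"]["replicate_sd"]
        assert np.nanmax(sd.to_numpy()) < 3.0
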