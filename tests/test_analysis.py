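"""Conditioning statistics: valid-object filters, exact intervals and
tests, PRE/ON/OFF differences, bend smoothing, rates, rank tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from larvatrack import analysis as an
from larvatrack.classify import BehaviorEvent
from larvatrack.simulate import generate_bend_cohort


# ---------------------------------------------------------------------------
# valid-object filtering
# ---------------------------------------------------------------------------


def _track(positions, lid=0, frame_dt=0.05, t0=0.0):
    """positions: list of (x, y) per frame starting at t0."""
    rows = []
    f0 = int(round(t0 / frame_dt))
    for i, (x, y) in enumerate(positions):
        rows.append({"frame": f0 + i, "time_s": t0 + i * frame_dt,
                     "id": lid, "x_mm": x, "y_mm": y})
    return pd.DataFrame(rows)


def _steady_walk(duration_s, speed_mm_s, lid=0, t0=0.0, frame_dt=0.05):
    n = int(round(duration_s / frame_dt))
    xs = t0 * speed_mm_s + speed_mm_s * frame_dt * np.arange(n)
    return _track([(x, 0.0) for x in xs], lid=lid, t0=t0)


class TestValidObjects:
    def test_good_object_retained(self):
        tr = _steady_walk(120.0, 1.0)
        valid = an.filter_valid_objects(tr, 60.0, an.ValidObjectFilter.operant())
        assert valid[1] == {0}

    def test_first_bin_excluded_by_track_age(self):
        # detection starts at t=0, so it is not 20 s old at bin 0
        tr = _steady_walk(120.0, 1.0)
        valid = an.filter_valid_objects(tr, 60.0, an.ValidObjectFilter.operant())
        assert valid[0] == set()

    def test_mid_bin_appearance_excluded(self):
        tr = _steady_walk(90.0, 1.0, t0=30.0)
        valid = an.filter_valid_objects(tr, 60.0,
                                        an.ValidObjectFilter.operant(),
                                        duration_s=120.0)
        assert 0 not in valid[0]   # appeared mid-bin
        assert 0 in valid[1]       # 30 s old by bin-1 start, fully tracked

    def test_speed_spike_excluded_operant(self):
        n = 2400
        xs = np.cumsum(np.full(n, 1.0 * 0.05))
        xs[1200:] += 2.0  # instantaneous 2 mm jump -> smoothed spike > 1.5
        tr = _track([(x, 0.0) for x in xs])
        valid = an.filter_valid_objects(tr, 60.0, an.ValidObjectFilter.operant())
        assert 0 not in valid[1]

    def test_slow_object_excluded(self):
        tr = _steady_walk(120.0, 0.2)
        valid = an.filter_valid_objects(tr, 60.0, an.ValidObjectFilter.operant())
        assert 0 not in valid[1]

    def test_proof_variant_age_15s(self):
        tr = _steady_walk(60.0, 1.0, t0=40.0)
        valid = an.filter_valid_objects(tr, 5.0, an.ValidObjectFilter.proof(),
                                        duration_s=100.0)
        # 15 s after first detection -> eligible from t = 55 s (bin 11)
        assert 0 not in valid[10]
        assert 0 in valid[11]


# ---------------------------------------------------------------------------
# fractions, Clopper-Pearson, Fisher
# ---------------------------------------------------------------------------


class TestFractions:
    def test_zero_of_ten(self):
        lo, hi = an.clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)

    def test_sixteen_of_sixteen_closed_form(self):
        """At k = n the exact lower bound is (alpha/2)^(1/n)."""
        lo, hi = an.clopper_pearson(16, 16)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 16), abs=1e-9)
        assert lo == pytest.approx(0.794, abs=0.001)

    def test_fraction_counts_at_least_once_per_bin(self):
        beh = pd.DataFrame({
            "time_s": [0.0, 0.05, 0.10, 0.15],
            "id": [1, 1, 2, 2],
            "roll": [False, True, False, False],
        })
        frac = an.behavior_fraction_bins(beh, {0: {1, 2}}, "roll", 5.0)
        assert frac.iloc[0]["fraction"] == pytest.approx(0.5)

    def test_empty_valid_set_missing(self):
        beh = pd.DataFrame({"time_s": [], "id": [], "roll": []})
        frac = an.behavior_fraction_bins(beh, {0: set()}, "roll", 5.0)
        assert np.isnan(frac.iloc[0]["fraction"])


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def p_table(x):
        return (comb(row1, x) * comb(n - row1, col1 - x)) / comb(n, col1)

    p_obs = p_table(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    return sum(p_table(x) for x in range(lo, hi + 1)
               if p_table(x) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_three_zero_table(self):
        """[[3,0],[0,3]]: p = 2 / C(6,3) = 0.1 by enumeration."""
        from scipy.stats import fisher_exact
        _, p = fisher_exact([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert fisher_oracle(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 11, 4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        from scipy.stats import fisher_exact
        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_bonferroni_flag_uses_m_24(self):
        fa = pd.DataFrame([{"bin": 0, "k": 10, "n": 10}])
        fb = pd.DataFrame([{"bin": 0, "k": 0, "n": 10}])
        out = an.fisher_bins(fa, fb)
        assert out.iloc[0]["p"] < 0.05 / 24
        assert bool(out.iloc[0]["significant"])


# ---------------------------------------------------------------------------
# percentage bending (classical)
# ---------------------------------------------------------------------------


def _beh_table(lid, bend_fn, duration=300.0, frame_dt=0.05):
    t = np.arange(0, duration, frame_dt)
    return pd.DataFrame({"time_s": t, "id": lid, "bend": [bend_fn(x) for x in t]})


class TestPercentageBending:
    onsets = [100.0, 165.0, 230.0]
    offsets = [120.0, 185.0, 250.0]

    def test_always_on_never_off(self):
        def fn(t):
            return any(o <= t < o + 20 for o in self.onsets)
        beh = _beh_table(1, fn)
        out = an.percentage_bending_difference(beh, self.onsets, self.offsets)
        assert out[1] == pytest.approx(100.0)

    def test_equal_gives_zero(self):
        beh = _beh_table(1, lambda t: True)
        out = an.percentage_bending_difference(beh, self.onsets, self.offsets)
        assert out[1] == pytest.approx(0.0)

    def test_forty_minus_sixty(self):
        def fn(t):
            frame = int(round(t / 0.05))
            in_on = any(o <= t < o + 20 for o in self.onsets)
            in_off = any(o <= t < o + 20 for o in self.offsets)
            if in_on:
                return frame % 5 < 2     # 40% of ON frames
            if in_off:
                return frame % 5 < 3     # 60% of OFF frames
            return False
        beh = _beh_table(1, fn)
        out = an.percentage_bending_difference(beh, self.onsets, self.offsets)
        assert out[1] == pytest.approx(-20.0, abs=0.5)

    def test_incomplete_window_excluded(self):
        beh = _beh_table(1, lambda t: False, duration=240.0)
        out = an.percentage_bending_difference(beh, self.onsets, self.offsets)
        assert 1 not in out.index

    def test_no_rounds_error(self):
        with pytest.raises(ValueError):
            an.percentage_bending_difference(_beh_table(1, lambda t: False),
                                             [], [])


# ---------------------------------------------------------------------------
# bend smoothing and rates (operant)
# ---------------------------------------------------------------------------


def _bend(side, a, b):
    return BehaviorEvent("bend", side, a, b)


class TestSmoothBendEvents:
    def test_same_side_gap_merged(self):
        out = an.smooth_bend_events([_bend("left", 0, 1.0), _bend("left", 1.1, 2.0)])
        assert len(out) == 1
        assert out[0].t_start == 0 and out[0].t_end == 2.0

    def test_short_bend_removed(self):
        out = an.smooth_bend_events([_bend("left", 0, 0.15)])
        assert out == []

    def test_different_sides_not_merged(self):
        out = an.smooth_bend_events([_bend("left", 0, 1.0), _bend("right", 1.1, 2.0)])
        assert len(out) == 2

    def test_merge_before_removal_order(self):
        """Two 150 ms same-side bends 100 ms apart merge into one 400 ms
        bend that survives; removal first would have deleted both."""
        out = an.smooth_bend_events([_bend("left", 0, 0.15), _bend("left", 0.25, 0.4)])
        assert len(out) == 1
        assert out[0].duration == pytest.approx(0.4)

    def test_idempotent(self):
        evs = [_bend("left", 0, 1.0), _bend("left", 1.1, 2.0),
               _bend("right", 3.0, 3.1), _bend("left", 5.0, 6.0)]
        once = an.smooth_bend_events(evs)
        twice = an.smooth_bend_events(once)
        assert once == twice

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            an.smooth_bend_events([_bend("left", 0, 1.0), _bend("left", 0.5, 2.0)])


class TestBendRates:
    def test_rate_counts_initiations(self):
        evs = {7: [_bend("left", 10 + i, 10.4 + i) for i in range(4)]}
        rates = an.bend_rates(evs, {0: {7}}, {7: "left"})
        row = rates.iloc[0]
        assert row.left_rate == 4
        assert row.stim_rate == 4
        assert row.difference == 4

    def test_bend_counts_in_initiation_bin(self):
        evs = {7: [_bend("left", 59.9, 61.5)]}
        rates = an.bend_rates(evs, {0: {7}, 1: {7}}, {7: "left"})
        assert rates[rates.bin == 0].iloc[0].left_rate == 1
        assert rates[rates.bin == 1].iloc[0].left_rate == 0

    def test_stim_unstim_difference(self):
        evs = {7: [_bend("left", i * 10, i * 10 + 1) for i in range(5)]
               + [_bend("right", i * 10 + 5, i * 10 + 6) for i in range(3)]}
        rates = an.bend_rates(evs, {0: {7}}, {7: "left"})
        assert rates.iloc[0].difference == pytest.approx(2.0)

    def test_uncorrelated_left_minus_right(self):
        evs = {7: [_bend("left", 1, 2), _bend("right", 5, 6), _bend("right", 8, 9)]}
        rates = an.bend_rates(evs, {0: {7}}, None)
        assert rates.iloc[0].difference == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


class TestRankTests:
    def test_cles_complete_separation(self):
        out = an.rank_tests([4, 5, 6], [1, 2, 3], mode="mann_whitney")
        assert out["cles"] == 1.0

    def test_cles_identical_samples(self):
        out = an.rank_tests([1, 2, 3], [1, 2, 3], mode="mann_whitney")
        assert out["cles"] == 0.5

    def test_exact_small_sample_p(self):
        """a=[1,2] vs b=[3,4]: full enumeration over C(4,2) rank splits
        gives two-sided p = 2/6."""
        out = an.rank_tests([1, 2], [3, 4], mode="mann_whitney")
        assert out["p"] == pytest.approx(2 / 6, abs=1e-12)

    def test_wilcoxon_paired_equals_vs_zero_on_differences(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 18)
        b = rng.normal(0.0, 1.0, 18)
        paired = an.rank_tests(a, b, mode="wilcoxon_signed")
        vs_zero = an.rank_tests(a - b, mode="wilcoxon_vs_zero")
        assert paired["p"] == pytest.approx(vs_zero["p"], abs=1e-12)
        assert paired["statistic"] == vs_zero["statistic"]

    def test_all_zero_differences_p1_with_warning(self):
        with pytest.warns(UserWarning):
            out = an.rank_tests(np.zeros(6), mode="wilcoxon_vs_zero")
        assert out["p"] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            an.rank_tests([], mode="wilcoxon_vs_zero")


# ---------------------------------------------------------------------------
# end-to-end recovery of an injected side bias
# ---------------------------------------------------------------------------


class TestRecovery:
    def test_injected_delta_recovered_within_binomial_se(self):
        """A cohort with stimulated-side excess delta must come back from
        the smoothing + rate pipeline within the event-count standard
        error."""
        delta = 3.0   # bends/min excess
        base = 6.0
        n, dur = 40, 120.0
        events, sides = generate_bend_cohort(n, dur, rate_per_min=base,
                                             delta_per_min=delta, seed=11)
        events = {k: an.smooth_bend_events(v) for k, v in events.items()}
        valid = {b: set(range(n)) for b in range(int(dur // 60))}
        rates = an.bend_rates(events, valid, sides)
        mean_diff = rates["difference"].mean()
        # Poisson counts: Var(diff per min) ~ (2*base+delta)/ (dur/60)
        se = np.sqrt((2 * base + delta) / (dur / 60.0)) / np.sqrt(len(rates))
        assert abs(mean_diff - delta) <= 2 * se
        stat = an.rank_tests(rates["difference"].to_numpy(),
                             mode="wilcoxon_vs_zero")
        assert stat["p"] < 0.01

    def test_uncorrelated_cohort_not_significant(self):
        events, sides = generate_bend_cohort(40, 120.0, rate_per_min=6.0,
                                             delta_per_min=0.0, seed=13)
        events = {k: an.smooth_bend_events(v) for k, v in events.items()}
        valid = {b: set(events) for b in range(2)}
        rates = an.bend_rates(events, valid, None)
        stat = an.rank_tests(rates["difference"].to_numpy(),
                             mode="wilcoxon_vs_zero")
        assert stat["p"] > 0.05
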