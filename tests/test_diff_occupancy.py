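"""Differential occupancy calling: the 2-sigma / 105-bp rule and change tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pausedelta.diff_occupancy import (ChangeCallSet, call_change_intervals,
                                       change_frequency_table,
                                       classify_region_changes)
from pausedelta.genome_model import GenomicInterval, SignalTrack

SPACING = 35


def probe_track(values, chrom="c", spacing=SPACING):
    starts = spacing * np.arange(len(values))
    return SignalTrack("probe_scores",
                       {chrom: (starts, starts + spacing, np.asarray(values, float))},
                       probe_spacing=spacing)


def brute_force_calls(treated_vals, control_vals, k=2.0, min_span=105,
                      spacing=SPACING):
    """Independent run scanner: per-probe diffs, global median/SD, naive scan."""
    diffs = [np.asarray(t, float) - np.asarray(c, float)
             for t, c in zip(treated_vals, control_vals)]
    all_d = np.concatenate(diffs)
    m, sd = float(np.median(all_d)), float(np.std(all_d))
    up, down = [], []
    for ci, d in enumerate(diffs):
        for dest, sel in ((up, d >= m + k * sd), (down, d <= m - k * sd)):
            run = []
            for i, flag in enumerate(list(sel) + [False]):
                if flag:
                    run.append(i)
                else:
                    if run and (run[-1] - run[0]) * spacing + spacing >= min_span:
                        dest.append((ci, run[0] * spacing, run[-1] * spacing + spacing))
                    run = []
    return up, down


def as_tuples(intervals, chrom_index):
    return sorted((chrom_index[iv.chrom], iv.start, iv.end) for iv in intervals)


class TestCallChangeIntervals:
    def test_identical_tracks_give_no_calls(self):
        v = np.random.default_rng(0).normal(size=50)
        calls = call_change_intervals(probe_track(v), probe_track(v.copy()))
        assert calls.up == [] and calls.down == []

    def test_three_probe_run_spans_exactly_105_bp(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.1, 200)
        treat = base.copy()
        treat[50:53] += 5.0
        calls = call_change_intervals(probe_track(treat), probe_track(base))
        assert len(calls.up) == 1 and calls.down == []
        iv = calls.up[0]
        assert iv.length == 105
        assert (iv.start, iv.end) == (50 * SPACING, 53 * SPACING)

    def test_two_probe_run_is_below_the_three_feature_minimum(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.1, 200)
        treat = base.copy()
        treat[50:52] += 5.0
        calls = call_change_intervals(probe_track(treat), probe_track(base))
        assert calls.up == []

    def test_matches_brute_force_scanner_on_random_tracks(self):
        rng = np.random.default_rng(2)
        chroms = ["c1", "c2"]
        cidx = {c: i for i, c in enumerate(chroms)}
        for _ in range(25):
            sizes = [int(rng.integers(20, 400)) for _ in chroms]
            tvals = [rng.normal(0, 1, n) for n in sizes]
            cvals = [rng.normal(0, 1, n) for n in sizes]
            # sprinkle structured runs so calls actually occur
            for v in tvals:
                for _ in range(3):
                    s = int(rng.integers(0, max(1, len(v) - 6)))
                    v[s:s + int(rng.integers(1, 6))] += float(rng.normal(0, 6))
            treated = SignalTrack("probe_scores", {
                c: (SPACING * np.arange(n), SPACING * np.arange(n) + SPACING, v)
                for c, n, v in zip(chroms, sizes, tvals)}, probe_spacing=SPACING)
            control = SignalTrack("probe_scores", {
                c: (SPACING * np.arange(n), SPACING * np.arange(n) + SPACING, v)
                for c, n, v in zip(chroms, sizes, cvals)}, probe_spacing=SPACING)
            got = call_change_intervals(treated, control)
            exp_up, exp_down = brute_force_calls(tvals, cvals)
            assert as_tuples(got.up, cidx) == sorted(exp_up)
            assert as_tuples(got.down, cidx) == sorted(exp_down)

    def test_swapping_conditions_exchanges_up_and_down(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 300)
        b = a + rng.normal(0, 1, 300)
        b[40:45] += 8
        b[200:206] -= 8
        fwd = call_change_intervals(probe_track(b), probe_track(a))
        rev = call_change_intervals(probe_track(a), probe_track(b))
        assert fwd.up == rev.down and fwd.down == rev.up

    def test_constant_shift_moves_median_not_calls(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 300)
        b = a + rng.normal(0, 1, 300)
        b[100:104] += 7
        c1 = call_change_intervals(probe_track(b), probe_track(a))
        c2 = call_change_intervals(probe_track(b + 3.0), probe_track(a))
        assert c2.stats.median == pytest.approx(c1.stats.median + 3.0)
        assert c2.stats.sd == pytest.approx(c1.stats.sd)
        assert c1.up == c2.up and c1.down == c2.down

    def test_mismatched_probe_grids_rejected(self):
        t = probe_track(np.zeros(10))
        c = probe_track(np.zeros(11))
        with pytest.raises(ValueError, match="mismatch"):
            call_change_intervals(t, c)


class TestClassifyRegionChanges:
    def _calls(self):
        return ChangeCallSet(
            up=[GenomicInterval("c", 1000, 1105)],
            down=[GenomicInterval("c", 1000, 1210), GenomicInterval("c", 5000, 5105)])

    def test_single_direction_overlap(self):
        calls = self._calls()
        labels = classify_region_changes(calls, {"p": GenomicInterval("c", 4950, 5150)})
        assert labels["p"] == "DOWN"

    def test_conflict_rescored_none_and_logged(self):
        calls = self._calls()
        labels = classify_region_changes(calls, {"b": GenomicInterval("c", 900, 1300)})
        assert labels["b"] == "NONE"
        assert calls.conflicts == ["b"]

    def test_larger_span_wins_rule(self):
        calls = self._calls()
        labels = classify_region_changes(calls, {"b": GenomicInterval("c", 900, 1300)},
                                         conflict_rule="larger_span_wins")
        assert labels["b"] == "DOWN"  # 210 bp beats 105 bp

    def test_no_overlap_is_none(self):
        labels = classify_region_changes(self._calls(),
                                         {"x": GenomicInterval("c", 9000, 9100)})
        assert labels["x"] == "NONE"


class TestChangeFrequencyTable:
    def _table(self, a, b, c, d):
        # a DOWN among binding, b non-DOWN binding, c DOWN non-binding, ...
        labels = pd.Series(["DOWN"] * a + ["NONE"] * b + ["DOWN"] * c + ["NONE"] * d)
        strata = pd.Series([True] * (a + b) + [False] * (c + d))
        return change_frequency_table(labels, strata)

    def test_equal_proportions_give_p_one(self):
        tab = self._table(5, 5, 5, 5)
        assert tab.loc["DOWN", "fisher_p"] == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric_enumeration(self):
        tab = self._table(10, 0, 0, 10)
        # two-sided Fisher p by full enumeration of the hypergeometric support
        from math import comb
        n, K, N = 20, 10, 10  # total, binding, changed
        probs = [comb(K, x) * comb(n - K, N - x) / comb(n, N)
                 for x in range(0, 11)]
        p_obs = probs[10]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert tab.loc["DOWN", "fisher_p"] == pytest.approx(expected)

    def test_designed_rate_difference_recovered(self):
        rng = np.random.default_rng(8)
        n = 500
        down_b = rng.random(n) < 0.5
        down_n = rng.random(n) < 0.25
        labels = pd.Series(np.where(np.concatenate([down_b, down_n]), "DOWN", "NONE"))
        strata = pd.Series([True] * n + [False] * n)
        tab = change_frequency_table(labels, strata)
        sd = 100 * np.sqrt(0.5 * 0.5 / n + 0.25 * 0.75 / n)
        diff = tab.loc["DOWN", "pct_binding"] - tab.loc["DOWN", "pct_nonbinding"]
        assert abs(diff - 25.0) <= 3 * sd
        assert tab.loc["DOWN", "fisher_p"] < 1e-6

    def test_empty_stratum_warns_and_gives_missing_p(self):
        labels = pd.Series(["DOWN", "NONE"])
        strata = pd.Series([True, True])
        with pytest.warns(UserWarning, match="empty stratum"):
            tab = change_frequency_table(labels, strata)
        assert np.isnan(tab.loc["DOWN", "fisher_p"])


def test_depletion_down_calls_more_frequent_in_bound_gene_bodies(study):
    """On synthetic depletion data the DOWN-in-body frequency among
    cohesin-bound units exceeds that among unbound units (directional
    recovery of the designed body-specific effect)."""
    from pausedelta.synthetic_data import simulate_chip

    genome = study.genome
    treated, _ = simulate_chip(genome.truth, "Rpb3", "depleted", 501)
    control, _ = simulate_chip(genome.truth, "Rpb3", "control", 502)
    calls = call_change_intervals(treated, control)
    act = study.active[study.active].index
    body = genome.regions.body_intervals()
    regions = {u: body[u] for u in act if u in body}
    labels = classify_region_changes(calls, regions)
    bound = genome.truth.units["cohesin_bound"].reindex(labels.index)
    tab = change_frequency_table(labels, bound)
    assert tab.loc["DOWN", "pct_binding"] > tab.loc["DOWN", "pct_nonbinding"]
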