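import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promtarget import scoring
from promtarget.core import ConfigError, PromoterModel, ValidationError
from conftest import make_probe_row, random_probe_track


def brute_force_window_median(probes, values, window):
    """O(n^2) reference: median over same-chromosome midpoints within w/2."""
    out = {}
    for p in probes:
        members = [
            values[q.probe_id]
            for q in probes
            if q.chrom == p.chrom and abs(q.midpoint - p.midpoint) <= window / 2
        ]
        out[p.probe_id] = float(np.median(members))
    return pd.Series(out)


class TestGlobalMedianNormalize:
    def test_control_median_zero_after_shift(self):
        values = pd.Series({"c1": 0.5, "c2": 0.7, "c3": 0.9, "p1": 2.0})
        out = scoring.global_median_normalize(values, ["c1", "c2", "c3"])
        assert out["p1"] == pytest.approx(2.0 - 0.7)
        assert np.median(out[["c1", "c2", "c3"]]) == pytest.approx(0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(size=50), index=[f"p{i}" for i in range(50)])
        controls = [f"p{i}" for i in range(10)]
        a = scoring.global_median_normalize(values, controls)
        b = scoring.global_median_normalize(values + 3.7, controls)
        assert np.allclose(a, b)

    def test_even_control_count_uses_middle_mean(self):
        values = pd.Series({"c1": 1.0, "c2": 2.0, "c3": 10.0, "c4": 20.0})
        out = scoring.global_median_normalize(values, list(values.index))
        assert out["c1"] == pytest.approx(1.0 - 6.0)

    def test_no_controls_requires_explicit_fallback(self):
        values = pd.Series({"p1": 1.0, "p2": 3.0})
        with pytest.raises(ValidationError, match="fallback"):
            scoring.global_median_normalize(values, [])
        out = scoring.global_median_normalize(values, [], fallback_all_probes=True)
        assert out["p1"] == pytest.approx(-1.0)


class TestSmoothWindowMedian:
    def test_constant_values_unchanged(self):
        probes = [make_probe_row(f"p{i}", "chr1", 1000 + 100 * i, 60, "g") for i in range(10)]
        values = pd.Series(3.25, index=[p.probe_id for p in probes])
        out = scoring.smooth_window_median(probes, values)
        assert np.allclose(out, 3.25)

    def test_five_probe_toy_all_smoothed_to_two(self, five_probe_promoter):
        _, probes, values = five_probe_promoter
        out = scoring.smooth_window_median(probes, values)
        assert np.allclose(out[[p.probe_id for p in probes]], 2.0)

    def test_isolated_probe_keeps_own_value(self):
        probes = [
            make_probe_row("p0", "chr1", 1000, 60, "g"),
            make_probe_row("p1", "chr1", 5000, 60, "g"),
        ]
        values = pd.Series({"p0": 4.0, "p1": -2.0})
        out = scoring.smooth_window_median(probes, values)
        assert out["p0"] == 4.0 and out["p1"] == -2.0

    def test_no_smoothing_across_chromosomes(self):
        probes = [
            make_probe_row("a1", "chr1", 1000, 60, "g1"),
            make_probe_row("a2", "chr1", 1100, 60, "g1"),
            make_probe_row("b1", "chr2", 1000, 60, "g2"),
        ]
        values = pd.Series({"a1": 0.0, "a2": 10.0, "b1": 100.0})
        out = scoring.smooth_window_median(probes, values)
        assert out["a1"] == 5.0  # even-count median of chr1 pair only
        assert out["b1"] == 100.0

    def test_unsorted_input_is_an_error(self):
        probes = [
            make_probe_row("p1", "chr1", 1100, 60, "g"),
            make_probe_row("p0", "chr1", 1000, 60, "g"),
        ]
        values = pd.Series({"p0": 1.0, "p1": 2.0})
        with pytest.raises(ValidationError, match="sorted"):
            scoring.smooth_window_median(probes, values)

    def test_boundary_probe_included(self):
        # midpoints exactly window/2 apart are in each other's windows
        probes = [
            make_probe_row("p0", "chr1", 1000, 60, "g"),
            make_probe_row("p1", "chr1", 1200, 60, "g"),
        ]
        values = pd.Series({"p0": 0.0, "p1": 10.0})
        out = scoring.smooth_window_median(probes, values, window=400)
        assert out["p0"] == 5.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=120))
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        probes, values = random_probe_track(rng, n)
        fast = scoring.smooth_window_median(probes, values)
        slow = brute_force_window_median(probes, values, 400)
        assert np.allclose(fast[slow.index], slow)


class TestMax400:
    def test_five_probe_toy_max_is_two(self, five_probe_promoter):
        prom, probes, values = five_probe_promoter
        smoothed = scoring.smooth_window_median(probes, values)
        rec = scoring.max400_score(prom, probes, smoothed, "rep1")
        assert rec.max400 == pytest.approx(2.0)

    def test_single_probe_promoter(self):
        prom = PromoterModel.from_tss("g1", "chr1", "+", 10_000)
        probes = [make_probe_row("p0", "chr1", 9_900, 60, "g1")]
        rec = scoring.max400_score(prom, probes, {"p0": 1.5}, "rep1")
        assert rec.max400 == 1.5 and rec.peak_probe_id == "p0"

    def test_tie_goes_to_tss_nearest_probe(self):
        prom = PromoterModel.from_tss("g1", "chr1", "+", 10_000)
        probes = [
            make_probe_row("far", "chr1", 9_000, 60, "g1"),
            make_probe_row("near", "chr1", 9_900, 60, "g1"),
        ]
        rec = scoring.max400_score(prom, probes, {"far": 2.0, "near": 2.0}, "rep1")
        assert rec.peak_probe_id == "near"

    def test_zero_probes_yields_missing_record(self):
        prom = PromoterModel.from_tss("g1", "chr1", "+", 10_000)
        assert scoring.max400_score(prom, [], {}, "rep1") is None

    def test_adding_constant_shifts_every_score(self):
        rng = np.random.default_rng(3)
        prom = PromoterModel.from_tss("g1", "chr1", "+", 10_000)
        probes = [make_probe_row(f"p{i}", "chr1", 8_000 + 100 * i, 60, "g1") for i in range(20)]
        values = pd.Series(rng.normal(size=20), index=[p.probe_id for p in probes])
        base = scoring.max400_score(prom, probes, scoring.smooth_window_median(probes, values), "r")
        shifted = scoring.max400_score(
            prom, probes, scoring.smooth_window_median(probes, values + 1.25), "r"
        )
        assert shifted.max400 == pytest.approx(base.max400 + 1.25)
        assert shifted.peak_probe_id == base.peak_probe_id

    def test_invariant_to_probe_input_order(self):
        rng = np.random.default_rng(4)
        prom = PromoterModel.from_tss("g1", "chr1", "+", 10_000)
        probes = [make_probe_row(f"p{i}", "chr1", 8_000 + 100 * i, 60, "g1") for i in range(15)]
        values = pd.Series(rng.normal(size=15), index=[p.probe_id for p in probes])
        smoothed = scoring.smooth_window_median(probes, values)
        recs = [
            scoring.max400_score(prom, list(perm), smoothed, "r")
            for perm in (probes, probes[::-1])
        ]
        assert recs[0] == recs[1]


class TestTopKConsensus:
    def _records(self, scores):
        from promtarget.core import Max400Record

        return [Max400Record(pid, "rep1", s, f"{pid}_p", 0.0) for pid, s in scores.items()]

    def test_k_at_least_n_returns_all(self):
        recs = self._records({"a": 1.0, "b": 2.0})
        assert scoring.top_k(recs, 10) == {"a", "b"}

    def test_distinct_scores_match_sort_oracle(self):
        rng = np.random.default_rng(9)
        scores = {f"g{i}": float(s) for i, s in enumerate(rng.permutation(200))}
        recs = self._records(scores)
        oracle = {g for g, _ in sorted(scores.items(), key=lambda kv: -kv[1])[:50]}
        assert scoring.top_k(recs, 50) == oracle

    def test_boundary_ties_break_by_id(self):
        recs = self._records({"b": 1.0, "a": 1.0, "c": 2.0})
        assert scoring.top_k(recs, 2) == {"c", "a"}

    def test_identical_sets_consensus(self):
        calls = scoring.consensus([{"a", "b"}, {"a", "b"}, {"a", "b"}], m=2)
        assert scoring.consensus_members(calls) == {"a", "b"}
        assert all(c.n_support == 3 for c in calls)

    def test_pairwise_disjoint_sets_empty_consensus(self):
        calls = scoring.consensus([{"a"}, {"b"}, {"c"}], m=2)
        assert scoring.consensus_members(calls) == set()
        assert {c.promoter_id for c in calls} == {"a", "b", "c"}

    def test_m_greater_than_n_is_config_error(self):
        with pytest.raises(ConfigError):
            scoring.consensus([{"a"}, {"b"}], m=3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_sets_match_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(30)]
        sets = [set(rng.choice(universe, size=rng.integers(0, 20), replace=False)) for _ in range(3)]
        calls = scoring.consensus(sets, m=2)
        union = sets[0] | sets[1] | sets[2]
        oracle = {g for g in union if sum(g in s for s in sets) >= 2}
        assert scoring.consensus_members(calls) == oracle
        for c in calls:
            assert c.n_support == sum(c.promoter_id in s for s in sets)
        # size bounds
        members = scoring.consensus_members(calls)
        assert len(members) <= sum(len(s) for s in sets)
        assert members >= (sets[0] & sets[1] & sets[2])
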