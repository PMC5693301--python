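"""Tests for detection scoring and condition comparisons."""

import numpy as np
import pytest

from tebench.evaluation import (PairCall, classify_detections,
                                compare_conditions_counts,
                                compare_conditions_delays, delay_deviation,
                                summaries_to_frame)
from tebench.models import CouplingGraph

GRAPH = CouplingGraph(
    nodes=("A", "B", "C", "D"),
    direct_edges=(("A", "B", 4, 0.4), ("B", "C", 6, 0.4)),
)
# indirect: A->C; unconnected: the remaining 9 ordered pairs


def calls_from(sig_pairs, u_stars=None):
    u_stars = u_stars or {}
    calls = {}
    for s in GRAPH.nodes:
        for t in GRAPH.nodes:
            if s != t:
                calls[(s, t)] = PairCall(significant=(s, t) in sig_pairs,
                                         u_star=u_stars.get((s, t), 1))
    return calls


class TestClassify:
    def test_perfect_calls(self):
        calls = calls_from({("A", "B"), ("B", "C"), ("A", "C")},
                           {("A", "B"): 4, ("B", "C"): 6})
        s = classify_detections([calls], GRAPH)
        assert s.fndc == 0.0
        assert s.fnic == 0.0
        assert s.fp == 0.0
        assert s.delay_dev_mean == 0.0

    def test_no_calls_at_all(self):
        s = classify_detections([calls_from(set())], GRAPH)
        assert s.fndc == 100.0
        assert s.fnic == 100.0
        assert s.fp == 0.0
        assert np.isnan(s.delay_dev_mean)

    def test_fnic_fraction_arithmetic(self):
        """1 of 4 expected indirect detections -> FNIC = 75%."""
        datasets = [calls_from({("A", "C")})] + \
                   [calls_from(set())] * 3
        s = classify_detections(datasets, GRAPH)
        assert s.fnic == 75.0

    def test_missing_pair_raises(self):
        calls = calls_from(set())
        del calls[("D", "A")]
        with pytest.raises(ValueError, match="missing pair"):
            classify_detections([calls], GRAPH)

    def test_fp_counts_unconnected_including_reversals(self):
        s = classify_detections([calls_from({("B", "A")})], GRAPH)
        assert s.n_fp_pairs == 9
        assert s.n_fp_detected == 1

    def test_fp_mode_including_indirect(self):
        calls = calls_from({("A", "C")})
        s = classify_detections([calls], GRAPH, fp_includes_indirect=True)
        assert s.n_fp_pairs == 10
        assert s.n_fp_detected == 1

    def test_excess_indirect_not_negative_fnic(self):
        """More indirect detections than expected clamps FNIC at 0 and
        tracks the excess separately."""
        g = CouplingGraph(nodes=("A", "B", "C"),
                          direct_edges=(("A", "B", 2, 1.0),
                                        ("B", "C", 2, 1.0)))
        calls = {(s, t): PairCall(significant=True, u_star=2)
                 for s in g.nodes for t in g.nodes if s != t}
        # expected indirect = 1 (A->C); force a second "dataset" whose
        # expected count is already saturated
        s = classify_detections([calls], g)
        assert s.fnic == 0.0
        assert s.excess_indirect == 0

    def test_percentages_recomputable_from_counts(self):
        datasets = [calls_from({("A", "B")}), calls_from({("B", "C")})]
        s = classify_detections(datasets, GRAPH)
        assert s.fndc == 100.0 * (s.n_direct_expected - s.n_direct_detected) \
            / s.n_direct_expected
        row = s.to_row()
        assert row["fndc_pct"] == s.fndc


class TestDelayDeviation:
    def test_exact_estimates_give_zero(self):
        calls = calls_from({("A", "B"), ("B", "C")},
                           {("A", "B"): 4, ("B", "C"): 6})
        assert delay_deviation([calls], GRAPH) == 0.0

    def test_single_connection_arithmetic(self):
        calls = calls_from({("B", "C")}, {("B", "C"): 4})
        assert delay_deviation([calls], GRAPH) == 2.0

    def test_mean_over_datasets_and_connections(self):
        """Deviations {1,2,0,1} over 2 datasets x 2 connections -> 1.0."""
        d1 = calls_from({("A", "B"), ("B", "C")},
                        {("A", "B"): 5, ("B", "C"): 8})   # devs 1, 2
        d2 = calls_from({("A", "B"), ("B", "C")},
                        {("A", "B"): 4, ("B", "C"): 7})   # devs 0, 1
        assert delay_deviation([d1, d2], GRAPH) == 1.0

    def test_undetected_connections_yield_nan_marker(self):
        assert np.isnan(delay_deviation([calls_from(set())], GRAPH))

    def test_decimated_expected_delays(self):
        """At decimation 2 the modeled delays become 2 and 3 samples; a
        delay of 4/10 would be undetectable by design."""
        calls = calls_from({("A", "B"), ("B", "C")},
                           {("A", "B"): 2, ("B", "C"): 3})
        assert delay_deviation([calls], GRAPH, decimation=2) == 0.0
        s = classify_detections([calls_from({("A", "B")},
                                            {("A", "B"): 1})],
                                GRAPH, decimation=10)
        assert s.n_undetectable_delays == 1
        assert s.delay_deviations == []


class TestFisherComparison:
    def make_summary(self, detected, total):
        calls_list = []
        # build via direct counts: reuse classify on synthetic calls
        g = GRAPH
        per_ds = []
        for i in range(total // 2):
            sig = set()
            if detected > 0:
                sig.add(("A", "B"))
                detected -= 1
            if detected > 0:
                sig.add(("B", "C"))
                detected -= 1
            per_ds.append(calls_from(sig))
        return classify_detections(per_ds, g)

    def test_identical_tables_p_one(self):
        a = self.make_summary(10, 20)
        res = compare_conditions_counts(a, a, n_comparisons=1)
        assert res.p_value == 1.0
        assert not res.significant

    def test_extreme_tables_significant(self):
        a = self.make_summary(100, 100)
        b = self.make_summary(0, 100)
        res = compare_conditions_counts(a, b, n_comparisons=1)
        assert res.p_value < 1e-20
        assert res.significant

    def test_two_sided_symmetry(self):
        a = self.make_summary(30, 100)
        b = self.make_summary(60, 100)
        p1 = compare_conditions_counts(a, b).p_value
        p2 = compare_conditions_counts(b, a).p_value
        assert p1 == pytest.approx(p2)

    def test_bonferroni_threshold(self):
        a = self.make_summary(30, 100)
        b = self.make_summary(52, 100)
        r1 = compare_conditions_counts(a, b, n_comparisons=1)
        r50 = compare_conditions_counts(a, b, n_comparisons=50)
        assert r1.alpha_adjusted == 0.05
        assert r50.alpha_adjusted == 0.001
        if r1.p_value > 0.001:
            assert not r50.significant


class TestRankSumComparison:
    def test_identical_samples_maximal_p(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_conditions_delays(a, a)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(5, 6, 20)
        res = compare_conditions_delays(a, b)
        assert res.significant

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 2, 15)
        b = rng.uniform(1.5, 2.5, 15)
        p_raw = compare_conditions_delays(a, b).p_value
        p_log = compare_conditions_delays(np.log(a), np.log(b)).p_value
        assert p_raw == pytest.approx(p_log)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions_delays([], [1.0])


def test_summaries_to_frame_roundtrip():
    s = classify_detections([calls_from({("A", "B")})], GRAPH,
                            condition="demo")
    df = summaries_to_frame([s])
    assert df.loc[0, "condition"] == "demo"
    assert df.loc[0, "fndc_pct"] == 50.0
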