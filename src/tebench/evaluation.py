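"""Scoring of significant-edge calls against the ground-truth graph.

Four summary parameters per condition:

FNDC
    False negative direct connections, as a percentage of all simulated
    direct connections (edges x datasets).
FNIC
    False negative indirect connections, 100 * (1 - p_est / p_exp) from
    detected vs expected positive indirect pairs; clamped to [0, 100]
    with excess detections tracked separately.
FP
    False positives, as a percentage of unconnected ordered pairs
    (indirect pairs are scored by FNIC, not FP, by default; a comparison
    mode counts detected indirect pairs as FP as some earlier
    Granger-causality benchmarks did).
dd
    Mean absolute deviation of the estimated from the modeled
    interaction delay, over detected direct connections only.  For
    decimated data the modeled delay is re-expressed at the reduced
    sampling rate; delays that round below one sample are undetectable
    by design and excluded from delay scoring.

Condition comparisons use Fisher's exact test on the detection counts
and the Wilcoxon rank-sum test on per-dataset delay deviations, both
two-sided with Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CouplingGraph

__all__ = ["PairCall", "DetectionSummary", "classify_detections",
           "delay_deviation", "compare_conditions_counts",
           "compare_conditions_delays", "ComparisonResult",
           "summaries_to_frame"]


@dataclasses.dataclass(frozen=True)
class PairCall:
    """Outcome of significance testing for one ordered channel pair."""

    significant: bool
    u_star: int | None = None
    p_value: float | None = None
    te_mean: float | None = None


@dataclasses.dataclass
class DetectionSummary:
    """Detection-error summary for one condition, with the raw counts
    from which every percentage can be recomputed."""

    condition: str
    n_datasets: int
    # direct
    n_direct_expected: int
    n_direct_detected: int
    # indirect
    n_indirect_expected: int
    n_indirect_detected: int
    # false positives
    n_fp_pairs: int
    n_fp_detected: int
    fp_includes_indirect: bool
    # delay deviations of detected direct connections
    delay_deviations: list[float]
    per_dataset_delay_dev: list[float]
    n_undetectable_delays: int = 0

    @property
    def fndc(self) -> float:
        missed = self.n_direct_expected - self.n_direct_detected
        return 100.0 * missed / self.n_direct_expected

    @property
    def fnic(self) -> float:
        if self.n_indirect_expected == 0:
            return float("nan")
        raw = 100.0 * (1.0 - self.n_indirect_detected
                       / self.n_indirect_expected)
        return float(np.clip(raw, 0.0, 100.0))

    @property
    def excess_indirect(self) -> int:
        """Indirect detections beyond the expected count (not negative
        FNIC; tracked separately)."""
        return max(0, self.n_indirect_detected - self.n_indirect_expected)

    @property
    def fp(self) -> float:
        if self.n_fp_pairs == 0:
            return float("nan")
        return 100.0 * self.n_fp_detected / self.n_fp_pairs

    @property
    def delay_dev_mean(self) -> float:
        if not self.delay_deviations:
            return float("nan")
        return float(np.mean(self.delay_deviations))

    @property
    def delay_dev_sd(self) -> float:
        if len(self.per_dataset_delay_dev) < 2:
            return float("nan")
        return float(np.std(self.per_dataset_delay_dev, ddof=1))

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "n_datasets": self.n_datasets,
            "fndc_pct": self.fndc,
            "fnic_pct": self.fnic,
            "fp_pct": self.fp,
            "delay_dev_mean": self.delay_dev_mean,
            "delay_dev_sd": self.delay_dev_sd,
            "n_direct_expected": self.n_direct_expected,
            "n_direct_detected": self.n_direct_detected,
            "n_indirect_expected": self.n_indirect_expected,
            "n_indirect_detected": self.n_indirect_detected,
            "n_fp_pairs": self.n_fp_pairs,
            "n_fp_detected": self.n_fp_detected,
            "excess_indirect": self.excess_indirect,
            "n_undetectable_delays": self.n_undetectable_delays,
        }


def _decimated_delay(delay: int, decimation: int) -> int:
    """Modeled delay at the post-decimation sampling rate (0 if it
    rounds below one sample, i.e. undetectable by design)."""
    return int(round(delay / decimation))


def _restrict(pairs: Sequence[tuple[str, str]],
              allowed: set[tuple[str, str]] | None):
    if allowed is None:
        return list(pairs)
    return [p for p in pairs if p in allowed]


def classify_detections(calls_per_dataset: Sequence[Mapping[tuple[str, str],
                                                            PairCall]],
                        graph: CouplingGraph,
                        condition: str = "",
                        decimation: int = 1,
                        pairs: Sequence[tuple[str, str]] | None = None,
                        fp_includes_indirect: bool = False
                        ) -> DetectionSummary:
    """Score one condition's calls (one mapping per dataset) against the
    ground truth.

    ``pairs`` restricts scoring to a subset of ordered pairs (e.g. one
    branch of a larger network); by default every ordered pair of the
    graph must be present in every dataset's calls, and a missing pair
    raises.
    """
    allowed = set(pairs) if pairs is not None else None
    direct = [(s, t, d) for s, t, d, _w in graph.direct_edges
              if allowed is None or (s, t) in allowed]
    indirect = _restrict(graph.indirect_pairs(), allowed)
    unconnected = _restrict(graph.unconnected_pairs(), allowed)
    fp_pairs = unconnected + (indirect if fp_includes_indirect else [])

    required = [(s, t) for s, t, _d in direct] + indirect + unconnected
    n_ds = len(calls_per_dataset)
    n_direct_detected = 0
    n_indirect_detected = 0
    n_fp_detected = 0
    deviations: list[float] = []
    per_ds_dev: list[float] = []
    n_undetectable = 0
    for calls in calls_per_dataset:
        for p in required:
            if p not in calls:
                raise ValueError(f"calls are missing pair {p}")
        ds_devs = []
        for s, t, d in direct:
            call = calls[(s, t)]
            if call.significant:
                n_direct_detected += 1
                d_exp = _decimated_delay(d, decimation)
                if d_exp < 1:
                    n_undetectable += 1
                elif call.u_star is not None:
                    dev = abs(call.u_star - d_exp)
                    deviations.append(dev)
                    ds_devs.append(dev)
        if ds_devs:
            per_ds_dev.append(float(np.mean(ds_devs)))
        n_indirect_detected += sum(calls[p].significant for p in indirect)
        n_fp_detected += sum(calls[p].significant for p in fp_pairs)
    return DetectionSummary(
        condition=condition,
        n_datasets=n_ds,
        n_direct_expected=len(direct) * n_ds,
        n_direct_detected=n_direct_detected,
        n_indirect_expected=len(indirect) * n_ds,
        n_indirect_detected=n_indirect_detected,
        n_fp_pairs=len(fp_pairs) * n_ds,
        n_fp_detected=n_fp_detected,
        fp_includes_indirect=fp_includes_indirect,
        delay_deviations=deviations,
        per_dataset_delay_dev=per_ds_dev,
        n_undetectable_delays=n_undetectable,
    )


def delay_deviation(calls_per_dataset, graph: CouplingGraph,
                    decimation: int = 1,
                    pairs: Sequence[tuple[str, str]] | None = None) -> float:
    """Mean |estimated - modeled| interaction delay (samples) over
    detected direct connections across datasets; NaN (undefined-result
    marker) if no direct connection was detected."""
    summary = classify_detections(calls_per_dataset, graph,
                                  decimation=decimation, pairs=pairs)
    return summary.delay_dev_mean


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    significant: bool
    alpha_adjusted: float
    statistic: float | None = None
    table: tuple | None = None


def _counts_for(summary: DetectionSummary, metric: str) -> tuple[int, int]:
    if metric == "fndc":
        det = summary.n_direct_detected
        tot = summary.n_direct_expected
    elif metric == "fnic":
        det = min(summary.n_indirect_detected, summary.n_indirect_expected)
        tot = summary.n_indirect_expected
    elif metric == "fp":
        det = summary.n_fp_detected
        tot = summary.n_fp_pairs
    else:
        raise ValueError("metric must be one of fndc, fnic, fp")
    return det, tot - det


def compare_conditions_counts(summary_a: DetectionSummary,
                              summary_b: DetectionSummary,
                              n_comparisons: int = 1,
                              metric: str = "fndc",
                              alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Fisher's exact test on the 2x2 detection table of one
    metric, with Bonferroni-adjusted alpha = 0.05 / n_comparisons."""
    a = _counts_for(summary_a, metric)
    b = _counts_for(summary_b, metric)
    if sum(a) == 0 or sum(b) == 0:
        raise ValueError("cannot compare conditions with zero total counts")
    table = (a, b)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    alpha_adj = alpha / n_comparisons
    return ComparisonResult(p_value=float(p), significant=bool(p <= alpha_adj),
                            alpha_adjusted=alpha_adj, statistic=float(odds),
                            table=table)


def compare_conditions_delays(devs_a: Sequence[float],
                              devs_b: Sequence[float],
                              n_comparisons: int = 1,
                              alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test on per-dataset delay deviations,
    Bonferroni-adjusted."""
    a = np.asarray(devs_a, dtype=float)
    b = np.asarray(devs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    stat, p = stats.ranksums(a, b)
    alpha_adj = alpha / n_comparisons
    return ComparisonResult(p_value=float(p), significant=bool(p <= alpha_adj),
                            alpha_adjusted=alpha_adj, statistic=float(stat))


def summaries_to_frame(summaries: Sequence[DetectionSummary]) -> pd.DataFrame:
    """Tabulate detection summaries, one condition per row."""
    return pd.DataFrame([s.to_row() for s in summaries])
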