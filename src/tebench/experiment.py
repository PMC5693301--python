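"""End-to-end benchmark orchestration.

A :class:`Condition` bundles a model, a preprocessing chain and the
estimation/inference settings.  :func:`run_condition` executes, per
dataset: simulate -> preprocess -> optimize embeddings on the
preprocessed data -> scan candidate delays for every analyzed ordered
pair -> trial-shuffle surrogates + permutation test -> score against the
ground-truth graph.  :func:`run_benchmark` sweeps a condition grid and
compares each condition against a control with Fisher's exact /
Wilcoxon rank-sum tests under Bonferroni correction.

Default scale knobs are desk-scale; ``full_fidelity()`` restores the
full protocol (100 datasets, 20 trials, 190100 permutations).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import (DetectionSummary, PairCall, classify_detections,
                         compare_conditions_counts, compare_conditions_delays,
                         summaries_to_frame)
from .inference import (FULL_PROTOCOL_N_PERM, make_trial_surrogates,
                        scan_permutation_test)
from .models import CouplingGraph, ModelSpec, TrialEnsemble, simulate
from .preprocessing import FilterSpec, apply_filter, decimate_ensemble
from .state_space import (DEFAULT_D_RANGE, DEFAULT_TAU_FACTORS, act_ensemble,
                          optimize_embedding)
from .te import TEConfig, TEScanResult, scan_delays, te_spo

__all__ = ["Condition", "ConditionResult", "BenchmarkResult", "run_condition",
           "run_benchmark", "clmm_branch_pairs", "full_fidelity"]

logger = logging.getLogger("tebench")


@dataclasses.dataclass(frozen=True)
class Condition:
    """One fully reproducible benchmark condition.

    ``model.n_samples`` is the post-preprocessing trial length; with
    ``decimation`` r > 1 the simulation runs r times longer so decimated
    trials keep that length.  ``pairs`` restricts the analysis to a
    subset of ordered channel pairs (None = all ordered pairs).
    ``seed`` determines simulation, estimator jitter, surrogate
    shuffling and the permutation null.
    """

    name: str
    model: ModelSpec
    filters: tuple[FilterSpec, ...] = ()
    decimation: int = 1
    u_range: tuple[int, ...] = tuple(range(1, 11))
    k: int = 4
    n_perm: int = 10_000
    alpha: float = 0.05
    d_range: tuple[int, ...] = DEFAULT_D_RANGE
    tau_factors: tuple[float, ...] = DEFAULT_TAU_FACTORS
    max_theiler: int = 100
    ragwitz_max_points: int | None = 600
    pairs: tuple[tuple[str, str], ...] | None = None
    seed: int = 0


@dataclasses.dataclass
class ConditionResult:
    condition: Condition
    graph: CouplingGraph
    calls_per_dataset: list[dict[tuple[str, str], PairCall]]
    summary: DetectionSummary
    scans: list[dict[tuple[str, str], TEScanResult]]
    completed_fraction: float
    embeddings: list[dict]


def full_fidelity(cond: Condition) -> Condition:
    """Restore the full-fidelity protocol scale for a condition."""
    model = dataclasses.replace(cond.model, n_datasets=100, n_trials=20)
    return dataclasses.replace(cond, model=model,
                               n_perm=FULL_PROTOCOL_N_PERM,
                               ragwitz_max_points=None)


def clmm_branch_pairs(m: int, include_unconnected: int = 0
                      ) -> tuple[tuple[str, str], ...]:
    """Ordered pairs of one branch of the logistic-map network: its five
    direct edges, three indirect pairs, and optionally the first few
    unconnected pairs within the branch (reversals)."""
    if m not in (1, 2, 3):
        raise ValueError("branch index must be 1, 2 or 3")
    ns, c2, c3, c4 = f"Xns{m}", f"X{m}2", f"X{m}3", f"X{m}4"
    direct = [(ns, c2), (c2, c3), (c2, c4), (c3, c4), (c2, "Xi")]
    indirect = [(ns, c3), (ns, c4), (ns, "Xi")]
    unconnected = [(c2, ns), (c3, c2), (c4, c2), (c4, c3), ("Xi", c2),
                   (c3, ns), (c4, ns), ("Xi", ns), (c3, "Xi"), (c4, "Xi")]
    return tuple(direct + indirect + unconnected[:include_unconnected])


def _all_ordered_pairs(nodes: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple((s, t) for s in nodes for t in nodes if s != t)


def _preprocess(ens: TrialEnsemble, cond: Condition) -> TrialEnsemble:
    for f in cond.filters:
        ens = apply_filter(ens, f)
    if cond.decimation != 1:
        ens = decimate_ensemble(ens, cond.decimation)
    return ens


def _analyze_dataset(data: np.ndarray, graph: CouplingGraph,
                     channels: Sequence[str], cond: Condition,
                     rng: np.random.Generator
                     ) -> tuple[dict, dict, dict]:
    """Embedding optimization, delay scans and permutation tests for one
    dataset; ``data`` is (n_trials, n_channels, n_samples)."""
    pairs = cond.pairs if cond.pairs is not None else _all_ordered_pairs(channels)
    needed = sorted({c for p in pairs for c in p})
    idx = {c: channels.index(c) for c in needed}
    embeddings, acts = {}, {}
    for c in needed:
        trials = data[:, idx[c], :]
        a = min(act_ensemble(trials), cond.max_theiler)
        emb = optimize_embedding(trials, act_value=a, d_range=cond.d_range,
                                 tau_factors=cond.tau_factors, k_neighbors=4,
                                 theiler=a, max_points=cond.ragwitz_max_points)
        embeddings[c], acts[c] = emb, a
    calls: dict[tuple[str, str], PairCall] = {}
    scans: dict[tuple[str, str], TEScanResult] = {}
    for s, t in pairs:
        W = max(acts[s], acts[t])
        cfg = TEConfig(k=cond.k, u_range=tuple(cond.u_range),
                       theiler_window=W,
                       jitter_seed=int(rng.integers(2**31)))
        src = data[:, idx[s], :]
        tgt = data[:, idx[t], :]
        scan = scan_delays(src, tgt, embeddings[s], embeddings[t], cfg, rng)
        # the surrogate pairing goes through the identical delay scan, and
        # the permutation test repeats the max-over-u selection inside
        # every permutation, keeping the test calibrated despite the scan
        surr_tgt = make_trial_surrogates(tgt, rng)
        surr_scan = scan_delays(src, surr_tgt, embeddings[s], embeddings[t],
                                cfg, rng)
        pres = scan_permutation_test(scan.per_trial_te,
                                     surr_scan.per_trial_te,
                                     n_perm=cond.n_perm, alpha=cond.alpha,
                                     rng=rng)
        calls[(s, t)] = PairCall(significant=pres.significant,
                                 u_star=scan.u_star, p_value=pres.p_value,
                                 te_mean=float(scan.te_at_u_star.mean()))
        scans[(s, t)] = scan
    return calls, scans, {c: embeddings[c] for c in needed}


def run_condition(cond: Condition,
                  fp_includes_indirect: bool = False) -> ConditionResult:
    """Run one condition end to end over all of its datasets.

    A failure inside one dataset is logged and skipped; the result
    reports the completed fraction.
    """
    sim_spec = dataclasses.replace(
        cond.model,
        n_samples=cond.model.n_samples * cond.decimation,
        rng_seed=cond.seed)
    t_start = time.perf_counter()
    ens, graph = simulate(sim_spec)
    ens = _preprocess(ens, cond)
    logger.info("condition %s: simulated+preprocessed %d datasets in %.1fs",
                cond.name, ens.n_datasets, time.perf_counter() - t_start)
    rng = np.random.default_rng(np.random.SeedSequence([cond.seed, 1]))
    calls_all, scans_all, emb_all = [], [], []
    n_failed = 0
    for i_ds in range(ens.n_datasets):
        t0 = time.perf_counter()
        try:
            calls, scans, embs = _analyze_dataset(
                ens.values[i_ds], graph, list(ens.channels), cond, rng)
        except Exception:
            logger.exception("condition %s dataset %d failed; skipping",
                             cond.name, i_ds)
            n_failed += 1
            continue
        calls_all.append(calls)
        scans_all.append(scans)
        emb_all.append(embs)
        logger.info("condition %s dataset %d/%d done in %.1fs", cond.name,
                    i_ds + 1, ens.n_datasets, time.perf_counter() - t0)
    summary = classify_detections(calls_all, graph, condition=cond.name,
                                  decimation=cond.decimation,
                                  pairs=cond.pairs,
                                  fp_includes_indirect=fp_includes_indirect)
    return ConditionResult(condition=cond, graph=graph,
                           calls_per_dataset=calls_all, summary=summary,
                           scans=scans_all,
                           completed_fraction=1 - n_failed / ens.n_datasets,
                           embeddings=emb_all)


@dataclasses.dataclass
class BenchmarkResult:
    results: dict[str, ConditionResult]
    control: str
    summary_table: pd.DataFrame
    comparison_table: pd.DataFrame


def run_benchmark(conditions: Sequence[Condition], control: str,
                  alpha: float = 0.05) -> BenchmarkResult:
    """Run a condition grid and compare every condition against the
    control (Fisher's exact on FNDC/FNIC/FP counts, rank-sum on delay
    deviations), Bonferroni-corrected over the grid per metric."""
    names = [c.name for c in conditions]
    if control not in names:
        raise ValueError(f"control condition {control!r} not in the grid")
    results = {c.name: run_condition(c) for c in conditions}
    summary_table = summaries_to_frame([r.summary for r in results.values()])
    ctrl = results[control].summary
    ctrl_devs = results[control].summary.per_dataset_delay_dev
    n_cmp = max(1, len(conditions) - 1)
    rows = []
    for name, res in results.items():
        if name == control:
            continue
        row: dict = {"condition": name}
        for metric in ("fndc", "fnic", "fp"):
            try:
                cmp_res = compare_conditions_counts(res.summary, ctrl, n_cmp,
                                                    metric=metric, alpha=alpha)
                row[f"{metric}_p"] = cmp_res.p_value
                row[f"{metric}_significant"] = cmp_res.significant
            except ValueError:
                row[f"{metric}_p"] = float("nan")
                row[f"{metric}_significant"] = False
        devs = res.summary.per_dataset_delay_dev
        if devs and ctrl_devs:
            cmp_res = compare_conditions_delays(devs, ctrl_devs, n_cmp,
                                                alpha=alpha)
            row["delay_p"] = cmp_res.p_value
            row["delay_significant"] = cmp_res.significant
        else:
            row["delay_p"] = float("nan")
            row["delay_significant"] = False
        rows.append(row)
    comparison_table = pd.DataFrame(rows)
    return BenchmarkResult(results=results, control=control,
                           summary_table=summary_table,
                           comparison_table=comparison_table)
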