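"""End-to-end synthetic study: simulate, quantify, group, compare.

``run_study`` executes the whole analysis on one simulated genome and
returns the headline summary statistics together with all intermediate
tables, so scripts and tests can drill into any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import chip_quant, crm_predict, efficiency_stats, proseq_quant
from .genome_model import GenomicInterval
from .proseq_quant import ReplicateTracks
from .synthetic_data import (SimulationConfig, SimulatedGenome, simulate_chip,
                             simulate_expression, simulate_genome,
                             simulate_proseq)


@dataclass
class StudyResult:
    summary: dict
    genome: SimulatedGenome
    quant: dict[str, pd.DataFrame]
    active: pd.Series
    groups: pd.Series
    pause: dict[str, pd.Series]
    efficiency: pd.DataFrame | None = None
    crm_summary: pd.DataFrame | None = None


def _seed_stream(seed: int):
    """Deterministic child seeds (< 2**31) for each stochastic stage."""
    ss = np.random.SeedSequence(seed)
    for s in ss.generate_state(32):
        yield int(s % (2 ** 31))


def run_study(config: SimulationConfig | None = None, seed: int = 0,
              n_replicates: int = 2) -> StudyResult:
    """Simulate a genome and run the full quantification/grouping analysis.

    Returns a :class:`StudyResult` whose ``summary`` holds the recovered
    statistics: the top/zero cohesin-group median pause-index ratio in
    control and after depletion, the median percent pause change at
    cohesin-free units, the PRO-seq replicate correlation, the extragenic
    CRM count and its cohesin-bound percentage, and the top/zero efficiency
    ratio.
    """
    config = config or SimulationConfig()
    seeds = _seed_stream(seed)
    genome = simulate_genome(config, next(seeds))
    truth = genome.truth

    # --- PRO-seq quantification, both conditions, replicate-averaged
    quant: dict[str, pd.DataFrame] = {}
    rep_rpm: dict[str, list[pd.Series]] = {}
    for cond in ("control", "depleted"):
        samples = [simulate_proseq(truth, cond, config.depth, next(seeds))
                   for _ in range(n_replicates)]
        reps = [ReplicateTracks(s.plus, s.minus, s.library_size) for s in samples]
        q = proseq_quant.quantify_regions(reps[0].plus, reps[0].minus,
                                          genome.regions,
                                          library_size=reps[0].library_size,
                                          replicates=reps[1:])
        quant[cond] = q
        per_rep = []
        for r in reps:
            qi = proseq_quant.quantify_regions(r.plus, r.minus, genome.regions,
                                               library_size=r.library_size)
            per_rep.append(qi["promoter_rpm"] + qi["body_rpm"])
        rep_rpm[cond] = per_rep
    active = proseq_quant.call_active(quant["control"])

    rep_r = float(stats.pearsonr(rep_rpm["control"][0],
                                 rep_rpm["control"][1]).statistic) \
        if n_replicates >= 2 else float("nan")

    # --- cohesin grouping from the simulated ChIP track
    coh_track, coh_calls = simulate_chip(truth, "cohesin", "control",
                                         next(seeds), with_calls=True)
    coh_regions = genome.regions.cohesin_intervals()
    uids = list(truth.units.index)
    scores = pd.Series(
        chip_quant.mean_region_score(coh_track, [coh_regions[u] for u in uids]),
        index=uids)
    groups = chip_quant.assign_cohesin_groups(scores)

    # --- pause indices and depletion effects
    pause = {c: proseq_quant.pause_index(quant[c]) for c in quant}
    act_idx = active[active].index

    def _group_ratio(pi: pd.Series) -> float:
        med = pi.loc[act_idx].groupby(groups.loc[act_idx]).median()
        return float(med["G4"] / med["G1"])

    ratio_control = _group_ratio(pause["control"])
    ratio_depleted = _group_ratio(pause["depleted"])

    promoters = genome.regions.promoter_intervals()
    bound = chip_quant.call_binding([promoters[u] for u in uids], calls=coh_calls)
    bound = pd.Series(bound, index=uids)
    unbound_active = act_idx.intersection(bound[~bound].index)
    pct_change = 100.0 * (pause["depleted"].loc[unbound_active]
                          / pause["control"].loc[unbound_active] - 1.0)
    median_pause_change_unbound = float(pct_change.median())

    summary = {
        "n_units": len(uids),
        "n_active": int(active.sum()),
        "replicate_pearson_r": rep_r,
        "pause_ratio_top_vs_zero_control": ratio_control,
        "pause_ratio_top_vs_zero_depleted": ratio_depleted,
        "median_pause_change_unbound_pct": median_pause_change_unbound,
    }

    # --- CRM prediction and occupancy
    crms = crm_predict.predict_crms(genome.features["dhs"],
                                    genome.features["k4me1"],
                                    genome.features["k27ac"])
    extragenic, _ = crm_predict.filter_extragenic(crms, genome.units)
    per_crm, crm_summary = crm_predict.crm_occupancy(
        extragenic, {"cohesin": coh_calls})
    summary["n_crms"] = len(crms)
    summary["n_extragenic_crms"] = len(extragenic)
    if len(extragenic):
        summary["extragenic_crm_cohesin_bound_pct"] = float(
            crm_summary.loc["cohesin", "pct_occupied"])

    # --- efficiency
    expr = simulate_expression(truth, next(seeds))
    mrna = efficiency_stats.aggregate_expression(
        expr.rename(columns={"signal": "signal"})[["gene_id", "signal"]])
    eff = efficiency_stats.efficiency_table(mrna, quant["control"])
    eff_active = eff.loc[eff.index.intersection(act_idx)]
    med = eff_active["efficiency_control"].groupby(
        groups.loc[eff_active.index]).median()
    summary["efficiency_ratio_top_vs_zero"] = float(med["G4"] / med["G1"])

    return StudyResult(summary=summary, genome=genome, quant=quant,
                       active=active, groups=groups, pause=pause,
                       efficiency=eff, crm_summary=crm_summary)
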