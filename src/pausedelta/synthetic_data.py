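"""Synthetic genomes with known ground truth for the full analysis pipeline.

The generator emulates the statistical structure of the real datasets the
pipeline is built for: a gene-dense chromosome of non-overlapping stranded
transcription units; promoter cohesin levels drawn from a zero-inflated
positive distribution and falling into four groups (edges 1/2/4 in MAT-score
units); promoter-proximal pause indices whose group medians rise with the
cohesin level (top/zero-group ratio 3.7 by default); stranded base-resolution
PRO-seq tracks with a pause peak downstream of the TSS; ~35-bp-spacing
tiling-array ChIP tracks built from triangular-kernel point sites and flat
occupancy blocks plus Gaussian noise; intergenic candidate regulatory
elements (DHS + H3K4me1 + H3K27ac) of which 96% bind cohesin; and a
multi-probe expression table whose mRNA-per-polymerase efficiency factor
doubles from the zero-cohesin to the top-cohesin group.

Depletion of the cohesin loader is modelled multiplicatively: promoter
PRO-seq density at cohesin-free units drops to 75% (a median 25% pause
decrease), while gene-body density at cohesin-bound units drops to ~57%,
which raises the top/zero pause-index ratio from 3.7 to 8.7.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_model import (BindingCallSet, GenomicInterval, RegionSet,
                           SignalTrack, TranscriptionUnit, derive_regions)

CONDITIONS = ("control", "depleted")
CHIP_FACTORS = ("cohesin", "Rpb3", "Ser2P", "CycT", "Cdk12", "H3K4me1", "H3K27ac")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.  Defaults are the study conditions."""

    n_units: int = 2000
    chrom: str = "chr2L"
    chrom_length: int | None = None          # derived from the layout if None
    # gene geometry
    gene_length_median: float = 2500.0
    gene_length_sigma: float = 0.5           # lognormal sigma
    min_gene_length: int = 600
    gap_min: int = 800
    gap_max: int = 2200
    # regions
    promoter_halfwidth: int = 100
    cohesin_halfwidth: int = 200
    # cohesin levels (MAT-score units), four groups at edges 1/2/4
    bin_fractions: tuple = (0.4, 0.2, 0.2, 0.2)
    zero_fraction_lowest: float = 0.7        # exact zeros within the lowest group
    edge_margin: float = 0.15                # keep levels clear of interior edges
    top_bin_scale: float = 2.0               # exponential tail above the top edge
    # pausing and transcription (top/zero median-PI ratio 3.7)
    bin_pi_medians: tuple = (2.0, 2.0 * 3.7 ** (1 / 3), 2.0 * 3.7 ** (2 / 3), 7.4)
    pi_sigma: float = 0.35                   # lognormal spread within a group
    body_density_median: float = 1.0         # arbitrary occupancy units / bp
    body_density_sigma: float = 0.6
    # depletion effects: (cohesin-free, cohesin-bound) multipliers
    depletion_promoter_mult: tuple = (0.75, 1.0)
    depletion_body_mult: tuple = (1.0, 3.7 / (0.75 * 8.7))
    # PRO-seq
    depth: int = 2_000_000                   # reads per replicate
    background_frac: float = 0.02
    pause_peak: tuple = (20, 60)             # offsets downstream of the TSS
    pause_decay: float = 0.12                # geometric decay across the peak
    antisense_fraction: float = 0.0          # divergent promoter transcription
                                             # as a fraction of promoter signal
    # ChIP
    probe_spacing: int = 35
    chip_noise_sd: float = 0.25
    kernel_halfwidth: int = 300
    binding_threshold: float = 1.5           # score units, on the noiseless track
    # CRMs
    n_crms: int = 60
    crm_fraction_near_tss: float = 0.25
    n_decoy_dhs: int = 30
    dhs_width: int = 150
    mark_halfwidth: int = 300
    crm_cohesin_bound_frac: float = 0.96
    crm_polii_bound_frac: float = 0.45
    # expression / efficiency (top group makes 2x the mRNA per polymerase)
    efficiency_factors: tuple = (1.0, 2 ** (1 / 3), 2 ** (2 / 3), 2.0)
    expression_noise_sigma: float = 0.25
    multi_probe_fraction: float = 0.5

    def validate(self) -> None:
        if not np.isclose(sum(self.bin_fractions), 1.0):
            raise ValueError("bin_fractions must sum to 1")
        if any(f < 0 for f in self.bin_fractions):
            raise ValueError("bin_fractions must be non-negative")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 <= self.background_frac < 1):
            raise ValueError("background_frac must be in [0, 1)")
        if not (0 <= self.crm_cohesin_bound_frac <= 1):
            raise ValueError("crm_cohesin_bound_frac must be a fraction")


@dataclass
class TruthTable:
    """Ground truth of one simulated genome.

    ``units`` has one row per transcription unit (coordinates, cohesin level
    and group, per-condition promoter/body densities and pause index,
    efficiency factor); ``crms`` one row per placed DHS (element coordinates,
    marks present, binding truth).
    """

    units: pd.DataFrame
    crms: pd.DataFrame
    chrom: str
    chrom_length: int
    config: SimulationConfig


@dataclass
class SimulatedGenome:
    units: list[TranscriptionUnit]
    regions: RegionSet
    truth: TruthTable
    features: dict[str, list[GenomicInterval]]


@dataclass
class ProseqSample:
    plus: SignalTrack
    minus: SignalTrack
    library_size: int


GROUP_LABELS = ("G1", "G2", "G3", "G4")


def _draw_cohesin_levels(rng: np.random.Generator, bins: np.ndarray,
                         cfg: SimulationConfig) -> np.ndarray:
    m = cfg.edge_margin
    levels = np.zeros(len(bins))
    lo = bins == 0
    nz = lo & (rng.random(len(bins)) >= cfg.zero_fraction_lowest)
    levels[nz] = rng.uniform(0.0, 1.0 - m, nz.sum())
    for b, (a, bnd) in enumerate([(1.0 + m, 2.0 - m), (2.0 + m, 4.0 - m)], start=1):
        sel = bins == b
        levels[sel] = rng.uniform(a, bnd, sel.sum())
    sel = bins == 3
    levels[sel] = 4.0 + m + rng.exponential(cfg.top_bin_scale, sel.sum())
    return levels


def simulate_genome(config: SimulationConfig, seed: int) -> SimulatedGenome:
    """Lay out transcription units, cohesin/pausing truth and CRM features."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_units

    lengths = np.maximum(
        config.min_gene_length,
        np.round(rng.lognormal(np.log(config.gene_length_median),
                               config.gene_length_sigma, n)).astype(int)) if n else np.array([], int)
    gaps = rng.integers(config.gap_min, config.gap_max + 1, n + 1) if n else np.array([config.gap_min])
    starts = np.zeros(n, dtype=int)
    pos = int(gaps[0])
    for i in range(n):
        starts[i] = pos
        pos += int(lengths[i]) + int(gaps[i + 1])
    chrom_length = pos + config.gap_max
    if config.chrom_length is not None:
        if config.chrom_length < chrom_length:
            raise ValueError(
                f"chrom_length {config.chrom_length} too short for {n} units; "
                f"need >= {chrom_length} (use a longer chromosome)")
        chrom_length = config.chrom_length
    strands = rng.choice(["+", "-"], n)

    units = [TranscriptionUnit(f"tu{i + 1}",
                               GenomicInterval(config.chrom, int(starts[i]),
                                               int(starts[i] + lengths[i]), strands[i]))
             for i in range(n)]
    regions = derive_regions(units, config.promoter_halfwidth, config.cohesin_halfwidth)

    bins = rng.choice(len(config.bin_fractions), size=n, p=config.bin_fractions) if n else np.array([], int)
    levels = _draw_cohesin_levels(rng, bins, config)
    bound = levels >= 1.0
    pi = np.array([config.bin_pi_medians[b] for b in bins]) * np.exp(
        rng.normal(0.0, config.pi_sigma, n)) if n else np.array([])
    body_density = rng.lognormal(np.log(config.body_density_median),
                                 config.body_density_sigma, n)
    prom_density = pi * body_density
    pm = np.where(bound, config.depletion_promoter_mult[1], config.depletion_promoter_mult[0])
    bm = np.where(bound, config.depletion_body_mult[1], config.depletion_body_mult[0])

    tss = np.array([u.tss for u in units], dtype=int) if n else np.array([], int)
    units_df = pd.DataFrame({
        "unit_id": [u.id for u in units],
        "chrom": config.chrom,
        "start": starts, "end": starts + lengths,
        "strand": strands, "tss": tss,
        "cohesin_level": levels,
        "cohesin_bin": [GROUP_LABELS[b] for b in bins],
        "cohesin_bound": bound,
        "pi_control": pi,
        "body_density_control": body_density,
        "promoter_density_control": prom_density,
        "pi_depleted": pi * pm / bm,
        "body_density_depleted": body_density * bm,
        "promoter_density_depleted": prom_density * pm,
        "efficiency_factor": [config.efficiency_factors[b] for b in bins],
    }).set_index("unit_id") if n else pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "tss", "cohesin_level",
                 "cohesin_bin", "cohesin_bound", "pi_control",
                 "body_density_control", "promoter_density_control",
                 "pi_depleted", "body_density_depleted",
                 "promoter_density_depleted", "efficiency_factor"])
    if n:
        bt = regions.table
        units_df["body_start"] = bt["body_start"]
        units_df["body_end"] = bt["body_end"]
        units_df["body_empty"] = bt["body_empty"]
    else:
        units_df["body_start"] = units_df["body_end"] = units_df["body_empty"] = []

    crms_df, features = _place_crms(rng, config, units, chrom_length)
    truth = TruthTable(units_df, crms_df, config.chrom, chrom_length, config)
    return SimulatedGenome(units, regions, truth, features)


def _place_crms(rng: np.random.Generator, cfg: SimulationConfig,
                units: list[TranscriptionUnit], chrom_length: int):
    """Place CRM and decoy DHS features in intergenic gaps."""
    chrom = cfg.chrom
    half = cfg.dhs_width // 2
    # intergenic gaps wide enough to host an extragenic element
    need = 2 * 500 + 200 + 20
    gap_centers = []
    for a, b in zip(units, units[1:]):
        if b.span.start - a.span.end >= need:
            gap_centers.append((a.span.end + b.span.start) // 2)
    n_extra = int(round(cfg.n_crms * (1 - cfg.crm_fraction_near_tss)))
    n_near = cfg.n_crms - n_extra
    n_needed = n_extra + cfg.n_decoy_dhs
    if len(gap_centers) < n_needed and cfg.n_crms > 0:
        raise ValueError(
            "not enough wide intergenic gaps to place CRMs; use a longer "
            "chromosome or fewer units")
    picks = (rng.choice(len(gap_centers), size=n_needed, replace=False)
             if n_needed else np.array([], int))
    rows, dhs, k4, k27 = [], [], [], []

    def add_feature(center: int, has_k4: bool, has_k27: bool, near_tss: bool,
                    expected_extragenic: bool):
        d = GenomicInterval(chrom, center - half, center + half)
        dhs.append(d)
        # near-TSS features get narrow marks so they cannot reach into
        # neighbouring gaps and accidentally complete a decoy DHS
        mark_hw = half + 20 if near_tss else cfg.mark_halfwidth
        if has_k4:
            k4.append(GenomicInterval(chrom, center - mark_hw, center + mark_hw))
        if has_k27:
            k27.append(GenomicInterval(chrom, center - mark_hw, center + mark_hw))
        is_crm = has_k4 and has_k27
        mid = (d.start + d.end) // 2
        coh_bound = bool(rng.random() < cfg.crm_cohesin_bound_frac) if is_crm else False
        coh_level = float(2.0 + rng.exponential(2.0)) if coh_bound else 0.0
        rows.append({
            "dhs_start": d.start, "dhs_end": d.end,
            "element_start": mid - 100, "element_end": mid + 100,
            "center": mid, "is_crm": is_crm,
            "has_k4me1": has_k4, "has_k27ac": has_k27,
            "near_tss": near_tss, "expected_extragenic": expected_extragenic and is_crm,
            "cohesin_bound": coh_bound, "cohesin_level": coh_level,
            "polii_bound": bool(rng.random() < cfg.crm_polii_bound_frac) if is_crm else False,
        })

    for i in range(n_extra):
        add_feature(int(gap_centers[picks[i]]), True, True, False, True)
    for i in range(cfg.n_decoy_dhs):
        mode = i % 3
        add_feature(int(gap_centers[picks[n_extra + i]]),
                    mode == 0, mode == 1, False, False)
    # near-TSS elements exercise the extragenic filter: half inside units,
    # half upstream of a TSS within the 500-bp exclusion zone
    eligible = [u for u in units if u.span.length >= 900 and u.tss >= 400]
    if n_near and eligible:
        chosen = rng.choice(len(eligible), size=min(n_near, len(eligible)), replace=False)
        for j, ui in enumerate(chosen):
            u = eligible[ui]
            sgn = 1 if u.strand == "+" else -1
            center = u.tss + sgn * (400 if j % 2 == 0 else -250)
            add_feature(int(center), True, True, True, False)
    crms_df = pd.DataFrame(rows, columns=[
        "dhs_start", "dhs_end", "element_start", "element_end", "center",
        "is_crm", "has_k4me1", "has_k27ac", "near_tss", "expected_extragenic",
        "cohesin_bound", "cohesin_level", "polii_bound"])
    features = {"dhs": sorted(dhs), "k4me1": sorted(k4), "k27ac": sorted(k27)}
    return crms_df, features


# ---------------------------------------------------------------------------
# PRO-seq


def _positions_to_track(chrom: str, positions: np.ndarray, strand: str) -> SignalTrack:
    if len(positions) == 0:
        return SignalTrack("base_counts", {}, strand=strand)
    pos, counts = np.unique(positions, return_counts=True)
    return SignalTrack("base_counts", {chrom: (pos, pos + 1, counts.astype(float))},
                       strand=strand)


def simulate_proseq(truth: TruthTable, condition: str, depth: int,
                    seed: int) -> ProseqSample:
    """Simulate one stranded PRO-seq replicate at the given sequencing depth.

    Expected reads per unit region are proportional to the truth density
    times the region length; promoter reads land on a geometrically decaying
    pause peak at TSS+20..+60 (sense strand), body reads uniformly over the
    body, and a small background is scattered on both strands.  The recorded
    library size is exactly the number of reads written to the two tracks.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    u = truth.units
    if depth == 0 or len(u) == 0:
        return ProseqSample(SignalTrack("base_counts", {}, strand="+"),
                            SignalTrack("base_counts", {}, strand="-"), 0)

    prom_w = (u[f"promoter_density_{condition}"].to_numpy()
              * 2 * cfg.promoter_halfwidth)
    body_len = (u["body_end"].fillna(0) - u["body_start"].fillna(0)).to_numpy(float)
    body_w = u[f"body_density_{condition}"].to_numpy() * body_len
    total_w = prom_w.sum() + body_w.sum()
    signal_reads = depth * (1.0 - cfg.background_frac)
    lam_p = prom_w / total_w * signal_reads
    lam_b = body_w / total_w * signal_reads
    n_p = rng.poisson(lam_p)
    n_b = rng.poisson(lam_b)
    n_bg = rng.poisson(cfg.background_frac * depth)

    lo, hi = cfg.pause_peak
    offsets = np.arange(lo, hi + 1)
    w = (1 - cfg.pause_decay) ** (offsets - lo)
    w /= w.sum()
    tss = u["tss"].to_numpy(int)
    sgn = np.where(u["strand"].to_numpy() == "+", 1, -1)

    n_as = (rng.poisson(cfg.antisense_fraction * lam_p)
            if cfg.antisense_fraction > 0 else np.zeros(len(u), dtype=int))
    plus_pos, minus_pos = [], []
    for i in range(len(u)):
        dest = plus_pos if sgn[i] == 1 else minus_pos
        if n_p[i]:
            off = rng.choice(offsets, size=n_p[i], p=w)
            dest.append(tss[i] + sgn[i] * off)
        if n_b[i] and body_len[i] > 0:
            bs, be = int(u["body_start"].iloc[i]), int(u["body_end"].iloc[i])
            dest.append(rng.integers(bs, be, n_b[i]))
        if n_as[i]:
            # divergent peak mirrored upstream, on the antisense strand
            anti = minus_pos if sgn[i] == 1 else plus_pos
            off = rng.choice(offsets, size=n_as[i], p=w)
            anti.append(tss[i] - sgn[i] * off)
    if n_bg:
        bg_pos = rng.integers(0, truth.chrom_length, n_bg)
        bg_strand = rng.random(n_bg) < 0.5
        plus_pos.append(bg_pos[bg_strand])
        minus_pos.append(bg_pos[~bg_strand])

    plus = np.concatenate(plus_pos) if plus_pos else np.array([], int)
    minus = np.concatenate(minus_pos) if minus_pos else np.array([], int)
    library = int(len(plus) + len(minus))
    return ProseqSample(_positions_to_track(truth.chrom, plus, "+"),
                        _positions_to_track(truth.chrom, minus, "-"),
                        library)


# ---------------------------------------------------------------------------
# ChIP


def _factor_signal_model(truth: TruthTable, factor: str, condition: str):
    """Point sites [(pos, amp)] and blocks [(start, end, amp)] for a factor."""
    cfg = truth.config
    u = truth.units
    crm = truth.crms
    sites: list[tuple[int, float]] = []
    blocks: list[tuple[int, int, float]] = []
    hw = cfg.promoter_halfwidth
    if factor == "cohesin":
        for t, lvl in zip(u["tss"], u["cohesin_level"]):
            if lvl > 0:
                sites.append((int(t), float(lvl)))
        for r in crm.itertuples(index=False):
            if r.cohesin_bound:
                sites.append((int(r.center), float(r.cohesin_level)))
    elif factor in ("Rpb3", "Ser2P", "CycT", "Cdk12"):
        pd_ = u[f"promoter_density_{condition}"].to_numpy()
        bd = u[f"body_density_{condition}"].to_numpy()
        for i in range(len(u)):
            t = int(u["tss"].iloc[i])
            if factor in ("Rpb3", "CycT", "Cdk12"):
                blocks.append((t - hw, t + hw, float(pd_[i])))
            if factor in ("Rpb3", "Ser2P") and not u["body_empty"].iloc[i]:
                blocks.append((int(u["body_start"].iloc[i]),
                               int(u["body_end"].iloc[i]), float(bd[i])))
        for r in crm.itertuples(index=False):
            if r.is_crm and r.polii_bound:
                sites.append((int(r.center), 2.5))
    elif factor in ("H3K4me1", "H3K27ac"):
        col = "has_k4me1" if factor == "H3K4me1" else "has_k27ac"
        for r in crm.itertuples(index=False):
            if getattr(r, col):
                amp = 1.0 + 0.8 * float(r.cohesin_level)
                sites.append((int(r.center), amp))
    else:
        raise ValueError(f"unknown factor {factor!r}")
    return sites, blocks


def simulate_chip(truth: TruthTable, factor: str, condition: str, seed: int,
                  with_calls: bool = False,
                  ) -> tuple[SignalTrack, BindingCallSet | None]:
    """Simulate a probe-resolution ChIP enrichment track for one factor.

    Probe scores are the sum of triangular-kernel point-site contributions
    (normalized so the mean score over the 400-bp cohesin window equals the
    site amplitude) and flat occupancy blocks, plus Gaussian noise.  With
    ``with_calls`` a binding call set is emitted: merged probe intervals
    where the *noiseless* signal reaches the configured threshold.
    """
    if factor not in CHIP_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    spacing = cfg.probe_spacing
    starts = np.arange(0, truth.chrom_length - spacing + 1, spacing, dtype=np.int64)
    mids = starts + spacing // 2
    signal = np.zeros(len(starts))

    W = float(cfg.kernel_halfwidth)
    # mean triangular weight over the +/-cohesin_halfwidth window
    norm = 1.0 / (1.0 - cfg.cohesin_halfwidth / (2.0 * W))
    sites, blocks = _factor_signal_model(truth, factor, condition)
    for pos, amp in sites:
        lo = np.searchsorted(mids, pos - W, side="left")
        hi = np.searchsorted(mids, pos + W, side="right")
        d = np.abs(mids[lo:hi] - pos)
        signal[lo:hi] += amp * norm * (1.0 - d / W)
    for bs, be, amp in blocks:
        lo = np.searchsorted(mids, bs, side="left")
        hi = np.searchsorted(mids, be, side="left")
        signal[lo:hi] += amp

    noisy = signal + rng.normal(0.0, cfg.chip_noise_sd, len(signal))
    track = SignalTrack("probe_scores",
                        {truth.chrom: (starts, starts + spacing, noisy)},
                        probe_spacing=spacing)
    calls = None
    if with_calls:
        above = signal >= cfg.binding_threshold
        intervals = []
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                intervals.append(GenomicInterval(
                    truth.chrom, int(starts[i]), int(starts[j]) + spacing))
                i = j + 1
            else:
                i += 1
        calls = BindingCallSet(factor, intervals, significance="synthetic")
    return track, calls


# ---------------------------------------------------------------------------
# expression


def simulate_expression(truth: TruthTable, seed: int) -> pd.DataFrame:
    """Per-probe expression table with 1-3 probes per gene.

    Per-gene mRNA signal is efficiency_factor x body density x lognormal
    noise, per condition, split across the gene's probes; summing a gene's
    probe rows recovers the gene signal exactly.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    rows = []
    for uid, r in truth.units.iterrows():
        sig = {}
        for cond in CONDITIONS:
            noise = (np.exp(rng.normal(0.0, cfg.expression_noise_sigma))
                     if cfg.expression_noise_sigma > 0 else 1.0)
            sig[cond] = r["efficiency_factor"] * r[f"body_density_{cond}"] * noise
        k = int(rng.integers(2, 4)) if rng.random() < cfg.multi_probe_fraction else 1
        frac = rng.dirichlet(np.ones(k))
        for j in range(k):
            rows.append({"probe_id": f"{uid}_p{j + 1}", "gene_id": uid,
                         "signal": sig["control"] * frac[j],
                         "signal_depleted": sig["depleted"] * frac[j]})
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "signal",
                                       "signal_depleted"])


# ---------------------------------------------------------------------------
# config round-trip (plain-text key=value, TOML-compatible scalars)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            if isinstance(val, tuple):
                fh.write(f"{key} = {list(val)}\n")
            elif isinstance(val, str):
                fh.write(f'{key} = "{val}"\n')
            elif val is None:
                continue
            else:
                fh.write(f"{key} = {val}\n")


def load_config(path) -> SimulationConfig:
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    fields_ = SimulationConfig.__dataclass_fields__
    kwargs = {}
    for key, val in raw.items():
        if key not in fields_:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = tuple(val) if isinstance(val, list) else val
    return SimulationConfig(**kwargs)
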