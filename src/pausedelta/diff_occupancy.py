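"""Differential ChIP occupancy calling between conditions.

The change caller works on per-probe score differences (treated - control)
over a shared probe grid.  With m the genome-wide median and sigma the
standard deviation of all differences, an UP call is a maximal run of
consecutive probes with difference >= m + k*sigma whose span reaches
``min_span`` bp (three 35-bp features = 105 bp by default); DOWN is the
mirror with difference <= m - k*sigma.  The span of a run of probes is
(last probe start - first probe start) + probe_spacing, so three probes at
35-bp spacing span exactly 105 bp, and the emitted interval is
[first probe start, last probe start + probe_spacing).

Regions (promoters, gene bodies, CRM elements) are then labelled UP / DOWN /
NONE by 1-bp overlap with the called intervals; regions hit by both
directions are rescored NONE by default and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomicInterval, SignalTrack, overlap


@dataclass
class DiffStats:
    """Genome-wide summary of per-probe differences."""

    median: float
    sd: float
    n_probes: int


@dataclass
class ChangeCallSet:
    up: list[GenomicInterval]
    down: list[GenomicInterval]
    stats: DiffStats | None = None
    conflicts: list[str] = field(default_factory=list)


def _runs_to_intervals(chrom: str, starts: np.ndarray, mask: np.ndarray,
                       spacing: int, min_span: int) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            span = int(starts[j] - starts[i]) + spacing
            if span >= min_span:
                out.append(GenomicInterval(chrom, int(starts[i]), int(starts[j]) + spacing))
            i = j + 1
        else:
            i += 1
    return out


def call_change_intervals(treated: SignalTrack, control: SignalTrack, k: float = 2.0,
                          min_span: int = 105) -> ChangeCallSet:
    """Call absolute occupancy increases/decreases between two probe tracks.

    Both tracks must share the same probe grid.  The median and SD are taken
    over all probes of all chromosomes jointly (genome-wide), but runs never
    cross chromosome boundaries.
    """
    for t in (treated, control):
        if t.kind != "probe_scores":
            raise ValueError("change calling requires probe_scores tracks")
    if set(treated.chroms()) != set(control.chroms()):
        raise ValueError("probe grids mismatch: different chromosomes")
    spacing = treated.probe_spacing or control.probe_spacing
    if spacing is None:
        raise ValueError("probe_spacing must be set on one of the tracks")

    diffs: dict[str, np.ndarray] = {}
    all_d = []
    for chrom in treated.chroms():
        st, _, vt = treated.data[chrom]
        sc, _, vc = control.data[chrom]
        if len(st) != len(sc) or not np.array_equal(st, sc):
            raise ValueError(f"probe grids mismatch on {chrom}")
        d = vt - vc
        diffs[chrom] = d
        all_d.append(d)
    d_all = np.concatenate(all_d)
    if len(d_all) < 2:
        raise ValueError("need at least 2 probes")
    m = float(np.median(d_all))
    sd = float(np.std(d_all, ddof=0))

    up: list[GenomicInterval] = []
    down: list[GenomicInterval] = []
    if sd == 0.0:
        # no variation between conditions (e.g. identical tracks): nothing
        # can differ by k sigma, so no calls
        return ChangeCallSet(up=up, down=down, stats=DiffStats(m, sd, len(d_all)))
    for chrom in treated.chroms():
        starts = treated.data[chrom][0]
        d = diffs[chrom]
        up.extend(_runs_to_intervals(chrom, starts, d >= m + k * sd, spacing, min_span))
        down.extend(_runs_to_intervals(chrom, starts, d <= m - k * sd, spacing, min_span))
    return ChangeCallSet(up=up, down=down, stats=DiffStats(m, sd, len(d_all)))


def classify_region_changes(calls: ChangeCallSet, regions: dict[str, GenomicInterval],
                            conflict_rule: str = "none_on_conflict") -> pd.Series:
    """Label each region UP / DOWN / NONE by 1-bp overlap with call intervals.

    Regions overlapping both an UP and a DOWN interval are rescored NONE
    under the default rule (and appended to ``calls.conflicts``); under
    ``larger_span_wins`` the direction whose overlapping interval has the
    larger total span wins (ties -> NONE).
    """
    if conflict_rule not in ("none_on_conflict", "larger_span_wins"):
        raise ValueError(f"unknown conflict rule {conflict_rule!r}")
    ids = list(regions)
    ivs = [regions[i] for i in ids]
    up_hits = overlap(ivs, calls.up, min_overlap=1)
    down_hits = overlap(ivs, calls.down, min_overlap=1)
    labels = []
    for rid, uh, dh in zip(ids, up_hits, down_hits):
        if uh and dh:
            if conflict_rule == "none_on_conflict":
                calls.conflicts.append(rid)
                labels.append("NONE")
            else:
                up_span = max(calls.up[j].length for j in uh)
                down_span = max(calls.down[j].length for j in dh)
                if up_span > down_span:
                    labels.append("UP")
                elif down_span > up_span:
                    labels.append("DOWN")
                else:
                    calls.conflicts.append(rid)
                    labels.append("NONE")
        elif uh:
            labels.append("UP")
        elif dh:
            labels.append("DOWN")
        else:
            labels.append("NONE")
    return pd.Series(labels, index=pd.Index(ids, name="region_id"), name="change")


def change_frequency_table(labels: pd.Series, strata: pd.Series) -> pd.DataFrame:
    """Change-frequency contingency tables per direction with Fisher's exact test.

    ``strata`` is a boolean Series (True = cohesin-binding) aligned with
    ``labels``.  For each direction (UP, DOWN) the 2x2 table is
    (changed, unchanged) x (binding, non-binding); the two-sided Fisher exact
    p and per-stratum percentages are reported.  An empty stratum yields a
    missing p with a warning.
    """
    import warnings

    strata = strata.reindex(labels.index)
    rows = []
    for direction in ("UP", "DOWN"):
        changed = labels == direction
        a = int((changed & strata).sum())        # changed, binding
        b = int((~changed & strata).sum())       # unchanged, binding
        c = int((changed & ~strata).sum())       # changed, non-binding
        d = int((~changed & ~strata).sum())      # unchanged, non-binding
        if a + b == 0 or c + d == 0:
            warnings.warn(f"{direction}: empty stratum, no test", stacklevel=2)
            p = np.nan
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append({
            "direction": direction,
            "changed_binding": a, "unchanged_binding": b,
            "changed_nonbinding": c, "unchanged_nonbinding": d,
            "pct_binding": 100.0 * a / (a + b) if a + b else np.nan,
            "pct_nonbinding": 100.0 * c / (c + d) if c + d else np.nan,
            "fisher_p": p,
        })
    return pd.DataFrame(rows).set_index("direction")
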