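"""Region-level ChIP score summaries, cohesin grouping and binding calls.

Probe scores are MAT-style enrichment values on a tiling-array grid.  A probe
belongs to a region iff its midpoint lies inside the region (half-open).
Active units are ranked into four cohesin groups by their mean score over the
400-bp window around the TSS, with edges at 1, 2 and 4: G1 "<1" (including
negative scores), G2 "[1,2)", G3 "[2,4)", G4 ">=4".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import BindingCallSet, GenomicInterval, SignalTrack, overlap

GROUP_LABELS = ("G1", "G2", "G3", "G4")
DEFAULT_EDGES = (1.0, 2.0, 4.0)


def mean_region_score(track: SignalTrack, regions: list[GenomicInterval]) -> np.ndarray:
    """Mean probe score per region (probe midpoint in region); NaN if no probe."""
    if track.kind != "probe_scores":
        raise ValueError("mean_region_score requires a probe_scores track")
    mids: dict[str, tuple[np.ndarray, np.ndarray]] = {
        chrom: track.probe_midpoints(chrom) for chrom in track.chroms()}
    out = np.full(len(regions), np.nan)
    for i, reg in enumerate(regions):
        if reg.chrom not in mids:
            continue
        m, v = mids[reg.chrom]
        lo = np.searchsorted(m, reg.start, side="left")
        hi = np.searchsorted(m, reg.end, side="left")
        if hi > lo:
            out[i] = float(np.mean(v[lo:hi]))
    return out


def assign_cohesin_groups(scores: pd.Series,
                          edges: tuple[float, float, float] = DEFAULT_EDGES) -> pd.Series:
    """Bin per-unit mean cohesin-window scores into the four groups.

    Interior edges are left-closed ([1,2), [2,4)); scores >= the top edge go
    to G4; anything below the first edge (including negatives) is G1.  Units
    with missing scores get NA and are excluded from group analyses.
    """
    idx = np.digitize(scores.to_numpy(dtype=float), bins=np.asarray(edges), right=False)
    labels = pd.Series(pd.array([GROUP_LABELS[i] for i in idx]),
                       index=scores.index, name="cohesin_group")
    return labels.where(scores.notna())


def chip_pause_index(promoter_mean, body_mean):
    """ChIP-based pause index: promoter mean / body mean, both required > 0."""
    p = np.asarray(promoter_mean, dtype=float)
    b = np.asarray(body_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / b
    ratio = np.where((p > 0) & (b > 0), ratio, np.nan)
    return float(ratio) if ratio.ndim == 0 else ratio


def call_binding(regions: list[GenomicInterval], calls: BindingCallSet | None = None,
                 track: SignalTrack | None = None, threshold: float | None = None,
                 min_probes: int = 1) -> np.ndarray:
    """Per-region bound flags from binding-call intervals or a scored track.

    Mode A (``calls``): bound iff the region overlaps a call interval by at
    least 1 bp.  Mode B (``track`` + ``threshold``): bound iff a run of at
    least ``min_probes`` consecutive probes with score >= threshold overlaps
    the region — a thresholding substitute for array p-value calls.
    """
    if (calls is not None) == (track is not None):
        raise ValueError("supply exactly one of calls= or track=")
    if calls is not None:
        hits = overlap(regions, calls.intervals, min_overlap=1)
        return np.array([len(h) > 0 for h in hits])
    if threshold is None:
        raise ValueError("mode B requires a threshold")
    run_intervals: list[GenomicInterval] = []
    spacing = track.probe_spacing or 1
    for chrom in track.chroms():
        starts, _, values = track.data[chrom]
        above = values >= threshold
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                if j - i + 1 >= min_probes:
                    run_intervals.append(
                        GenomicInterval(chrom, int(starts[i]), int(starts[j]) + spacing))
                i = j + 1
            else:
                i += 1
    hits = overlap(regions, run_intervals, min_overlap=1)
    return np.array([len(h) > 0 for h in hits])


def track_correlation(a: SignalTrack, b: SignalTrack) -> tuple[float, int]:
    """Pearson r between two probe tracks over shared probe positions.

    Probes are matched on (chrom, start).  Returns ``(r, n_shared)``; r is NaN
    when fewer than 3 probes are shared or either side has zero variance.
    """
    xs, ys = [], []
    for chrom in set(a.chroms()) & set(b.chroms()):
        sa, _, va = a.data[chrom]
        sb, _, vb = b.data[chrom]
        common, ia, ib = np.intersect1d(sa, sb, return_indices=True)
        if len(common):
            xs.append(va[ia])
            ys.append(vb[ib])
    if not xs:
        return float("nan"), 0
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), n
    r = stats.pearsonr(x, y).statistic
    return float(r), n
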