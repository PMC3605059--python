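"""Cis-regulatory module (CRM) prediction and occupancy scoring.

A candidate CRM is called where a DNase I hypersensitive site (DHS) overlaps
both an H3K4me1 and an H3K27ac interval (>= 1 bp each); the element is a
fixed-width (200 bp) window centered on the DHS midpoint.  The extragenic
subset excludes elements overlapping any annotated transcription unit or
lying closer than 500 bp (edge-to-TSS, inclusive at 500) to any TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (BindingCallSet, GenomicInterval, SignalTrack,
                           TranscriptionUnit, overlap)
from .diff_occupancy import ChangeCallSet, classify_region_changes


@dataclass
class CRM:
    """A 200-bp candidate regulatory element centered on a DHS midpoint."""

    id: str
    element: GenomicInterval
    dhs: GenomicInterval
    marks: frozenset[str] = frozenset({"H3K4me1", "H3K27ac"})
    clamped: bool = False
    extragenic: bool | None = None


def predict_crms(dhs: list[GenomicInterval], k4me1: list[GenomicInterval],
                 k27ac: list[GenomicInterval], width: int = 200) -> list[CRM]:
    """Predict CRMs from DHS + H3K4me1 + H3K27ac co-occurrence.

    A DHS yields a CRM iff it overlaps at least one interval of each mark by
    >= 1 bp.  The element is ``[mid - width/2, mid + width/2)`` with
    ``mid = floor((start + end) / 2)`` of the DHS; elements clamped at the
    chromosome start are flagged.
    """
    if width % 2:
        raise ValueError("width must be even")
    half = width // 2
    hits1 = overlap(dhs, k4me1, min_overlap=1)
    hits2 = overlap(dhs, k27ac, min_overlap=1)
    crms: list[CRM] = []
    for i, d in enumerate(dhs):
        if not (hits1[i] and hits2[i]):
            continue
        mid = (d.start + d.end) // 2
        start = mid - half
        clamped = start < 0
        element = GenomicInterval(d.chrom, max(start, 0), mid + half)
        crms.append(CRM(id=f"crm{len(crms) + 1}", element=element, dhs=d, clamped=clamped))
    return crms


def filter_extragenic(crms: list[CRM], annotation: list[TranscriptionUnit],
                      min_tss_dist: int = 500) -> tuple[list[CRM], pd.DataFrame]:
    """Keep CRMs outside all unit spans and >= min_tss_dist from every TSS.

    Distance is measured from the element's nearest edge to the TSS and the
    boundary is inclusive (exactly ``min_tss_dist`` -> kept).  Returns the
    extragenic subset (with ``extragenic`` flags set on all inputs) and a log
    of removed CRMs with the reason (unit overlap vs TSS proximity).
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    spans = [u.span for u in annotation]
    unit_hits = overlap([c.element for c in crms], spans, min_overlap=1)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for u in annotation:
        tss_by_chrom.setdefault(u.chrom, [])
    for u in annotation:
        tss_by_chrom[u.chrom].append(u.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    kept: list[CRM] = []
    removed = []
    for c, hits in zip(crms, unit_hits):
        reason = None
        if hits:
            reason = "unit_overlap"
        else:
            tss = tss_by_chrom.get(c.element.chrom)
            if tss is not None and len(tss):
                # distance from nearest element edge: 0 if a TSS falls inside
                j = np.searchsorted(tss, c.element.start)
                cands = tss[max(0, j - 1):j + 2]
                dist = min(
                    max(c.element.start - t, t - (c.element.end - 1), 0) for t in cands)
                if dist < min_tss_dist:
                    reason = "tss_proximity"
        c.extragenic = reason is None
        if reason is None:
            kept.append(c)
        else:
            removed.append({"crm_id": c.id, "reason": reason})
    log = pd.DataFrame(removed, columns=["crm_id", "reason"])
    return kept, log


def crm_occupancy(crms: list[CRM], callsets: dict[str, BindingCallSet],
                  proseq: tuple[SignalTrack, SignalTrack] | None = None,
                  changes: dict[str, ChangeCallSet] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate CRMs with factor occupancy, PRO-seq density and change labels.

    Returns ``(per_crm, summary)``.  ``per_crm`` has one row per CRM with a
    ``bound_<factor>`` flag per binding call set (1-bp overlap), per-strand
    PRO-seq densities over the element, and a ``change_<factor>`` label.
    ``summary`` gives per factor the percent of CRMs occupied and — over the
    denominator of CRMs bound by that factor in control cells only — the
    percent with DOWN and UP changes.
    """
    elements = [c.element for c in crms]
    per = pd.DataFrame(index=pd.Index([c.id for c in crms], name="crm_id"))
    for factor, cs in callsets.items():
        hits = overlap(elements, cs.intervals, min_overlap=1)
        per[f"bound_{factor}"] = [len(h) > 0 for h in hits]
    if proseq is not None:
        plus, minus = proseq
        per["proseq_plus_density"] = [plus.region_sum(e) / e.length for e in elements]
        per["proseq_minus_density"] = [minus.region_sum(e) / e.length for e in elements]
    if changes:
        region_map = {c.id: c.element for c in crms}
        for factor, cc in changes.items():
            per[f"change_{factor}"] = classify_region_changes(cc, region_map)

    rows = []
    n = len(crms)
    for factor in callsets:
        bound = per[f"bound_{factor}"]
        row = {"factor": factor,
               "pct_occupied": 100.0 * bound.sum() / n if n else np.nan,
               "n_bound": int(bound.sum())}
        if changes and factor in changes:
            denom = per.loc[bound, f"change_{factor}"]
            row["pct_down"] = (100.0 * (denom == "DOWN").sum() / len(denom)
                               if len(denom) else np.nan)
            row["pct_up"] = (100.0 * (denom == "UP").sum() / len(denom)
                             if len(denom) else np.nan)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("factor") if rows else pd.DataFrame()
    return per, summary
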