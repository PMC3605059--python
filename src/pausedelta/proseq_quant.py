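"""Per-unit quantification of transcriptionally engaged Pol II from PRO-seq.

Reads are summed over each unit's promoter window and gene body on the
unit's sense strand only, normalized to reads per million (RPM) against the
sample's total mapped reads, and converted to densities (RPM per bp).  The
pause index is the ratio of promoter density to gene-body density; active
units are those with at least 1 RPM in both regions in the control sample
(inclusive threshold).  Replicates are normalized individually and their RPM
values averaged; raw counts are never pooled across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import RegionSet, SignalTrack

QUANT_COLUMNS = [
    "promoter_raw", "body_raw", "promoter_rpm", "body_rpm",
    "promoter_density", "body_density", "promoter_length", "body_length",
]


@dataclass
class ReplicateTracks:
    """One PRO-seq replicate: plus/minus strand count tracks + library size."""

    plus: SignalTrack
    minus: SignalTrack
    library_size: float | None = None

    def resolved_library_size(self) -> float:
        if self.library_size is not None:
            return float(self.library_size)
        # total mapped reads in the sample's two strand tracks
        return self.plus.total() + self.minus.total()


def _sense_track(rep: ReplicateTracks, strand: str) -> SignalTrack:
    return rep.plus if strand == "+" else rep.minus


def quantify_regions(plus: SignalTrack, minus: SignalTrack, regions: RegionSet,
                     library_size: float | None = None,
                     replicates: list[ReplicateTracks] | None = None) -> pd.DataFrame:
    """Quantify promoter and gene-body PRO-seq signal per transcription unit.

    Returns a DataFrame indexed by unit id with raw counts (summed across
    replicates for reporting), replicate-averaged RPM, densities (RPM/bp) and
    region lengths.  Counts are taken from the unit's sense strand only;
    regions outside the track's extent count 0.

    Parameters
    ----------
    plus, minus:
        Base-count tracks of the first (or only) replicate.
    library_size:
        Total mapped reads of that replicate; defaults to the tracks' total.
    replicates:
        Additional replicates.  RPM values are computed per replicate then
        averaged.
    """
    for t in (plus, minus):
        if t.kind != "base_counts":
            raise ValueError("quantify_regions requires base_counts tracks")
    reps = [ReplicateTracks(plus, minus, library_size)] + list(replicates or [])
    for r in reps:
        if r.resolved_library_size() <= 0:
            raise ValueError("library_size must be positive")

    prom = regions.promoter_intervals()
    body = regions.body_intervals()
    rows = []
    for uid, reg in regions.table.iterrows():
        strand = reg["strand"]
        p_iv = prom.get(uid)
        b_iv = body.get(uid)
        p_rpms, b_rpms, p_raws, b_raws = [], [], [], []
        for rep in reps:
            track = _sense_track(rep, strand)
            lib = rep.resolved_library_size()
            p_raw = track.region_sum(p_iv) if p_iv is not None else 0.0
            b_raw = track.region_sum(b_iv) if b_iv is not None else 0.0
            p_raws.append(p_raw)
            b_raws.append(b_raw)
            p_rpms.append(p_raw * 1e6 / lib)
            b_rpms.append(b_raw * 1e6 / lib)
        p_len = p_iv.length if p_iv is not None else 0
        b_len = b_iv.length if b_iv is not None else 0
        p_rpm = float(np.mean(p_rpms))
        b_rpm = float(np.mean(b_rpms))
        rows.append({
            "unit_id": uid,
            "promoter_raw": float(np.sum(p_raws)), "body_raw": float(np.sum(b_raws)),
            "promoter_rpm": p_rpm, "body_rpm": b_rpm,
            "promoter_density": p_rpm / p_len if p_len else np.nan,
            "body_density": b_rpm / b_len if b_len else np.nan,
            "promoter_length": p_len, "body_length": b_len,
        })
    out = pd.DataFrame(rows).set_index("unit_id") if rows else pd.DataFrame(
        columns=QUANT_COLUMNS)
    return out


def call_active(quant: pd.DataFrame, min_rpm: float = 1.0) -> pd.Series:
    """Active iff promoter RPM >= min_rpm AND body RPM >= min_rpm (inclusive).

    ``quant`` must be the control-condition table.  Units with an empty body
    (body_length 0) are inactive.
    """
    active = (quant["promoter_rpm"] >= min_rpm) & (quant["body_rpm"] >= min_rpm)
    active &= quant["body_length"] > 0
    return active.rename("active")


def pause_index(quant: pd.DataFrame) -> pd.Series:
    """Promoter density / body density per unit; NaN where body density is 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = quant["promoter_density"] / quant["body_density"]
    pi = pi.where(quant["body_density"] > 0)
    return pi.rename("pause_index")


def fold_change(control: pd.DataFrame, treated: pd.DataFrame,
                pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-unit log2 fold-changes (treated vs control).

    Columns: ``promoter_rpm_lfc, body_rpm_lfc, pause_index_lfc``.  With
    pseudocount 0, units with a zero on either side get NaN (flagged missing)
    rather than +/-inf.  The pause-index fold-change is computed from the two
    pause indices directly (no pseudocount).
    """
    if not control.index.equals(treated.index):
        if set(control.index) != set(treated.index):
            raise ValueError("control and treated tables cover different unit sets")
        treated = treated.reindex(control.index)

    def _lfc(a: pd.Series, b: pd.Series) -> pd.Series:
        num, den = b + pseudocount, a + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(num / den)
        return pd.Series(out, index=a.index).where((num > 0) & (den > 0))

    pi_c, pi_t = pause_index(control), pause_index(treated)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_lfc = np.log2(pi_t / pi_c)
    pi_lfc = pd.Series(pi_lfc, index=control.index).where((pi_c > 0) & (pi_t > 0))
    return pd.DataFrame({
        "promoter_rpm_lfc": _lfc(control["promoter_rpm"], treated["promoter_rpm"]),
        "body_rpm_lfc": _lfc(control["body_rpm"], treated["body_rpm"]),
        "pause_index_lfc": pi_lfc,
    })
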