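"""Core genomic coordinate types, annotation/signal readers and interval arithmetic.

All coordinates are 0-based, half-open (BED-native).  ``GenomicInterval`` is the
substrate for every region definition downstream: the 200-bp promoter window
around the transcription start site (TSS), the gene body (the rest of the
annotated transcription unit), and the 400-bp cohesin-scoring window.

Signal comes in two flavours, both stored in :class:`SignalTrack`:

* ``base_counts`` — base-resolution non-negative integer counts, one track per
  strand, as produced by PRO-seq 3'-end mapping (bedGraph on disk);
* ``probe_scores`` — tiling-microarray enrichment scores (MAT-score style),
  real-valued, on a nominal probe spacing (default 35 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an annotation or track file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptionUnit:
    """An annotated, strand-aware transcription unit.

    The TSS is the strand-dependent end of the span: ``span.start`` on the
    plus strand, ``span.end - 1`` on the minus strand.
    """

    id: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError("stranded annotation required")

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom


@dataclass
class RegionSet:
    """Per-unit promoter / gene-body / cohesin-window regions.

    ``table`` has one row per transcription unit, indexed by unit id, with
    columns ``chrom, strand, tss, unit_start, unit_end, promoter_start,
    promoter_end, body_start, body_end, cohesin_start, cohesin_end,
    body_empty``.  Units whose span lies entirely inside the promoter window
    have no body (``body_empty`` True, body coordinates NA) and are excluded
    from pause/efficiency computations downstream.
    """

    table: pd.DataFrame
    promoter_halfwidth: int
    cohesin_halfwidth: int

    @property
    def unit_ids(self) -> list[str]:
        return list(self.table.index)

    def _intervals(self, prefix: str) -> dict[str, GenomicInterval]:
        out = {}
        for uid, row in self.table.iterrows():
            s, e = row[f"{prefix}_start"], row[f"{prefix}_end"]
            if pd.isna(s):
                continue
            out[uid] = GenomicInterval(row["chrom"], int(s), int(e), row["strand"])
        return out

    def promoter_intervals(self) -> dict[str, GenomicInterval]:
        return self._intervals("promoter")

    def body_intervals(self) -> dict[str, GenomicInterval]:
        return self._intervals("body")

    def cohesin_intervals(self) -> dict[str, GenomicInterval]:
        return self._intervals("cohesin")

    def unit_intervals(self) -> dict[str, GenomicInterval]:
        return self._intervals("unit")


class SignalTrack:
    """Sorted, non-overlapping scored intervals per chromosome.

    Parameters
    ----------
    kind:
        ``"base_counts"`` (non-negative integer counts per base) or
        ``"probe_scores"`` (real-valued probe enrichment scores).
    data:
        Mapping chrom -> ``(starts, ends, values)`` numpy arrays.  Intervals
        are sorted and validated as non-overlapping within a chromosome.
    strand:
        For ``base_counts`` tracks, the strand the counts belong to.
    probe_spacing:
        For ``probe_scores`` tracks, the nominal probe spacing in bp.
    """

    def __init__(self, kind: str, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 strand: str | None = None, probe_spacing: int | None = None):
        if kind not in ("base_counts", "probe_scores"):
            raise ValueError(f"unknown track kind {kind!r}")
        self.kind = kind
        self.strand = strand
        self.probe_spacing = probe_spacing
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ParseError(f"empty or inverted interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ParseError(f"overlapping intervals on {chrom}")
            if kind == "base_counts":
                if np.any(values < 0):
                    raise ParseError(f"negative counts on {chrom}")
                if np.any(values != np.round(values)):
                    raise ParseError(f"non-integer counts on {chrom}")
            elif not np.all(np.isfinite(values)):
                raise ParseError(f"non-finite probe scores on {chrom}")
            self.data[chrom] = (starts, ends, values)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]], kind: str,
                     strand: str | None = None, probe_spacing: int | None = None) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, rows in by_chrom.items():
            arr = np.array(rows, dtype=float)
            data[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(kind, data, strand=strand, probe_spacing=probe_spacing)

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self.data.values())

    def total(self) -> float:
        """Sum of value x width over all intervals (total reads for counts)."""
        return float(sum(np.sum(v * (e - s)) for s, e, v in self.data.values()))

    def region_sum(self, region: GenomicInterval) -> float:
        """Sum of value x overlap-width over the region (strand-agnostic)."""
        if region.chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[region.chrom]
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if hi <= lo:
            return 0.0
        s, e, v = starts[lo:hi], ends[lo:hi], values[lo:hi]
        ov = np.minimum(e, region.end) - np.maximum(s, region.start)
        return float(np.sum(v * np.clip(ov, 0, None)))

    def probe_midpoints(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(midpoints, values) for one chromosome of a probe_scores track."""
        starts, ends, values = self.data[chrom]
        return (starts + ends) // 2, values

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms():
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.kind != other.kind or set(self.data) != set(other.data):
            return False
        return all(
            np.array_equal(self.data[c][0], other.data[c][0])
            and np.array_equal(self.data[c][1], other.data[c][1])
            and np.allclose(self.data[c][2], other.data[c][2], rtol=0, atol=0)
            for c in self.data
        )


@dataclass
class BindingCallSet:
    """Significant-binding intervals for one factor (e.g. ChIP at p<=1e-3)."""

    factor: str
    intervals: list[GenomicInterval]
    significance: str = ""

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping (not merely abutting) intervals."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            out[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


# ---------------------------------------------------------------------------
# interval arithmetic


def overlap(query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval],
            min_overlap: int = 1) -> list[list[int]]:
    """For each query interval, indices of subject intervals overlapping it.

    Half-open semantics: intervals that merely touch do not overlap.  A pair
    is reported iff the overlap length is at least ``min_overlap`` bp.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[int]] = {}
    for j, iv in enumerate(subject):
        by_chrom.setdefault(iv.chrom, []).append(j)
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, idx in by_chrom.items():
        starts = np.array([subject[j].start for j in idx])
        ends = np.array([subject[j].end for j in idx])
        order = np.argsort(starts, kind="stable")
        index[chrom] = (starts[order], ends[order], np.array(idx)[order])
    hits: list[list[int]] = []
    for q in query:
        row: list[int] = []
        if q.chrom in index:
            starts, ends, idx = index[q.chrom]
            hi = np.searchsorted(starts, q.end, side="left")
            ov = np.minimum(ends[:hi], q.end) - np.maximum(starts[:hi], q.start)
            row = sorted(int(j) for j in idx[:hi][ov >= min_overlap])
        hits.append(row)
    return hits


def derive_regions(units: Sequence[TranscriptionUnit], promoter_halfwidth: int = 100,
                   cohesin_halfwidth: int = 200) -> RegionSet:
    """Derive promoter, gene-body and cohesin-scoring windows per unit.

    Promoter = TSS +/- ``promoter_halfwidth`` (the 200-bp window); body = the
    portion of the unit span strictly downstream (in transcription direction)
    of the promoter window; cohesin window = TSS +/- ``cohesin_halfwidth``
    (the 400-bp window).  Windows extending below coordinate 0 are clamped
    with a warning.  Units shorter than the downstream promoter half have an
    empty body and are flagged.
    """
    if promoter_halfwidth <= 0 or cohesin_halfwidth <= 0:
        raise ValueError("halfwidths must be positive")
    rows = []
    for u in units:
        tss = u.tss
        prom_s, prom_e = tss - promoter_halfwidth, tss + promoter_halfwidth
        coh_s, coh_e = tss - cohesin_halfwidth, tss + cohesin_halfwidth
        if prom_s < 0 or coh_s < 0:
            warnings.warn(f"unit {u.id}: window clamped at coordinate 0", stacklevel=2)
            prom_s, coh_s = max(prom_s, 0), max(coh_s, 0)
        if u.strand == "+":
            body_s, body_e = tss + promoter_halfwidth, u.span.end
        else:
            body_s, body_e = u.span.start, tss - promoter_halfwidth
        body_empty = body_e <= body_s
        rows.append({
            "unit_id": u.id, "chrom": u.chrom, "strand": u.strand, "tss": tss,
            "unit_start": u.span.start, "unit_end": u.span.end,
            "promoter_start": prom_s, "promoter_end": prom_e,
            "body_start": pd.NA if body_empty else body_s,
            "body_end": pd.NA if body_empty else body_e,
            "cohesin_start": coh_s, "cohesin_end": coh_e,
            "body_empty": body_empty,
        })
    table = pd.DataFrame(rows).set_index("unit_id") if rows else pd.DataFrame(
        columns=["chrom", "strand", "tss", "unit_start", "unit_end",
                 "promoter_start", "promoter_end", "body_start", "body_end",
                 "cohesin_start", "cohesin_end", "body_empty"])
    return RegionSet(table, promoter_halfwidth, cohesin_halfwidth)


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_annotation(path, dialect: str = "bed6") -> list[TranscriptionUnit]:
    """Read transcription units from BED6 or a headered TSV.

    TSV dialect expects columns ``chrom, start, end, id, strand`` (a ``score``
    column is tolerated and ignored).
    """
    if dialect == "bed6":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end", "id", "score", "strand"],
                         dtype={"chrom": str, "id": str, "strand": str})
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "strand": str})
        missing = {"chrom", "start", "end", "id", "strand"} - set(df.columns)
        if missing:
            raise ParseError(f"TSV annotation missing columns: {sorted(missing)}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    units: list[TranscriptionUnit] = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in ("+", "-"):
            raise ParseError(f"line {lineno}: stranded annotation required (got {row.strand!r})")
        if int(row.end) <= int(row.start):
            raise ParseError(f"line {lineno}: end <= start")
        if row.id in seen:
            raise ParseError(f"line {lineno}: duplicate unit id {row.id!r}")
        seen.add(row.id)
        units.append(TranscriptionUnit(
            str(row.id), GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)))
    return units


def read_signal_track(path, kind: str, strand: str | None = None,
                      probe_spacing: int | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (records may be unsorted)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str},
                     float_precision="round_trip")
    recs = [(r.chrom, int(r.start), int(r.end), float(r.value))
            for r in df.itertuples(index=False)]
    return SignalTrack.from_records(recs, kind, strand=strand, probe_spacing=probe_spacing)


def write_signal_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            # repr gives the shortest exact round-trip for probe scores
            v = int(value) if track.kind == "base_counts" else repr(value)
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (name/score/strand columns optional)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    return [GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
            for r in df.itertuples(index=False)]


def write_bed_intervals(intervals: Sequence[GenomicInterval], path,
                        names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_binding_calls(path, factor: str, significance: str = "") -> BindingCallSet:
    return BindingCallSet(factor, read_bed_intervals(path), significance)
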