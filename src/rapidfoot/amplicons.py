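"""Validation of aligned long reads as DamID amplicons, and fragment counting.

A genuine DamID amplicon is a PCR product between two methylated,
DpnI-cut GATC sites, so *both* aligned ends of a read must fall at (or
within a small tolerance of) a GATC motif.  Reads failing this dual-end
test are chimeras, degraded fragments or mismapped reads and are dropped.
Retained reads are converted to per-GATC-fragment coverage counts.

The "end" of a read is its aligned reference span (soft-clips excluded):
adapter and barcode remnants show up as clips, while the genomic
footprint is the aligned interval.  Distance is measured from the read
end to the closed 4-bp motif interval, which is anchor-free and symmetric
for this palindromic motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gatc import GATCIndex, MOTIF_LEN


@dataclass
class AlignedRead:
    """Coordinate-level alignment record (the subset of SAM we consume)."""

    read_id: str
    chrom: str
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    mapq: int = 60
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if not self.is_unmapped and self.ref_start >= self.ref_end:
            raise ValueError(f"read {self.read_id!r}: ref_start >= ref_end")


@dataclass
class FilterParams:
    """Amplicon validation parameters.

    ``end_tolerance`` is the maximum distance (bp, inclusive) between a
    read end and the nearest GATC motif interval; reads are never
    extended (``read_extension`` is fixed at 0 — amplicon ends are real
    molecule ends, not sonication artefacts).
    """

    end_tolerance: int = 8
    min_mapq: int = 10
    keep_secondary: bool = False
    read_extension: int = 0

    def __post_init__(self) -> None:
        if self.end_tolerance < 0:
            raise ValueError("end_tolerance must be >= 0")
        if self.read_extension != 0:
            raise ValueError("read_extension is fixed at 0 for amplicon data")


@dataclass
class FilterReport:
    n_reads_in: int = 0
    n_reads_kept: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {
            "unmapped": 0,
            "secondary": 0,
            "supplementary": 0,
            "low_mapq": 0,
            "end_mismatch": 0,
        }
    )


@dataclass
class FragmentCounts:
    """Per-GATC-fragment amplicon coverage for one library.

    ``counts`` is aligned row-for-row with the fragment table from
    :func:`rapidfoot.gatc.make_fragments`.  A long amplicon increments
    every fragment it covers, so ``counts.sum() >= n_reads_kept``.
    """

    library_id: str
    counts: np.ndarray
    n_reads_in: int
    n_reads_kept: int
    n_anomalous: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _motif_distance(pos: int, motifs: np.ndarray) -> float:
    """Distance from a point to the nearest motif interval [m, m+4].

    Zero anywhere on the closed interval (a read ending exactly at the
    downstream edge of a motif is a perfect cut), boundary distance
    outside.  Infinite if the chromosome has no motifs.
    """
    if motifs.size == 0:
        return np.inf
    i = np.searchsorted(motifs, pos)
    best = np.inf
    if i < motifs.size:
        best = min(best, max(motifs[i] - pos, 0))
    if i > 0:
        m = motifs[i - 1]
        best = min(best, max(pos - (m + MOTIF_LEN), 0))
    return float(best)


def _nearest_motif(pos: int, motifs: np.ndarray) -> int:
    i = int(np.searchsorted(motifs, pos))
    cands = []
    if i < motifs.size:
        cands.append((max(motifs[i] - pos, 0), int(motifs[i])))
    if i > 0:
        cands.append((max(pos - (int(motifs[i - 1]) + MOTIF_LEN), 0), int(motifs[i - 1])))
    return min(cands)[1]


def validate_read(
    read: AlignedRead, index: GATCIndex, params: FilterParams | None = None
) -> tuple[bool, tuple[int, int] | None]:
    """Dual-end test: is this read a DamID amplicon?

    Returns ``(True, (left_motif_start, right_motif_start))`` when both
    aligned ends lie within ``end_tolerance`` bp of a GATC motif
    interval, else ``(False, None)``.  Flag/MAPQ screening is the
    caller's job (see :func:`filter_alignments`); this checks geometry
    only.

    Raises
    ------
    KeyError
        If the read's chromosome is absent from the index.
    """
    params = params or FilterParams()
    if read.chrom not in index.motif_starts:
        raise KeyError(
            f"read {read.read_id!r}: chromosome {read.chrom!r} not in GATC index"
        )
    motifs = index.motif_starts[read.chrom]
    d_start = _motif_distance(read.ref_start, motifs)
    d_end = _motif_distance(read.ref_end, motifs)
    if d_start <= params.end_tolerance and d_end <= params.end_tolerance:
        return True, (_nearest_motif(read.ref_start, motifs), _nearest_motif(read.ref_end, motifs))
    return False, None


def filter_alignments(
    reads, index: GATCIndex, params: FilterParams | None = None
) -> tuple[list[AlignedRead], FilterReport]:
    """Screen an alignment stream down to valid DamID amplicons.

    Rejection order: unmapped, secondary (unless kept), supplementary,
    low MAPQ, then the dual-end motif test.  The result is
    order-independent: each read is judged on its own.
    """
    params = params or FilterParams()
    report = FilterReport()
    kept: list[AlignedRead] = []
    for read in reads:
        report.n_reads_in += 1
        if read.is_unmapped:
            report.rejected["unmapped"] += 1
            continue
        if read.is_secondary and not params.keep_secondary:
            report.rejected["secondary"] += 1
            continue
        if read.is_supplementary:
            report.rejected["supplementary"] += 1
            continue
        if read.mapq < params.min_mapq:
            report.rejected["low_mapq"] += 1
            continue
        ok, _ = validate_read(read, index, params)
        if not ok:
            report.rejected["end_mismatch"] += 1
            continue
        kept.append(read)
        report.n_reads_kept += 1
    return kept, report


def count_fragments(
    kept_reads,
    fragments: pd.DataFrame,
    params: FilterParams | None = None,
    library_id: str = "library",
    n_reads_in: int | None = None,
) -> FragmentCounts:
    """Convert validated amplicons into per-fragment coverage counts.

    A fragment is incremented when its whole interval lies inside
    ``[ref_start - tol, ref_end + tol)``: a true amplicon is a union of
    consecutive complete fragments and the tolerance absorbs end jitter.
    A kept read that covers no complete fragment under this rule is
    tallied as anomalous rather than silently dropped.
    """
    params = params or FilterParams()
    tol = params.end_tolerance
    counts = np.zeros(len(fragments), dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in fragments.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp.index.to_numpy(),
        )
    n_kept = 0
    n_anomalous = 0
    for read in kept_reads:
        n_kept += 1
        starts, ends, rows = by_chrom[read.chrom]
        lo = np.searchsorted(starts, read.ref_start - tol, side="left")
        hi = np.searchsorted(ends, read.ref_end + tol, side="right")
        if hi > lo:
            counts[rows[lo]: rows[hi - 1] + 1] += 1
        else:
            n_anomalous += 1
    return FragmentCounts(
        library_id=library_id,
        counts=counts,
        n_reads_in=n_kept if n_reads_in is None else n_reads_in,
        n_reads_kept=n_kept,
        n_anomalous=n_anomalous,
    )
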