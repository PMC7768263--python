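"""GATC motif indexing and restriction-fragment partition.

DamID signal lives on the intervals between consecutive GATC motifs
("GATC fragments"): Dam methylates GATC adenines, DpnI cuts methylated
GATCs, and the resulting amplicons are unions of consecutive fragments.
Everything downstream (amplicon validation, counting, normalization) is
anchored on the index built here.

Coordinates are 0-based, half-open throughout.  Fragment boundaries are
placed at motif *start* positions rather than at the biological cut site
two bases in; the two-base offset is far inside the end tolerance used by
the amplicon filter, and a single convention avoids off-by-one drift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MOTIF = "GATC"
MOTIF_LEN = 4

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")
_MOTIF_RE = re.compile(MOTIF)


class SequenceFormatError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass
class GATCIndex:
    """Sorted GATC motif start positions per chromosome.

    Attributes
    ----------
    chrom_lengths : dict of str -> int
        Length of each chromosome in bp.
    motif_starts : dict of str -> ndarray
        Strictly increasing 0-based motif start positions per chromosome.
    """

    chrom_lengths: dict[str, int]
    motif_starts: dict[str, np.ndarray]

    @property
    def n_motifs(self) -> int:
        return int(sum(len(v) for v in self.motif_starts.values()))

    def __post_init__(self) -> None:
        for chrom, starts in self.motif_starts.items():
            starts = np.asarray(starts, dtype=np.int64)
            self.motif_starts[chrom] = starts
            if chrom not in self.chrom_lengths:
                raise ValueError(f"chromosome {chrom!r} missing a length")
            if starts.size and (
                starts[0] < 0 or starts[-1] > self.chrom_lengths[chrom] - MOTIF_LEN
            ):
                raise ValueError(f"motif position out of bounds on {chrom!r}")
            if starts.size > 1 and not np.all(np.diff(starts) > 0):
                raise ValueError(f"motif positions not strictly increasing on {chrom!r}")


@dataclass
class GATCStats:
    """Motif count and inter-motif spacing summary.

    Spacing is the difference between consecutive motif starts within a
    chromosome, pooled genome-wide; absent (None) when no chromosome has
    two motifs.
    """

    n_motifs: int
    mean_spacing: float | None = None
    median_spacing: float | None = None
    spacings: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64), repr=False)


def find_gatc_sites(genome: dict[str, str]) -> GATCIndex:
    """Scan a genome for GATC motifs.

    Parameters
    ----------
    genome : mapping of chromosome name -> sequence
        Sequences over {A,C,G,T,N}, case-insensitive.  Windows containing
        N never match, so soft-masked genomes keep their motifs but
        hard-masked stretches contribute none.

    Returns
    -------
    GATCIndex

    Raises
    ------
    SequenceFormatError
        If a sequence contains non-DNA characters.
    """
    chrom_lengths: dict[str, int] = {}
    motif_starts: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        seq = str(seq)
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTNacgtn"))
            raise SequenceFormatError(
                f"chromosome {chrom!r} contains non-DNA characters: {bad}"
            )
        chrom_lengths[chrom] = len(seq)
        positions = [m.start() for m in _MOTIF_RE.finditer(seq.upper())]
        motif_starts[chrom] = np.asarray(positions, dtype=np.int64)
    return GATCIndex(chrom_lengths=chrom_lengths, motif_starts=motif_starts)


def make_fragments(index: GATCIndex) -> pd.DataFrame:
    """Partition each chromosome into GATC fragments.

    Boundaries sit at motif start positions; fragments tile
    ``[0, chrom_length)`` without gaps or overlaps, so a chromosome with
    ``k`` motifs yields ``k + 1`` fragments (a motif-free chromosome is a
    single fragment).

    Returns
    -------
    DataFrame with columns ``chrom``, ``start``, ``end``, ``fragment_id``
    (ordinal within chromosome); row order is the genome-wide fragment
    order used by all count and score vectors.
    """
    rows = []
    for chrom, length in index.chrom_lengths.items():
        starts = index.motif_starts.get(chrom, np.empty(0, dtype=np.int64))
        if starts.size and starts[-1] > length - MOTIF_LEN:
            raise ValueError(
                f"motif at {int(starts[-1])} on {chrom!r} beyond length {length}"
            )
        bounds = np.concatenate(([0], starts[starts > 0], [length]))
        bounds = np.unique(bounds)
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "start": bounds[:-1],
                "end": bounds[1:],
                "fragment_id": np.arange(len(bounds) - 1, dtype=np.int64),
            }
        )
        rows.append(frame)
    frags = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "fragment_id"]
    )
    return frags


def gatc_stats(index: GATCIndex) -> GATCStats:
    """Pooled inter-motif spacing statistics across chromosomes."""
    spacings = [
        np.diff(starts)
        for starts in index.motif_starts.values()
        if starts.size >= 2
    ]
    if not spacings:
        return GATCStats(n_motifs=index.n_motifs)
    pooled = np.concatenate(spacings)
    return GATCStats(
        n_motifs=index.n_motifs,
        mean_spacing=float(np.mean(pooled)),
        median_spacing=float(np.median(pooled)),
        spacings=pooled,
    )
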