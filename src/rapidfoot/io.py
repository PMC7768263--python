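"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, alignment records through pysam (SAM or
BAM), tabular formats (BED, bedGraph, counts, calls) through pandas.
All genomic output is 0-based half-open (BED convention); GFF3 input is
converted from 1-based closed coordinates on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicons import AlignedRead, FragmentCounts
from .gatc import GATCIndex, GATCStats, MOTIF_LEN
from .occupancy import OccupancyTrack


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------ alignments

def read_alignments(path) -> list[AlignedRead]:
    """Load coordinate-level records from SAM/BAM via pysam."""
    reads: list[AlignedRead] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                reads.append(
                    AlignedRead(
                        read_id=rec.query_name, chrom="*", ref_start=0, ref_end=1,
                        mapq=rec.mapping_quality, is_unmapped=True,
                    )
                )
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    mapq=rec.mapping_quality,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                )
            )
    return reads


def write_sam(reads, chrom_lengths: dict[str, int], path) -> None:
    """Serialise coordinate records as SAM (fully-matching CIGAR, * sequence)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        tid = {c: i for i, c in enumerate(chrom_lengths)}
        for read in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read.read_id
            if read.is_unmapped:
                rec.is_unmapped = True
                fh.write(rec)
                continue
            rec.reference_id = tid[read.chrom]
            rec.reference_start = read.ref_start
            rec.mapping_quality = read.mapq
            rec.cigartuples = [(0, read.ref_end - read.ref_start)]
            rec.is_secondary = read.is_secondary
            rec.is_supplementary = read.is_supplementary
            fh.write(rec)


# ----------------------------------------------------------- BED & index

def write_motif_bed(index: GATCIndex, path) -> None:
    rows = [
        (chrom, int(p), int(p) + MOTIF_LEN, "GATC")
        for chrom, starts in index.motif_starts.items()
        for p in starts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_fragment_bed(fragments: pd.DataFrame, path) -> None:
    fragments[["chrom", "start", "end", "fragment_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_stats_tsv(stats: GATCStats, path) -> None:
    pd.DataFrame(
        {
            "n_motifs": [stats.n_motifs],
            "mean_spacing": [stats.mean_spacing],
            "median_spacing": [stats.median_spacing],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genes_bed(path) -> pd.DataFrame:
    """BED4+/BED6 gene annotations (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if "strand" not in df:
        df["strand"] = "."
    return df[["gene_id", "chrom", "start", "end", "strand"]]


_GFF_ID = re.compile(r"(?:^|;)(?:ID|gene_id|Name)=([^;]+)")


def read_genes_gff(path, feature: str = "gene") -> pd.DataFrame:
    """GFF3 gene annotations; converts 1-based closed to 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attr"],
    )
    df = df[df["type"] == feature].copy()
    df["gene_id"] = df["attr"].str.extract(_GFF_ID, expand=False)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    out["score"] = 0
    out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ------------------------------------------------------- counts & tracks

def write_counts_tsv(counts: FragmentCounts, fragments: pd.DataFrame, path) -> None:
    out = fragments[["chrom", "start", "end", "fragment_id"]].copy()
    out["count"] = counts.counts
    out.attrs = {}
    with open(path, "w") as fh:
        fh.write(
            f"# library_id={counts.library_id}\tn_reads_in={counts.n_reads_in}"
            f"\tn_reads_kept={counts.n_reads_kept}\tn_anomalous={counts.n_anomalous}\n"
        )
        out.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> tuple[FragmentCounts, pd.DataFrame]:
    with open(path) as fh:
        meta_line = fh.readline().lstrip("# ").strip()
        meta = dict(item.split("=", 1) for item in meta_line.split("\t"))
        df = pd.read_csv(fh, sep="\t")
    fragments = df[["chrom", "start", "end", "fragment_id"]].copy()
    counts = FragmentCounts(
        library_id=meta["library_id"],
        counts=df["count"].to_numpy(),
        n_reads_in=int(meta["n_reads_in"]),
        n_reads_kept=int(meta["n_reads_kept"]),
        n_anomalous=int(meta.get("n_anomalous", 0)),
    )
    return counts, fragments


def write_bedgraph(track: OccupancyTrack, path) -> None:
    out = track.fragments[["chrom", "start", "end"]].copy()
    out["score"] = track.scores
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path) -> OccupancyTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "score"])
    frags = df[["chrom", "start", "end"]].copy()
    frags["fragment_id"] = frags.groupby("chrom").cumcount()
    return OccupancyTrack(fragments=frags, scores=df["score"].to_numpy())


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_set(genes: set[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def read_expression_tsv(path) -> pd.DataFrame:
    """Two-column gene_id / tpm table (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if "tpm" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "tpm"])
    return df[["gene_id", "tpm"]]
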