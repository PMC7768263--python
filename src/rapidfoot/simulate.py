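"""Synthetic genomes, annotations and DamID amplicon libraries.

The generator emulates the statistical structure the occupancy pipeline
assumes, with known ground truth at every level:

* a random genome with GATC motifs at roughly the background rate of a
  uniform sequence (4^-4 per position) plus optionally planted extra
  motifs, so fragment sizes resemble a motif-dense genome;
* non-overlapping genes on both strands, ~2 kb long, a fixed fraction of
  which are expressed with log-normal levels (the rest are silent);
* a saturating methylation model: a fragment inside a gene expressed at
  level e is methylated with probability 1 - exp(-kappa * e).  Once a
  region is fully methylated further transcription adds nothing — the
  plateau that bounds DamID's dynamic range;
* per-fragment accessibility weights (log-normal) shared between the
  fusion and control libraries, which is exactly what dividing by the
  Dam-only control is meant to cancel;
* amplicons spanning 1-3 consecutive fragments with geometrically
  decaying length (mimicking size selection), ends jittered a few bp
  around the flanking motifs, plus a controllable fraction of noise
  reads with one end far from any motif.

Reads are emitted directly as coordinate-level alignment records, so the
whole pipeline is testable without an external aligner; a SAM writer in
:mod:`rapidfoot.io` serialises them when files are needed.

All randomness flows from a single seed through spawned child streams
(one per stage), so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .amplicons import AlignedRead
from .gatc import GATCIndex, find_gatc_sites, make_fragments

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Generative parameters; defaults are the small study-scale preset."""

    n_chroms: int = 1
    chrom_length: int = 3_000_000
    gatc_enrichment: float = 1.0  # extra planted motifs, in units of the 1/256 background
    n_genes: int = 500
    expressed_fraction: float = 0.3
    expression_mu: float = 1.0  # log-normal log-scale mean of expression levels
    expression_sigma: float = 1.0
    methylation_rate: float = 0.5  # kappa: slope of the saturation curve
    baseline_methylation: float = 0.05  # Dam background on silent chromatin
    accessibility_sigma: float = 0.5  # log-scale spread of accessibility weights
    n_reads_fusion: int = 200_000
    n_reads_control: int = 200_000
    end_jitter_max: int = 8
    noise_fraction: float = 0.05
    gene_length_log_mu: float = float(np.log(2000.0))
    gene_length_log_sigma: float = 0.25
    min_gap: int = 500
    max_gap: int = 3000
    short_gap_genes: int = 0  # genes forced to sit short_gap_bp behind a same-strand neighbor
    short_gap_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_genes, self.n_reads_fusion, self.n_reads_control) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.expressed_fraction < 1:
            raise ValueError("expressed_fraction must be in (0, 1)")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.gatc_enrichment < 0 or self.methylation_rate <= 0:
            raise ValueError("gatc_enrichment >= 0 and methylation_rate > 0 required")

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimParams":
        """Unit-test scale: one 200 kb chromosome, 40 genes, 10k reads."""
        return cls(
            chrom_length=200_000,
            n_genes=40,
            n_reads_fusion=10_000,
            n_reads_control=10_000,
            seed=seed,
        )

    @classmethod
    def small(cls, seed: int = 0) -> "SimParams":
        """Study-scale preset (the defaults): 3 Mb, 500 genes, 200k reads/library."""
        return cls(seed=seed)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated libraries."""

    expression: pd.DataFrame  # gene_id, expression, expressed
    fragment_expression: np.ndarray  # expression level backing each fragment
    methylation_prob: np.ndarray  # fusion methylation probability per fragment
    accessibility: np.ndarray  # shared accessibility weight per fragment
    n_noise_reads: dict[str, int] = field(default_factory=dict)


@dataclass
class SimResult:
    params: SimParams
    genome: dict[str, str]
    planted_motifs: dict[str, np.ndarray]
    index: GATCIndex
    fragments: pd.DataFrame
    genes: pd.DataFrame
    truth: SimTruth
    fusion_reads: list[AlignedRead]
    control_reads: list[AlignedRead]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genome(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Random genome plus planted GATC motif truth positions.

    Bases are i.i.d. uniform (background motif rate 1/256 per position);
    ``gatc_enrichment`` plants additional motifs at a Poisson rate of
    ``gatc_enrichment / 256`` per bp, spaced at least 4 bp apart so no
    plant destroys another.
    """
    if params.chrom_length < 1000:
        raise ValueError("chrom_length < 1000 is too short to place genes")
    rng = rng or _streams(params.seed, 4)[0]
    genome: dict[str, str] = {}
    planted: dict[str, np.ndarray] = {}
    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _BASES[rng.integers(0, 4, size=params.chrom_length)]
        n_extra = rng.poisson(params.chrom_length * params.gatc_enrichment / 256)
        pos = np.sort(rng.integers(0, params.chrom_length - 4, size=n_extra))
        if pos.size:
            keep = np.concatenate(([True], np.diff(pos) >= 4))
            pos = pos[keep]
            for p in pos:
                arr[p: p + 4] = _BASES[[2, 0, 3, 1]]  # G A T C
        genome[chrom] = arr.tobytes().decode("ascii")
        planted[chrom] = pos
    return genome, planted


def simulate_annotation(
    genome: dict[str, str],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping genes with expression ground truth.

    Gene lengths are log-normal around 2 kb; inter-gene gaps uniform in
    [min_gap, max_gap], except the first ``short_gap_genes`` gene pairs,
    whose second member is placed exactly ``short_gap_bp`` behind a
    same-strand predecessor to exercise the operon-proximity filter.
    Exactly ``round(expressed_fraction * n_genes)`` genes (chosen at
    random) are expressed, with log-normal levels; the rest are silent.
    """
    rng = rng or _streams(params.seed, 4)[1]
    chroms = list(genome)
    per_chrom = int(np.ceil(params.n_genes / len(chroms)))
    rows = []
    gi = 0
    n_forced = 0
    for chrom in chroms:
        length = len(genome[chrom])
        cursor = rng.integers(params.min_gap, params.max_gap)
        prev_strand = None
        while gi < params.n_genes and len([r for r in rows if r[1] == chrom]) < per_chrom:
            glen = int(np.clip(
                rng.lognormal(params.gene_length_log_mu, params.gene_length_log_sigma),
                200, 20_000,
            ))
            force_short = n_forced < params.short_gap_genes and prev_strand is not None
            gap = params.short_gap_bp if force_short else int(
                rng.integers(params.min_gap, params.max_gap + 1)
            )
            start = cursor + gap if rows and rows[-1][1] == chrom else cursor
            end = start + glen
            if end > length - params.min_gap:
                break
            strand = prev_strand if force_short else ("+" if rng.random() < 0.5 else "-")
            if force_short:
                n_forced += 1
            rows.append((f"gene{gi:05d}", chrom, start, end, strand))
            prev_strand = strand
            cursor = end
            gi += 1
    if gi < params.n_genes:
        raise ValueError(
            f"could only place {gi} of {params.n_genes} genes; "
            "reduce n_genes or enlarge the genome"
        )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    n_expr = int(round(params.expressed_fraction * params.n_genes))
    expressed_idx = rng.choice(params.n_genes, size=n_expr, replace=False)
    levels = np.zeros(params.n_genes)
    levels[expressed_idx] = rng.lognormal(
        params.expression_mu, params.expression_sigma, size=n_expr
    )
    expression = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "expression": levels,
            "expressed": levels > 0,
        }
    )
    return genes, expression


def _fragment_expression(
    fragments: pd.DataFrame, genes: pd.DataFrame, expression: pd.DataFrame
) -> np.ndarray:
    """Expression level backing each fragment (largest-overlap gene, else 0)."""
    level = dict(zip(expression["gene_id"], expression["expression"]))
    out = np.zeros(len(fragments))
    frag_arrays = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy(), grp.index.to_numpy())
        for chrom, grp in fragments.groupby("chrom", sort=False)
    }
    for g in genes.itertuples(index=False):
        if g.chrom not in frag_arrays:
            continue
        starts, ends, rows = frag_arrays[g.chrom]
        lo = np.searchsorted(ends, g.start, side="right")
        hi = np.searchsorted(starts, g.end, side="left")
        for k in range(lo, hi):
            ov = min(ends[k], g.end) - max(starts[k], g.start)
            flen = ends[k] - starts[k]
            # a fragment mostly inside the gene belongs to the gene
            if ov > 0.5 * flen or ov == flen:
                out[rows[k]] = level[g.gene_id]
    return out


def _sample_noise_end(
    pos: int, motifs: np.ndarray, length: int, tol: int, rng: np.random.Generator
) -> int:
    """A coordinate near ``pos`` but > tol bp from every motif interval."""
    for _ in range(200):
        cand = int(np.clip(pos + rng.integers(-300, 301), 1, length - 1))
        i = np.searchsorted(motifs, cand)
        d = np.inf
        if i < motifs.size:
            d = min(d, max(motifs[i] - cand, 0))
        if i > 0:
            d = min(d, max(cand - (motifs[i - 1] + 4), 0))
        if d > tol:
            return cand
    raise RuntimeError("could not place a noise end; motif density too high")


def simulate_damid_library(
    index: GATCIndex,
    fragments: pd.DataFrame,
    fragment_expression: np.ndarray,
    accessibility: np.ndarray,
    params: SimParams,
    role: str,
    rng: np.random.Generator,
    n_reads: int | None = None,
) -> tuple[list[AlignedRead], int]:
    """Sample amplicon alignment records for one library.

    Fusion fragment weight is accessibility * (methylation probability +
    baseline); the control weight is accessibility alone.  Amplicons run
    over 1-3 consecutive fragments (geometric length decay), both ends
    jittered uniformly within ±end_jitter_max of the flanking motif
    boundary; a ``noise_fraction`` of reads get one end moved beyond the
    end tolerance of any motif.  Returns the reads and the number of
    noise reads actually planted.
    """
    if role not in ("fusion", "control"):
        raise ValueError("role must be 'fusion' or 'control'")
    n_reads = n_reads if n_reads is not None else (
        params.n_reads_fusion if role == "fusion" else params.n_reads_control
    )
    p_meth = np.clip(1.0 - np.exp(-params.methylation_rate * fragment_expression), 0, 1 - 1e-12)
    if role == "fusion":
        weights = accessibility * (p_meth + params.baseline_methylation)
    else:
        weights = accessibility.copy()
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total fragment weight")
    prob = weights / total
    frag_chrom = fragments["chrom"].to_numpy()
    frag_start = fragments["start"].to_numpy()
    frag_end = fragments["end"].to_numpy()
    chrom_last_row = {
        chrom: int(grp.index.max()) for chrom, grp in fragments.groupby("chrom", sort=False)
    }
    chrom_len = index.chrom_lengths
    jit = params.end_jitter_max
    start_rows = rng.choice(len(fragments), size=n_reads, p=prob)
    # geometric length decay over 1..3 fragments (p = 0.5, truncated)
    lengths = np.minimum(rng.geometric(0.5, size=n_reads), 3)
    jitters = rng.integers(-jit, jit + 1, size=(n_reads, 2))
    noise_flags = rng.random(n_reads) < params.noise_fraction
    noise_side = rng.integers(0, 2, size=n_reads)
    reads: list[AlignedRead] = []
    n_noise = 0
    for r in range(n_reads):
        row = int(start_rows[r])
        chrom = frag_chrom[row]
        last = min(row + int(lengths[r]) - 1, chrom_last_row[chrom])
        length = chrom_len[chrom]
        rs = int(np.clip(frag_start[row] + jitters[r, 0], 0, length - 2))
        re_ = int(np.clip(frag_end[last] + jitters[r, 1], rs + 1, length))
        if noise_flags[r]:
            motifs = index.motif_starts[chrom]
            if noise_side[r] == 0:
                rs = _sample_noise_end(rs, motifs, length, jit, rng)
            else:
                re_ = _sample_noise_end(re_, motifs, length, jit, rng)
            if rs >= re_:
                rs, re_ = min(rs, re_), max(rs, re_)
                if rs == re_:
                    re_ += 1
            n_noise += 1
        reads.append(
            AlignedRead(
                read_id=f"{role}_{r:07d}", chrom=chrom, ref_start=rs, ref_end=re_,
            )
        )
    return reads, n_noise


def simulate_dataset(params: SimParams | None = None) -> SimResult:
    """Run the full generator: genome, genes, truth, and both libraries."""
    params = params or SimParams()
    g_rng, a_rng, acc_rng, lib_rng = _streams(params.seed, 4)
    genome, planted = simulate_genome(params, g_rng)
    index = find_gatc_sites(genome)
    fragments = make_fragments(index)
    genes, expression = simulate_annotation(genome, params, a_rng)
    frag_expr = _fragment_expression(fragments, genes, expression)
    accessibility = acc_rng.lognormal(0.0, params.accessibility_sigma, size=len(fragments))
    fus_rng, ctl_rng = _streams(int(lib_rng.integers(0, 2**31 - 1)), 2)
    fusion_reads, n_noise_f = simulate_damid_library(
        index, fragments, frag_expr, accessibility, params, "fusion", fus_rng
    )
    control_reads, n_noise_c = simulate_damid_library(
        index, fragments, frag_expr, accessibility, params, "control", ctl_rng
    )
    p_meth = np.clip(1.0 - np.exp(-params.methylation_rate * frag_expr), 0, 1 - 1e-12)
    truth = SimTruth(
        expression=expression,
        fragment_expression=frag_expr,
        methylation_prob=p_meth,
        accessibility=accessibility,
        n_noise_reads={"fusion": n_noise_f, "control": n_noise_c},
    )
    return SimResult(
        params=params,
        genome=genome,
        planted_motifs=planted,
        index=index,
        fragments=fragments,
        genes=genes,
        truth=truth,
        fusion_reads=fusion_reads,
        control_reads=control_reads,
    )
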