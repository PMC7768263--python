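"""Pipeline configuration and end-to-end orchestration.

A single validated config drives index → filter → normalize → call →
sets → profiles, writing every artifact under one output directory and a
manifest listing outputs with a hash of the configuration.  Stage
outputs are pure functions of (inputs, parameters, seed): rerunning an
identical config reproduces byte-identical text outputs.  The global
seed fans out to per-stage seeds by stable derivation, so adding a stage
never shifts another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as rio
from .amplicons import FilterParams, count_fragments, filter_alignments
from .gatc import find_gatc_sites, gatc_stats, make_fragments
from .genecalls import CallParams, call_expressed, detected_set, gene_occupancy
from .occupancy import NormParams, normalize_counts
from .profiles import ProfileParams, metagene
from .simulate import SimParams, simulate_dataset

log = logging.getLogger("rapidfoot")


class FilterConfig(BaseModel):
    end_tolerance: int = 8
    min_mapq: int = 10
    keep_secondary: bool = False


class NormConfig(BaseModel):
    pseudocount: float = Field(0.5, gt=0)
    scaling: str = "library_size"
    chip_pseudocount: float = 8.0

    @field_validator("scaling")
    @classmethod
    def _scaling(cls, v):
        if v not in ("library_size", "kde_mode"):
            raise ValueError("scaling must be 'library_size' or 'kde_mode'")
        return v


class CallConfig(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    n_permutations: int = Field(10_000, ge=100)
    min_fragments_per_gene: int = 1


class ProfileConfig(BaseModel):
    n_body_bins: int = Field(100, ge=2)
    flank_bp: int = 1000
    n_flank_bins: int = 20
    bin_size_genes: int = Field(690, ge=1)


class SimConfig(BaseModel):
    preset: str = "tiny"
    n_genes: int | None = None
    chrom_length: int | None = None
    n_reads_fusion: int | None = None
    n_reads_control: int | None = None


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-friendly)."""

    outdir: str
    seed: int = 0
    genome: str | None = None
    genes: str | None = None
    fusion_alignments: str | None = None
    control_alignments: str | None = None
    simulate: SimConfig | None = None
    filter: FilterConfig = FilterConfig()
    normalize: NormConfig = NormConfig()
    call: CallConfig = CallConfig()
    profile: ProfileConfig = ProfileConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "outputs": []}

    def emit(name: str):
        manifest["outputs"].append(name)
        return outdir / name

    try:
        if config.simulate is not None:
            sp = (
                SimParams.tiny(seed=_stage_seed(config.seed, "simulate"))
                if config.simulate.preset == "tiny"
                else SimParams.small(seed=_stage_seed(config.seed, "simulate"))
            )
            for fld in ("n_genes", "chrom_length", "n_reads_fusion", "n_reads_control"):
                v = getattr(config.simulate, fld)
                if v is not None:
                    sp = sp.__class__(**{**sp.__dict__, fld: v})
            log.info("simulate: preset=%s seed=%d", config.simulate.preset, sp.seed)
            sim = simulate_dataset(sp)
            rio.write_fasta(sim.genome, emit("genome.fa"))
            rio.write_genes_bed(sim.genes, emit("genes.bed"))
            sim.truth.expression.to_csv(emit("expression_truth.tsv"), sep="\t", index=False)
            rio.write_sam(sim.fusion_reads, sim.index.chrom_lengths, emit("fusion.sam"))
            rio.write_sam(sim.control_reads, sim.index.chrom_lengths, emit("control.sam"))
            genome, genes = sim.genome, sim.genes
            fusion_reads, control_reads = sim.fusion_reads, sim.control_reads
        else:
            for fld in ("genome", "genes", "fusion_alignments", "control_alignments"):
                p = getattr(config, fld)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config field {fld!r}: missing file {p!r}")
            genome = rio.read_fasta(config.genome)
            genes = (
                rio.read_genes_gff(config.genes)
                if str(config.genes).endswith((".gff", ".gff3"))
                else rio.read_genes_bed(config.genes)
            )
            fusion_reads = rio.read_alignments(config.fusion_alignments)
            control_reads = rio.read_alignments(config.control_alignments)

        log.info("stage index")
        index = find_gatc_sites(genome)
        fragments = make_fragments(index)
        rio.write_motif_bed(index, emit("gatc_motifs.bed"))
        rio.write_fragment_bed(fragments, emit("gatc_fragments.bed"))
        rio.write_stats_tsv(gatc_stats(index), emit("gatc_stats.tsv"))

        log.info("stage filter")
        fparams = FilterParams(**config.filter.model_dump())
        kept_f, report_f = filter_alignments(fusion_reads, index, fparams)
        kept_c, report_c = filter_alignments(control_reads, index, fparams)
        counts_f = count_fragments(kept_f, fragments, fparams, "fusion", report_f.n_reads_in)
        counts_c = count_fragments(kept_c, fragments, fparams, "control", report_c.n_reads_in)
        rio.write_counts_tsv(counts_f, fragments, emit("counts_fusion.tsv"))
        rio.write_counts_tsv(counts_c, fragments, emit("counts_control.tsv"))
        with open(emit("filter_report.txt"), "w") as fh:
            for name, rep in (("fusion", report_f), ("control", report_c)):
                fh.write(f"{name}.n_reads_in: {rep.n_reads_in}\n")
                fh.write(f"{name}.n_reads_kept: {rep.n_reads_kept}\n")
                for k, v in rep.rejected.items():
                    fh.write(f"{name}.rejected.{k}: {v}\n")

        log.info("stage normalize")
        nparams = NormParams(**config.normalize.model_dump())
        track = normalize_counts(counts_f, counts_c, nparams, fragments=fragments)
        rio.write_bedgraph(track, emit("occupancy.bedgraph"))

        log.info("stage call")
        cparams = CallParams(
            seed=_stage_seed(config.seed, "call"), **config.call.model_dump()
        )
        values = gene_occupancy(track, genes)
        calls = call_expressed(values, track, cparams)
        rio.write_calls_tsv(calls, emit("gene_calls.tsv"))

        log.info("stage sets")
        detected = detected_set([calls], mode="any", alpha=cparams.alpha)
        rio.write_gene_set(detected, emit("detected_genes.txt"))

        log.info("stage profiles")
        pparams = ProfileParams(**config.profile.model_dump())
        prof = metagene(track, genes, pparams)
        import pandas as pd

        pd.DataFrame(
            {"position": prof.positions, "mean_score": prof.mean_score, "n_genes": prof.n_genes}
        ).to_csv(emit("metagene.tsv"), sep="\t", index=False)
    except Exception:
        manifest["status"] = "failed"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["status"] = "ok"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
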