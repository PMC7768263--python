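"""Per-gene occupancy aggregation, significance calls, and tissue-set algebra.

A gene's occupancy is the overlap-length-weighted mean of the scores of
the GATC fragments its body touches (introns included — the polymerase
transits them, and DamID cannot resolve isoforms anyway).  Significance
is assessed against a stratified genome-wide permutation null: for each
observed fragment count n, null gene scores are means of n fragment
scores taken from random permutations of the genome-wide score vector.
This is distribution-free, respects per-gene fragment counts, and is
reproducible under a seed.  Empirical p-values are plus-one corrected
and adjusted by Benjamini–Hochberg.

Tissue-level definitions:

* detected      — FDR < alpha in at least one replicate;
* consistent    — FDR < alpha in every replicate;
* unique        — in one tissue's consistent set and no other's;
* shared_all    — in every tissue's consistent set.

Marker-candidate refinement removes genes detected in any whole-animal
sample (a marker of a rare cell type must be invisible genome-wide) and
genes with another transcript ending strictly less than ``upstream_gap``
bp upstream (likely operon members whose promoter is not their own).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .occupancy import OccupancyTrack


@dataclass
class CallParams:
    alpha: float = 0.05
    n_permutations: int = 10_000
    min_fragments_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def gene_occupancy(track: OccupancyTrack, genes: pd.DataFrame) -> pd.DataFrame:
    """Overlap-weighted mean fragment score per gene body.

    Parameters
    ----------
    genes : DataFrame with columns gene_id, chrom, start, end (0-based
        half-open) and optionally strand.

    Returns
    -------
    DataFrame with gene_id, occupancy, n_fragments.  Genes overlapping no
    fragment (e.g. on an unindexed chromosome arm) get NaN occupancy and
    n_fragments 0.
    """
    frags = track.fragments
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in frags.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            track.scores[grp.index.to_numpy()],
        )
    chrom_ends = {c: int(e[-1]) for c, (s, e, _) in by_chrom.items()}
    occ = np.full(len(genes), np.nan)
    nfr = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes.itertuples(index=False)):
        if g.chrom not in by_chrom:
            continue
        starts, ends, scores = by_chrom[g.chrom]
        if g.start < 0 or g.end > chrom_ends[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id!r} [{g.start},{g.end}) outside chromosome bounds"
            )
        lo = np.searchsorted(ends, g.start, side="right")
        hi = np.searchsorted(starts, g.end, side="left")
        if hi <= lo:
            continue
        w = np.minimum(ends[lo:hi], g.end) - np.maximum(starts[lo:hi], g.start)
        occ[i] = np.average(scores[lo:hi], weights=w)
        nfr[i] = hi - lo
    return pd.DataFrame(
        {"gene_id": genes["gene_id"].to_numpy(), "occupancy": occ, "n_fragments": nfr}
    )


def _null_means(
    scores: np.ndarray, strata: np.ndarray, n_perm: int, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Permutation null of mean fragment score for each stratum size.

    One genome-wide permutation per iteration serves every stratum: the
    mean of its first n elements is a draw of an n-fragment null gene.
    """
    max_n = int(strata.max())
    out = {int(n): np.empty(n_perm) for n in strata}
    ns = [int(n) for n in strata]
    for b in range(n_perm):
        perm = rng.permutation(scores)
        cs = np.cumsum(perm[:max_n])
        for n in ns:
            out[n][b] = cs[n - 1] / n
    return out


def call_expressed(
    values: pd.DataFrame,
    track: OccupancyTrack,
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Significance calls for per-gene occupancy values.

    ``values`` is the output of :func:`gene_occupancy`.  For each gene,
    p = (1 + #{null >= observed}) / (B + 1) within its fragment-count
    stratum; genes below ``min_fragments_per_gene`` (or with no
    fragments) are excluded from testing and carry NaN p/FDR.  FDR is
    Benjamini–Hochberg over all tested genes.
    """
    params = params or CallParams()
    if len(values) < 10:
        raise ValueError("need at least 10 genes to calibrate an FDR")
    rng = np.random.default_rng(params.seed)
    testable = (values["n_fragments"] >= params.min_fragments_per_gene) & np.isfinite(
        values["occupancy"]
    )
    out = values.copy()
    out["p_value"] = np.nan
    out["fdr"] = np.nan
    if not testable.any():
        return out
    n_frag = out.loc[testable, "n_fragments"].to_numpy()
    max_n = len(track.scores)
    clipped = np.minimum(n_frag, max_n)
    if (clipped < n_frag).any():
        warnings.warn("some genes span more fragments than the genome pool; clipped")
    strata = np.unique(clipped)
    nulls = _null_means(track.scores, strata, params.n_permutations, rng)
    obs = out.loc[testable, "occupancy"].to_numpy()
    B = params.n_permutations
    p = np.empty(obs.size)
    for j, (o, n) in enumerate(zip(obs, clipped)):
        null = nulls[int(n)]
        p[j] = (1 + np.count_nonzero(null >= o)) / (B + 1)
    out.loc[testable, "p_value"] = p
    out.loc[testable, "fdr"] = multipletests(p, method="fdr_bh")[1]
    return out


def detected_set(
    calls: list[pd.DataFrame], mode: str = "any", alpha: float = 0.05
) -> set[str]:
    """Union ("any") or intersection ("all") of significant genes across replicates."""
    if not calls:
        raise ValueError("need at least one replicate")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    universes = [set(c["gene_id"]) for c in calls]
    universe = set.intersection(*universes)
    if any(u != universe for u in universes):
        warnings.warn("replicate gene universes differ; restricted to common universe")
    sig = [
        set(c.loc[(c["fdr"] < alpha) & c["gene_id"].isin(universe), "gene_id"])
        for c in calls
    ]
    return set.union(*sig) if mode == "any" else set.intersection(*sig)


@dataclass
class TissueSets:
    consistent: dict[str, set[str]]
    unique: dict[str, set[str]]
    shared_all: set[str]
    venn: dict[frozenset, int]


def tissue_partition(consistent: dict[str, set[str]]) -> TissueSets:
    """Unique-per-tissue sets, shared core, and the full Venn region table.

    ``unique[t]`` is tissue t's consistent set minus every other tissue's;
    ``venn`` maps each non-empty tissue combination to the count of genes
    in exactly those tissues (regions are disjoint and sum to the union).
    """
    tissues = list(consistent)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    unique = {
        t: consistent[t] - set.union(*(consistent[o] for o in tissues if o != t))
        for t in tissues
    }
    shared_all = set.intersection(*consistent.values())
    venn: dict[frozenset, int] = {}
    universe = set.union(*consistent.values())
    membership = {g: frozenset(t for t in tissues if g in consistent[t]) for g in universe}
    from itertools import combinations

    for k in range(1, len(tissues) + 1):
        for combo in combinations(tissues, k):
            key = frozenset(combo)
            venn[key] = sum(1 for m in membership.values() if m == key)
    return TissueSets(consistent=consistent, unique=unique, shared_all=shared_all, venn=venn)


def upstream_neighbor_gaps(
    genes: pd.DataFrame, same_strand_only: bool = True
) -> pd.Series:
    """Strand-aware gap (bp) to each gene's nearest upstream neighbor.

    For a + strand gene, upstream is the nearest gene ending at or before
    its start; for a − strand gene, the nearest gene starting at or after
    its end.  ``same_strand_only`` restricts neighbors to the same strand
    (operons run in one direction).  NaN when no neighbor exists.
    """
    gaps = pd.Series(np.nan, index=genes["gene_id"].to_numpy(), dtype=float)
    for chrom, grp in genes.groupby("chrom", sort=False):
        recs = grp.sort_values("start").reset_index(drop=True)
        for i, g in recs.iterrows():
            if same_strand_only:
                others = recs[(recs["strand"] == g["strand"]) & (recs["gene_id"] != g["gene_id"])]
            else:
                others = recs[recs["gene_id"] != g["gene_id"]]
            if g["strand"] == "+":
                ups = others[others["end"] <= g["start"]]
                if len(ups):
                    gaps[g["gene_id"]] = g["start"] - ups["end"].max()
            else:
                downs = others[others["start"] >= g["end"]]
                if len(downs):
                    gaps[g["gene_id"]] = downs["start"].min() - g["end"]
    return gaps


def marker_candidates(
    target_unique: set[str],
    whole_animal_detected: list[set[str]],
    genes: pd.DataFrame,
    upstream_gap: int = 200,
    same_strand_only: bool = True,
) -> set[str]:
    """Refine tissue-unique genes into marker candidates.

    Removes genes detected in ANY whole-animal replicate set, genes with
    an upstream neighbor ending strictly less than ``upstream_gap`` bp
    away (a neighbor exactly ``upstream_gap`` bp away is retained), and
    genes with no strand annotation (gap undecidable; warned).
    """
    candidates = set(target_unique)
    for wa in whole_animal_detected:
        candidates -= wa
    sub = genes[genes["gene_id"].isin(candidates)]
    missing = sub[~sub["strand"].isin(["+", "-"])]["gene_id"]
    if len(missing):
        warnings.warn(f"{len(missing)} candidate(s) lack strand; excluded")
        candidates -= set(missing)
    gaps = upstream_neighbor_gaps(genes, same_strand_only=same_strand_only)
    for gid in sorted(candidates):
        gap = gaps.get(gid, np.nan)
        if np.isfinite(gap) and gap < upstream_gap:
            candidates.discard(gid)
    return candidates


def set_overlap(a: set[str], b: set[str]) -> tuple[int, float | None]:
    """|a ∩ b| and the fraction of a covered by b (None for empty a)."""
    inter = len(a & b)
    return inter, (inter / len(a) if a else None)


def subset_similarity_test(subset_values, full_values) -> dict:
    """Classical two-sample Student's t-test (pooled variance).

    Used to check that a refined candidate subset has occupancy values
    similar to the set it was drawn from.  Returns t, p, and each group's
    mean/SD (ddof=1).
    """
    x = np.asarray(subset_values, dtype=float)
    y = np.asarray(full_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return {
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_subset": float(x.mean()),
        "sd_subset": float(x.std(ddof=1)),
        "mean_full": float(y.mean()),
        "sd_full": float(y.std(ddof=1)),
    }
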