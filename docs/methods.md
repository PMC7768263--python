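# Methods

## Signal model

RAPID reads out transcription indirectly: a Dam methyltransferase fused
to a shared RNA polymerase subunit methylates adenines in GATC motifs
near transcribed DNA. The unit of signal is the **GATC fragment** — the
interval between two consecutive GATC motifs — because DpnI cuts at
methylated GATCs and the sequenced amplicons are unions of consecutive
fragments. Methylation accumulates between DNA replications, so the
signal is a time-integrated footprint, not an occupancy snapshot: highly
expressed genes saturate ("plateau effect") once every GATC in the gene
body is methylated, and very lowly expressed genes are rarely visited by
a Dam-carrying polymerase.

All coordinates are 0-based half-open. GFF3 input is converted from
1-based closed on read; BED and bedGraph output stay 0-based half-open.

## Stage by stage

### GATC index

Motifs are found by case-insensitive exact scan; windows containing N
never match, so soft-masked genomes keep their motifs. Fragment
boundaries are placed at motif *start* positions rather than at the
biological cut site two bases in: the 2 bp offset is far inside the
amplicon end tolerance, and a single convention avoids off-by-one
drift. Spacing statistics are differences of consecutive motif starts
within a chromosome, pooled genome-wide for mean and median. An
alternative "mean spacing" definition — genome length divided by motif
count — differs on real genomes because chromosome ends and motif-poor
regions enter the denominator; the pooled-difference definition is the
one reported.

### Amplicon filter

A read is accepted as a DamID amplicon when **both** aligned ends are
within `end_tolerance` bp (default 8, inclusive) of a GATC motif. The
"end" is the aligned reference span with soft-clips excluded, since
adapter remnants appear as clips while the genomic footprint is the
aligned interval. Distance is measured to the closed 4 bp motif
interval rather than to a single anchor base: the choice of anchor is
unstated in the underlying protocol, interval distance is symmetric for
this palindromic motif, and any residual convention difference (≤ 3 bp)
is absorbed by the 8 bp tolerance. Secondary and supplementary
alignments are dropped by default and the MAPQ floor is 10 — amplicons
are short unique fragments, and multimappers would inflate fragment
counts; both are tunable. Reads are never extended.

Counting rule: a fragment is incremented when its entire interval lies
within `[ref_start − δ, ref_end + δ)`. A true amplicon is a union of
complete consecutive fragments, so whole-fragment containment with the
δ margin is the faithful rule; midpoint or fractional-overlap rules
would let end jitter leak counts into flanking fragments. A kept read
that covers no complete fragment is tallied as anomalous, never
silently dropped.

### Occupancy normalization

Default scaling is library-size: each library is scaled to its total
and a counts-per-million pseudocount ψ (default 0.5 CPM) added to both
before the log2 ratio. The score is computed as a difference of logs so
that swapping fusion and control negates every score *exactly* (to the
last bit), which the antisymmetry test asserts. An optional
`kde_mode` scaling subtracts the kernel-density mode of the score
distribution afterwards — appropriate when most fragments are unbound
and the silent bulk should read zero; with plain library-size scaling
the silent bulk sits below zero whenever expressed genes absorb a large
share of fusion reads. No smoothing is applied anywhere.

The ChIP-style comparison path is separate: coverage vectors are scaled
to a common fixed reference total (default 10⁶) before a raw-count
pseudocount of 8 is added. Scaling to a *fixed* reference, rather than
to each other, is what makes the score invariant under joint depth
changes while keeping the pseudocount's influence stable.

### Gene calls

Per-gene occupancy is the overlap-length-weighted mean of fragment
scores across the annotated gene body, introns included — polymerase
transits introns and DamID cannot resolve isoforms. Significance uses a
stratified genome-wide permutation null: for each permutation the
fragment-score vector is shuffled once, and for every observed
fragment-count stratum n the mean of the first n entries is one null
draw; a gene's p-value is the plus-one-corrected fraction of null draws
at or above its occupancy, `p = (1 + #{null ≥ obs}) / (B + 1)`, with
B = 10,000 permutations by default. The null compares a gene's weighted
mean against unweighted null means of the same fragment count; for the
fragment-size distributions in play the difference is negligible
relative to the permutation resolution. FDR is Benjamini–Hochberg
(via statsmodels), asserted exact against the closed-form step-up on a
hand-listed p-vector.

Set definitions: *detected* = FDR < α in ≥ 1 replicate; *consistent* =
in all replicates; *unique* = one tissue's consistent set minus the
union of the others' (no additional effect-size threshold — none is
specified by the protocol this implements); *shared* = intersection
across tissues. Marker refinement removes candidates detected in ANY
whole-animal replicate (the most stringent exclusion), and genes whose
strand-aware upstream neighbor ends strictly less than 200 bp before
their start — likely operon members transcribed from an upstream
promoter. Same-strand neighbors are considered by default (operons run
in one direction); an any-strand mode is exposed. A neighbor exactly
200 bp away is retained. The subset-similarity check is a classical
pooled-variance Student's t-test, not Welch.

### Profiles and bootstrap

Metagene profiles expand fragment scores to per-base values (each base
inherits its fragment's score), rescale each gene body to 100 equal
bins, add 1 kb flanks in 20 fixed-bp bins, reverse minus-strand genes
so the TSS is always left, and average across genes unweighted. Genes
shorter than the body grid are skipped and counted; flank bases beyond
a chromosome end are treated as missing.

Ranked-bin comparison sorts genes by occupancy ascending (ties broken
by gene id for determinism) and averages expression over consecutive
bins of 690 genes (the bin width that splits a ~20,700-gene genome into
30 bins; configurable).

The true-positive-rate estimator is a plain percentile bootstrap:
resample the n binary reporter outcomes with replacement B times
(default 10,000; the convergence test uses 100,000) and take the 2.5/97.5
percentiles of the resampled positive fraction. As B → ∞ these converge
to exact quantiles of Binomial(n, k/n)/n; for 8 positives of 11 the
lower bound is 5/11 ≈ 45.5% and the upper bound is 11/11 = 100%.
A percentile bootstrap of 8/11 cannot produce an upper bound below
10/11, so any smaller published upper bound for this ratio must come
from a different resampling scheme (e.g. adding smoothing or a prior);
only the lower bound is treated as reproducible here, and the
extrapolation helper accepts any interval. Extrapolation multiplies
the interval by the detected-gene total, rounding exactly or to the
nearest 100 for headline-style reporting. BCa and normal-approximation
intervals were deliberately not used: with n = 11 the percentile
interval is the least-assumption choice and is directly checkable
against the exact binomial.

## Synthetic-data generator

The generator emulates: (i) a uniform-random genome (background GATC
rate 4⁻⁴ per bp) with optional extra motifs planted at a Poisson rate,
spaced ≥ 4 bp so plants never destroy each other; (ii) non-overlapping
~2 kb genes on both strands with gaps of 0.5–3 kb, a fixed 30% of which
are expressed with log-normal(μ=1, σ=1) levels (an exact count, not
Bernoulli, so truth sets have deterministic size); (iii) saturating
methylation: a fragment backed by a gene at expression e is methylated
with probability `1 − exp(−κ·e)`, κ = 0.5 — the simplest kinetics with
the right plateau behaviour; no quantitative methylation kinetics are
established for this system, so κ is an exposed free parameter;
(iv) log-normal per-fragment accessibility (σ = 0.5) shared by both
libraries — the confounder the Dam-only division must cancel; fusion
fragment weight is `accessibility × (p_meth + baseline)` with baseline
0.05 (background methylation of silent chromatin), control weight is
accessibility alone; (v) amplicons spanning 1–3 consecutive fragments
with geometric length decay (mimicking size selection), both ends
jittered uniformly within ±8 bp of the flanking motif boundary;
(vi) a 5% noise fraction of reads with one end placed > 8 bp from every
motif, which the end filter must reject. Reads are emitted directly as
coordinate-level alignment records (serialisable to SAM), skipping an
aligner dependency.

Two presets: `tiny` (200 kb, 40 genes, 10k reads/library; unit-test
scale, < 1 s) and `small` (3 Mb, 500 genes, 200k reads/library; the
study-scale configuration used by the end-to-end recovery tests,
~20 s). All randomness flows from one seed through spawned child
streams, one per stage, so adding a stage never shifts another stage's
draws; the pipeline derives per-stage seeds from the global seed by
hashing stage names.

**What passing on synthetic data does and does not show.** The
generator reproduces the features the statistics rely on — fragment
structure, end geometry, accessibility confounding, saturation,
expression-dependent coverage — but not nanopore base-calling error,
PCR-cycle bias, replication-timing erasure in dividing cells, GATC
density covariation with gene class, or isoform structure. Recovery
results on synthetic data therefore validate the *inference machinery*
(filtering, normalization, calibration of the permutation null, FDR
control), not the biological accuracy of RAPID on any particular real
library.

## Numerical choices and degenerate inputs

- Empty genome → empty index; a chromosome with < 2 motifs contributes
  no spacings; stats are reported absent when no chromosome has two.
- Zero-total libraries and mismatched fragment lists are structural
  errors; the pseudocount guarantees finite scores otherwise.
- Zero-variance tracks make Pearson correlation undefined; reported as
  absent with a warning, not as an exception.
- Genes spanning more fragments than the pool (pathological) are
  clipped to the pool size with a warning; genes under
  `min_fragments_per_gene` carry NaN p/FDR and are excluded from BH.
- Permutation p-values are plus-one corrected, so the smallest
  attainable p is 1/(B+1) and no p is ever 0.
- Ranked bins: the last bin may be short; it is reported with its own
  gene count rather than merged.

## Known limitations

- The per-read Python loop in filtering and counting handles the
  hundreds of thousands of reads used here in seconds, but very large
  libraries (tens of millions of reads) would want a vectorised path.
- The permutation null treats fragments as exchangeable genome-wide;
  strong large-scale covariates (chromatin domains, GC) would argue for
  a blocked or local permutation, not implemented.
- `kde_mode` centering assumes a unimodal silent bulk; it will
  mis-center degenerate score distributions with a dominant expressed
  mode.
- The upstream-neighbor scan is quadratic per chromosome; fine for
  annotation sizes used here (≤ thousands of genes per chromosome).
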