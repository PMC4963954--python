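# Methods and design notes

This note records the models, conventions and deliberate choices behind
`epigsc`, in the spirit of a methods appendix: what each procedure assumes,
which knobs matter, what the synthetic data does and does not emulate, and
where the design was genuinely open.

## Coordinates and regions

All intervals are 0-based half-open (BED convention) internally; the one
1-based input (the bisulfite position column) is converted at the reader.
The promoter is the strand-aware window [TSS−2000, TSS+500) — 2500 bp
exactly — used uniformly for bivalent calling, the peak–promoter fraction
and methylation scoring. A peak's "center" is the floored midpoint.
Nearest-TSS distances are signed in transcribed orientation (upstream
negative); ties on absolute distance resolve to the lexicographically
smaller gene id so results are order-independent. An unsigned mode is
available (`signed=False`).

## Tracks and clustering

Coverage is binned at 50 bp; RPKM for a bin with count c is
c / (bin_kb × library_millions), with the library size defined as the
total number of binned reads. Reads are treated as point positions (5′
ends); fragment-shift handling belongs to upstream peak calling and is out
of scope here.

The clustering pipeline is blur → sqrt → window matrix → K-means:

- **Blur**: rectangular (boxcar) mean with *truncated* edges — the mean is
  taken over the in-bounds part of the window, so constant signal is
  preserved exactly at chromosome ends. The half-width default is 1 bin
  (150-bp effective window); the kernel width is a free parameter because
  only the kernel shape, not its width, is conventionally fixed.
- **sqrt**: elementwise square root (variance-stabilising for counts,
  damping outliers); negative input is rejected rather than clipped.
- **Window matrix**: one row per region over [center−5 kb, center+5 kb) at
  the track bin width (200 columns at defaults); out-of-chromosome columns
  are zero-filled so all rows align.
- **K-means**: explicit Lloyd iterations with seeded k-means++
  initialisation, Euclidean distance, at most 300 iterations or until no
  centroid moves more than 1e-6. Writing Lloyd's loop out (rather than
  wrapping a library fit) lets the result carry its full inertia trace —
  asserted non-increasing in tests — and makes the stopping rule explicit;
  a library K-means serves as an independent cross-check on separated data.
  Empty clusters re-seed at the worst-fit point. Labels are renumbered by
  descending centroid mean, because raw K-means label order is arbitrary
  and irreproducible. Rows and columns are *not* standardised before
  clustering — only blur and sqrt are applied — since the inputs are
  already on a common RPKM scale; users clustering heterogeneous tracks
  should be aware of this.

Defaults: k = 4 for enhancer clustering (shared / cell-type-specific ×2 /
weak is the expected structure), k = 3 for promoter methylation; both
configurable.

## Chromatin state

Enhancer candidates are H3K4me1 peaks, by default excluding those whose
center lies within 2 kb of any TSS (promoter-proximal H3K4me1 reflects
promoter chromatin; the exclusion is a flag because either convention is
defensible). "Presence of H3K27ac" is ≥ 1 bp overlap between peak
intervals; a minimum-overlap-fraction option exists for stricter callers.
Active ∪ poised partitions the candidate set by construction. Bivalent
promoters require any-overlap of both H3K4me3 and H3K27me3 with the
promoter window; the count is monotone non-increasing as either peak set
shrinks (property-tested).

Cell-type-specific enhancer sets are derived from the clustering, not from
naive set subtraction, because subtraction is brittle against
near-threshold peaks; each cluster class exports a BED and a
nearest-gene-within-200-kb set for expression comparison.

## Methylation

Two assay families with different physics are reduced to per-window scores:

- **Capture (enrichment)**: rms = window RPKM / window CpG count. Dividing
  by CpG count compensates enrichment's dependence on local CpG density.
  This is a deliberately simple monotone surrogate for full coupling-factor
  machinery: every downstream consumer (clustering, calling, correlation,
  any-window gene calls) is monotone in the score, so a monotone surrogate
  preserves the analysis semantics. Windows without CpGs are `no_data` —
  capture signal is uninterpretable where there is nothing to capture.
- **Bisulfite**: ams = ΣC/Σ(C+T) pooled over the window's CpGs (C =
  unconverted = methylated evidence). Pooling weights sites by coverage; a
  per-site averaging option would weight sites equally — pooling is the
  default because it is the maximum-likelihood estimate under a common
  within-window methylation level. Windows with summed coverage below 10
  (a conventional bisulfite minimum) are `no_data`.

**Calling.** Bisulfite windows are tested with one-sided exact binomial
tails P(X ≥ ΣC | n = Σ(C+T), p₀) for p₀ = 0.25 (*methylated*) and 0.75
(*highly methylated*). The two test families are Benjamini–Hochberg
adjusted separately — they answer different questions over the same windows
— and called at FDR < 0.01, high call taking precedence. Capture windows
are tested against the matched input library: an exact binomial on the
capture count out of capture+input with null proportion equal to the
capture library's share of pooled depth, BH across windows, and called
highly methylated only when additionally the depth-normalised fold change
(pseudocount 1) exceeds 2. The input library is the natural comparator
because capture experiments sequence a matched input; testing against a
flat genome background would confound mappability and copy effects the
input absorbs. BH is used for "FDR adjustment" throughout (the default in
this literature's toolchain); the procedure is a parameter.

**Comparison.** Cross-platform agreement is the Pearson correlation of
per-window scores over windows where both assays have data (pairs with
`no_data` dropped and the pair count reported; an option scores them as 0
instead). Gene-level promoter methylation is "any of the five 500-bp
windows called methylated-or-higher" — the permissive reading; gene bodies
use any called 1-kb tile. For the promoter/body co-methylation fraction the
body call counts only tiles *fully inside* the promoter-trimmed body
interior (1-kb margin past the TSS): with plain overlap, a methylated
promoter island would put its own tile onto the gene body and force the
co-methylation fraction to 1.0 regardless of the body's true state.
Transposable-element methylation frequency is the per-family fraction of
loci overlapping a called window, optionally restricted to loci overlapping
CpG islands (the restriction changes only the denominator); empty families
report no-data, not zero.

## Expression statistics

The paired Wilcoxon signed-rank test drops zero differences (the standard
convention), uses midranks for ties, and computes the exact two-sided p for
n ≤ 25 by dynamic programming over the sign-flip null of the rank sum —
identical to full 2ⁿ enumeration (the test oracle) but polynomial. Above
n = 25 it switches to the normal approximation with tie and continuity
corrections; the two branches agree to ~0.01 at the boundary.

Replicate-free differential expression between two count libraries uses a
per-gene two-sided exact binomial of the first library's count out of the
pooled count against the library-share null — the classical two-library
count comparison — with BH q-values and a pseudocount-1 depth-normalised
fold change. Its empirical type-I error on null libraries sits slightly
below nominal (≈ 0.04 at α = 0.05 with ~200-count genes), the usual mild
conservatism of discrete exact tests. It is a single-library-pair test by
design; replicate-aware modelling is out of scope.

## The synthetic-data generator

The generator's defaults are the package's reference study conditions: one
10-Mb chromosome, 500 genes, 100 enhancers in each of four classes
(shared / fgsc-specific / esc-specific / weak), ~1e6 reads per ChIP or
capture library in 50-bp bins, negative-binomial read noise with dispersion
0.1, bisulfite coverage Poisson(30) per CpG with beta-binomial methylation
levels around 0.8 (methylated) and 0.05 (unmethylated) at concentration 50,
and 30 % of promoters methylated per germline sex of which 60 % are shared
between sexes (60 female-only, 60 male-only, 90 shared). These magnitudes
are ordinary for mammalian ChIP/bisulfite work at desk scale; the noise
models (negative binomial for read counts, beta-binomial for bisulfite) are
the field's standard choices and make recovery tests honest rather than
trivially exact.

Layout: the chromosome is divided into equal ≥ 18-kb slots, one gene per
slot, with fixed intra-slot zones for the gene body (+ strand-aware
promoter), one distal enhancer, one transposable-element locus, one
imprinted-DMR-like locus, and promoter-free H3K4me3 peaks. The zoning
guarantees that planted features never collide and that every enhancer is
> 2 kb from every TSS (so the promoter-proximal exclusion never removes a
planted enhancer). CpGs lie on a sparse background grid (150-bp spacing)
with dense islands (10-bp spacing) at 70 % of promoters, at every other TE
locus of each family, and at DMR loci. Promoter methylation is planted only
at CpG-island promoters: enrichment assays cannot register methylation
where there are no CpGs, so island-free "methylated" promoters would be
unmeasurable by construction rather than by assay limitation. Capture reads
concentrate on methylated CpGs (expected bin count ∝ methylated-CpG count,
plus 20 % uniform background); the matched input is uniform.

Couplings emulated: methylated fgsc promoters are expressed ~4× lower in
fgsc; genes nearest a cell-type-specific active enhancer are boosted ~4× in
that cell type; 150 knockdown-responsive genes gain 2–6× in the knockdown
condition; 92 % of promoter-methylated genes are also body-methylated; TE
families differ in methylation frequency between the sexes (LINE/LTR/IAP
higher in the male germline, DNA/SINE higher in the female, per-locus
Bernoulli); DMR loci alternate female-only/male-only methylation.

What the simulation does **not** emulate — and hence what passing recovery
tests do and do not show: no read-level sequences or alignment artifacts,
no mappability or GC structure in the background, no copy-number variation,
no fragment-size effects, no biological replicates, one chromosome, and
planted classes that are well-separated in signal. Recovery at ~100 %
therefore validates the *logic and calibration* of the analysis chain
(normalisation, tests, FDR, partitions, orientation handling), not its
power on marginal real-world signal; the noise dispersions are honest but
the effect sizes are deliberately clear.

Determinism: every assay draws from its own child stream
(`default_rng([seed, stream_id])`), so adding or reordering assays does not
perturb others, and full bundles are byte-identical across runs and
platforms.

## Pipeline and problem sizes

The orchestrated pipeline (simulate → cluster → chromatin → methylation →
integration) passes data between stages as files, caches each stage by an
input digest (config section + upstream digests), and writes a
`summary.json` with sorted keys and no timestamps, so fixed-seed reruns are
byte-identical. The full default-scale pipeline (10-Mb genome, 200k bins,
2500 promoter windows, 10k tiles, 10k-gene DE calibration) completes in
well under a minute on one core; unit tests use a 1.08-Mb, 60-gene
configuration of the same generator.

## Numerical choices and degenerate inputs

- Exact binomial tails come from the regularised incomplete beta
  (`scipy.stats.binom.sf`), verified against full pmf summation to 1e-12
  for all n ≤ 25.
- BH is statsmodels' step-up, verified against a literal implementation and
  permutation-invariant; q ≥ p always.
- Pearson correlation is undefined on constant vectors and reported as an
  error, not silently NaN; fewer than 3 paired windows is an explicit
  insufficient-data error.
- Zero-coverage bisulfite windows and zero-CpG capture windows are
  `no_data` and propagate as such (never counted as unmethylated).
- Zero-read libraries produce all-zero RPKM tracks rather than dividing by
  zero; empty peak sets make the promoter-overlap fraction an error rather
  than 0/0.
- K-means with k greater than the row count, mismatched row ids across
  matrices, or non-aligned flank/bin width are rejected up front.

## Known limitations

- The rms surrogate is monotone-equivalent, not numerically equivalent, to
  coupling-factor-normalised enrichment scores; absolute rms values are not
  comparable across packages.
- The two-library DE test models technical (counting) noise only; with
  biological replicates a dispersion-aware test should replace it.
- Gene-level methylation calls inherit the any-window rule's asymmetry: a
  single called window flags the gene, so gene-level precision depends on
  window-level FDR control.
- The bedGraph reader relies on the writer's header comment for bin width
  and library size; foreign bedGraphs import with defaults.
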