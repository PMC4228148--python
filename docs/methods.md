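# Methods

## Genome partition

All coordinates are internally 0-based half-open; GFF3 (1-based
inclusive) is converted on input, BED consumed natively.  For each
chromosome and strand, the footprints of annotated genes are subtracted
from `[0, L)`; every maximal remaining gap becomes an intergenic block.
Blocks longer than `window_size` (default 500 bp) are tiled with
windows of that size anchored at the block's left edge; a trailing
remainder shorter than `min_window` (default 100 bp) is absorbed into
the final window, otherwise it becomes its own window.  Windows are
therefore between `min_window` and `window_size + min_window − 1` bases
long, except single-window blocks, which are kept whole at any length.
Left-edge anchoring is an arbitrary but fixed choice; the partition is
exactly complete and disjoint per strand, which the test suite asserts
(sum of region lengths equals chromosome length, adjacent boundaries
coincide).

Gene space includes non-coding genes (including tRNA genes) by default,
so a tRNA gene splits the intergenic blocks of its own strand;
`include_noncoding_in_genespace=False` restores a protein-coding-only
subtraction.  Both strands receive windows over their full intergenic
space because the libraries are strand-specific and antisense/cryptic
transcription is the object of study.

## Read counting

A fragment is reduced to its 5′-most reference base (leftmost base on
the plus strand, rightmost on the minus strand; proper pairs are
collapsed to the mate-union span first) and assigned to the single
same-strand region containing that point.  A point rule on a disjoint
partition guarantees that each unique fragment is counted exactly once
— conservation is structural, not approximate — at the cost of
occasionally crediting a boundary-spanning read to the region holding
its 5′ end only.  Fractional or majority-overlap assignment is
deliberately not offered.

Uniqueness defaults to reported-hit-count == 1 where the aligner
provides it (NH tag), else mapping quality ≥ 10; both are configurable.
Library strandedness defaults to the `reverse` dialect (first read
antisense to the transcript), the common convention for dUTP-based
stranded kits; `forward` and `unstranded` are available.  Replicate
agreement is summarized as Pearson r of log2(count + 1) across all
regions; the antisense fraction counts unique fragments whose 5′ base
falls inside a protein-coding footprint on the opposite strand.

## Differential expression

The statistics follow the classical negative-binomial exact-test
formulation for two-condition count data.

**Normalization.**  Median-of-ratios size factors
`s_j = median_i k_ij / (Π_v k_iv)^(1/m)` over regions with all-positive
counts (gene rows dominate this set; silent intergenic windows
contribute nothing).  Size factors are estimated once from the full
region × sample matrix and shared by both analysis scopes.

**Dispersion.**  NB variance is parameterized as `μ + αμ²`.  Per
region, a method-of-moments estimate
`α_i = max(0, (v_i − μ_i ξ)/μ_i²)` uses the within-condition sample
variance of normalized counts pooled across conditions (`v_i`), the
overall normalized mean (`μ_i`), and `ξ = mean_j(1/s_j)` for the
shot-noise term.  The parametric curve `α(μ) = a0 + a1/μ` is fit by
least squares **over regions with μ ≥ 5 normalized counts**
(`fit_mean_floor`): with two replicates per condition the moment
estimator has one degree of freedom per condition, and below a few
counts it is clipped noise whose extreme 1/μ leverage would dominate
the intercept (in experiments it inflated a0 about four-fold).  The
per-region dispersion used by the test is the fitted value
(`dispersion_sharing="fit-only"`, the method's original formulation);
the conservative `maximum` sharing mode — elementwise max of empirical
and fitted — is available in the configuration, but at two replicates
per condition it sacrifices roughly 15–20 % detection per window to
dispersion-estimate noise, which defeats the purpose of the intergenic
screen.  On data with many replicates, where the empirical estimates
are informative, `maximum` is the safer choice.

**Exact test.**  Conditional on a region's total `K = kA + kB`, the
pooled normalized mean under the null is `q = K/(S_A + S_B)` with `S_c`
the summed size factors of condition `c`; each condition sum is NB with
mean `S_c q` and variance `S_c q + α q² Σ_{j∈c} s_j²`.  The p-value is
the total conditional probability of all splits `(a, K−a)` whose
probability does not exceed the observed one (relative tie tolerance
1e-7).  Dispersion 0 is handled as the Poisson limit; `K = 0` gives
p = 1.  For `K > 10,000` the enumeration is pruned outward from the
modal split until the remaining tail mass is below 1e-12 of the
conditional total; exactness is asserted against arbitrary-precision
enumeration for all `K ≤ 50` over a grid of dispersions and size-factor
ratios.

**Multiple testing.**  BH adjustment is applied within gene regions and
within intergenic windows separately, with independent filtering first:
regions whose *smallest achievable* conditional p-value (the most
extreme split at their total) cannot reach the padj cutoff are removed,
and a threshold on the region total K is then chosen on a quantile grid
to maximize the number of discoveries.  Because the exact test
conditions on K, the p-value is independent of K under the null, making
K a textbook-valid filter statistic.  At realistic depths the majority
of intergenic windows are near-silent and untestable; filtering them
out is what makes the window-level screen sensible at all.  Filtered
regions keep their raw p-value and are flagged `tested = False` with no
padj.  Fold changes are `(mean_mut + c)/(mean_wt + c)` with pseudocount
`c = 1` normalized count, so de-repression from zero is finite;
all-zero regions report p = 1 and an undefined fold change.

## Chain building and classification

Significant up-regulated intergenic windows of the same block are
merged into chains.  Adjacency is strict (`contiguity_gap = 0` bases)
and a chained window must carry mutant-condition expression of at least
`expression_continuity_ratio = 0.1` of the block's strongest
significant window.  Windows that are not themselves BH-significant may
still join a chain: *interior* windows (between two significant
windows) join on expression continuity alone, while *terminal*
extensions must additionally be nominally significant (raw p < 0.05) or
lie closer, on a log scale, to the chain maximum than to the data set's
silent-window level (above their geometric mean).  The asymmetry
matters: an interior weak draw flanked by strong signal is almost
certainly the same transcript, whereas unconstrained terminal growth
lets baseline noise stretch a chain onto a gene end or across a tDNA
and silently change its category.

Each chain receives exactly one category, first match wins:

1. **readthrough** — contiguous with the 3′ end of a same-strand
   upstream gene, span overlaps a tDNA, and expression continues past
   the tDNA's far edge (continuity ratio satisfied on the distal side);
2. **five_prime_extension** — contiguous with the 5′ end of a
   same-strand downstream gene;
3. **three_prime_extension** — contiguous with the 3′ end of a
   same-strand upstream gene;
4. **derepressed_intergenic** — everything else.

Readthrough outranks the extensions because a readthrough chain also
touches a gene's 3′ end.  Chains contiguous with genes on both flanks
are categorized by this precedence and flagged ambiguous.  Nearest-site
distance is strand-blind (closest edges, 0 when overlapping or
abutting; ties to the smaller site start), with proximity at ≤ 500 bp
by default.  Down-regulated significant windows are reported but not
categorized.  The published analyses this module emulates merged and
judged such regions by manual browser inspection; these rules are an
explicit, deterministic stand-in, not a claim about any author's visual
criterion.

## Synthetic data

The generator inverts the analysis model.  A genome is assembled from
locus cassettes (event cassettes with fixed internal geometry,
background genes, background tDNAs, ETC sites) placed left-to-right
with random 300–900 bp spacers across a configurable number of
chromosomes; event cassettes are mirrored to the minus strand with
probability 1/2.  Event geometries guarantee realizability: extension
events elevate windows abutting the relevant gene end; readthrough
events elevate windows continuing from a gene's 3′ end across a
*convergent* (opposite-strand) tDNA and beyond it — a same-strand tDNA
is itself an annotated gene and would split the block; de-repression
elevates one isolated window ~300 bp from a tDNA; trans events elevate
a coding gene with no nearby site, mimicking an indirect
regulon-mediated response.

Counts are drawn per region as `NB(mean = s_j · q_i · effect_ij, α)`
with defaults: two replicates per condition; library size factors
(0.8, 1.0, 1.1, 1.25); log-normal gene baseline means
(meanlog = log 50, sdlog = 1); intergenic baseline mean 0.5 (near
silent); dispersion α = 0.1; planted fold 16, within the observed
4.8–21-fold range of the mis-expression phenomena the pipeline targets.
The read-level path emits stranded 100-b records with 5′ positions
uniform within each region, exactly realizing a drawn count matrix, so
counting can be exercised end to end.  Everything is a pure function of
the seed.

What the generator does **not** emulate: positional coverage profiles
within a region (reads are uniform), fragment-length and GC biases,
sequencing errors, multi-mapping ambiguity, overlapping or nested gene
models, and genuinely graded expression decay along an extension.
Passing the planted-event tests therefore demonstrates the statistical
and geometric machinery, not robustness to alignment artifacts.

## Problem sizes and expected variation

The standard scenario (200 genes, 40 tDNAs, 10 ETC sites, 10 events per
class, ~1,400 regions) runs the full pipeline in about a second;
calibration checks use 10,000 regions.  These sizes give each planted
window totals of K ≈ 15–35 — deliberately shallow, in the regime where
a 2 + 2 exact test is marginal.  Per-window detection at these settings
is ≈ 0.85–0.95, so with 10 events per class the per-class recall of the
single-window (de-repressed) class fluctuates between 0.7 and 1.0
across seeds; multi-window classes are buffered by bridging.  This is a
property of the study design being emulated (two replicates, near-silent
baselines), not of the implementation.

## Numerical choices

- Exact-test tie tolerance 1e-7 (relative) when comparing split
  probabilities; enumeration pruning tail 1e-12 of the conditional
  total for K > 10,000.
- Dispersion floor 1e-8; negative fitted dispersions clipped to it.
- Median-of-ratios falls back to per-sample medians over rows positive
  in that sample (with a warning) when no row is positive everywhere.
- Pearson r is undefined (NaN, flagged) when a replicate column is
  constant; the antisense fraction of an empty record set is NaN.
- Degenerate catalogs (no genes) partition into pure window tilings;
  overlapping same-strand gene annotations are merged with a warning.
- All tabular outputs are TSV with deterministic row order (catalog
  order), so re-runs are byte-identical.

## Known limitations

- Exactly two conditions; no GLM designs, batch covariates, or
  shrinkage estimators of later vintages.
- The classifier sees the DE table and catalog only, not base-level
  coverage; a readthrough whose signal dies inside a window but past
  the tDNA edge is still called readthrough.
- Proximity is strand-blind by design; directional effects are captured
  by the category geometry, not the distance.
- No motif discovery: the site registry is annotation- and
  user-BED-driven.
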