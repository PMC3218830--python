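# Methods

This note documents the models, defaults and numerical choices behind
`capstrat`, and what the synthetic-data generator does and does not emulate.

## Coordinate and interval conventions

All internal coordinates are 0-based half-open (BED convention); VCF and
samtools-depth positions are converted at the I/O boundary. Interval
algebra (merge / subtract / intersect) is a sweep-line over sorted
endpoints in which *bookended* intervals merge (`[0,5)` + `[5,10)` →
`[0,10)`), so a subregion's span is always the number of distinct bases it
covers. Chromosome names are matched by exact string equality — no
`chr`-prefix normalisation — because the generator controls its own names.
A base may belong to several subregion classes; each class is summarised
independently, with no priority assignment.

Rule-based subregion construction follows the conventions of capture-panel
curation: RefSeq/Vega-specific regions are the CCDS-subtraction residue
with fragments *shorter than* 50 bp discarded (length exactly 50 is kept);
conserved UTRs keep intervals with conservation LOD score ≥ 100
(inclusive); regulome inputs keep ORegAnno-style annotations strictly
shorter than 50 bp and ChIP-seq sites with enrichment ≥ 300 (inclusive).

## Coverage stratification

"Average coverage" of a subregion is the pooled per-base mean over all its
bases, not the mean of per-target means: a handful of extremely deep
targets should (and does) skew the subregion mean while leaving the pooled
median representative, and the package reports both. Capture-ability is
the ratio of pooled means (subregion / CCDS); the enrichment ratio divides
capture-ability under capture by the same quantity under WGS, so 1 is the
no-capture-effect pivot, > 1 enrichment, < 1 depletion.

GC-binned coverage uses per-target GC (ambiguous bases excluded from the
denominator) in bins of width 0.05 and averages per-target mean depths
within a bin — here the per-target average is the right unit because the
bin variable is a target-level property.

The mappability proxy reports the fraction of k-mers (default k = 21,
canonicalised with their reverse complements) starting in a region that
occur exactly once in the whole genome. This is a deliberate, documented
proxy for read-simulation-and-remap experiments: it captures sequence
uniqueness at the probe/read scale without modelling an aligner.

## Variant metrics

Site filters are inclusive at their thresholds: quality ≥ 30, alt-read
fraction ≥ 0.15, and depth ≥ 10× for callability ("minimum", "at least",
"or higher"). Low-mapping-quality reads (MAPQ < 11) are assumed removed
upstream, before depth and allele counts are formed; a site-level filter on
the low-MAPQ read fraction exists for sensitivity analysis and defaults to
off. The filter tally attributes each removed call to the first failing
rule in the fixed order quality → zero depth → alt fraction → low-MAPQ, and
always conserves counts.

Variant density uses callable bases (≥ 10× within the subregion) as the
denominator *and* restricts the numerator to calls at callable positions;
using the raw span instead would deflate densities exactly in the
poorly-covered classes the analysis is about. The choice is switchable by
passing an unfiltered span.

The mutation spectrum keeps all 12 directed substitution types — no
reverse-complement collapsing — because the relative weights of C→T and
G→A differ between CpG-rich regulatory and coding sequence. Ts:Tv is
reported as NaN (not infinity) when no transversions are observed.

Panel-MAF classes: *private* means the panel frequency is missing or 0,
*fixed* means exactly 1 ("fixed" is interpreted literally as
frequency-1-in-panel; the field's usage is loose and this is the one
self-consistent reading). Intermediate frequencies are histogrammed over
user-supplied interior bin edges; class fractions always sum to 1.

Two tests are provided. Coverage comparisons use the Mann–Whitney rank-sum
test: exact enumeration of the permutation null (correct under ties, via
midranks) for total n ≤ 20, tie-corrected normal approximation above; the
two-sided exact p is the probability of a U at least as far from its null
mean as observed. Density comparisons use an exact conditional binomial
test — given k₁+k₂ total variants on spans n₁, n₂, k₁ is
Binomial(k₁+k₂, n₁/(n₁+n₂)) under equal rates — with the two-sided p formed
by doubling the smaller tail, capped at 1: simple, conservative and exactly
testable against rational-arithmetic enumeration. No multiple-testing
correction is applied; reports list raw p-values.

## The synthetic-data generator

The generator emulates the *observables* of a region-stratified capture
study; its defaults are the study conditions the package is calibrated
around.

**Genome and targets.** Chromosomes are i.i.d. sequences at background GC
0.40; each class's targets are apportioned across chromosomes by length,
placed without overlap with multinomially drawn gaps, and re-drawn at the
class GC. Default classes (count × length, GC, density as bp-per-variant):
CCDS 1500×200 bp at GC 0.50 and 1/1,500; conserved UTR 800×150 at 0.30 and
1/2,300; non-conserved UTR 800×200 at 0.40 and 1/925; regulome 1200×100 at
0.70 and 1/750; predicted exons 800×150 at 0.55 and 1/714; RefSeq/Vega-
specific 600×150 at 0.48 and 1/1,200; intron 300×2,000 at 0.40 and 1/850;
miRNA 200×100 at 0.55 and 1/1,500. These GC modes and densities reproduce
the characteristic ordering of capture studies: conserved classes sparse
(purifying selection), predicted exons and regulome dense.

**Depth.** Expected depth at base *i* is `λ(i) = d0 · m(g_i)^e` with
`m(g) = exp(−(g−g0)²/(2σ²))`, `g_i` the GC fraction of a 100 bp centred
window (probe-length scale; truncated at chromosome ends), and `e = β`
under capture, 1 under WGS. The Gaussian-in-GC form is this package's own
model of the well-known unimodal coverage–GC relationship; the capture
exponent is the simplest mechanism that *exacerbates* an existing platform
bias rather than adding an independent one. Defaults d0 = 100, g0 = 0.50,
σ = 0.17, β = 1.5 place a 70%-GC subregion below 50% relative coverage
under capture while leaving balanced-GC classes near 1. Noise is Poisson by
default; a negative-binomial option (shape θ) is available because real
capture depth is overdispersed. Note that window-GC sampling jitter makes
the realised mean depth at a nominal GC slightly exceed the point
evaluation of `m` (Jensen effect on a locally convex curve); at GC 0.70
with defaults the realised relative coverage is ~39% against the
point-formula 35%.

**Variants.** Each class generates a homogeneous Poisson process at rate
`1/one_in_x` per bp over its targets (duplicate positions collapsed; no
linkage, SNVs only). The substitution type is drawn conditional on the
reference base with probabilities proportional to the class's 12-type
spectrum weights; with the uniform-within-class weight helper the realised
Ts:Tv equals the weight-implied ratio regardless of base composition. Site
quality is N(80, 20) truncated at 0 (so ~1% of simulated calls fail the
quality-30 filter and the filter path is exercised), depth Poisson(100)
conditioned positive, alt fraction Beta(8, 8) (heterozygous-like), low-MAPQ
fraction Beta(1, 19) (mean 5%, matching typical mapping-quality losses).
Panel MAF mixes point masses at 0 (private) and 1 (fixed) with
Uniform(0.01, 0.99) otherwise; default private fractions are 9% (CCDS),
12% (intron), 16% (predicted exons).

**Conservation.** Per-base scores are drawn per class: coding-like classes
from a positively shifted normal, intron from N(0, 1), predicted exons
from a 0.70/0.15/0.15 mixture of N(0,1), N(2.5,1), N(−2.5,1) — heavier in
*both* tails than intron, the signature of a class containing both
constrained and accelerated bases.

**Determinism.** All draws flow from one master seed through named
substreams (genome, depth-capture, depth-wgs, variants, conservation), so
identical config + seed give byte-identical FASTA/BED/VCF/track outputs
and each component can be regenerated independently.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: read-level artefacts (duplicates, strand
bias, error profiles), alignment ambiguity and mismapping, indels and
multi-allelic sites, linkage disequilibrium, fragment-level capture
chemistry (probe tiling, steric effects), and any correlation between
depth and variant-call quality. Recovery tests show the *estimators* are
unbiased and correctly normalised under the stated generative model, not
that the model captures every bias of a real capture experiment.

## Problem sizes and runtime

The default shipped configuration uses a 10 Mb genome (2 × 5 Mb), which
runs the full pipeline in well under a minute; the test suite exercises a
600 kb shrunk version of the same configuration. Parameter-recovery checks
simulate 10–15 Mb of callable sequence per class with 10 replicate seeds
for density statistics (sampling error ≲ 1% on the replicate mean), 10,000
variants for spectrum recovery (5% tolerance ≈ 2 standard errors) and
5,000 for MAF classes. These sizes were chosen so every recovery band is a
multiple of the relevant standard error, not a fit to any particular draw.

## Known limitations

- Depth tracks are held as dense per-chromosome arrays; genomes far beyond
  ~10⁸ bp would need a sparse or chunked representation.
- The exact Mann–Whitney path enumerates all index subsets and is used only
  up to total n = 20.
- `read_depth_track` without declared chromosome sizes infers each
  chromosome's length from the last listed position; trailing zero-depth
  bases must be declared explicitly.
- The k-mer uniqueness proxy counts k-mers *starting* in a region, so the
  final k−1 positions of a region contribute k-mers extending beyond it.
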