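# Methods

## Coordinate conventions

All coordinates are 0-based half-open internally. BED input is native;
GTF (1-based closed) is converted on read. For a plus-strand gene the
TSS is the interval start; for a minus-strand gene the TSS is the
interval end, so `tss > tes` and the gene body is always
`[min(tss, tes), max(tss, tes))`. The promoter is the strand-aware
`promoter_bp` (default 2000) bases immediately upstream of the TSS;
"downstream" is the same width past the TES. A BED12 gene keeps its
block structure as exons and its thick interval as the CDS span; a GTF
gene merges the exon intervals of all its transcripts into one model
(no isoform resolution — the union acts as a single maximal model, and
the merge is logged).

## Genome partition

Every base receives exactly one of seven classes. Per gene, candidate
labels are: promoter, downstream, exonic bases inside the CDS span →
`cds`, exonic bases 5′ of it → `utr5` and 3′ of it → `utr3`
(strand-aware), body minus exons → `intron`. A gene with no annotated
CDS contributes all exonic bases to the `cds` bucket — a deliberate
simplification that keeps the class set fixed at seven; it is logged
per gene. Conflicts between genes are resolved by a fixed priority,
default `promoter > utr5 > cds > utr3 > downstream > intron`
(configurable), with unlabeled bases intergenic. Promoter-first suits
promoter-centric statistics: a regulatory region is not demoted because
a neighbor's intron happens to overlap it. The implementation paints a
per-base class-code array per chromosome from lowest to highest
priority and extracts maximal runs; the test suite checks it against an
independent per-base brute-force labeler, and property tests assert
exact completeness (class base counts sum to the genome length),
gene-order invariance, and mirror symmetry.

## Peak calling

The scan is a deliberately minimal Poisson model:

- background rate λ = library_size / genome_length per base, genome-wide
  only — no local (dynamic) background;
- windows of width 2·bandwidth (600 bp default) step by bandwidth/2
  (150 bp); a window with k tags is significant when
  P(X ≥ k; λ·width) < p_threshold (default 10⁻⁴);
- significant windows separated by ≤ bandwidth merge; the summit is the
  argmax of the extended-fragment pileup (151 bp step ties broken
  leftmost), the score −log₁₀ of the best window p (capped at 324 when
  p underflows);
- fragment extension is fixed at 150 bp; no fragment-shift model is
  estimated. An `mfold` parameter is accepted for interface
  compatibility with model-building callers and logged as unused.

The step of bandwidth/2 keeps peak boundaries stable under small
translations of the signal; the merge gap of one bandwidth joins the
two windows a single bimodal site produces. Window significance is
monotone in the threshold by construction; merged-peak counts are
checked for monotonicity on a seeded dataset (merging can in principle
split a region when a bridging window drops out, so the guarantee is
empirical at the peak level). Null calibration is asserted on seeded
uniform tags: the significant-window fraction must stay within 10× the
nominal p (slack for overlapping-window correlation; the discrete
Poisson test is conservative, so the observed rate is typically far
below nominal).

Summary arithmetic matches published precision conventions: mapping
percentages are 100·count/total rounded half-up to two decimals, mean
peak length is total/count rounded half-up to an integer, and output
bases is the exact product reads × read length. One published
sequencing-summary row is internally inconsistent under these
definitions (its printed output-bases and percentage cells do not equal
the quotients of its own printed counts); the quotient/product
definitions are implemented and only self-consistent rows are used as
exact checks.

## Feature assignment and relative enrichment

A peak is assigned by its **summit** position (alternatives — midpoint,
any-overlap multi-counting — would break the fractions-sum-to-one
property a single-assignment distribution needs). Relative enrichment
is peak_fraction / base_fraction per class; classes with zero bases are
omitted rather than reported as division by zero. The identity
Σ base_fraction · RE = Σ peak_fraction = 1 is asserted to 10⁻¹² on
random tables.

## Composite profiles

Coverage is extended-fragment depth scaled to reads per million
(10⁶/library size) — "normalized reads" made explicit. Per gene the
anchor ±flank region (default ±5 kb) is extracted, reversed for
minus-strand genes, averaged within fixed windows, then averaged across
genes. The default window is 200 bp (50 windows over 10 kb); a 40-window
variant (250 bp) is available via the `window` parameter, since both
conventions appear in practice for the same span. Genes whose region
crosses a chromosome boundary are excluded, not padded (padding with
zeros would fabricate depletion), and the exclusion count is logged.
The anchor value used by shape checks is the mean of the two windows
straddling the anchor. Expression stratification ranks genes by
decreasing value, breaks ties by gene id so the split is deterministic,
and cuts into near-equal contiguous blocks with the remainder assigned
to the highest classes.

## Occupancy dynamics

Occupied = ≥ 1 base of peak overlap (threshold configurable) with the
union of promoter and gene body; since the promoter abuts the body the
union is a single interval per gene. Any-overlap was chosen over a
summit-in-region rule as the simplest auditable criterion; it is
monotone in both the peak set and the promoter width, and both
monotonicities are tested. The three-sample Venn decomposition is exact
set algebra, checked against exhaustive membership enumeration.

## Over-representation, rank percentiles, qPCR

The ORA is the plain hypergeometric upper tail P(X ≥ k) with
Benjamini–Hochberg adjustment across reported terms — deliberately not
a replica of any annotation-service's modified score, whose versioned
annotation background is not reproducible; what is reproducible is the
statistic's structure (−log₁₀ p and ranks). p-values are validated
against exhaustive subset enumeration for all universe sizes ≤ 12. The
default universe is all annotated genes, overridable for array-design
backgrounds. Rank percentile is 100·rank/n_terms by ascending p with
deterministic tie-breaks; absent terms are reported missing, never 0.
qPCR fold over IgG is 2^(Ct_IgG − Ct_ChIP).

## Synthetic data generator

The generator defines the study conditions used by every shape and
recovery test:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 2 Mb | smallest genome giving ~26 k scan windows and stable null statistics |
| genes | 80, lengths 12–16 kb | bodies longer than the 5 kb flank so TSS signal cannot leak into the TES composite, which must stay flat |
| margins | 7 kb per gene side | promoter (2 kb) + profile flank (5 kb) never truncated or overlapping |
| background | 200 tags/kb | ≈ 0.8 M background tags per sample, ~30× window depth |
| signal site | fragment-center Gaussians at TSS ± 300 bp, σ = 80 bp, dip zone ± 75 bp | two flanking-nucleosome modes; after 150 bp fragment extension the composite shows two maxima two windows either side of the TSS and a ≥ 3× dip over it |
| signal load | 1000 tags × class amplitude {high 4, middle 3, low 2, lowest 1.5} | expected best-window folds ≈ 7–18× over background, so "strong" (≥ 8-fold) genes span the upper three classes |
| samples | intensity / occupied fraction: MEF 1.0/0.80, Day7 1.5/0.65, iPSC 0.75/0.55 | mean composite height ∝ intensity × occupied fraction, ordering the intermediate sample highest and the endpoint lowest while the occupied-gene count shrinks monotonically across the course |

Each tag is a read off one end of a 150 bp fragment (50/50), so
extension-based pileup centers on the fragment. Randomness is one
`numpy` Generator stream per (seed, sample id) — samples are
independently reproducible and byte-identical on re-run. The planted
truth records, per gene, the signal intervals (± 3σ around each mode)
and the expected best-window fold over background, computed in closed
form from the Gaussian mass captured by a 600 bp window.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: mappability and GC bias, duplicate reads,
copy-number variation, local background variation (the single global λ
is exactly right here by construction and would be the caller's main
weakness on real chromatin), overlapping genes and isoform diversity,
and signal at enhancers or gene bodies away from the TSS.

## Numerical choices and degenerate inputs

Rounding is decimal half-up where published tables demand it (two
decimals for percentages, integers for mean lengths); everything else
is float64. Empty tag sets and empty peak lists are errors where an
estimate would be undefined (background rate, distribution fractions,
summaries); an empty *peak call result* is not an error. Zero-base
classes are omitted from enrichment; genes at chromosome edges are
excluded from profiles; promoter windows clip at chromosome bounds.
Summit ties break to the leftmost maximum. BH q-values are clipped to 1.

## Problem sizes

Tests and the acceptance script run the full generator defaults
(~1 M tags per sample, 80 genes, 4 Mb genome) for shape and recovery
checks, 100-seed toy annotations (≤ 30 kb, ≤ 4 genes) for partition
algebra, and exhaustive enumeration up to universe 12 for the ORA
oracle — sizes at which every oracle is exact and the full suite
completes in well under a minute.
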