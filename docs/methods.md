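# Methods

## The measurement model

SuperSAGE quantifies a transcriptome as counts of 26-bp tags: NlaIII cuts
cDNA at `CATG`, and EcoP15I releases the anchor plus the 22 downstream bases.
Identical tags are aggregated into *unitags*; a library is the map
unitag → count plus the total sequenced-tag mass N.  Tags sequenced exactly
once (*singlets*) are removed before analysis as likely artifacts, but N
retains the pre-exclusion mass, so normalization is unaffected by the filter.
Singlet exclusion is applied per library by default (`singlet_scope` is a
deliberate choice rather than a fact about the protocol: pooled exclusion
across libraries is equally defensible, and callers who want it can pool the
multisets before `build_library`).

Tag extraction from a reference sequence takes the 3'-most `CATG` with a
full 22-nt tail (complete-digestion model); `all_sites` mode emulates partial
digestion by emitting every qualifying site.  If the 3'-most site has a
short tail, the extractor falls back to the next upstream qualifying site
(`fallback_upstream=True`), maximizing tag recovery under the same enzyme
model.  Candidate tags containing `N` are dropped, not disambiguated.

*Sister unitags* — pairs at Hamming distance exactly one outside the shared
anchor — are detected with a masked-position hash index (22 buckets per tag);
the all-pairs scan is retained in the test suite as the oracle.

## Differential expression

Two libraries are compared per unitag with the exact conditional test of
Audic & Claverie: under the null of equal underlying frequency, given the
pooled count n = x + y, the count y in library 2 is Binomial(n, N2/(N1+N2)).
The two-sided p-value doubles the smaller tail (observed outcome included),
capped at 1.  Tails are computed via `scipy.stats.binom` log-CDF/log-SF, so
counts up to 10^6+ are stable.  Ties at p = α are non-significant (strict
`p < 0.05`), and no multiple-testing correction is applied, matching the
original analysis protocol; the raw p-values are reported so users can apply
Benjamini–Hochberg downstream if they wish.

Fold changes use normalized frequencies (tags per million by default; the
divisor is configurable).  A zero frequency is replaced by one *on the
normalized scale* before forming the ratio R = f1'/f2'; the signed fold
change is R when R ≥ 1 and −1/R otherwise, so |FC| ≥ 1 always and negative
values mean repression.  Zero substitution after normalization is the
convention consistent with published magnitudes such as FC = 110.4 for a tag
absent from one library.  Counts, not frequencies, enter the test;
frequencies are used only for FC and reporting.

Calls: UR if p < α and FC > 1; DR if p < α and FC < −1; NS otherwise
(including FC exactly 1).

## Anchoring and region classification

A tag is anchored on a reference if the full 26-mer aligns with at most one
mismatch and the `CATG` anchor matches exactly on the aligned strand.  This
replaces permissive local alignment (BLASTn at e ≤ 0.001, score > 42): for a
26-mer, a full-length ≤1-mismatch match strictly dominates that regime, and
the exact matcher has no seeding heuristics.  The index files every
CATG-anchored reference window under its exact sequence and its 22
one-position-masked variants; a query is a handful of dictionary lookups.
Strand policy: plus-only for oriented transcript (EST) references, both
strands for chromosomes/scaffolds, each overridable.  A sliding Hamming scan
over CATG sites is kept as the independent test oracle.

Anchor sites are classified against gene models (GFF3, converted to 0-based
half-open internally) by interval arithmetic on the 26-nt hit: wholly inside
one exon → exon; wholly inside one intron → intron; otherwise overlapping a
gene → exon/intron border; overlapping no gene → intergenic.  Across
overlapping genes the most specific category wins (exon > intron > border).

## Annotation and GO summaries

A description is *adequate* when non-empty and free of blacklisted
placeholder words (default `unknown`, `clone`, `chromosome`; word-boundary,
case-insensitive).  The blacklist is configuration, not hard-coded truth —
the original filtering is described only by example.  Best-hit selection
follows three-round redundancy elimination: hits with an adequate description
*and* GO terms beat hits with only one of the two, which beat hits with
neither; within a class, taxon tier (focal species < related legume < other
angiosperm < other), then alignment score (26 − 2·mismatches, a monotone
surrogate for the bit score), length, identity, and finally target id.  The
taxon-tier map ships with a soybean-centric default (Glycine tier 1;
Phaseolus, Vigna, Medicago, Lotus, Cicer, Pisum, Arachis tier 2) and is
user-replaceable.

GO summaries count distinct UR and DR tags per assigned term; a tag with k
terms contributes to k rows, and no GO-DAG ancestor propagation is performed.

## Reporting

Percentages are rounded half-up to one decimal (18.083 → 18.1); note that
banker's rounding would break several published marginals.  Venn partitions
of 2–4 named sets return all 2^k − 1 exclusive regions; sizes sum to the
union by construction and are tested against a membership oracle.  The
four-way characterization (description+GO / description only / GO only /
neither) is exhaustive and disjoint.  A tag absent from both libraries of a
contrast is excluded from that contrast's universe, which is why per-contrast
totals differ.

## Clustering and heat-map export

DE unitags are clustered on signed FC profiles across contrasts.  A unitag
not expressed in a contrast is *missing*, never zero (|FC| ≥ 1 makes 0 a
fake signal); similarities are computed pairwise-complete over shared
columns, and a pair with no shared column gets similarity 0 with a warning.
Default similarity is the uncentered correlation with average linkage —
the Cluster 3.0 convention — with Pearson/Euclidean and
complete/single/centroid available.  Ties in the minimum distance break
toward the smaller node-id pair, making trees deterministic.  Average
linkage follows the Lance–Williams update and is tested against
`scipy.cluster.hierarchy` on the same distance matrix (the scipy route is an
oracle, not the implementation, because scipy cannot form pairwise-complete
distances over missing data).  Output is TreeView-compatible CDT/GTR with
missing cells as empty fields; a red/black/green heat map is an optional
matplotlib extra, the CDT/GTR files being the contractual artifacts.

## qPCR relative expression (REST convention)

Efficiency comes from the standard-curve slope, E = 10^(−1/slope) − 1, with
amplification base 1 + E (storing E as a fraction and using 1 + E in ratios
avoids the classic factor-of-interpretation bug).  Technical replicates are
averaged within biological replicate first; per gene,
ΔCt = mean Ct(control) − mean Ct(treatment) and the expression factor is
(1+E)^ΔCt; the reported ratio divides the target factor by the geometric
mean of the reference-gene factors (geNorm convention for combining the two
reference genes).  Significance is a pair-wise fixed-reallocation
randomization test: whole biological-replicate samples are reassigned
between groups jointly across genes, extremeness is |log ratio|, the
observed allocation is counted, and the space is enumerated exhaustively
when it has ≤ 10,000 arrangements (3v3 gives 20, so the smallest attainable
p is 2/20 = 0.1), otherwise sampled with a seeded generator.  Agreement
with the tag-based call requires at least one timepoint significant in the
matching direction.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design — four libraries (tolerant and
sensitive accessions, control and six-timepoint stress bulk) with default
total masses of 1,030,443 (tolerant pair) and 1,520,843 (sensitive pair)
tags split between control and bulk.  Transcript abundances follow a
log-normal spectrum (σ = 1.2); counts are drawn multinomially with the exact
library size.  A planted fraction of transcripts (default 0.28 with 65% UR,
mirroring the observed DE proportions in the tolerant stress-vs-control
contrast) carries log-uniform effect sizes in [2, 50].  Planted transcripts'
baselines are floored at the median abundance (stress-responsive transcripts
quantifiable by tag counting), and planted-DR mass is rescaled to offset
planted-UR mass gain so that one-sided planting does not shift every null
transcript's relative frequency — without this, the closure of the
multinomial turns planted signal into a compositional artifact on the nulls.
Substitution errors at a per-base rate spawn sister tags in the 22 non-anchor
positions; singlets arise naturally.  A decoy chromosome embeds a subset of
transcripts as two-exon genes with introns and intergenic spacers (GFF3
provided) so region classification is exercised end to end.

Not emulated: realistic base composition, read-level qualities, partial
digestion biases, transcript-family cross-hybridization, or biological
replicate variation (the design has none at the library level).  Passing the
recovery tests therefore demonstrates the pipeline's statistical machinery
under the stated generative model, not robustness to those real-data
features.

## Problem sizes and numerical choices

Simulation-backed experiments run at one tenth of the study's sequencing
depth (library sizes ×0.1, 2,000 transcripts), a scale the package adopts
for its reference experiments: the null calibration uses 10,000 unitags with
Poisson means log-uniform on [5, 5000] at N = 10^6 (the lower bound keeps
most mass above the regime where the discrete test's conservatism dominates);
recovery averages 20 seeded replicates; qPCR recovery uses 100 seeded Ct
tables at noise σ = 0.1 cycles.  All randomness flows through
`numpy.random.default_rng` seeds recorded in run manifests; identical seeds
give byte-identical generator outputs.  Exact-test equivalence to direct
summation is asserted to 1e-9 relative error for counts ≤ 30; clustering
height equivalence to the reference oracle to 1e-10.

## Known limitations

- The anchoring matcher tolerates at most one mismatch by design; it is not
  a general aligner and does not handle indels or spliced alignment.
- The exact test assumes a single measurement per library; with biological
  replicates a dispersion-aware model (negative binomial) is preferable and
  out of scope here.
- GO summaries count assigned terms only; no enrichment statistics.
- The published contrast tables ship as summary counts; the underlying
  libraries are not distributed, so absolute unitag counts of the original
  survey are not reproducible here.
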