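# Methods

## Data model

A pooled library of ~50 conspecific adults is treated as an
allele-frequency pool, not a diploid individual: the per-sample alt-allele
proportion `f = AD_alt / (AD_ref + AD_alt)` estimates the population
frequency of the alternate allele in that species. A sample is *missing*
at a site when its genotype is uncalled or its informative depth is zero.
The dosage matrix stores the alt-allele proportion; the reference-allele
dosage is its complement `1 − f`, and every downstream quantity is either
invariant under complementation (PCA variance, distances) or label-swapped
(specific targets preserved, low/high pairs exchanged), a property the test
suite asserts, so the storage convention carries no modelling content.

Coordinates: VCF positions are 1-based; intervals are 0-based half-open
(BED). The single conversion lives in `intervals.vcf_pos_to_zero_based`.

## Filtering cascade

Stages run in a fixed order — site class, depth, fixed, flank, call rate —
each producing `out = in − removed` accounting that must chain exactly.

* **Site class.** Biallelic SNV ⇔ exactly one alt allele and both alleles
  1 bp.
* **Depth.** DP > 10, strict, evaluated in every sample with a genotype
  call; a missing DP fails that sample. Missing-genotype samples are not
  evaluated (they are handled by the call-rate stage).
* **Fixed.** All non-missing `f ≥ t_high` or all `≤ t_low`
  (defaults 0.9/0.1 — the same threshold vocabulary the diagnostic rules
  use). A site with no informative sample is removed as "no data".
* **Flank.** The closed window ±20 bp around the site must lie inside a
  covered interval for every sample, contain no other candidate variant
  (violations are mutual: two sites 10 bp apart both fail) and no N in the
  reference when one is supplied. "High-quality flanking sequence" has no
  canonical definition; covered + variant-free + N-free is this package's
  operationalization.
* **Call rate.** `CR = called / n_samples ≥ 0.5`, inclusive, because with
  four samples the stated intent "genotyped in at least two samples" is
  CR = 0.5 exactly.

A site-quality predicate (`QUAL < 20` fails) is available for
reference-evaluation reports but is deliberately not part of the cascade:
the quality category in published per-reference tables has no stated
definition, so the report merely prints the predicate it applied.

## Marker model

`DiagnosticPanel` holds the dosage matrix with a replicate → species map;
`fit()` returns a `PanelResults`.

* **Diagnostic rules.** Species labels: LOW iff *every* replicate
  `f ≤ t_low`; HIGH iff every replicate `f ≥ t_high`; else AMBIGUOUS
  (replicate disagreement is ambiguity, not averaging).
  Species-specific call: no AMBIGUOUS species and exactly one species alone
  on its side (1-vs-3). Pairwise call: clean 2-vs-2 split. The two call
  sets are disjoint by construction. Thresholds 0.1/0.9 are the loosest
  round values that reproduce every published fixture row (observed
  extremes: "rare" max 0.05, "high" min 0.914); they are parameters, not
  fitted quantities.
* **PCA.** Species rows (replicates averaged), variant columns centered and
  unit-scaled (sample sd, ddof = 1); missing values excluded from the
  moments and imputed to the column mean (0 after centering); zero-variance
  columns dropped and reported. Components come from the SVD of the scaled
  matrix; variance proportions are σ²ₖ/Σσ², so the nonzero components (at
  most n−1) sum to 1. Sign is fixed by making each loading vector's
  largest-magnitude entry positive; ranking ties break by (contig,
  position). The test suite checks the SVD route against a covariance
  eigendecomposition oracle at 1e-8.
* **Distances.** Euclidean on the same scaled matrix; complete-linkage
  hierarchical clustering supplies a leaf order. On the packaged fixture
  the smallest species-pair distance is TD01–TH04 (6.94), the two
  eulophids.
* **Projection.** New samples (mixtures, noisy replicates) are centered and
  scaled with the *training* moments then multiplied into the loading
  basis. Projection is affine, so a noiseless 50–50 mixture lands exactly
  at its parents' midpoint — asserted to 1e-8.

On the packaged 27-variant fixture the three variance proportions are
37.66 / 34.41 / 27.93 %. These differ from the percentages printed on the
study's projection figure, which evidently derive from a larger
"most informative" variant set of the full sequencing experiment rather
than the 27 printed markers; no construction of the printed matrix
(replicates separate or averaged, scaled or not, either dosage
orientation) reproduces those figures, so the package reports what the
27-variant matrix actually yields and separately asserts the
rank identity (three nonzero components summing to 100%), which holds for
any 4-sample matrix.

## Simulation

* **Mixtures.** Dosage-level convex combinations `p·A + (1−p)·B`; the
  study design is 15 pure replicates × 4 species = 60 and 6 pairs × 3
  proportions {0.25, 0.5, 0.75} = 18. The equal 15-per-species allocation
  is an assumption (only the total 60 is stated) and is configurable.
  Noise modes: `noiseless` (exact copy — the mode in which convexity,
  label symmetry and midpoint projection hold exactly) and `binomial`
  (each dosage resampled as `Binomial(depth, f)/depth`, default depth 30×,
  the study's target depth).
* **Classifier.** Linear SVM, C = 1, one-vs-rest, fixed seed; kernel and
  regularization are unspecified upstream, so they are exposed as
  configuration. Mixture correctness is judged against the majority
  parent (> 50%); at exactly 50–50 either parent counts. Persistence
  stores the training matrix and hyper-parameters as versioned JSON and
  refits on load — deterministic, hence prediction-identical, and free of
  binary pickles.

## Synthetic scenarios

The generator emulates the statistical shape of the pooled experiment:
a uniform-composition reference contig; planted variants on a 101 bp grid
with ≥ 60 bp margins (so flank windows never interact); per-sample
coverage equal to the contig minus a 30 bp gap just right of every
edge-proximal site (staggered 1 bp per sample) and two decoy gaps, keeping
every sample ≥ 95% covered. Planted categories and their designated
removal stages: indel and multiallelic (site class), low-depth (DP = 8 in
one sample), fixed (all species at 1.0), edge-proximal (< 20 bp from a
coverage boundary), missing-call (genotyped in a single sample, at f = 0.5
so no earlier stage touches it). Species-specific and pairwise profiles
use extreme frequencies with a deterministic sprinkling of near-threshold
values (0.03/0.97), matching the not-quite-fixed entries real pooled data
shows; noiseless emission sets `AD_alt = round(f·DP)`, binomial emission
draws `AD_alt ~ Binomial(DP, f)`.

GQ is synthesised as a Phred-capped genotype quality: posterior over the
three canonical pool classes f ∈ {0, ½, 1} with per-read error 10⁻³ and a
flat prior, `GQ = −10·log₁₀(1 − max posterior)`, capped at 127 (the cap
observed in the published tables). At 30× a clean pool yields GQ 90 (the
f = ½ competitor dominates the error term); the cap engages near 100×.

What the generator does **not** model: read-level alignment (no SAM/BAM),
paired-end inserts, per-cycle error profiles, within-species population
structure, or mapping bias against a diverged reference. Passing tests
therefore demonstrate correctness of the *computational* pipeline on data
with the assumed statistical shape, not robustness to real cross-species
mapping artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run on the 27-variant fixtures
and on synthetic scenarios of ~9–30 kb with ≤ 50 planted variants, sizes
chosen because every property under test (stage accounting, rule
behaviour, PCA identities) is scale-free; the brute-force oracles
(per-base interval intersection, per-base flank checking) are what limit
genome size, and 10 kb keeps them exact and fast. Stochastic checks use
fixed seeds: recall ≥ 0.9 over 20 binomial scenarios at 30×, and pure-
sample classification ≥ 0.95 over 200 binomial samples. Rank cutoffs in
PCA drop singular values below 10⁻¹⁰ relative to the largest; the
empty-overlap statistic reports nulls rather than NaNs; degenerate inputs
(empty tables, single samples, all-missing profiles) raise typed
`ValueError`s naming the offending entity.

## Known limitations

* Reference-evaluation category counts are predicates applied
  independently to the full variant set; published per-reference tables
  appear to mix sequential and overlapping accounting, and their printed
  percentages are not exactly consistent with their printed counts, so no
  numeric reproduction of those tables is claimed.
* The TOP100 concordance compares top-loading sets between the two stated
  filtering strategies; with fewer than 100 variants the intersection is
  bounded by the variant count.
* The pairwise planting interprets "per pair" as one variant per low-pair
  choice (6 ordered 2+2 splits of 4 species).
* The minimum-length QC rule is applied per read, not per read pair.
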