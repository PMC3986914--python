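# Methods

This note documents the models and procedures implemented in `chromtss`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model and coordinates

All intervals are 0-based half-open (BED convention); wiggle input
(1-based) is converted on read. An RTSS is a stranded interval with an
anchor at `floor((start+end)/2)`; the anchor is the reference point for all
profiles. Peak sets are never merged on read — merging happens only inside
the overlap-query index. Signal tracks are stored as sorted non-overlapping
intervals with zero fill outside coverage, which answers window-sum queries
identically to a dense per-bp expansion.

## Expression and location classification

The focal sample's tag counts partition RTSSs three ways: repressed is
exactly zero tags; expressed is at least the tag threshold (default 5;
`scaled_threshold` offers a library-size-scaled variant, e.g. 5 → 3 for a
~10M-tag library against a ~30M reference, floor 1); everything in between
is intermediate and excluded from both downstream sets, so that the
expressed and repressed references are unambiguous.

Location uses precedence annotated > proximal > intragenic > intergenic,
which makes the four categories exclusive. Annotated requires the RTSS
interval to contain a same-strand gene TSS base; proximal requires the RTSS
*anchor* within ±150 bp of a same-strand TSS (the anchor, not any overlap
of the interval, because the RTSS center is the single point all profile
machinery is anchored on); intragenic is any strand-agnostic overlap with a
gene span. Isolation (≥ 2 kbp from any other RTSS) is measured edge to
edge, inclusive at the bound, so two RTSSs exactly 2 kbp apart are both
isolated and the relation is symmetric by construction.

## Profiles

Reads are reduced to 5′ start positions and shifted +100/−100 bp by strand
(half the ~200 bp expected fragment length) before binning, so that both
strands' evidence converges on the protected fragment center. Binning uses
half-open 100 bp bins over [anchor−3000, anchor+3000); a position exactly
at the anchor falls in the first downstream bin. Minus-strand profiles are
reversed so index 0→59 always runs upstream→downstream in transcript
orientation; this is what lets asymmetric shapes (ramps in the transcript
direction) align across strands. Profiles under 100 total reads are
dropped before clustering.

Smoothing convolves with a 7-bin Gaussian kernel, σ = 1.5 bins, truncated
and renormalized, then trims 6 bins per side (60 → 48). Six bins — rather
than the 3 a 7-bin window naively implies — is chosen so the printed 48-bin
contract holds; every retained bin then has full kernel support, so a
constant profile stays exactly constant after smoothing.

## Two-level shape clustering

Distance is d = 1 − r (Pearson), emphasizing shape over intensity. The
correlation of a constant vector with anything is defined as 0 (d = 1),
everywhere in the package. The k-means variant mirrors the classical
`kcluster` semantics: each pass starts from a uniformly random assignment,
iterates arithmetic-mean centroids (not re-normalized) and
minimum-distance reassignment to convergence, repairs empty clusters by
seizing the point currently farthest from its centroid, and the best of
`npass` passes by total within-cluster distance wins. Ties in reassignment
break toward the lowest cluster index; the seed is explicit, so a fixed
seed gives bit-identical clusterings. Level 1 uses k = 5 and npass = 200
per mark on smoothed 48-bin profiles of expressed RTSSs; level 2 uses
k = 10 and npass = 1000 on the correlation-feature rows. Correlation
features are zeroed when the mark's raw profile total is below 100 reads;
an RTSS missing a mark entirely gets zeros for that mark's columns. A PCA
of the feature matrix is exported as a diagnostic of how much combinatorial
structure the features carry; it is not used to select k, which is fixed by
design.

## Poised selection

The pooled procedure sums raw 60-bin profiles over the active-mark panel
(DNase HS, H2A.Z, H3K4me1/2/3, H3K27ac, H3K9ac, H3K36me3, H3K79me2,
H4K20me1 by default; Pol II is deliberately excluded from the pool so it
remains an independent read-out). Totals are taken on raw profiles;
correlations on their smoothed versions, consistent with clustering. The
reference profiles are the mean smoothed pooled profiles of
peak-overlapping expressed and repressed RTSSs of the same dataset.

Criterion (iv) uses Williams' t (Steiger's recommended form) for two
dependent correlations sharing the candidate profile, df = n − 3 with
n = 48 smoothed bins, one-sided for r(profile, avg repressed) >
r(profile, avg expressed). Treating bins as observations ignores their
serial correlation, so the nominal p is approximate; the test's null
behaviour at n = 48 is checked against a trivariate-normal simulation in
the test suite. "Above" thresholds (1000 pooled reads, correlation 0.5)
are strict; "p ≤ 0.05" is inclusive. The per-mark variant applies all four
criteria per active mark with a 100-read total threshold and selects RTSSs
passing in ≥ 3 marks.

## Permutation tests

Peak-overlap significance repositions each RTSS uniformly within its own
chromosome (lengths and per-chromosome counts preserved), recomputes the
overlap count, and reports the add-one estimator
p = (1 + #{permuted ≥ observed})/(1 + n_perm), one-sided for enrichment
(a depletion tail is available). This is the simplest defensible null; it
ignores mappability gaps and clustering of RTSSs, which a circular-shift
null would partly retain. The CpG case–control test permutes case/control
labels across the combined promoter list (sizes preserved) with the
difference of bp-overlap fractions as statistic — a difference rather than
a ratio, so empty-overlap controls cannot blow up the statistic. Both tests
are calibrated under their own null in the acceptance suite (rejection at
0.05 within [0.01, 0.12] over 500 replicates).

## Expression-correlation validation

Pairwise Pearson correlations use tags-per-million, log(1+x)-transformed
counts by default (raw counts are available); CAGE counts are heavy-tailed
and a handful of extreme samples would otherwise dominate r. Within each
window around a gene TSS, all member pairs are pooled across anchors before
averaging (grand mean over pairs), so anchors with many members get
proportionally more weight than a mean-of-means would give them. The
random baseline is the mean over all pairs of 100 randomly drawn RTSSs.

## Synthetic data

The generator plants exactly the structure the pipeline is asked to
recover, at the default scale of 2000 RTSSs, 6 active marks + Pol II and
100 pseudo-samples on two 10 Mbp chromosomes with 600 genes:

- **Classes.** A joint expressed/repressed/intermediate ×
  annotated/proximal/intragenic/intergenic fraction table; placements are
  rejection-sampled against the real classification rule, so planted and
  recovered class labels agree exactly.
- **Expression.** Negative-binomial counts (dispersion 0.3) rather than
  Poisson, emulating CAGE overdispersion; class means differ by orders of
  magnitude and focal counts are coerced to respect the planted class.
  Two latent log-activity factors induce correlation: one shared by RTSSs
  within 50 kbp of a common anchor gene (sd 0.6) and one shared by RTSSs
  of the same metacluster (sd 0.4) — the structure the window-correlation
  validation measures.
- **Chromatin.** Each expressed RTSS carries one of 10 archetypes mapping
  every mark to a shape template (symmetric dip, downstream ramp, upstream
  ramp, flat, or absent); the no-dip center peak is reserved for the
  poised signature (active marks + Pol II + retained central nucleosome),
  matching the biology that motivates the selection procedure. Reads per
  enriched RTSS are Poisson(500 × scale) — a realistic strong-promoter
  window count at ENCODE-era depths — drawn multinomially over the
  oriented template bins, jittered within bins, strands 50/50, and
  **un-shifted** by ∓100 bp so the pipeline's shift step is exercised, not
  bypassed. Uniform background reads are added at 0.2 per kbp.
- **Context.** CpG islands cover promoters of expressed RTSSs with
  probability 0.7 (0.1 otherwise); excludable regions are placed clear of
  every RTSS so the mappability filter runs without disturbing planted
  counts.

Deliberately not emulated: nucleotide sequence, mappability structure,
replicate structure, and — importantly — promoter crowding. Real RTSSs
pile up within a few hundred bp and then share one chromatin state; here
enriched RTSSs are spaced ≥ 6 kbp apart so that every planted shape is
identifiable in its own window. Passing recovery tests therefore shows the
pipeline correctly recovers shape structure where it is identifiable; it
says nothing about deconvolving overlapping chromatin signatures, which the
isolated-RTSS analysis is the tool for on real data.

## Scale and determinism

Default test/acceptance problem sizes (2000 RTSSs, S = 100, 7 tag sets of
~0.5M reads, npass 200/1000) run the full pipeline in well under a minute
on one core; they are large enough that recovery scores are stable across
seeds. Every source of randomness flows from one master seed through
SHA-256-derived per-stage seeds (< 2³¹), and every output TSV carries a
provenance header (config hash + stage seed); reruns with the same config
and seed are byte-identical.

## Known limitations

- The dependent-correlations test treats smoothed bins as independent
  observations; its p-values are approximate (see above).
- The repositioning null ignores chromosome composition effects
  (GC/mappability), so real-data p-values are anti-conservative near
  assembly gaps.
- Level-1 k-means with k = 5 on data containing fewer true shapes splits
  clusters; metacluster features tolerate this, but the split subprofiles
  themselves are then near-duplicates.
- BigWig is not parsed; nucleosome-type signal is ingested as
  bedGraph/wiggle text.
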