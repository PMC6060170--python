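# Methods

This note documents the statistical model behind `plasmacna`, the choices
made where the underlying method leaves the design open, and what the
synthetic data generator does and does not emulate.

## Overview of the model

Plasma cell-free DNA (cfDNA) of a cancer patient is a mixture: a fraction
*f* (the tumour fraction) of fragments derives from tumour cells, the rest
from normal diploid cells. A genomic region present at copy number *c* in
the tumour therefore contributes sequencing coverage proportional to

    1 + f · (c − 2) / 2,

relative to its diploid expectation — the unique linear two-population
mixture consistent with a diploid background. Low-coverage single-end
whole-genome sequencing is summarized as read counts in non-overlapping
50-kb bins; everything downstream operates on these counts.

The pipeline stages are:

1. **Bin exclusion.** Bins with high cross-panel variance-to-mean ratio
   (above the 99th percentile of panel bins), mappability < 0.75, or repeat
   fraction > 0.5 are masked. All thresholds are configurable.
2. **LOESS GC adjustment** (per sample). A locally weighted quadratic
   regression of count on GC fraction (tricube weights, span 0.3) is fitted
   on unmasked autosomal bins and evaluated on a lattice of GC *quantiles*
   (so the local fit never extrapolates into a GC gap; the fitted curve is
   additionally clipped to [0.1×, 10×] the sample's median count — a bias
   outside that range is a fit artifact, not chemistry). Each count is
   multiplied by (median fitted value / fitted value at the bin's GC),
   flattening the GC trend while preserving the sample's median level.
   The smoother is written in-package because the installed LOESS
   implementations are locally linear and a quadratic local model tracks
   the curvature of GC bias curves.
3. **Reference panel + PCA smoothing.** GC-adjusted counts are converted to
   autosomal bin fractions. The panel stores per-bin medians and MADs and
   the top-K (default 10, capped at panel size − 2) principal components of
   the panel's log2(fraction/median) matrix. Loadings are made orthogonal
   to the constant vector: a global offset of a log-ratio profile carries
   no copy-number information and must never be projected on. A sample is
   smoothed by subtracting the projection of its log-ratio vector onto the
   component subspace; the residual is re-anchored at its median (robust to
   large altered shares) and mapped back to the count scale for fraction
   computations. Panel members themselves are smoothed **leave-one-out**
   (components refitted without the member), so the reference distribution
   reflects *out-of-sample* residual variance; in-sample projection
   understates the reference MAD several-fold and mis-calibrates every
   z-statistic built on it. If batch identifiers are present and a batch
   has ≥ 8 members, per-batch medians replace global medians for centering.
4. **Circular binary segmentation.** Per chromosome, the smoothed
   log-ratios are segmented with the Olshen–Venkatraman arc statistic:
   the arc (i, j] maximizing the pooled-variance two-sample t against its
   complement, assessed by permutation (default 1,000 shuffles, α = 0.01,
   minimum arc width 3 bins). Internally the scan maximizes the
   between-group sum of squares u = (n_in·n_out/n)·(mean difference)²,
   which is monotone in t with a permutation-invariant total sum of
   squares, so permutation exceedance is decided with a three-operation
   inner loop (numba-compiled); the permutation loop stops early as soon
   as significance at level α is ruled out, making null stretches cheap.
   Adjacent segments whose means differ by < 0.05 log2 units are merged.
   Full permutation is used rather than the hybrid tail approximation of
   production CBS implementations — simpler, adequate at this scale.
5. **Classification (CADET-style).** Each segment receives:
   - its **segment fraction**: normalized reads in the segment over
     normalized reads across all unmasked autosomal bins;
   - **Z_CBS**: the deviation of that fraction from its reference
     distribution — the same bin interval evaluated in every panel sample —
     in units of 1.4826 × MAD (the consistency factor makes "MADs from the
     median" behave like a z-score under normality; configurable to 1);
   - **Z_CHR**: the identical statistic for the whole host chromosome;
   - **LOR**: a Gaussian two-hypothesis log-odds that the fraction comes
     from a single-copy event at tumour fraction *f* rather than from
     diploid coverage. Both hypotheses are divided by the sample's
     genome-scale factor D = 1 + (f/2)(gained share − lost share), because
     all fractions share the autosomal denominator: for a focal event
     D ≈ 1, but a large event visibly depresses every other fraction and
     the hypotheses must live on the sample's own renormalized scale.
     Because fractions sum to one, "a share S gained" and "the complement
     lost" produce nearly identical profiles (they differ only at order
     f²); D is therefore chosen by scoring candidate configurations of the
     z-flagged segments (gains altered / losses altered / both / none,
     with sub-threshold segments free to take their best-fitting
     direction) by share-weighted squared error of predicted versus
     observed fraction ratios, adopting the winner only when it beats
     every rival by more than the panel noise floor and falling back to
     the share-weighted compromise otherwise.
     When no external *f* is supplied, the diploid baseline is
     anchored at the segments the median-centered log-ratios call
     unchanged, D is read off them, and *f* is implied from the altered
     segments' shifts — the "amount of CNV" route to tumour burden. This
     internal estimate assumes the altered share is below half the genome.
   - **BCL** (bootstrap confidence level): the median shift of the
     segment's counts from the rest of its chromosome is removed to form a
     baseline pool; pseudo-segments of the same length are resampled with
     replacement 1,000 times, the shift re-applied, and BCL is the
     proportion of bootstrap fractions whose |z| against the panel
     reference still reaches the threshold. Bootstrap seeding derives from
     the run seed plus the segment's bin coordinates, so results are
     independent of evaluation order.

   A segment is **called** iff |Z_CBS| ≥ 3.95, LOR > 0 and BCL ≥ 0.99; the
   direction follows the sign of Z_CBS, and the event is classified
   whole-chromosome when |Z_CBS| < 0.8·|Z_CHR|. Calls larger than 10 Mb
   (strict) are reported; significant same-direction neighbours separated
   only by masked bins, by < max(2.5 Mb, 10% of the combined span) of
   non-significant splinters, or by segments that independently pass the z
   threshold in the same direction, are stitched into one event and
   rescored in full before the size filter — wave artifacts and noise can
   carve short dips out of one contiguous event, and reporting should not
   split the event on them. Whole-chromosome gains on chr13/18/21 set
   trisomy flags; because a CBS segment that *is* the whole chromosome has
   Z_CBS = Z_CHR (making the scope comparison unsatisfiable), a significant
   gain covering ≥ 90% of a chromosome's unmasked bins also qualifies.
6. **Tumour fraction regression.** A ridge model maps included-bin
   fractions (bin count / total over included bins) to tumour fraction.
   Bins on chr13/18/21/X/Y are excluded — those chromosomes host the
   aneuploidies the platform screens for — and with fractions computed over
   included bins only, the estimate is *exactly* invariant to perturbations
   confined to the excluded chromosomes. Features are standardized; ridge
   regularization defaults to 1.0. The published estimator's trained
   coefficients are proprietary, so the model ships untrained and is fitted
   on synthetic panels (or any labelled training set).
7. **Cohort summaries.** Detection counts and rates per cancer type and
   FIGO stage group (I–II early, III–IV advanced; rates rounded half-up to
   one decimal as in clinical tables), Fisher's exact test for rate
   comparisons (chi-square optional), Mann–Whitney U (exact by enumeration
   for n₁+n₂ ≤ 12 — valid with ties — normal approximation with tie
   correction otherwise), Kaplan–Meier curves and the one-degree-of-freedom
   log-rank test. Kaplan–Meier and log-rank go through lifelines; Fisher
   and the large-sample Mann–Whitney through scipy.

## The synthetic data generator

The generator emulates the statistical structure the analysis must remove
or detect, on a reduced two-chromosome genome (120 + 30 Mb, 3,000 bins):

- **Depth**: expected 500 reads per 50-kb bin (low-coverage NIPT-style
  sequencing), with a 5% lognormal sample-level depth jitter.
- **GC bias**: a multiplicative quadratic curve g(gc) = 1 + 0.8(gc−0.4)
  − 4(gc−0.4)², normalized to g(0.4) = 1. The GC track varies at sub-2-Mb
  periods, so the GC curve is uncorrelated with multi-megabase events (as
  in real genomes, where GC composition fluctuates locally).
- **Batch artifacts**: two shared low-rank components with log-scale
  amplitudes 0.08 and 0.05, whose loadings are band-passed white noise
  ("waves" with 1.5–15 Mb periods). Megabase-scale coverage waves are the
  canonical higher-order artifact of low-coverage WGS; chromosome-scale
  drift is deliberately absent. At these amplitudes the artifact
  eigenvalues dominate the panel noise floor, which is what makes a
  20-sample panel PCA able to estimate and remove them — weaker artifacts
  are both less realistic and (counter-intuitively) harder to remove.
- **Count noise**: gamma-Poisson (negative binomial) with dispersion
  0.002 — twice the Poisson variance at depth 500, typical of well-behaved
  shallow-WGS libraries; dispersion 0 recovers Poisson for analytic tests.
- **Tumour signal**: per-bin mean multiplied by 1 + f·w·(c−2)/2 with
  partial-overlap weight w.
- **Determinism**: all draws flow from explicit integer seeds through
  numpy SeedSequence spawning; truth files record the seeds.

Not emulated: fragment-length differences between tumour and background
cfDNA (the detection method uses no length feature), read-level errors,
mappability structure beyond per-bin annotations, and germline CNVs.
Passing tests on this generator therefore demonstrate the pipeline's
statistical behaviour under its own model assumptions — correct null
calibration, power at the stated effect sizes, exact rule arithmetic — not
performance on real plasma libraries, which carry additional unmodelled
structure.

## Study problem sizes

The end-to-end operating-point checks run on the reduced genome with a
20-sample reference panel at depth 500: 20 tumour-free replicates for
specificity (expected: zero reported calls), 20 replicates of a 100-Mb
copy-3 event at f = 0.10 for sensitivity (reported with ≥ 80% reciprocal
overlap), 20 replicates of a 9-Mb event at f = 0.3 for the strict 10-Mb
reporting rule, and a 100-sample training / 30-sample held-out design for
tumour-fraction recovery (fractions uniform on [0, 0.3], fixed two-event
profile). On this reduced genome a 100-Mb event is two-thirds of the
autosome, which stresses the fraction renormalization far harder than any
real-genome event would — the genome-scale handling in the LOR exists
precisely for this regime.

## Numerical choices and degenerate inputs

- Zero counts are floored at 0.5 before fraction/log operations.
- A constant value vector yields T = 0 and no split; a zero-variance split
  (noiseless step) yields T = ∞ and p below any α barring permutation ties.
  With short two-valued runs a non-trivial share of permutations ties the
  observed statistic exactly, bounding the permutation p from below — an
  intrinsic property of exact ties, not of the search.
- Arc ties are broken by smallest start index, then smallest end index.
- A degenerate panel (identical samples) disables PCA with a warning and
  reports zero MADs; degenerate GC (all equal) makes the LOESS step an
  identity with a warning.
- A segment covering its whole chromosome bootstraps from itself (with a
  warning) since no out-of-segment baseline exists.
- The tumour-fraction floor for the LOR is 0.01 so the two hypotheses
  never coincide.

## Known limitations

- The reference distribution of a CBS-discovered segment is that exact bin
  interval evaluated across panel samples; with a 20-sample panel the MAD
  estimate carries ~20% relative noise, which the 3.95 threshold absorbs
  in practice but which would matter at larger panel sizes.
- In roughly 1 in 20 sensitivity replicates, a wave-artifact dip inside the
  event plus the post-CBS merge pass erases one event boundary and the
  event is missed; this is a segmentation fragility, not a classification
  one, and is visible in the seeded studies.
- The internal tumour-fraction/genome-scale estimator assumes the altered
  share of the genome is below one half; above that the median anchor sits
  inside the altered territory and directionality can invert. Supplying an
  external estimate (the regression model) avoids the assumption.
- Survival fields of the bundled example cohort are synthetic (the study's
  patient-level follow-up is unpublished); survival code paths are
  validated against hand-computed and simulated cases instead.
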