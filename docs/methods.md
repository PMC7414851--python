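# Methods

This note records the models implemented in `replimap`, the defaults that
matter, and what the synthetic benchmarks do and do not demonstrate.

## Genomic coordinate model and binning

All coordinates are 0-based half-open (BED dialect) in every format the
package reads or writes (chrom.sizes, bedGraph, BED, window tables). A
single convention end to end removes the usual off-by-one error class.

The analysis unit is a grid of equal-width windows (default 50 kb) tiling
each chromosome from position 0. The terminal partial window is dropped by
default (flag `keep_partial` to retain it): TPM scaling and equal-count
quantiles assume equal widths, and the dropped bp count is logged and
recorded on the grid. Score tracks are binned by coverage-length-weighted
means; windows with no overlapping interval are explicitly missing (NaN),
never silently zero, and are excluded from quantile schemes with their
count logged. Tags are assigned to the single window containing their
fragment midpoint — each tag counted exactly once, so
assigned + discarded = input holds exactly; this matches "tags per
million" semantics better than fractional overlap splitting would.

## TPM, enrichment, selection, quantiles

* TPM: counts scaled so the genome-wide sum is 10⁶; no length term because
  windows are equal width.
* Enrichment: log₂((ChIP+c)/(Input+c)) on TPM, pseudocount c = 1 TPM by
  default. c regularises empty windows; c = 0 is allowed only when both
  tracks are strictly positive.
* Enriched windows: enrichment strictly > 0 (windows exactly at 0 are
  excluded).
* Matched controls: the same number of windows drawn uniformly without
  replacement from all retained windows, seeded. Enriched windows are not
  excluded from the pool by default (an `exclude` argument exists);
  exclusion would bias the control RT distribution away from the factor's
  preferred compartment and overstate the contrast.
* Quantiles (n = 25 by default): windows sorted ascending, ties broken by
  genomic order via a stable sort, split into n contiguous bins whose
  sizes differ by at most one, remainder to the lowest quantiles.
  Quantile 1 = latest RT / most-B. The trend statistic is the Spearman ρ
  between quantile index and quantile mean coverage.
* Box summaries: quartiles by linear interpolation; whiskers at the most
  extreme values within 1.5×IQR of the hinges (standard Tukey convention).
* No multiple-testing correction is applied: each reported comparison is a
  single pairwise test.

## Mann–Whitney rank-sum test

Two-sided throughout. The U statistic is computed from midranks. For
min(n, m) ≤ 8 the p-value is exact: every assignment of the pooled
observations is enumerated (midranks make this valid under ties), and
p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1. Larger samples use the
tie-corrected normal approximation with continuity correction
(scipy.stats). The two branches agree within 0.01 at n = m = 9, and the
exact branch is validated against an independent brute-force enumeration
in the tests. If all pooled observations are identical, p = 1.

Significance labels on PLA comparisons follow the convention
"significant" for p < 0.001 and "NS" for p > 0.05; intermediate p-values
are reported as numbers. The raw p is always reported alongside the
label.

## Compartment eigenvector

Per chromosome (eigenvectors are not comparable across chromosomes):

1. **Masking.** Bins with fewer than 25% nonzero contacts are masked
   before balancing; Knight–Ruiz is unstable on near-empty rows. The
   threshold is configurable and the masked count logged.
2. **KR balancing.** The inner-outer Newton iteration with conjugate-
   gradient inner solves and safeguarded step bounds, run to a relative
   row-sum tolerance of 1e-12 (achieves ~1e-13 on the 200-bin synthetic
   matrix). On non-convergence the package falls back to square-root
   coverage normalisation x_i = 1/√(row sum) with a logged warning.
3. **Observed/expected.** Each entry divided by the mean of retained
   entries on its genomic-distance diagonal; distances with no retained
   pairs stay missing.
4. **Pearson matrix.** Correlation of O/E row profiles over the columns
   finite in every retained row; zero-variance rows are masked with a
   warning; diagonal set to 1.
5. **PC1.** Eigenvector of the column-centred covariance with the largest
   eigenvalue, unit norm. The pre-orientation sign is fixed by making the
   largest-magnitude loading positive; a near-degenerate top of the
   spectrum or an explained-variance share below 0.2 is flagged.
6. **Orientation.** The sign is flipped if the eigenvector correlates
   negatively with the reference track (RT by default), so positive =
   A = early/open. |corr| < 0.05 leaves the sign unchanged and flags the
   track ambiguous.

The Pearson matrix is computed on O/E rather than on balanced counts:
without the distance normalisation, the strong decay makes all row
profiles nearly collinear and PC1 reflects distance, not compartments.
The whole chain is invariant to scaling the raw counts by any positive
constant.

## Synthetic data

The generators are pure functions of their config (seed included); each
generator role draws from its own fixed child stream of the master seed,
so adding a generator never perturbs existing outputs.

* **Genome.** Compartment labels form alternating A/B blocks with
  geometric lengths (memoryless — the simplest process with a
  controllable mean block length, default 500 kb ≈ the coarse scale of
  real compartment blocks at 50-kb resolution). Block-length means are
  split so the expected A fraction equals `frac_A`. RT is +μ in A and −μ
  in B plus Gaussian noise; μ = 1.5 and σ = 0.5 by default, giving RT
  spans comparable to log₂(Early/Late) tracks in cultured human cells and
  corr(RT, compartment) ≈ 0.95. Histone-mark counts are multinomial with
  weight `mark_contrast` (default 4) in the favoured compartment.
* **ChIP counts.** Multinomial with p_i ∝ exp(β·RT_i). β > 0 emulates an
  early-biased factor, β < 0 a late-biased one, β = 0 an input library.
  The magnitude |β| = 1 used in examples and benchmarks is a calibration
  choice — window-level effect sizes for such factors are not published —
  and produces clean but not saturated contrasts (mean TPM spans roughly
  two orders of magnitude across RT quantiles).
* **Contact matrix.** Expected intensity ∝ max(|i−j|, 1)^(−decay) ·
  (1 + boost·1[same compartment]), Poisson-sampled on the upper triangle
  and mirrored. The max(·, 1) convention handles the diagonal, which the
  power law alone leaves undefined.
* **PLA images.** Non-overlapping nuclei (dart throwing; infeasible
  packings raise) rendered as bright disks on the DAPI channel; foci as
  Gaussian spots (σ = 1.5 px) at uniform positions inside the nucleus,
  counts ~ Poisson(λ); Gaussian read noise on both channels. By default
  foci within a nucleus are kept ≥ 8 px apart by rejection sampling so
  that counting benchmarks are well-posed; real PLA foci can fall below
  the resolution limit and merge, so exact-recovery results on these
  fixtures bound the optics-limited case, not the general one. With
  `shared_nuclei` the same field is reused across conditions, emulating
  sequential rounds of imaging.
* **Rigid drift.** `shift_and_rotate_stack` rotates about the plane
  centre then translates, plane-wise, with spline interpolation
  (bilinear by default); intensity pushed out of frame beyond 1% is
  warned about.

What the simulations do **not** model: read-level sequencing (fragment
lengths, GC bias, mappability), unmappable regions, continuous
compartment strength (labels are binary), TADs or any sub-compartment
Hi-C structure, optics beyond an isotropic Gaussian PSF, touching nuclei,
or focus photometry. Passing benchmarks therefore demonstrate the
correctness of the statistical machinery under its stated assumptions,
not robustness to every artefact of real data.

One consequence is worth stating explicitly: because the simulated
contact matrix depends on compartment labels only, the recovered
eigenvector is two-level, and its within-compartment variation is noise
unrelated to RT. Ranking windows by such an eigenvector orders them
randomly within compartments, which caps the Spearman trend across 25
eigenvector quantiles near 1 − (f_A³ + f_B³) ≈ 0.75 in expectation
(measured ≈ 0.72) however strong the factor's bias — in contrast to real
eigenvectors, whose continuous amplitude tracks RT. The RT-quantile
trend, which is what the biased factors directly couple to, reaches
|ρ| = 1.0.

## PLA quantification

Segmentation: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole
filling → connected components → area filter (default min 200 px²). Otsu
always splits an image, so a guard requires the threshold to sit at least
4 robust-σ (MAD-based) above the background median before any foreground
is accepted; pure-noise images yield zero nuclei. Touching nuclei are not
separated (no watershed); the simulator guarantees separation, and this
is a stated limitation for dense real fields.

Focus detection: white top-hat (disk radius 4 px) as a band-pass, then a
robust threshold at median + 6·1.4826·MAD of the filtered image,
labelling, and a size filter (2 px² ≤ area ≤ 50 px² by default). The
ceiling rejects aggregates and staining blobs; the defaults are package
choices, configurable per dataset. Centroids are intensity-weighted.

Assignment is by centroid containment — unambiguous and order-independent
— and foci outside every nucleus are excluded. Quantification is 2-D, on
single planes or maximum-intensity projections; registration projects
stacks the same way.

Registration estimates the transform that takes round 1 onto round 2
(rotation about the image centre, then translation — the same
parametrisation the simulator applies, so ground-truth drifts are
recovered directly; correcting round 2 applies the inverse). Translation
comes from the upsampled phase-correlation peak; rotation from a coarse
angular grid (±20°, 2° steps) refined by golden-section search on the
post-alignment Pearson correlation to 0.02°. A final correlation below
0.2 flags the transform unreliable. Recovery on synthetic fields is
within 0.05 px and 0.05° — comfortably inside the 0.5 px / 0.5°
tolerance the benchmarks assert.

Overlap between registered rounds: greedy nearest-neighbour matching
within a radius (default use: 2 px), fraction = matches / min(n₁, n₂).
The null re-places round-2 foci uniformly within their parent nuclei;
p = fraction of permutations with at least the observed matches. This is
an explicit operationalisation of the qualitative "do the two signals
colocalise" question; no standard printed statistic exists for it.

## Problem sizes and determinism

Default benchmark sizes: 10-Mb genome (200 windows of 50 kb), 200-bin
contact matrix with ~2×10⁶ contacts, 10⁶ ChIP tags per sample, 60 nuclei
per PLA arm (λ = 4 vs 1) in 512×512 fields. These sizes give the
statistical machinery realistic granularity (8 windows per quantile,
sub-percent multinomial noise per window) while every pipeline completes
in seconds.

Every stochastic step draws from `numpy.random.default_rng` seeded from
the run seed; pipelines echo their resolved config, write a manifest with
full tag/window bookkeeping, and contain no timestamps, so reruns with
the same config and seed are byte-identical.
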