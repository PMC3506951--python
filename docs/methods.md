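# Methods

This note records the models, parameter choices and numerical conventions
behind phscreen, and what the synthetic data do and do not establish.

## Calibration model

The excitation ratio of cytosolic pHluorin responds sigmoidally to pH. We
model it as a four-parameter Boltzmann curve in pH,
`R(pH) = r_min + (r_max − r_min)/(1 + 10^(k·(pH_mid − pH)))`, fitted to
buffer standards by unweighted least squares (`scipy.optimize.curve_fit`,
slope bounded positive). The form was chosen for the two properties the
pipeline actually relies on — strict monotonicity and a closed-form
inverse — not as a mechanistic fluorophore model. Guards: ≥ 5 distinct
standards spanning ≥ 1.5 pH units, and Spearman ρ ≥ 0.8 between pH and
ratio (a flat or shuffled standard set aborts calibration rather than
fitting a meaningless curve).

Background is the per-plate, per-channel, per-timepoint mean of blank
wells, matching the per-plate measurement structure of a robot run.
Channel values ≤ 0 after subtraction and ratios outside the open interval
(r_min, r_max) propagate as NaN and are excluded from per-well means.
They are never clipped: clipping would drag the affected wells toward the
calibration asymptotes and bias Z-values.

## Growth rates

Raw OD600 is linearised with the quadratic
`OD_cor = 1.1252·OD_obs² + 0.6808·OD_obs − 0.0002` (a plate-reader-specific
empirical correction against cuvette measurements; its derivative is
positive for all non-negative readings, so the map is invertible where it
matters). μ(t) is the OLS slope of ln(OD_cor) over six consecutive points —
1 h at the 10-minute sampling the screen uses — assigned to the
window-centre time so that μ pairs without lag against the window-mean
pH_c of the same six points. Points with OD_cor ≤ 0 (possible near the
polynomial's small negative intercept at very low density, or from read
noise on blanks) are NaN-masked, not floored; flooring fabricates zero
slopes. Windows containing any masked point yield NaN; companion pH means
use a nanmean because a single masked fluorescence point should not void
an otherwise valid window.

## Screen statistics

Z-normalisation is strictly per replicate batch: each batch's wild-type
wells supply the mean and sample SD (ddof = 1), so wild-type Z-values have
mean 0 / SD 1 by construction and batch-to-batch drifts cancel. Batches
need ≥ 2 wild-type wells; in practice they should have many more (see
layout below).

The candidate rule — |Z| ≥ 2 in one primary screen and |Z| ≥ 1 in the
other — is read inclusively ("at least") and, by default, requires the two
deviations to share a sign; opposite-direction pairs are biologically
incoherent as a single call. Both thresholds and the same-sign requirement
are configurable.

Confirmation is a two-tailed two-sample t-test of a strain's rescreen
Z-values against the pooled rescreen wild-type Z-values, assuming equal
variances (Welch available by flag), at α = 0.01. Degenerate zero-variance
comparisons resolve deterministically (equal means → P = 1). Strains with
fewer than three usable replicates are reported "nd" rather than tested.
The Jackknife re-test drops exactly one minimum and one maximum replicate
(stable on ties) and discards calls whose trimmed P exceeds 0.1; it is
applied to the separately arrayed slow-grower strains by default
(configurable to all or none) and can only demote, never promote, a call.
No multiple-testing correction is applied in confirmation by default — the
screen design controls false positives through the two-stage selection
plus Jackknife — but Benjamini–Hochberg is available.

Condition profiling (external pH 3.0 / 7.5, respiratory carbon source)
runs an independent t-test per condition against the parent strain and
derives cross-condition sets, including the "pH-fragile" class (high
pH_c at external pH 7.5 but low at 3.0). The false-negative estimate
applies the duplicate-screen candidate rule to strains of known direction
and reports the per-direction miss fraction.

## The pH_c → growth-rate law

`μ = 10^((pH_c + a)/b)` is fitted as OLS of log₁₀ μ on pH_c (the relation
is linear in that space, which is also where the residual noise is closest
to homoscedastic); slope s and intercept c map to b = 1/s, a = c·b, with
standard errors by the delta method from the full coefficient covariance.
Points earlier than 1.5 h after inoculation are excluded — cells
re-alkalinise before growth resumes, so those points sit off the law — and
μ ≤ 0 points are dropped and counted, not floored. b must come out
positive; a non-positive slope aborts the fit. A nonlinear fit in μ space
is deliberately not the default (it would let the large early-exponential
rates dominate).

Divergence profiles standardise the residual μ_obs(t) − μ_pred(pH_c(t))
by the mean and SD of the same residual across wild-type replicate curves
at each timepoint, restricted to t = 4–9 h — late enough that growth is
established, and spanning the depletion transition where decoupling is
most visible. Timepoints with zero wild-type SD are masked with a warning.

**Classification test and correction factor.** Each strain's windowed
Z-values are compared to the pooled wild-type Z-values by a two-tailed
equal-variance t-test that treats timepoints as observations. Timepoints
are autocorrelated, so these P-values are anticonservative; rather than
model the autocorrelation, the pipeline multiplies every strain's P-value
by the smallest factor that renders each wild-type reference profile
non-significant in the same test (each reference profile tested
leave-one-out against the rest; factor = max(1, α / min P)). Because the
factor is set by the most extreme wild-type profile, a null strain is
flagged only if it beats the entire wild-type cohort — an exchangeability
argument that absorbs the anticonservatism without distributional
assumptions. Bonferroni over tested strains is available as an
alternative. Corrected P < 0.01 with positive mean Z → category III
(faster than the law allows), negative → category II, otherwise category
I. Classification is refused with fewer than 10 wild-type reference
profiles. Sign convention: residual = observed − predicted, so "decoupled"
is positive. Mutant strains are classified on profiles averaged across
their replicate curves (screens of this kind measure mutants in biological
duplicate), while the wild-type reference consists of individual replicate
curves; averaging the mutant replicates shrinks its null variance, which
makes the wild-type-floor correction conservative for replicated strains.

Clustering of profiles uses Euclidean distance with complete linkage
(`scipy.cluster.hierarchy`); inputs are sorted by strain id first, so the
dendrogram is deterministic under input reordering, and NaN points are
imputed with the profile mean only for clustering (never for testing).
The tree is exported as Newick with branch lengths taken from merge-height
differences.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) per term, over a flat user-supplied
term → strain annotation restricted to the screened background; fold
enrichment is (k/n)/(K/N). Terms with fewer than 2 background members are
skipped. Only enrichment is tested (no depletion tail), raw P-values are
tiered at 0.05/0.01/0.001, and ontology-graph propagation is out of scope
— annotations must arrive pre-propagated.

## Synthetic screens

The generator is phenomenological: it reproduces the statistical structure
the analysis assumes, not the underlying physiology.

* **pH trajectory**: plateau at 7.08 (the parent pH_c) plus a per-well
  biological offset ~ N(0, 0.05) — the replicate SD of the real parent
  population — then a linear ~0.3-unit decline through late exponential
  phase (5–8 h), a fall to pH 5.5 over 1 h at glucose depletion (8 h), and
  a hold; 0.02 pH units of per-timepoint jitter on top. Planted mutant
  offsets are confined to [−0.3, +0.5] pH units, the span single-gene
  deletions actually reach.
* **Growth**: OD integrates μ(t) = 10^((pH+a)/b) with a = −7.24, b = 0.73
  (trapezoidal in the exponent, exact for constant μ) from a corrected OD
  of 0.05 at inoculation. Decoupled strains grow at a fixed μ while
  pH_c stays above the 5.5 depletion floor and stop below it; planted
  slow strains scale the coupled rate by a constant. Raw OD readings are
  the inverse of the linearisation polynomial plus additive read noise
  (SD 0.002 OD, typical plate-reader repeatability).
* **Fluorescence**: channel signals carry the calibration-sigmoid ratio
  scaled by biomass (2000 AU per OD unit per channel), with 1%
  multiplicative noise per channel, plus a 50 AU background (SD 1 AU)
  that blank wells emit alone.
* **Design**: a fixed array layout per plate — 2 blanks, 19 wild-type
  wells (~20% of a 96-well plate, the wild-type fraction of the real
  screened array, which is what makes per-batch wild-type statistics
  stable), the rest mutants — simulated through two primary screening
  replicates and six rescreen replicates with fresh biological offsets
  and noise each pass. Everything is driven by one `numpy` generator, so
  output tables are bit-identical for a given (config, seed).

What the synthetic screens do **not** contain: plate-position and edge
effects, drift within a robot run, aberrant GFP localisation or lysis
artefacts, strain-specific lag phases, and any real genotype–phenotype
map. Passing tests therefore demonstrate that the statistics behave as
designed under the stated noise model — calibrated null rates, the
expected sensitivity at 3σ offsets, category recovery — not that the
biological conclusions of any particular screen are correct, and the real
screen's hit and category counts are not reproducible from synthetic data.

## Problem sizes in the shipped studies

The bundled end-to-end studies use a null screen of 14 plates (≥ 1,000
unplanted strains, 8 replicate passes), a sensitivity screen with 200
planted strains per direction at ±3 wild-type SD, a law fit on 190
wild-type replicate curves, and a classification cohort of 190 reference
curves plus 100 held-out wild-type strains and 15 + 15 planted category
II/III strains in biological duplicate. These sizes keep each study's
Monte-Carlo error well inside the margins being checked while completing
in seconds.

## Known limitations

* The timepoint-wise classification t-test is the screen's historical
  procedure; the correction factor controls its false positives but the
  raw P-values themselves should not be interpreted as calibrated.
* The calibration sigmoid is fitted unweighted; strongly heteroscedastic
  standards would warrant weights.
* The OD linearisation polynomial is instrument-specific; reusing it on
  another reader without recalibration shifts μ multiplicatively.
* Enrichment assumes pre-propagated annotations and ignores term overlap.
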