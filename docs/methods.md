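# Methods

This note documents the models, numerical choices and limitations behind
`mbfmri`: what the simulator generates, what each analysis stage assumes,
and what the tests do and do not demonstrate about real data.

## Acquisition physics

A scheme is parameterized by TR, multiband factor MB, in-plane SENSE factor
S, voxel dimensions, flip angle and volume count. Two closed forms carry
the physics:

- Ernst angle `θ_E = arccos(exp(−TR/T1))`, the signal-maximizing flip
  angle of a spoiled gradient-echo sequence;
- steady-state signal at the Ernst angle, `s = √((1−E)/(1+E))`,
  `E = exp(−TR/T1)`, which a brute-force saturation-recovery iteration
  confirms in the tests.

Grey-matter T1 defaults to 1.5 s at 3 T (configurable). That single value
reproduces four of the five bundled flip angles exactly after half-up
rounding (79°, 75°, 64°, 51°) and predicts 49° where the bundled table
lists 50° at TR 0.63 s — no single T1 is consistent with all five rows, so
the one-degree discrepancy is inherent and documented rather than patched.
Angles are reported rounded half-up to integer degrees; full precision is
kept internally. White-matter T1 defaults to 0.9 s with proton density 0.75
relative to grey matter, which makes grey–white baseline contrast shrink
monotonically as TR shortens across the five bundled TRs — the saturation
behaviour the CNR analysis measures.

## The synthetic cohort

The generator defines the study conditions; it is not tuned per analysis.

**Task.** 13 blocks per condition (CA — complex action; CC — complex
control), 7 s each, randomized order, inter-block intervals drawn uniformly
on [8, 12] s (the distribution is a choice; only the range is given by the
design), 10 s lead-in/out. Sessions come out at roughly 8 minutes, matching
every bundled scheme's `n_volumes × TR` within 10 %.

**Phantom.** Default grid 32×38×32 at 3 mm synthetic voxels, affine centred
at the origin. Concentric ellipsoids define CSF core, white-matter shell
and grey-matter shell; a Voronoi tessellation of random grey-matter seeds
gives ≥ 10 atlas regions; the CA−CC effect map is a set of well-separated
Gaussian blobs (unit peak) confined to grey matter — plumbing that stands
in for normalized anatomy and the action-observation network, with no claim
of anatomical realism. Twenty network templates are smooth multi-blob
fields with unit peak; the last three are placed deep (white matter/CSF)
and given low planted amplitude, mimicking artefactual/deep components that
behave differently from cortical networks.

**Signal model.** Per voxel: baseline = proton density × steady-state
signal at the scheme's TR (scaled to ≈ 100 units); task signal =
effect map × subject amplitude (percent of baseline) × HRF-convolved CA
boxcar; network fluctuations = template × smooth random time course;
sinusoidal respiratory (0.3 Hz) and cardiac (1.0 Hz) components sampled at
the volume times, strongest in CSF — aliasing at long TR emerges from the
sampling, not from an explicit model; linear + slow-cosine drift; motion
parameters as smoothed random walks with step "jerks" that also inject a
small baseline-gradient-shaped signal change.

**Noise.** Thermal noise is an AR(1) process (φ = 0.35 by default) whose
*stationary* SD is `σ0 · g(v) · (V_ref / V_voxel)` percent of the local
baseline, with V_ref = 2.7³ mm³. The g-factor map is synthetic: unity at
the reference acceleration MB·S = 2, above it
`g = 1 + a·(MB·S − 2)/2 · w(v)` with `w` a centrally peaked Gaussian
profile (unfolding is hardest far from the coils) and a = 0.25. Between-
subject variability is a single multiplicative amplitude per subject, drawn
once (mean 1 % signal change, SD 0.3 %) and shared across that subject's
sequences; regional heterogeneity of between-subject variance is out of
scope. One global seed expands into per-subject/per-sequence/per-stage
streams by fixed spawn-key arithmetic, so any single run is reproducible in
isolation.

The default effect size of 1 % signal change at the activation peak is a
free simulator parameter (nothing in the acquisition fixes it); analyses
that need a planted truth state the amplitude they use.

## First-level GLM

Canonical HRF: double gamma (response delay 6 s, undershoot delay 16 s,
dispersions 1, response:undershoot 6:1), 32 s support, peak-normalized;
its argmax lands near 5 s. Optional temporal (1 s finite difference) and
dispersion (numerical derivative in the dispersion parameter) derivatives
give 4- or 6-column task sets.

Design columns in order: task regressors (boxcars built at 16 sub-TR bins,
convolved, sampled at the middle bin — no slice-timing exists in synthetic
data — then mean-centred), mean-centred nuisance columns (6 motion, then
CompCor components), a discrete-cosine high-pass set with
`K = floor(2·T_total/128 s)` columns, intercept last. Nuisance regressors
enter unfiltered alongside the cosine set (whether they should be high-pass
filtered first is ambiguous in common practice; including the cosine set in
the same model projects both jointly). Rank deficiency raises an error
naming the most collinear column pair.

CompCor components are the top principal components of the unsmoothed
in-mask (CSF, then WM) voxel×time matrix after mean and linear-trend
removal, unit-variance and mutually orthogonal; 5 + 5 by default for the
16-regressor total.

Estimation is GLS with an autocorrelation model pooled over brain (by
preference grey-matter) voxels, estimated from a first OLS pass:

- `ar1`: single pooled lag-1 coefficient, AR(1) Toeplitz correlation;
- `exp-basis` (default): the pooled autocorrelation function (30 lags) is
  fit by nonnegative least squares on a delta plus exponentials with decay
  constants 1, 4 and 16 lags, normalized to ρ(0) = 1 — a covariance-basis
  model of the kind designed for short-TR data, whose autocorrelation a
  single AR(1) coefficient underfits; the basis is this package's own
  documented choice and the option is exposed;
- `none`: OLS.

The fitted correlation is inverted through a Cholesky factor (with a 1e−8
diagonal ridge for numerical safety) into a whitening transform;
`dof = T − rank(X)`; residual variance = whitened RSS / dof, zeroed where
the fit is exact to rounding error; zero-variance voxels are flagged out of
all statistics rather than producing infinities. Residuals are stored
unwhitened — they feed effective tSNR and the pseudo-rest analysis.
Residualization for pseudo-rest projects out *every* design column via a QR
projector on unsmoothed data.

Gaussian smoothing is separable with `σ = FWHM/(2√(2 ln 2))` per axis in
mm, respecting voxel size; the task pipeline smooths at 6 mm before the
GLM, the pseudo-rest pipeline smooths the residuals.

## Group level

Random effects: one-sample t per voxel over subject contrast maps,
`dof = N − 1`; the second-level residual variance map is the per-voxel
sample variance. P-values are two-sided by default (one-sided available);
the data never say which sidedness the field's default software used for
this contrast, and two-sided is that software's convention. Voxel-level
Benjamini–Hochberg at q = 0.05 is followed by a fixed cluster-extent filter
(k = 50 in the full-scale configuration; small-grid analyses scale k down)
under 18-connectivity by default — 6/18/26 are all supported because the
convention is rarely stated. The reported t cutoff is the smallest |t|
among FDR survivors.

Effective smoothness uses the classic residual-derivative estimator:
variance-normalize each residual frame, take finite differences along each
axis over in-mask neighbour pairs, and `FWHM_i = voxel_i ·
√(4 ln 2 / var(Δz_i))` averaged over frames. The derivative variance is
floored at 2 (the white-noise value), so estimates never fall below the
voxel-size floor; finite differences overestimate FWHM by ~8 % at 6 mm on
3 mm voxels, inside the tests' tolerance.

Truncation keeps the first `floor(fraction · n_volumes)` volumes and the
blocks wholly inside them; runs whose truncation loses a condition entirely
are dropped from truncated group analyses (a warning fires below 2 blocks
per condition).

## Variance decomposition

The fixed-effects model is the stack of all subjects' runs with a
block-diagonal design. Block-diagonality means the pooled quantities never
require the full matrix: the contrast leverage `c X⁻ X⁻ᵀ cᵀ` is the sum of
per-subject leverages and the pooled residual variance C is the
dof-weighted combination of per-subject residual sums of squares (an
algebraic identity the tests verify). With c the concatenation of each
subject's CA−CC weights, `σ² = (1/N) · leverage · C` is the mean
per-subject estimation variance — the only reading dimensionally consistent
with the second-level residual variance it is subtracted from. `Σ² =
ResMS_RFX − σ²` may come out negative by sampling noise; negatives are
preserved and their in-mask frequency reported, and that frequency grows as
the true between-subject variance shrinks. The fixed-effects fit reuses the
first-level whitening choice for comparability.

ROI summaries average a map inside 6 mm spheres around world-coordinate
centres. The default centre list is the five published peak coordinates
(for real, MNI-normalized data); synthetic pipelines derive centres from
the phantom's activation blob peaks instead, since the phantom's grid does
not span an MNI bounding box. The source text mentions a sixth ROI in
passing but lists five coordinates; five are implemented.

## Concordance

For a (test, reference) map pair, ROC positives are the reference's
positively activated FDR survivors *before* cluster filtering — an upper
level set of the reference t map, so an identical test map separates
perfectly (AUC 1) and the sweep is genuinely threshold-free. Single
hit/false-alarm rates are evaluated at the test map's own FDR + cluster
mask against the same truth; the roles are deliberately asymmetric. AUC
uses trapezoids over threshold sweeps with tied scores collapsed into
single steps, equivalent to rank-based pair counting with half credit for
ties (verified against a brute-force pair oracle).

Region tables report the percentage of each atlas region's in-mask voxels
that are significant; a region is "active" at ≥ 5 % exactly. Table
concordance gives the Pearson correlation of percentage vectors, the
correlation of binary flags, and the ROC over regions scoring one table's
percentages against the other's flags.

## Pseudo-rest dual regression

Stage 1 regresses each residual volume on the 20 template maps (z-scored
over the mask — the templates' native scales differ and z-scoring
stabilizes the coefficients) plus an intercept, yielding 20 time courses
per run; collinear templates are rejected by name. A complete spatial
partition of the mask is inherently collinear with the intercept after
z-scoring — template sets must not tile the brain exactly. Stage 2 fits the
smoothed full series on those time courses plus the nuisance columns, the
cosine drift set and an intercept, with the same whitening as the task GLM,
giving per-network beta and t maps. Group counts run the full
RFX → FDR → cluster chain per network; cumulative curves plot
`N_seq(t ≥ x)/N_ref` from the reference scheme's FDR cutoff `x₀` upward,
with `N_ref` the reference's positive FDR survivor count so the reference
curve starts at exactly 1.

## Metrics

Raw tSNR = temporal mean / temporal SD; effective tSNR replaces the SD with
the GLM-residual SD; per-unit-time tSNR multiplies by `√(1/TR)`, crediting
faster sampling — it is this package's documented definition, constructed
rather than copied from any source, since no public formula exists for the
"predicted" variant some studies report. Grey–white CNR = (mean GM − mean
WM baseline) / mean pooled temporal SD.

The power calculator inverts the noncentral-t power function of a
one-sample t-test by bisection (`brentq`, xtol 1e−10): the smallest d with
`P(T'(n−1, d√n) ≥ t_crit) ≥` the target power. One-tailed α = 0.05 and
power 0.80 are the defaults because that pair reproduces the three
published minimal detectable effect sizes (2.3 at n = 3, 0.7 at n = 14,
≈ 0.5 at n = 23) after rounding; both are exposed as flags since the
original calculation's settings are unstated.

## Problem sizes

The test suite and the acceptance script run everything at desk scale as
the package's own configuration: phantoms of 16³–32×38×32 voxels, cohorts
of 8–20 subjects, full-length runs (200–780 volumes at the bundled TRs).
The variance-recovery cohort uses 20 subjects on a ~8,700-voxel mask with
white thermal noise so the planted variances have closed forms; null FDR
calibration uses 200 replicate 15-subject group analyses; the directional
comparisons use 10 subjects × 4 schemes. The five bundled schemes and the
23-subject default of `simulate_cohort` mirror the full-scale study design.

## What passing tests do and do not show

The simulator has smooth convex anatomy, no susceptibility dropout, EPI
distortion, slice-leakage or registration error, stationary noise, and a
single HRF shared by all voxels and subjects. Recovery and calibration
results therefore validate the *analysis machinery* — estimator
correctness, FDR control, variance-component identities, dual-regression
plumbing, the direction of TR/voxel-size/g-factor trade-offs under the
stated noise physics — not the magnitudes any real scanner comparison would
produce. Headline numbers from real cohorts (specific t-histogram shapes,
hit-rate matrices, percentage count increases) depend on real anatomy and
artefacts and are outside what a synthetic cohort can certify.
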