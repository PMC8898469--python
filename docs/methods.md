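# Methods

This note documents the models, estimators and numerical choices in
glymphkit, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying measurement procedures left
the details open.

## Signal model and T1 estimation

The variable-flip-angle (VFA) series is modelled by the ideally spoiled
gradient-echo steady state

S(θ) = M0 · sin(B1·θ) · (1 − E1) / (1 − E1·cos(B1·θ)), E1 = exp(−TR/T1),

with TR = 16 ms, six nominal angles (2°, 5°, 10°, 15°, 20°, 30°) and a
per-voxel multiplicative transmit scale B1. Assumptions: perfect
spoiling, a single echo (the TE-dependent T2\* factor is constant across
angles and is absorbed into M0), and instantaneous excitation. No
k-space or readout-train simulation is attempted; the magnitude model
above is the whole forward problem.

T1 and M0 are estimated by the classical linearization: with effective
angles θᵢ_eff = B1·θᵢ, the points (xᵢ, yᵢ) = (Sᵢ/tan θᵢ_eff, Sᵢ/sin
θᵢ_eff) lie on a line with slope E1 and intercept M0(1 − E1); an
*unweighted* ordinary least-squares line gives T1 = −TR/ln(slope). The
linearization re-weights noise across angles, which produces a small
bias at finite SNR (measured at well under 1% median bias at
peak-signal SNR 50 in the suite); no iterative re-weighting is applied
because the downstream cluster rule is a coarse 1700 ms window.
Validity rules: a fit is kept only if all sines are nonzero, the design
has nonzero spread, and the slope lies strictly in (0, 1); everything
else (negative or super-unity slopes from noise, zero signal) is masked
invalid rather than clipped, so artifacts can never enter the tracer
window as spurious "reached" tissue.

## B1 mapping

The double-angle method uses a long-TR pair at α = 70° and 2α: the
ratio S_2α/(2 S_α) = cos(B1·α), inverted by arccos after clamping the
ratio to [−1, 1]. Voxels whose base-angle signal is below 5% of the
image's 99th percentile are flagged invalid — arccos is ill-conditioned
there and low-signal voxels are air or background anyway. An optional
validity-weighted 3D Gaussian smoothing (default σ = 2 voxels) is
applied, the customary regularisation for double-angle maps; it is a
switchable pre-conditioner, not part of the estimator, and the
exactness properties in the test suite are stated for the unsmoothed
estimator (any finite kernel perturbs a curved field).

## Tracer-window volumetrics

A voxel counts as tracer-reached when its fitted T1 lies in
[lo, hi] = [1, 1700] ms, *both bounds inclusive* — the boundary
convention is declared and tested rather than inherited silently.
Every in-range voxel counts: no connected-component or minimum-cluster
filtering is applied, because the measurement is defined as pure
thresholding. Cluster and ROI volumes are voxel count × voxel volume
(0.18³ mm³ by default), computed exactly in physical units; percentages
can be normalized by total intracranial volume (the default) or by
brain-parenchymal volume — both denominators appear in published usage,
so both are computed and the choice is recorded on the result.

## AQP4 micrograph metrics

Segmentation uses a robust-background threshold: discard the dimmest
and brightest 5% of pixels, then threshold at trimmed mean + 2·SD
(these are the conventional defaults of that thresholding family). The
binary mask is hole-filled, 8-connected components are labelled, and
objects under 3 µm² are dropped. The classifier is deliberately
rule-based and auditable: reject if aspect ratio > 3 (oblique sections)
or area under the floor, otherwise capillary iff equivalent diameter
= 2√(area/π) < 10 µm, with exactly 10 µm counting as a small vessel.

Polarization index = max object intensity / median intensity of the
background region, where the background is the object dilated by
32.5 µm of *Euclidean boundary distance* minus the union of all
segmented objects — excluding every object (not just the focal one)
prevents a bright neighbour from inflating the background median. PI is
invariant to multiplicative rescaling; an additive offset c maps it to
(max + c)/(bg + c), which the suite asserts explicitly. The radial CV
partitions the object's above-threshold pixels into 8 equal angular
wedges about the centroid and reports population-SD/mean of the wedge
means; using the above-threshold (wall) pixels rather than the filled
object makes a circumferentially uniform wall read exactly CV = 0 and
keeps the metric from being diluted by the dim lumen.

The area-fraction fractionator places 100 µm × 100 µm counting frames
on a 200 µm × 200 µm grid (area sampling fraction ¼) whose origin is
drawn uniformly from the grid period — the only stochastic step, driven
entirely by the seed — with probe markers every 10 µm inside each
frame; the estimate is hits/total markers in the ROI. Uniformity of the
random offset makes each marker marginally uniform over the field, so
the estimator is unbiased for the pixel-area fraction (verified over
200 placements in the suite). ROIs smaller than one frame fall back to
a full-ROI marker lattice with a warning.

## Statistics

Welch's two-sample t-test is the primitive, implemented from group
summaries (n, mean, dispersion) because published tables are a
first-class input: per-group SE is the SEM (or SD/√n), SE_diff adds in
quadrature, df follows Welch–Satterthwaite, and the CI uses the t
quantile at that df. The raw-data route computes the summaries and
delegates, making the two paths identical by construction; the suite
additionally checks agreement with an independent implementation.
Dispersion kind (SD vs SEM) is an explicit argument — published "±"
values are not always labelled, and the harness records the
interpretation used instead of guessing one globally. Tests are
two-sided throughout and no multiplicity correction is applied,
matching the source analyses. Table reproduction rounds half away from
zero to one decimal (the convention of the printed tables) while
retaining full precision.

The mixed model for per-vessel data clustered by animal is the
random-intercept model y_ij = β0 + β1·genotype + u_i + ε_ij, fitted by
restricted maximum likelihood profiling the single variance ratio
λ = σ²_u/σ²_ε: for fixed λ the GLS solution and profiled REML deviance
have closed forms via per-cluster sums (Woodbury), leaving a 1-D
bounded minimisation over log λ with the λ = 0 boundary examined
explicitly. The boundary handling is the reason for implementing the
profile directly: general-purpose mixed-model optimisers are fragile
exactly when the between-animal variance is zero, which is the regime
where the model must degrade gracefully to OLS (and does, to machine
precision). On non-degenerate data the fit matches an independent REML
implementation to ~1e−5. The fixed-effect p is a Wald normal p; with
the per-animal object counts involved (hundreds) the normal/t
distinction is immaterial.

## Synthetic data: what it emulates and what it does not

The brain phantom is compartment plumbing, not anatomy: ellipsoidal
intracranial space, ventricles, olfactory bulb, an unreached deep core
whose complement forms the tracer-reached shell, plus extracranial
nasal-cavity and lymph-node targets. Default tissue values (ms):
unreached parenchyma 2000, reached parenchyma drawn per-voxel from
U(900, 1500), ventricular CSF 3200, nasal fluid 1200, lymph nodes 1400
— chosen so "reached" compartments sit inside the 1–1700 ms window and
"unreached" ones outside it at high-field-plausible post-contrast
values. These are free parameters: no published pre/post-contrast
tissue T1 values were available to pin them, and the phantom's reached
fraction (~78% of parenchyma under the default geometry) is likewise
arbitrary rather than an emulation of in vivo transport percentages.
The B1 field is a smooth low-order polynomial ramp min-max scaled to
[0.85, 1.15], a typical transmit-inhomogeneity span that exercises the
correction without pathological angles. Noise is Rician,
√((S+n₁)² + n₂²), applied per image from a single seeded generator;
geometry is analytic and seed-independent, so only the within-label T1
draw and the noise consume randomness. The phantom does not emulate
motion, partial volume beyond rasterisation, B0 effects, or
time-resolved tracer kinetics (the measurement is a single
post-circulation time point by design).

Micrographs render each vessel as an annulus (outer diameter = the
ground-truth diameter, so the hole-filled segmented object matches the
10 µm rule consistently) on a flat background at 0.325 µm/px — a 20×
objective with 6.5 µm camera pixels, which makes the 32.5 µm background
expansion exactly 100 px. The brightest wall pixel is set exactly to
PI_true × background, and circumferential heterogeneity is a single
angular mode 1 + a·cos(φ − φ0) whose amplitude is solved by
root-finding so the *measured* wedge CV of the noiseless rendering
equals the prescribed value (the discrete pixel geometry and background
baseline make a closed form inaccurate at the percent level). Vessels
must keep their expanded background annuli free of other vessels;
layouts violating this are rejected. Not emulated: out-of-plane
vessels, uneven illumination, multi-channel labeling, or realistic
endfoot texture — so passing recovery tests demonstrates estimator
correctness on the stated object model, not robustness to every
property of real micrographs.

## Problem sizes in the suite

The test and demo configurations use phantoms of 28³–64³ voxels
(the full 100³ acquisition matrix is the library default), noise
Monte-Carlo blocks of 4,000 voxels per T1 value, 200 stereology grid
placements, and 10,000-replicate calibration runs for the Welch type-I
error and CI coverage; these sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

- The linearized fit's noise bias, while small at the SNRs used, is not
  corrected; nonlinear re-fitting would be the next refinement.
- The rule-based vessel classifier replaces a trained-classifier step
  in the original workflow; its thresholds (aspect 3.0, area 3 µm²) are
  declared defaults, not learned ones.
- Printed-summary reproduction inherits the rounding of the published
  inputs; recomputed p-values can differ from printed ones in the third
  decimal for that reason alone.
- The drainage ROIs are inputs (phantom labels here); no automated
  segmentation of anatomy is provided.
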