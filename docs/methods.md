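# Methods

This note documents the models implemented in `mrtplan`, the choices made
where the underlying experimental workflow leaves the numerical recipe open,
and what the synthetic-data generators do and do not emulate.

## Clonogenic survival and the LQ fit

Plating efficiency (PE) is the mean over replicate dishes of
colonies/seeded; the surviving fraction at dose D is
`SF(D) = PE_irradiated / PE_control`. Colony counts are not clipped at the
seeding number: colonies are scored after ~15 doubling times, so the count is
bounded by seeding only in expectation, and only non-negativity is enforced.
The spread of SF is propagated from the per-dish standard deviation of both
records by first-order ratio rules. A control with zero colonies in every
dish is a hard error rather than a pseudo-count: silently imputing a PE would
bias every SF derived from it. An irradiated record with zero colonies
everywhere is likewise unrepresentable as a (positive) survival point; the
report pipeline skips such dose levels with a warning, which matches how
unscorable plates are treated in practice.

The linear-quadratic model `SF(D) = exp(−αD − βD²)` is fitted by weighted
least squares of `−ln SF` on `(D, D²)` with both coefficients constrained
non-negative (scipy's bounded-variable least squares, which lands exactly on
the boundary for pure-linear data). Weights are inverse variances of
`ln SF`, `var(ln SF) ≈ (sd/SF)²`; points without a spread get unit weight.
Parameter standard errors come from the weighted normal-equation covariance,
scaled by the reduced chi-square when no spreads are supplied. At an active
non-negativity bound the covariance is the unconstrained approximation —
adequate for reporting, and the fit itself is exact. Fitting requires at
least 3 points spanning 2 distinct positive doses.

Iso-survival doses solve `βD² + αD + ln s = 0` in closed form (with the
`β = 0` linear fallback), and `RER₁₀` is the ratio of the reference dose to
the test dose at 10% survival. From the fitted parameter sets, the 2 T
condition gives 1.27 against conventional X-rays; the 3 T condition gives
4.03, inside the ±0.28 uncertainty of the reported 4.07 (which was evidently
computed from unrounded fit parameters).

### Microbeam mixture survival

Survival under a spatially fractionated field is modelled as two
populations: a fraction `f_peak = width/pitch = 50/400 = 0.125` of cells
inside beamlet paths receiving `valley_dose × PVDR`, the rest receiving the
valley dose, each surviving per the broad-beam LQ fit. The area-fraction
weighting is a deliberate formalization of the qualitative two-population
picture (peak-path cells are ablated at clinically relevant valley doses);
it reduces to the broad-beam model when `PVDR = 1` or `f_peak = 0` and can
only lower survival otherwise.

## Microbeam field model

The lateral field is an idealized top-hat comb — peak dose inside half-open
beamlet intervals, valley dose between, optionally convolved with a periodic
Gaussian penumbra (periodic wrapping preserves the integral exactly). The
comb preserves precisely the quantities downstream analysis consumes (peak,
valley, PVDR, area fractions); beamline physics (spectra, scatter kernels,
collimator transmission) is out of scope. PVDR is measured the way a strip
dosimeter traverse is analysed: the 5 central beamlet maxima over the mean
of the associated valleys, each valley sampled over the central 20% of the
inter-peak gap ("near-midway", robust to penumbra without leaving the valley
plateau), with one standard deviation across the 5 peak/valley pairs as the
uncertainty.

Depth dependence is one exponential per component. Anchors are fitted by
log-linear least squares (exact passthrough for exactly two anchors, so the
two-anchor curve reproduces its calibration points bit-for-bit), stored at
the anchor depths, and queried by log-linear interpolation — exact for
exponential decay. Queries outside the anchored span raise rather than
extrapolate. The default calibration pins the valley to the 15 Gy
prescription at the 5.5 mm tumor depth with PVDR 71, decaying with the
linear attenuation coefficient of water near the 81 keV mean beam energy
(0.0184 mm⁻¹); the stated intrinsic peak/valley dose rates and the measured
PVDR of the high-dose-rate configuration are mutually inconsistent as
printed, so the PVDR is treated as an independent calibrated input rather
than derived from the rates.

Scan delivery: a field of intrinsic height `h` scanned vertically at speed
`s` exposes each point for `h/s` seconds, so
`speed = rate × h / prescription`; with the 5 Gy/s valley rate and the
0.5 mm field this reproduces the reference 0.5 mm/s scan.

## Tumor segmentation and depth profiles

Segmentation is a global intensity threshold (≥ threshold), optionally
reduced to the largest 6-connected component (default on, to suppress noise
speckle). The threshold is a required parameter — the imaging workflow this
emulates does not define a universal value — and the applied value is
recorded in the result. Volumes are voxel count × voxel volume. The
volume-versus-depth profile bins masked voxels into half-open `[lo, hi)`
depth bins along the beam axis, with depth = voxel-center slice position
plus a skin-surface offset (phantoms have no skin, so the offset locates the
surface explicitly). The default bin width is the slice spacing, which makes
the binning lossless at native resolution; bins always sum exactly to the
mask volume. Voxel indices are 0-based and physical positions are voxel
centers.

## DVH, coverage metrics and EUD

Depth bins are mapped to doses at bin centers from the chosen component of
the depth-dose curve. Tumor coverage is computed on the **valley**
component: the prescription is a valley dose, and in the mixture picture
beamlet-path cells are ablated outright; peak-component tables are reported
for the organ at risk. The cumulative DVH places its steps exactly at the
pair doses (the regular grid is augmented with them). D90 inverts the
cumulative curve at 0.9 by linear interpolation between step corners, ties
broken toward the lower dose (conservative coverage). V-at-prescription and
the under-dosed volume partition the total volume exactly.

The equivalent uniform dose is
`EUD = D_ref · ln( Σ wᵢ · SF_ref^(Dᵢ/D_ref) ) / ln(SF_ref)` with
volume-normalized weights `wᵢ = vᵢ/Σvⱼ`. The commonly printed form carries
both a `1/N` prefactor and per-voxel volumes `vᵢ`; the normalized weighting
is the dimensionally consistent reading, reduces to `(1/N)Σ` for
equal-volume voxels, and is what forces the uniform-dose identity
`EUD(D,…,D) = D`. `D_ref` defaults to 8 Gy — the minimum valley dose a tumor
voxel can receive inside the treatment field — and `SF_ref` defaults to the
mixture-model survival at an 8 Gy valley dose under the 2 T parameters
(≈ 0.115), since the in-field survival at the reference dose is a measured
curve value, not a printed constant. EUD always lies in `[min Dᵢ, max Dᵢ]`
and below the volume-weighted mean dose (cold spots dominate).

## Cohort statistics

MST is the arithmetic mean and MeST the median of the per-animal survival
times, censored animals included at their observed time: the endpoints
summarise observed lifespan, and the cured animal's 528-day span is part of
the outcome (this reproduces the reported 135/44 days for the treated arm).
Kaplan–Meier curves (via lifelines) instead treat censoring properly, so the
cured animal holds the curve at 0.2 rather than dropping it to zero. ILS is
`100 × (treated − control)/control` per statistic, reported at 2 significant
figures; the arithmetic mean-based ILS from the reconstructed times is 577%,
which rounds to 580% — the reported 570% evidently uses a coarser rounding
of the inputs, and comparisons should use the 2-significant-figure band. No
hypothesis testing is added; the source analysis reports none.

## Synthetic-data generators

The generators define the study conditions for all tests:

- **Phantoms**: ellipsoidal tumor (smooth shape with an analytic volume for
  ground truth) on a uniform background, additive Gaussian noise, 97 µm
  default in-plane pixels. Real contrast CT has structured noise,
  beam-hardening, partial-volume gradients at the tumor rim and non-ellipsoid
  shapes; passing tests therefore validate the measurement chain
  (threshold → volume → depth profile), not robustness to CT physics.
- **Clonogenic assays**: colony counts Poisson with mean
  `seeded × PE_control × SF_LQ(D)`, triplicate dishes, dose-0 controls always
  included, 1000 cells seeded over doses 1–8 Gy. Real assays add
  overdispersion (pipetting, counting); the Poisson model is the minimal
  noise floor.
- **Depth doses**: single exponential per component through supplied anchors
  — adequate over the few-cm depths used here, not a transport calculation.
- **Cohorts**: log-normal event times per group plus a cure fraction handled
  as administrative censoring at the observation horizon (the cured animal's
  observation simply ended), defaults emulating the 5-vs-5 design with a
  ~21-day control median and a 20% cure rate in the treated arm.

All randomness flows from one integer seed per generator call; identical
specs give bit-identical outputs.

## Problem sizes and numerics

Tests and the acceptance script use 40³–48³ voxel phantoms (97 µm), 3 dishes
× 6 doses × up to 4 replicate experiments per assay (matching the repeated
broad-beam protocol), 100-replicate coverage checks for the fit's standard
errors, and 8 mm comb profiles at 5 µm steps — sizes chosen so every
property is exercised at full fidelity while the whole suite runs in
seconds. Degenerate inputs (zero-volume structures, empty masks with
component filtering, α = β = 0, out-of-span depths, sub-5-beamlet profiles)
raise `ValueError` with a description rather than returning sentinel values.

## Known limitations

- No photon transport: the depth-dose model is parametric and calibrated to
  anchors, and lateral × depth composition is separable.
- The mixture-survival weighting by geometric area fraction is an
  interpretation of a qualitatively described two-population effect.
- LQ fit standard errors at an active non-negativity bound are approximate.
- Segmentation is a single global threshold; per-slice or adaptive
  thresholding and any registration workflow are out of scope.
- Plan metrics on synthetic phantoms reproduce the *structure* of a
  per-subject plan summary; per-animal values depend on the real (not
  publicly available) tumor shapes.
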