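# Methods

`dynapet` implements the complete quantification chain used in dynamic
¹¹C-acetate cardiac PET — synthetic phantom, count simulation, four
reconstruction algorithms, ROI/TAC/SUV extraction, image-quality metrics,
1-tissue-compartment kinetic fitting with spillover correction, and
cross-method comparison statistics — on a desk-scale 2D geometry with known
ground truth. This note records the models, the parameter choices that
matter, and the limits of what the synthetic experiments demonstrate.

## Dynamic phantom

A single transaxial cardiac slice with four anatomical regions drawn in a
fixed overwrite order (background body < RV blood < LV blood < myocardium,
so the annulus boundary is deterministic): a water-equivalent body disc
(μ = 0.096 cm⁻¹ at 511 keV), an RV blood disc, an LV blood disc of radius
11 mm, and an 8 mm-thick myocardial annulus around the LV cavity. Anatomy is
specified in millimetres and is grid-independent for fields of view above
~110 mm; the test default is 64×64 voxels of 2 mm (the full-scale clinical
grid is accepted through the configuration but is not exercised by default —
the mathematics is identical and the small grid keeps experiments fast
enough to iterate on).

Regional activity (kBq/mL):

* **Blood pools** follow a parametric arterial input function C_P(t). The
  default is a Feng-type 4-exponential bolus,
  `(a1·t − a2 − a3)e^{λ1 t} + a2 e^{λ2 t} + a3 e^{λ3 t}` (t in minutes past
  a 10 s arrival delay), with the classical rate constants
  (λ = −4.1339, −0.1191, −0.01043 min⁻¹) and amplitudes rescaled so the peak
  is ≈150 kBq/mL, a typical LV blood-pool concentration after a ~740 MBq
  injection. A gamma-variate model and a constant (calibration) model are
  also available. The RV curve leads the LV curve by 4 s to mimic
  right-heart transit.
* **Tissue** follows the 1-tissue-compartment model (below) driven by the
  decay-free input; defaults K₁ = 0.8 mL/min/mL, k₂ = 0.2 min⁻¹ for
  myocardium (the magnitude reported for acetate in patients) and
  K₁ = 0.1, k₂ = 0.05 for the low-uptake body background.
* **Physical decay** of ¹¹C is applied as a common factor 2^(−t/T½) with
  T½ = 20.0 min (the rounded clinical value; the exact physical half-life is
  20.364 min; configurable). Generated frames are therefore *not*
  decay-corrected, like raw scanner frames.

Frames hold the time-average of the decaying activity over each frame
window, computed by composite Simpson integration on a 0.5 s grid (frame
boundaries of the supported protocols are multiples of the step; the
integration error is far below 0.1% even for 10 s frames). The clinical
framing 15×10 s, 15×30 s, 16×60 s, 7×120 s (53 frames, 40 min) is the
default protocol.

Simulation units are kBq/mL throughout; no injected-activity-to-image
calibration is modelled (the scanner calibration factor is an explicit
configuration scale, default such that simulation units round-trip). Body
weight for SUV is a required configuration value (default 70 kg, dose
740 MBq).

## System model and count simulation

2D parallel-beam geometry, 180 angles over [0°, 180°) by default (96 in the
desk-scale experiment configuration), radial bin = voxel size. The system
response factors as normalization × attenuation × (optional PSF) ×
geometry, with optional TOF binning:

* **Geometry**: pixel-driven linear-interpolation splatting. Each voxel
  centre projects to a continuous radial coordinate; its value, weighted by
  the voxel size so projections approximate line integrals (value·mm), is
  shared between the two neighbouring bins. The forward/back pair is one
  sparse matrix and its transpose — adjoint to machine precision by
  construction, which the EM update requires. (A ray-driven interpolating
  projector would be equally standard; the matrix form was chosen because
  exact adjointness comes for free and subset row-slicing is trivial.)
* **Attenuation**: per-LOR factors exp(−∫μ dl) computed with the same
  geometric projector from the phantom μ-map.
* **Normalization**: unity by default (no detector-efficiency model; the
  factors are configurable). Dead time is not modelled.
* **PSF**: shift-invariant radial Gaussian in sinogram space, default FWHM
  4 mm, applied with zero boundary so the factor is self-adjoint.
  Depth-of-interaction (shift-variant) response is out of scope.
* **TOF**: each voxel's contribution at each angle is distributed over TOF
  bins by a Gaussian kernel in its position along the LOR; default 13 bins
  of 30 mm with an 80 mm FWHM kernel (≈530 ps timing resolution — the
  scanner's actual resolution is not published, so a mid-range clinical
  value was adopted). Kernel weights are renormalized per contribution after
  truncating negligible bins, so summing a TOF sinogram over bins reproduces
  the non-TOF sinogram exactly.

Counts: expected trues = forward(frame activity) × frame duration × a count
scale (default 5·10⁻³ counts per kBq/mL·mm·s, giving ~10⁵–10⁶ prompts in a
mid-scan 30 s frame — single-slice clinical statistics). Randoms are uniform
at 20% of the trues total; scatter is a 50 mm-FWHM radial blur of the trues
rescaled to 25% of the trues total. Prompts are Poisson with a seeded
generator; per-subject and per-frame streams derive from one master seed via
`SeedSequence` spawning, so cohorts extend without reshuffling.

## Reconstruction

**OP-OSEM family.** The multiplicative update cycles interleaved angular
subsets (subset q = angles ≡ q mod n_subsets, sequential order within each
iteration) and keeps randoms and scatter expectations in the denominator
rather than pre-subtracting them. A 10⁻¹² floor guards degenerate
denominators and sensitivities; voxels with zero sensitivity are frozen at
zero. OSEM ignores TOF (data summed over bins); TOF uses the TOF-resolved
operator; TPSF additionally models the detector PSF. With one subset the
code path is exact MLEM. Per-iteration snapshots can be kept to feed
convergence analyses without re-running.

Defaults mirror the clinical protocol: OSEM 20 iterations × 10 subsets
(EM-equivalent 200) with a 6.5 mm Gaussian post-filter; TOF and TPSF 10 × 10
(EM-equivalent 100) with 5.0 mm. Post-filtering uses σ = FWHM/2.3548 with
reflective boundaries (sum-preserving to rounding).

**FBP.** Prompts minus randoms and scatter, divided by attenuation and
normalization, ramp-filtered per angle via zero-padded FFT (Hann apodization
by default since no analytic filter is prescribed for the clinical
comparison), then backprojected with the geometric adjoint and scaled by
π/(n_angles·voxel). TOF data are summed over bins first. FBP is linear and
admits negative values.

**Decay conversion.** Reconstructed frames divide by frame duration and the
frame-averaged decay factor (e^{−λt₀} − e^{−λt₁})/(λΔt), referencing the
correction to the injection time (whether clinical software references
injection or frame start is not standardized; injection-time referencing is
used and stated here).

## ROIs, TACs, SUV, image quality

The clinical ROI scheme: four 5 mm myocardial ROIs at 0/90/180/270° on the
annulus mid-wall, a 10 mm LV blood-pool ROI (image-derived input function
and contrast background) and a 10 mm RV ROI (spillover). Voxels are included
by centre-in-circle without partial-volume weighting; ROIs are fixed across
frames. "Averaging the four myocardial ROIs" is implemented as voxel
pooling, which equals the mean of per-ROI means for equal-sized ROIs (the
symmetric phantom case). CV = signal SD / signal mean uses the population
(n) SD — the convention is stated because either choice is defensible.
Contrast = (signal − background)/background. SUV_mean(t) = concentration of
the frame containing t divided by dose/weight (tissue density 1 g/mL),
evaluated by default at 2, 5, 10 and 30 min.

## Kinetic model and fitting

C_t(t) = K₁ ∫₀ᵗ C_P(u) e^{−k₂(t−u)} du, with C_P the image-derived LV TAC
(no metabolite or plasma-to-whole-blood correction, matching clinical
practice for this tracer). The solver resamples the input linearly onto a
uniform grid (default 0.5 s) and applies the exponential-integrator
recurrence that is *exact* for piecewise-linear inputs; against closed forms
and a high-accuracy ODE integration it agrees to <10⁻⁸ at 0.006 s
resolution and ~10⁻⁴ at the default fitting resolution.

The measured myocardial curve is modelled as
(1 − v_lv − v_rv)·C_t + v_lv·C_LV + v_rv·C_RV — the standard geometric
dual-spillover mixture; the blood terms use the measured frame averages
directly. Fitting is bounded nonlinear least squares (trf) on
duration-weighted residuals (longer frames carry more counts; uniform
weights available), with K₁, k₂ ∈ [0, 5] and v ∈ [0, 0.5] (the upper bound
prevents blood-only degenerate fits), multi-started from three fixed points
so the result is deterministic. Noiseless 53-frame data identify all four
parameters to machine precision; at 5% multiplicative noise the median K₁
error is ~1%.

## Convergence experiments

On a frozen noisy phantom instance, CV/contrast are tracked per EM-
equivalent iteration (= iterations × subsets, 10 subsets fixed) on an
unfiltered mid-scan 30 s frame, and K₁/k₂ are re-fitted from full dynamic
series reconstructed at every snapshot level with identical ROIs and
initialization. The designed-in behaviours — TOF contrast at EM-equivalent
50 at or above non-TOF OSEM, and a TOF K₁ plateau within 2% beyond
EM-equivalent 100 — reproduce the qualitative convergence findings that
motivate the clinical choice of 200 (OSEM) and 100 (TOF/TPSF) EM-equivalent
iterations.

## Comparison statistics

Per method pair: OLS regression (slope, intercept, squared Pearson r) of
per-subject values, plus *both* the paired Student t and the Welch
unequal-variance t with Welch–Satterthwaite df (clinical method-agreement
tables are phrased ambiguously between the two, so both are emitted; the
Welch column is the table analogue). α = 0.05 per test without multiplicity
correction, with a Bonferroni column added for transparency. A sign-flip
permutation test provides a nonparametric cross-check of the paired p-value.
Null calibration uses cohorts of 24 subjects whose methods differ only by
noise; because the six pairwise tests within a cohort share method columns
and are dependent, the calibrated quantity is the type-I rate of a single
fixed pair across cohorts (exact binomial band), with the pooled fraction
reported alongside.

## What the synthetic experiments do and do not show

The generator reproduces the *structure* of the clinical data — framing,
count statistics, decay, attenuation, randoms/scatter, TOF/PSF physics,
blood/tissue kinetics, spillover through reconstruction blur — but not
patient anatomy (3D torso, motion, gating), detector-block effects,
dead time, metabolite kinetics, or inter-patient physiological variability
beyond Gaussian spread of K₁/k₂. Passing tests therefore demonstrate
algorithmic correctness and qualitative reproduction of convergence/
comparison behaviour, not agreement with any patient-derived parameter
values, which require the original (non-public) data.

## Numerical choices

* EM denominator/sensitivity floor 10⁻¹²; zero-sensitivity voxels pinned to 0.
* Gaussian kernels truncated at 8σ (post-filter) and renormalized TOF bins,
  so identity checks hold to ~10⁻¹⁶.
* FBP FFT padding to the next power of two ≥ 2×n_radial against circular
  convolution.
* Kinetic fit tolerances xtol = ftol = gtol = 10⁻¹⁰; covariance from the
  Gauss–Newton approximation scaled by RSS/dof.
* Degenerate inputs raise typed errors (empty masks, all-zero TACs,
  non-contiguous schedules, spillover fractions summing above 1); OSEM
  non-convergence is reported through the fit/result flags rather than
  exceptions.
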