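# Methods

## Scope and data model

All curves live in SUV units. Framed time-activity curves (TACs) carry a
`FrameSchedule` of contiguous frames (default 24 × 10 s, 12 × 30 s,
4 × 300 s; 30 min total); kinetic computation happens on a uniform 1-s grid
(`SampledCurve`). A framed value is attributed to its frame mid-time, a
(0, 0) anchor is prepended (pre-bolus activity is zero), and the last
mid-time value is extended to the scan end; linear interpolation fills the
grid. Decay correction is assumed already applied upstream; no half-life
handling exists here.

## Input functions

The whole-blood curve C_b contains parent [¹¹C]-acetate plus labelled
metabolites (mainly carbonate). The split uses an exponential
parent-fraction model with literature constants:

    C_p(t) = C_b(t) · exp(−0.104 · (t − 0.48))   for t ≥ 0.48 min,
    C_m = C_b − C_p,

no correction before the onset. Whether these constants differ between
thermal conditions is unresolved without direct blood sampling; they are
exposed as `MetaboliteCorrectionParams` so sensitivity to them can be
probed. Negative C_m from noise is clipped to zero with a logged count.

Delay between the aortic arch and the BAT-adjacent vessel is the
difference of maximum-initial-slope times (first differences of a
3-point moving average, restricted to the first 2 min, 1-s resolution —
the grid's native resolution; no sub-second refinement). Dispersion is
convolution with the normalized kernel (1/τ)e^(−t/τ); the discrete kernel
integrates the exponential over each 1-s cell, so a unit step maps exactly
to 1 − e^(−(t+½)/τ) and total area is preserved. τ is fitted by a 1-s grid
search on [0, 60] s plus bounded scalar refinement, over the first 2 min
only (later frames are contaminated by surrounding tissue). Both C_b and
C_p receive the same (delay, τ). Metabolite correction is applied after
delay/dispersion correction, since the parent-fraction clock is the blood
curve's own time base.

The analytic bolus model is the standard tri-exponential input form

    C_p(t) = (A₁(t−t₀) − A₂ − A₃)e^(−λ₁(t−t₀)) + A₂e^(−λ₂(t−t₀)) + A₃e^(−λ₃(t−t₀))

for t ≥ t₀ (zero before), λ₁ > λ₂ > λ₃ ≥ 0, fitted by multi-start bounded
least squares. `fit_analytic_blood` additionally pushes this model through
the frame-averaging measurement operator and matches measured *frame
values*, which undoes the peak flattening a pointwise fit to the
interpolated curve cannot; the CLI uses it to reconstruct smooth inputs
from framed blood files.

## Model bank

Ten linear compartment models (one to three tissue compartments; #8–#10
add a compartment fed by C_m). The measured signal is always
C_tot = (1−v_b)ΣCᵢ + v_b·C_b with whole blood (parent + metabolites) in
the vascular term. The four-compartment models (#5–#7) tie the oxidative
compartment's entry and exit rates to one shared free symbol — implemented
by parameter sharing in the declarative topology, not by penalty. Bounds:
K₁ ∈ [0, 5] mL/g/min, k ∈ [0, 10] min⁻¹, v_b ∈ [0, 1]; tissue density is
taken as 1 g/mL so K₁ and k combine dimensionlessly in SUV space.

The wiring of models #3, #6, #8 and #9 is not fully determined by the
source material; the encodings used here (series chain; irreversible
storage variant of #5; irreversible / reversible metabolite uptake added
to #1; reversible metabolite compartment added to #4 for #10) are
documented assumptions kept declarative so alternates can be swapped
without touching the simulator.

### Integration

The systems are linear with time-varying forcing. Integration is classic
fixed-step 4th-order Runge-Kutta at 0.5 s on the 1-s grid, with inputs
interpolated to quarter-second samples for the half-steps. Because one RK4
step of a linear system is an affine map C → R·C + f, the matrices R and
the three forcing weights are precomputed once per parameter vector and
the time loop reduces to a linear scan (numba-compiled when available;
identical arithmetic in the numpy fallback). The one-tissue model is
validated against an independent fine-grid convolution oracle
K₁e^(−k₂t) ⊛ C_p to < 0.1 % relative error.

## Fitting

Bounded nonlinear least squares (trust-region-reflective) minimizes the
uniformly weighted sum of squared residuals on the 1-s grid. Initial
guesses are 0.01 for K₁ and every rate constant and 0.1 for v_b — low rate
starts empirically favour the global minimum for acetate-like TAC shapes.
Single-start by default (multi-start ×{0.5, 2} behind a flag);
non-convergence is reported (`converged=False`), never silently retried,
so Monte-Carlo statistics count failures explicitly.

When the observation is a framed TAC, the model prediction is passed
through the same frame-average + mid-time-resample operator before
differencing. This keeps the forward model consistent with the data path:
without it, the framing error around the bolus peak aliases into the
parameters (2–6 % bias on noiseless self-fits), with it noiseless
self-fits recover truth to optimizer precision. Residuals remain
uniform-weight per 1-s grid point, which implicitly duration-weights
frames.

AIC = N·ln(RSS/N) + 2(P+1) with N grid points and P free parameters; a
per-comparison-set positive offset (`aic_scaled`) is a reporting
convention that cannot change ordering. AICc is available but off by
default.

## Monte-Carlo study

Frame noise is zero-mean Gaussian with SD 0.4 SUV at the 10-s reference
duration, scaled as sqrt(ref/duration) (counting statistics; a
constant-SD mode exists to test that assumption). One noise bank of 100
realizations per study, generated once from one seed and shared by every
model and condition, so model comparisons are not confounded by different
draws. Noise is added at the frame level; the noisy framed TAC is then
resampled and fitted exactly like measured data.

Per parameter: *stability* is the signed percent deviation of the
noiseless self-fit from truth; *accuracy* the signed percent deviation of
the mean over noisy fits; *COV* the SD/mean over noisy fits. Zero-truth
parameters are reported as undefined rather than divided by.

On the shipped presets the oxidation-parameter COV ranks the models
#1 < #7 ≈ #4 ≪ #6 < #5 at n = 100 — the stable two/three-tissue models
beat the over-parameterized four-compartment ones, which is the package's
reproduction of the study's qualitative conclusion.

## Sensitivity and identifiability

Relative sensitivity Sens_k(t) = (δTAC/TAC)/(δk/k) by central differences
at ±1 % (second-order accurate; the unperturbed TAC normalizes the
ratio). Evaluation starts at the first grid point where the reference TAC
exceeds 10⁻⁶ SUV; the t = 0 singularity is excluded rather than
regularized. Tied rates are perturbed as their single free symbol. The
sensitivity matrix integrates pairwise products (trapezoid) to the scan
end; its normalized inverse gives parameter correlations, with
pseudo-inverse fallback plus condition-number reporting near singularity —
the most complex models are expected to be near-unidentifiable and the
report must say so, not crash. Pairs with |corr| ≥ 0.7 are flagged.

A structural note on v_b: for models that trap label (#4, #7, #10), once
the blood pool has cleared (C_b → 0) the relative v_b sensitivity
plateaus at −v_b/(1−v_b) ≈ −0.11 for the remainder of the scan, whatever
the input shape. The early-concentration property (∫₀⁴|Sens_vb| >
∫₄³⁰|Sens_vb|) therefore holds — and is asserted — for the one-tissue
model #1, where late tissue and blood decay together; for the trapping
models the v_b effect on the *absolute* curve is still concentrated in
the bolus, but the relative-sensitivity integral is dominated by the long
late plateau.

## Synthetic cohorts

Four presets (`YS_warm`, `YS_cold`, `OS_warm`, `OS_cold`) emulate younger
and older subject groups in both thermal conditions. Each carries analytic
input-model shape parameters plus a whole-blood AUC anchor
(39/49/51/63 SUV·min over 30 min); amplitudes are calibrated at build
time so the anchor is hit exactly. Cold presets peak earlier (smaller t₀,
larger λ₁) with slower intermediate washout (smaller λ₂), mirroring the
measured difference between conditions. The whole-blood curve is built by
*inverting* the parent-fraction model (C_b = C_p·e^(+0.104(t−0.48))), so
metabolite-correcting a synthetic C_b recovers C_p to machine precision —
the round-trip is exact by construction, which keeps the correction tests
clean. Default injected delay (4 s) and dispersion (10 s) are plausible
aorta→subclavian values used only to exercise the correction path.

Ground-truth kinetics: model #7 uses K₁ = 0.07 mL/g/min, k₂ = 0.30,
k₃ = 0.14 min⁻¹, v_b = 0.10 and model #4 uses K₁ = 0.07, k₂ = 0.14,
k₃ = 0.05, v_b = 0.10 — the two reference simulation sets. Truths for the
other eight models are extrapolations sharing K₁ and v_b, with rates
chosen once for comparable noiseless TAC peaks; they are assumptions, not
reproductions. The truth table is shared across presets (per-cohort mean
parameters are not part of the reference material); conditions differ through the input
functions.

What the generator does *not* emulate: inter-subject anatomy/physiology
variation beyond AIF scaling/warping, ROI spill-over between vessel and
tissue, reconstruction-correlated noise, and partial-volume effects.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to every
real-data pathology.

## Problem sizes and determinism

The default study grid is 1801 points (30 min at 1 s); the Monte-Carlo
study uses 100 realizations, matching the stated protocol, and runs in a
few minutes on one core. Every stochastic path takes a single seed
(noise banks, AIF jitter); reports embed seed and package version, and
rerunning with the same seed reproduces outputs bit-identically.

## Known limitations

* Patlak's reversible-model null (slope ≈ 0) holds only once the tissue
  equilibrates with the input; with fast-clearing inputs a transient
  positive slope persists well past 10 min, so `t_star` should be chosen
  per input shape (default 10 min; the oracle tests use 15 min with a
  slow-tail input).
* The monoexponential index window (1.5–5 min) overlaps the
  vascular-dominated phase; K_mono is systematically far from the
  compartmental k₂ on blood-rich curves, which is visible in the worked
  example.
* AIC values on noiseless synthetic fits are dominated by float residuals
  and are only meaningful relative to one comparison set.
* Correlation matrices for models #5/#6/#10 sit near singularity by
  design; read them together with the reported condition number.
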