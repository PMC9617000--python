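# Methods

This note documents the models, parameter choices and numerical
decisions behind `neurovasc`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Activation analysis (`neurovasc.asl`)

**Signal model.** A dual-echo pCASL acquisition interleaves non-labelled
(control) and blood-labelled volumes at TR = 4550 ms; 54 pairs span
8 min 11 s, covering the 486-s visual paradigm (four 54-s stimulation
blocks flanked and separated by 54-s rest). Pairwise control − label
gives one perfusion-weighted volume per pair on an effective 9.1-s grid,
time-stamped at the pair midpoint. The BOLD series is the non-labelled
second-echo volumes (TE₂ = 31.7 ms).

**Preprocessing.** Spatial smoothing is Gaussian, FWHM 5 mm converted to
per-axis sigma by voxel size, reflective boundaries. The temporal
high-pass is Gaussian-weighted running-line detrending with weight sigma
equal to half the 90-s cutoff period; the *mean-centered* trend is
subtracted, so each voxel's temporal mean is preserved exactly and the
subsequent percent-of-mean conversion stays well defined. A linear drift
is removed exactly (a weighted line fit of a line is the line); a 20-s
sinusoid passes within 0.2 %; the 108-s paradigm fundamental is partially
attenuated (to ~0.87) — an unavoidable property of a 90-s cutoff.

**GLM.** The regressor is the unit boxcar convolved with the unit-area
gamma density with shape (mean/SD)² = 4 and scale SD²/mean = 1.5 s
(mean lag 6 s, SD 3 s), computed by midpoint-rule quadrature on a 50-ms
grid and interpolated to the sample times; a long block plateaus at
exactly 1, so β reads directly in percent signal change. The design
matrix is passed through the *same* temporal high-pass as the data —
standard GLM practice — which makes the filter transparent to the
response estimate: a noise-free response is recovered exactly rather
than attenuated by the 90-s/108-s mismatch. Each voxel's series is
converted to percent of its own temporal mean, mean-centered, and fitted
by OLS on [intercept, regressor]. z is derived from the t statistic of β
by matching tail probabilities at n − 2 degrees of freedom; numerically
perfect fits (underflowing tails) are capped at z = 40; zero-variance or
non-positive-mean voxels are flagged with β = z = 0.

**ROI rule.** Binarize at z > 3.1, take the largest 26-connected
component (ties broken deterministically by the smallest linear voxel
index), and keep voxels at or above that component's 90th z-percentile
(linear-interpolation percentile, inclusive threshold). An empty mask is
a valid outcome (`no_activation`). The rule is verified voxel-for-voxel
against a brute-force flood-fill + sort oracle on random maps.

**Responses and QC.** ΔBOLD is the mean β over the ROI. ΔCBF is the OLS
coefficient of the ROI-median percent-normalized CBF series on the block
regressor, with a two-sided t test; p ≥ 0.05 flags `no_cbf_response`,
ΔCBF > 400 % flags `anomalous`, and both exclude the subject, as does an
empty ROI. Simple pairwise subtraction is used (no surround subtraction),
plain OLS without prewhitening, and ΔCBF is reported in percent only —
absolute CBF calibration (M0, labelling efficiency, blood T1) is out of
scope since every downstream use is relative. No motion correction or
slice-timing correction is applied; motion enters only as a QC flag.

## 2. Resting physiology (`neurovasc.flow_oximetry`)

Vessel flow is mean through-plane velocity × ROI area (laminar flow
through a circular cross-section: the discretized parabola matches
π r² v_max/2 to better than 3 % at the default resolution). gCBF
normalizes the summed arterial flow to brain weight, volume × 1.05 g/ml.

Oximetry inverts the infinite-cylinder susceptibility model

Δφ = γ · B₀ · ΔTE · (Δχ_do · Hct · (1 − SvO₂)/6) · (3 cos²θ − 1)

for SvO₂, with γ the proton gyromagnetic ratio. Defaults: Δχ_do =
4π·0.27 ppm (SI), Hct 0.42, θ = 0 (vessel parallel to B₀); all are
configuration, not measurements. Inter-echo phase differences are
alias-corrected automatically by shifting each vessel voxel by the
multiple of 2π that brings it within π of the tissue median; a corrected
value within π/100 of the ±π boundary is refused as ambiguous, and the
magic angle (3 cos²θ = 1) is rejected. Estimates outside [0, 1] are
clamped with a warning. The estimate is invariant to a global phase
offset applied to both echoes.

CMRO₂ uses the Fick principle with the **monomer hemoglobin convention**:
[Hgb] in mmol/l (Danish clinical units) binds 1 mmol O₂ per mmol, so
gCMRO₂ = [Hgb]·gCBF·(SaO₂ − SvO₂) is in µmol O₂/100 g/min with **no ×4
tetramer factor**. Hgb and SaO₂ enter as scalars (blood sample, pulse
oximetry).

## 3. Breath-hold reactivity (`neurovasc.breath_hold`)

Per dynamic, A-V.O₂(t) = SaO₂ − SvO₂(t) and CMRO₂(t) = [Hgb]·flow(t)·
A-V.O₂(t); constants cancel in percent analyses. "Baseline" is the mean
over dynamics lying entirely inside the 50-s pre-first-hold window
(≥3 samples required). Each series is expressed as percent change from
its baseline mean and regressed on a cohort-mean regressor built in a
first pass over all subjects (mean percent-change curve per dynamic,
divided by its maximum absolute value, so responses that are decreases —
A-V.O₂ — normalize to −1). The coefficient, scaled by the regressor's
extreme value (±1), is the percent change at the response peak; a
decrease is reported negative. With one subject the regressor is that
subject's own normalized curve and the fit is exact in the noise-free
limit. Per-quantity regressors are used (flow, A-V.O₂, CMRO₂ have
different shapes and signs). End-tidal CO₂ is not modelled (not
measured), and no per-hold nonlinear shape fitting is attempted.

At small cohorts with noisy series the CMRO₂ regressor (a ~5 % response
against percent-level noise) is itself noisy, inflating per-subject
ΔCMRO₂ estimates; this resolves as the cohort grows and does not affect
the flow analysis, whose response is four times larger.

## 4. Spectroscopy (`neurovasc.mrs`)

Long-TE (288 ms) spectra are fitted with two Lorentzians by bounded
nonlinear least squares: lactate initialized at 1.33 ppm and NAA at
2.01 ppm (standard chemical shifts), centers bounded ±0.1 ppm,
amplitudes nonnegative. The lactate doublet is not resolved at this
linewidth and is modelled as a single line. Concentration = peak area ×
calibration scale; the absolute reference is acquisition-specific and
enters as configuration (default scale 1), so percent changes — the
quantity of interest — are calibration-free. A zero spectrum returns
zero concentrations; non-convergence returns a flagged fit.

## 5. Cohort statistics (`neurovasc.cohort_stats`)

Robust simple regression is IRLS with the Tukey bisquare loss
(c = 4.685) and a Huber scale estimate (statsmodels RLM); p values use
the normal approximation of the IRLS estimator, a documented
approximation, and R² is computed on the weighted fit. A numerically
perfect linear relation collapses the scale estimate, so the exact OLS
solution is returned in that case. On outlier-free Gaussian data the
estimator agrees with OLS to within one OLS standard error (~95 %
efficiency); under 10 % gross contamination its slope shift stays well
below the OLS shift. Missing data are handled complete-case per pair,
with n reported per row.

FDR correction is Benjamini–Hochberg step-up at q = 0.05 (statsmodels),
oracle-tested against a hand-rolled step-up; in correlation tables it is
applied within each predictor family. Stepwise selection is forward,
maximizing adjusted R², deterministic with ties going to the earlier
covariate in declared order. Longitudinal intelligence change z-scores
both measurements across the cohort (sample SD) before subtracting, so
the result is affine-invariant with mean exactly zero. Attrition
accounting is explicit arithmetic with a reconciliation check
(enrolled = completed + Σ exclusions). Exercise frequency enters models
as a binary "at least once a week" covariate.

## 6. The synthetic cohort (`neurovasc.synthetic`)

**What it emulates.** Phantom-geometry imaging with the study's timing:
a 32×32×8 pCASL matrix (timing parameters at acquisition values;
configurable up to the acquired matrix) with a centered 10×10×4
"visual cortex" block, laminar vessels on a 96×96 velocity map, a
circular sagittal-sinus cross-section with a tissue annulus on 64×64
dual-echo phase maps (optionally stored wrapped into (−π, π] to exercise
alias correction), 39-dynamic breath-hold series over 276 s, Lorentzian
spectra, and a cognition/health table.

**Truth definition.** The configured ΔCBF/ΔBOLD is the amplitude of the
HRF-convolved percent modulation about the series temporal mean at
regressor height 1 — i.e. precisely the quantity the GLM coefficient
estimates, which is also how such responses are operationally defined by
the estimator in practice. This makes noise-free round trips exact and
keeps population recovery unbiased. The breath-hold flow response is a
smoothstep ramp over each hold with exponential recovery (τ = 20 s),
normalized so its sampled maximum is exactly 1; the saturation series is
chosen so either the Fick CMRO₂ trajectory or the A-V.O₂ trajectory hits
its configured peak exactly. Velocity maps can be rendered with the
discrete flow integral scaled to the analytic laminar value
(`exact_flow`), separating discretization error from estimator error.

**Population defaults.** Activation CBF response N(77.1, 30.5) %
truncated at 0 and breath-hold flow response N(22.5, 7.4) % are the
study conditions; cognition couplings default to the reported headline
values (IST 2000R slope 0.112, R² 0.13, plus three further instruments),
with noise calibrated as σ² = slope²·var(x)·(1 − R²)/R² so the expected
sample R² matches. Quantities without reported population spreads use
field-typical values chosen once: BOLD response N(2.0, 0.8) % (3 T
visual stimulation), breath-hold CMRO₂ response N(5.0, 3.0) %, gCBF
N(50, 8) ml/100 g/min, SvO₂ N(0.62, 0.04), SaO₂ N(0.975, 0.01), [Hgb]
N(9.3, 0.7) mmol/l, brain volume N(1150, 100) ml, resting lactate
N(0.723, 0.15) with increments N(0.060, 0.126) mmol/l, NAA N(10, 1)
mmol/l. Default noise: image tSNR 100 (ASL), 3 % flow and 0.01
saturation noise per breath-hold dynamic, 0.02 rad phase noise.

**What it does not emulate.** No k-space/MR physics, no motion, no
realistic anatomy, no physiological confounds (cardiac/respiratory
noise, vessel pulsatility), no field inhomogeneity beyond a global
per-echo phase offset. Passing round trips therefore demonstrates
estimator correctness and statistical calibration under the assumed
signal model — not robustness to artifacts real scanner data may show.

**Determinism.** One seed drives the truth table; raw series are
generated lazily from per-subject, per-modality child seeds
(CRC32 of "seed|subject|modality", < 2³¹), so runs are bit-reproducible
without holding a cohort of 4-D series in memory.

## 7. Numerical and design notes

- The noise-free full-chain activation round trip is exercised with
  smoothing disabled: with zero noise every voxel in the smoothing halo
  fits the regressor perfectly, z saturates at the cap, and the
  percentile ROI rule degenerates to an uninformative tie. With noise —
  the realistic regime — z ranks response amplitude and the rule selects
  undiluted interior voxels as intended.
- Problem sizes used by the test suite and acceptance script (40-subject
  cohorts at the 32×32×8 default matrix, 200 replicate cohorts of 150
  for slope recovery) were chosen as the package's desk-scale defaults;
  all statistics scale to the acquired matrix via configuration.
- Percentile definition: linear interpolation, inclusive (≥) threshold.
  Component connectivity: 26-neighborhood in 3-D.
- The stats stage of `run_all` requires ≥3 QC-included subjects and is
  skipped (empty table) below that.
- `delta_te` and other echo times are milliseconds throughout the API;
  conversions to seconds happen inside the physics functions.
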