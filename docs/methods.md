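# Methods

This note documents the models and numerical choices behind `nirsdual`, the
defaults that matter, and what the synthetic study does and does not
emulate.

## Optical model

Continuous-wave fNIRS measures intensity at 750 and 830 nm plus an ambient
(no-illumination) reading per channel, at 10 Hz. After subtracting the
ambient trace, optical density is OD_λ(t) = −log₁₀(I_λ(t)/I₀_λ). The
baseline I₀ is the temporal mean of the cleaned session by default; a
first-30-s convention is available (`baseline="first30s"`). Since the output
is *relative* concentration change, the baseline choice shifts only the
zero point within a session.

The modified Beer–Lambert law relates OD changes to chromophore
concentration changes through the source–detector separation d and the
differential pathlength factor (DPF):

    OD_λ/(d·DPF_λ) = ε_HbO,λ·ΔHbO + ε_HbR,λ·ΔHbR

solved per sample by inverting the 2×2 extinction matrix. Defaults are the
standard compiled hemoglobin extinction values (1/(mM·cm)): ε_HbO = 0.5179,
ε_HbR = 1.4066 at 750 nm; 0.9740 and 0.6930 at 830 nm; DPF = 6.0 at both
wavelengths. These are configurable; they affect results only through a
per-channel scale, which the downstream z-standardization absorbs.

## Preprocessing choices

**Channel QC.** A channel is dropped for a session if any sample exceeds
4500 counts (saturation — applied to single samples, the conservative
reading that avoids averaging clipped segments into epochs), if its
calibration dark current exceeds 200 counts (mean statistic by default; max
available — the device reports a scalar, and which summary applies is
ambiguous), or if either wavelength correlates with the ambient trace at
r > 0.7 (the detector is reading background light, not tissue). Constant
traces make r undefined; that criterion is then skipped with a warning. QC
is evaluated per channel per session because the sensor is re-donned at the
mid-study break.

**Wavelet despiking.** OD series are decomposed (db5, 5 levels); within each
detail band coefficients are modeled as Gaussian with a robust scale
(1.4826·MAD) and those with two-sided tail probability below α = 0.1 are
zeroed before reconstruction. Motion spikes concentrate in few outlying
detail coefficients, so this suppresses them while oscillatory physiology
passes through; family/level/α are configurable. MAR operates on OD (after
conversion, before filtering), following the pipeline's stage order.

**Band-pass.** High-pass 0.005 Hz and low-pass 0.1 Hz, both linear-phase
FIR applied forward–backward (zero net phase, magnitude response squared).
The low-pass is a 661-tap Hamming windowed-sinc with a 0.05 Hz transition.
The high-pass needs full gain by 0.01 Hz; an equiripple (Parks–McClellan)
design reaches that in 1401 taps at 10 Hz, where a windowed-sinc would need
~6600 — longer than a session, hence unusable with reflection padding. The
combined response satisfies: ≥ 20 dB attenuation at DC and at 0.25 Hz
(in fact ~85 and ~136 dB), and ±0.45 dB ripple over [0.01, 0.08] Hz. The
forward–backward pair is applied as a single precomputed zero-phase kernel
via FFT convolution with odd-reflection padding; this is numerically
identical to `filtfilt` with the same taps (asserted in tests) and an order
of magnitude faster. Inputs shorter than the longest filter raise an error
naming the minimum duration; inputs shorter than 3× warn about edge
effects.

The stage order is fixed and recorded in each result's provenance:
reject → OD → wavelet MAR → band-pass → MBLL.

## Behavioral scoring

Valid FOV polygons have `bottom_max_size < 750` and `fov_area_ratio < 0.50`
(oversized footprints arise when the camera grazes the horizon and the
projected quadrilateral degenerates; thresholds are treated as opaque
attributes of the log). With C the union of valid polygons and the assigned
region ROI:

    scan = |C ∩ ROI| / |C ∪ ROI|,  not_scan = |ROI ∖ C| / |C ∪ ROI|,
    over_scan = |C ∖ ROI| / |C ∪ ROI|

The union denominator is the convention under which the three ratios sum to
exactly one; normalizing by |ROI| instead is available
(`denominator="roi"`) since coverage conventions vary between simulators.

Accuracy is 1 iff some contiguous run has the target in FOV at zoom ≤ 15°
(inclusive) lasting ≥ 3 s. Run duration is measured as timestamp span, which
makes the decision invariant to resampling the log to a finer grid. The 3-s
dwell is the trained criterion; setting `dwell_s=0` reduces the rule to
"ever in view at gate zoom". Subareas without a target score 1. AdpTF
divides accuracy by the 1-based subarea number, discounting later subareas
whose outcome can ride on earlier ones.

## Features, standardization, efficiency

Channel means are taken over [t₀+15 s, t₁−15 s) of each subarea — 90 s of a
2-min subarea — to wash out hemodynamic carry-over between back-to-back
subareas. Too-short windows yield missing values, never zeros, and
missingness propagates to the models (which drop cases listwise).

Standardization uses the sample (n−1) SD over the full observation pool per
measure — one pool across subjects, sessions and subareas, so that both
groups land on common axes. Per-session pools are available via
`standardize_within`. Mental effort from HbR is z(−HbR): HbR falls with
activation, so more-negative HbR means more effort. RE = (P−M)/√2 and
RI = (P+M)/√2 are a 45° rotation, so RE²+RI² = P²+M² holds identically;
positive RE reads "performance above effort expended", positive RI "both
high". RE/RI are computed at the observation level (standardize, then
rotate, before any averaging) on the focus channels {2, 7, 12} — the
channels with the largest dual-task effects in the planted effect map —
configurable.

## Grouping

Per subject, the median scan fraction over that subject's subareas is taken
for E1, E2, E3; OLS through the three medians (sessions coded 1–3; any
affine coding preserves the sign) gives a slope whose sign assigns the
group: positive → Attention-focused, negative → Accuracy-focused. An exact
zero (measure-zero with continuous scores) goes to Accuracy-focused with a
tie flag, since strictly positive slope is the membership test for the
other group. Medians make the rule invariant to subarea relabeling.

## Mixed models

Fixed structures use treatment coding with Group level order
(attention, accuracy) and Session order E1..H2. `1 + Group + Group:Session`
spans 10 columns (2 + 2×4), so with the random intercept and residual the
model has 12 parameters against 7 for `1 + Session`; adding the
uncorrelated short-channel random slope `(0 + Short|ID)` gives 13 and 8.
The standard comparisons therefore have 4, 8 and 5 degrees of freedom, and
the three-way `Group:Session:AdpTF` term adds 10 (AdpTF enters raw,
uncentered). Numerical optimization is delegated to statsmodels' `MixedLM`
(with a retry ladder over optimizers; a non-convergent model raises), using
ML for likelihood-ratio tests and REML for post hoc contrasts. ML and REML
log-likelihoods were verified against lme4 to 1e-4 on fixtures, and the
test suite keeps one live lme4/lmerTest cross-check.

Nesting for LRTs is verified by rank on a balanced template design — a
Session main effect is correctly recognized as nested inside Group:Session.

**Satterthwaite degrees of freedom** are computed in-package (statsmodels
provides none): for a contrast c, f(θ) = c'C(θ)c with
C(θ) = (X'V(θ)⁻¹X)⁻¹, df = 2f²/(g'Ag) where g = ∇_θ f by central
differences and A is the inverse observed information of the REML
log-likelihood in the variance parameters θ = (σ²_resid, τ_intercept
[, τ_short]), also by finite differences (relative step 1e-4). Variance
components estimated at the boundary (singular directions) are held fixed
at zero, as the reference implementations do; without this the numerical
Hessian is dominated by the flat direction. Against lmerTest/emmeans the
dfs agree to better than 2% (e.g. 13.76 vs 13.77 for a between-group
contrast at n = 13; 369.0 vs 369 within-group).

Contrasts are estimated-marginal-mean differences with covariates held at
their sample mean: 5 between-group (one per session) plus E1–E3, E3–H1 and
H1–H2 within each group — 11 enumerated comparisons per DV, a count the
report states explicitly. p values are BH-FDR-adjusted within each DV's
family. Cohen's d divides the contrast by √(σ²_resid + τ_intercept), the
total subject-level SD (`d_denominator="residual"` uses the residual SD
alone), with 0.2/0.5/0.8 read as small/medium/large. A heteroscedasticity
check (slope of |residual| on fitted values) flags DVs where a log₁₀
transform of the response is advisable; the pipeline surfaces the flag
rather than transforming silently.

## Synthetic study

The generator reproduces the study *design*: 13 subjects, sessions E1–E3
(easy) and H1–H2 (hard), six 120-s subareas per session with 10-s gaps,
10 Hz sampling, and a planted 6/7 split into groups whose subarea scan
fractions follow group base ± 0.1/session across easy sessions (hard
sessions hold the E3 level), with subject-level intercept SD 0.05 and
subarea noise SD 0.05. Accuracy trends run opposite: flat for the
attention group, rising for the accuracy group. Hemodynamics are per-
subarea boxcars convolved with a unit-area double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6), HbR = −⅓·HbO, both configurable; inter-subject
distributional parameters are stated assumptions, not reported values.
Channel amplitudes default to 0.5 µM with ±0.15 µM/session group divergence
on channels 2, 7 and 12. Noise comprises slow drift, Mayer (0.10 Hz),
respiratory (0.25 Hz) and cardiac (1.1 Hz) oscillations — placed so the
filter contract provably removes the latter two — white noise, Poisson
motion spikes, a shared extracerebral signal entering short channels at
unit gain and long channels at gain 0.3, and ADC effects (background light,
dark current, shot noise, integer quantization, clipping at 4500 counts).
One global seed expands into per-(subject, session, purpose) substreams via
hashed seed sequences, so any subject or session is reproducible in
isolation and bit-identical across runs.

The behavioral generator emits actual ROI/FOV polygon geometry (disjoint
grid cells realizing the planted coverage fractions exactly, plus injected
oversized polygons the scorer must discard) so that the scoring module is
genuinely exercised; a ratios-only fast mode emits score rows directly for
statistics-level simulation studies.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real recordings: task-evoked systemic/extracerebral
activity correlated with the paradigm (the short-channel random slope
absorbs shared superficial signal, not task-locked scalp responses),
serially correlated physiological noise beyond the fixed oscillations,
optode-coupling drift, subject-specific HRF shape variation, and any
renderer- or simulator-specific log formats.

## Problem sizes and verification

The simulation experiments use: grouping recovery over 100 replicate
studies at n = 13 (the acceptance script reports the fraction recovering
≥ 12/13 labels); type-I calibration of the Group × Session LRT over 1000
null replicates (test suite: 500) with rejection expected near α = 0.05 —
pooled over 3500 replicates the measured rate is 0.053 ± 0.004 — and power
over 200 replicates with a planted one-within-subject-SD divergent trend,
which is essentially 1 at these settings. End-to-end optical recovery is
checked noise-free: preprocessing applied to forward-modeled recordings
reproduces the band-passed ground truth with correlation > 0.9999 and
amplitude error < 0.1% per long channel (the acceptance thresholds are
0.99 and 5%).

## Known limitations

- No task-evoked systemic artifact removal (Kalman/state-space or adaptive
  filtering); the short-channel term is a variance component, not a
  regression-based superficial-signal subtraction.
- No within-epoch temporal analysis; features are single 90-s means.
- The Satterthwaite machinery assumes the two-component (plus optional
  short-slope) covariance structure this package fits; it is not a general
  mixed-model df engine.
- SNIRF support is a minimal purpose-built subset (continuous-wave
  amplitude, one data block, ambient as an aux series), not a full
  implementation of the format.
- With ~13 subjects, between-group contrasts rest on ~14 effective degrees
  of freedom; effect-size estimates at this n are unstable and the
  synthetic experiments make no claim about realistic effect magnitudes.
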