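# Methods

`spheromech` models how the direction of an applied force decides whether
the platelet integrin α_IIb_β_3 unfolds (and so activates the platelet) or
simply detaches from its ligand, and carries that mechanism through to
measurable consequences: AFM force-curve signatures, FRET conformational
maps, rolling/sliding kinematics of platelets at a wall, and coagulation
metrics of an extracorporeal circuit. Every analysis in the package runs on
seeded synthetic data whose statistical structure matches the assumptions
of the corresponding estimator; this note records the models, parameter
choices and numerical decisions.

## Coarse-grained unfolding model

The receptor leg is reduced to six domains, two hinge angles and a small
hydrogen-bond graph:

* baseline interdomain bonds PRO381–ARG563 (barrier 58 pN, gating the
  "Separation I4" stage) and SER367–SER551 (60 pN, "Separation I3");
* three latent contact bonds (LYS549–LYS402 ×2, LYS549–SER369) that engage
  only after normal load rotates Calf-1 onto Calf-2;
* hinge angles θ (Thigh/Calf-1, resting 45°) and φ (Calf-1/Calf-2,
  resting 140°).

Loading is a sharp-threshold event machine, not dynamics. Tangential force
F breaks the 58 pN bond iff F ≥ 58, then the 60 pN bond iff F ≥ 60, ramping
θ 45° → 60° → 75° (linear across stage intervals; only the endpoints are
constrained, the ramp shape is a presentation choice). Normal force rotates
φ 140° → 100°, forms the contact bonds, and then the weakest link decides:
the five-bond network withstands >140 pN collectively, so a ligand bond of
70 pN fails first and the receptor detaches still bent. The ligand check is
applied only on the normal pathway — sliding friction re-engages the
ligand and keeps transmitting force until the leg unfolds — and detachment
additionally requires the applied force to reach the ligand strength,
which keeps low-force protocols event-free. The 140 pN network strength is
modelled as a collective threshold (its decomposition into per-bond
barriers is not specified by the underlying data), and the two
LYS549–LYS402 bonds are treated as identical.

`bell_force_scale` provides the Bell-model bridge between loading-rate
regimes, f = f_ref + (k_BT/x‡)·ln(rate/rate_ref) with k_BT = 4.114 pN·nm at
298 K; with x‡ = 1.42 nm a 10⁶-fold rate increase roughly doubles a 40 pN
rupture force, which is the expected gap between steered-simulation and
AFM force scales. `activation_vs_tangential_fraction` is a deliberately
minimal linear response (20 % + 40 %·fraction) anchored at the measured
endpoints of the activation-reporter signal; no intermediate calibration
points exist, so no richer model is justified.

## AFM force-curve analysis

Sign convention: attractive load is negative; the rupture is the largest
single-step force increase back toward baseline, required to exceed 5×
the baseline noise SD (chosen well above the ~2 SD pre-rupture peak scale
so peaks are never mistaken for the jump; ties go to the latest step).
Noise is estimated robustly (median baseline, 1.4826×MAD), so uniform
force offsets and mild baseline drift are absorbed; a baseline window
whose quarter-medians disagree by >5 SD is rejected as overlapping the
ramp. The rupture magnitude is read from the sample at the left edge of
the jump relative to the baseline: at zero noise this equals the ramp
minimum, and under additive noise it is unbiased, whereas a running
minimum over a shallow ramp is biased low by several SD.

Pre-rupture peaks are measured on the detrended loading ramp. The default
detrender is an iteratively masked least-squares line (samples >2.5 robust
SD from the fit are excluded and the line refit), which is exact for the
linear ramps generated here; a centered moving-median detrender (window
5 % of the ramp, minimum 7 samples) is available for curved ramps but is
not the default because on a sloped ramp the moving median absorbs a large
fraction of a bump's amplitude (the bump shifts the window's order
statistics), which an amplitude-threshold test cannot tolerate. Amplitudes
are estimated by a matched filter — correlation with a unit Gaussian
template whose width (1 % of the ramp length) is shared with the
generator's bump width — giving an unbiased estimate with noise reduced by
~sqrt(template support); each amplitude is referenced to the median of the
filtered residual in a symmetric annulus (4–10 template widths) around the
peak, cancelling any residual linear trend. Candidates must clear a
prominence of 5× the filtered noise SD. A peak is significant iff its
amplitude strictly exceeds 1.96 baseline-noise SD; an exactly-1.96 SD peak
is therefore non-significant. A curve with ≥1 significant peak is
classified `unfolded`, otherwise `folded`. The significance test is
applied to the detrended signal (the raw ramp has no meaningful baseline
for a bump amplitude). With the default sizes, a 2.15 SD bump is separated
from the 1.96 SD threshold by >3 estimator SDs on a 65 536-sample curve
and the 6 pN (3 SD) unfolding peaks by >4 estimator SDs on a 4 096-sample
curve, so classification is stable across seeds.

Condition summaries use the sample SD (ddof = 1, zero for n = 1);
between-condition comparisons are Welch two-sample t tests.

## FRET photophysics

Standard Förster chain with the conventions: J = ∫f_D(λ)ε_A(λ)λ⁴dλ on the
donor grid (trapezoid, donor renormalized to unit area, acceptor linearly
interpolated), in M⁻¹cm⁻¹nm⁴; R0 = 0.02108·(κ²Φ_D n⁻⁴J)^(1/6) nm with
defaults κ² = 2/3, n = 1.33, Φ_D = 0.4; E = 1/(1+(r/R0)⁶) and its exact
inverse; FLIM efficiency E = 1 − τ_DA/τ_D. The two-state mixture treats a
region's apparent efficiency as a linear combination of a resting
(bent-closed, high-FRET) and an extended (active, FRET-dark) state:
f = (E_rest − E_region)/(E_rest − E_active). E_active defaults to the
Förster-law value at 19 nm (≈4.4×10⁻⁴) rather than exactly zero; the
difference in f is <0.1 %. Reported fractions are additionally rounded to
the nearest 10 % (half away from zero), which is the resolution the
apparent-efficiency inputs (~60 %, ~20 %) justify; the raw fraction is
always returned alongside. Pixelwise map deconvolution clamps out-of-range
pixels to [0, 1] and reports the clamp counts rather than erroring, since
noisy maps legitimately stray past the anchors.

## Trajectory kinematics

Displacement is the cumulative chord length of the centroid; rotation is
the unwrapped orientation (minimal-change branch; an exact 180° step is
kept positive), in radians. The rolling index radius·|total rotation| /
total displacement is 1 for ideal no-slip rolling and 0 for pure sliding;
the classifier threshold 0.5 is the midpoint of those signatures (no
empirical criterion exists to calibrate against). A zero-displacement
track has an undefined index and is labelled `unclassified`. Group
rolling-probability ratios carry Katz log-method confidence intervals.
The velocity trend is the sign of the least-squares slope of frame speed
vs time, with |slope| < 0.01 µm/s² called steady. Shape classification
uses a major/minor aspect-ratio cutoff of 1.3 (configurable; the imaging
criterion behind the published shape labels is not reproduced here).
`conformational_switch_time` is the desk kinematic estimate
extension/speed — 15 nm at 0.8 µm/s gives 18.75 ms.

## Device metrics

Clotting time is the first sample whose pressure rise *strictly* exceeds
the rule threshold (50 % of baseline, or an absolute +25 mmHg — identical
at the standard 50 mmHg baseline), evaluated on the raw series with no
interpolation between samples; a run that never crosses is censored
(clotting time serialized as null). Occlusion ratio is a plain count
fraction; thrombus mass sums dialyzer and canister contributions. Dose
conversion ng/mL → nM divides by the molar mass (colchicine 399.4 g/mol,
supplied as a constant, not hard-coded in the formula).

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` with one
explicit seed and no global state; identical seed and spec give
bit-identical output, and every generator records its ground truth in the
output's metadata so estimators can be scored against the realized (not
just nominal) truth.

* **Force curves** — 20 % flat baseline, linear ramp to −F with
  F ~ Normal(rupture_mean, rupture_sd), Gaussian bumps of the requested
  SD-unit amplitudes at fixed ramp fractions (width = the detector's
  template width), one-step jump to zero, short zero tail, i.i.d. Gaussian
  noise everywhere (default SD 2 pN, configurable; the true acquisition
  noise is instrument-dependent). At zero noise bump amplitudes are scaled
  by `peak_force_scale` instead.
* **Spectra** — Gaussian donor/acceptor bands (DiO-like 505/20 nm,
  Rhodamine-B-like 555/28 nm, ε_max 1.06×10⁵ M⁻¹cm⁻¹);
  `calibrate_spectra_to_r0` rescales ε_max in closed form (R0 ∝ ε_max^1/6)
  so a test can realize any target radius exactly.
* **Tracks** — motion along +x at 1 µm/s (constant, accelerating or
  decelerating profile), radius 1.25 µm (typical platelet; configurable);
  rolling tracks add slip×(arc/radius) to the orientation each frame,
  sliding tracks only angular noise. Orientation is stored wrapped, as a
  tracker would emit it. Cohorts draw each track's kind from the group's
  rolling probability (binomial structure by construction).
* **Device runs** — occlusion follows the logistic growth law seeded at
  1 % of its maximum; pressure = baseline/(1−occlusion), the resistance of
  identical parallel conduits losing members (a deliberately simple map —
  it is *not* claimed to reproduce any particular measured
  occlusion/pressure pair); ACT decays linearly from 140 s. A helper
  inverts the logistic so tests can place the threshold crossing at an
  exact sample.
* **Shape kinetics** — piecewise single-exponential (only endpoint values
  are constrained by observation): decay 0.90 → 0.10 with rate 0.15/min,
  recovery toward 0.65 with 0.08/min after drug removal at 60 min.
* **FLIM maps** — per-pixel Gaussian noise around region efficiencies on
  non-overlapping masks; background pixels are NaN.

What the generators deliberately do **not** emulate: instrument drift and
1/f noise in AFM baselines, worm-like-chain curvature of loading ramps,
photobleaching and spectral bleed-through, image-segmentation errors in
tracks and shape labels, and pulsatile pressure. Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to every artifact of real acquisitions.

## Problem sizes and numerical tolerances

Test and acceptance workloads use 2 048–65 536-sample curves (the largest
only where the 2.15-vs-1.96 SD margin demands a long averaging window),
40-curve condition summaries, 50-seed classification sweeps, 500-track
cohorts, and 1-min-sampled device runs; the full suite completes in a few
seconds. Zero-noise constructions are asserted exactly (no tolerance);
sampled quantities are asserted within 2–3 standard errors of the recorded
generative truth; closed-form identities (Förster round trip, R0
homogeneity, affine invariance of the mixture) at 1e−9…1e−12.

## Known limitations

The unfolding model is a rule machine: it reproduces event order, angle
endpoints and the direction dichotomy, but not force–extension profiles,
kinetics or temperature dependence. The mixture model assumes exactly two
conformational states with spatially uniform photophysics. The rolling
index needs the platelet radius; when metadata omits it the 1.25 µm
default biases the index for unusually large or small cells. The clotting
rule is evaluated on raw samples, so the reported clotting time is
quantized to the sampling interval.
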