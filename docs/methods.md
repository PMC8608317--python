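# Methods

## The model

The package estimates how visible the geometric structure of an
architectural hazard is to an observer with reduced vision, from nothing
but a luminance image of the scene, the scene's true geometric edges, and
two routine clinical measures: letter acuity (logMAR) and Pelli-Robson
contrast sensitivity (log10 units). The chain is

1. **CSF construction** — the clinical measures parameterize a contrast
   sensitivity function S(f) (f in cycles/degree);
2. **appearance filtering** — the image is decomposed into octave bands and
   content below the observer's contrast threshold at each band's frequency
   is removed;
3. **boundary extraction** — Canny edges of the filtered image mark the
   luminance boundaries the observer can still use;
4. **visibility matching** — every geometric-edge pixel is scored by its
   distance to the nearest luminance boundary, and the Hazard Visibility
   Score (HVS) of a region of interest is the mean score over the geometric
   pixels inside it.

A synthetic walkway/step stimulus family, a simulated binary-choice
observer, and the logistic validation statistics close the loop: the HVS
is validated by how well it predicts simulated identification accuracy.

## CSF: template and anchors

The CSF template is a truncated log-parabola: flat at the peak sensitivity
below the peak frequency, parabolic in (log f, log S) above it, crossing
S = 1 exactly at the cutoff frequency. Two anchors place the template for
an observer:

* **cutoff from acuity**: f_cut = f0 · 10^(−VA) with f0 = 30 cpd at
  logMAR 0 (the standard letter-acuity correspondence). Worsening acuity
  rigidly shifts the curve leftward on the log-frequency axis.
* **height from Pelli-Robson CS**: by default the *peak* sensitivity is
  10^CS. Pelli-Robson letters are large and their detection is mediated by
  low spatial frequencies near the observer's best sensitivity, so the
  chart score is read as peak log sensitivity. An alternative mode anchors
  S at a fixed reference frequency (1 cpd by default) instead; that mode is
  only satisfiable while the reference frequency lies below the cutoff —
  at severe acuities (VA ≳ 1.48 with f0 = 30) the cutoff falls below 1 cpd
  and the mode raises a configuration error naming the violated anchor.
  The peak anchor has no such failure region, which is why it is the
  default: the pipeline must accept the severe clinical range (VA up to
  ~1.7) that the validation experiments use.

The low-frequency plateau (rather than a two-sided parabola) makes the
band thresholds monotone in acuity: worsening acuity can only raise the
threshold at every frequency. The full parabola is available via
`CSFTemplate(low_frequency_plateau=False)`. The template bandwidth (peak
to cutoff distance per unit of log sensitivity, default 1.0 log10 unit) is
a free shape parameter; only the shift rule, not the exact template, is
constrained by the clinical literature the model follows.

When CS has not been measured (charts become unusable at very low acuity)
it is inferred from the empirical linear relation CS = 1.72 − 0.69·VA,
clamped at 0, and flagged `inferred-from-acuity`.

## Appearance filter

The filter bank is a cosine-log pyramid in the frequency domain: bands at
octave spacing, half-cosine profiles in log2 frequency that tile to unity,
a pure low-pass baseband, and mirror padding against wraparound. The top
band is high-pass (flat above its center) so every frequency up to Nyquist
belongs to a thresholdable band; otherwise supra-band content would hide
in the residual and survive filtering. Reconstruction (sum of bands plus
baseband) is exact by construction.

Band-limited contrast is band/low-pass, with the denominator floored at
10⁻⁶ cd/m². A band centered at or above the CSF cutoff is removed
entirely; elsewhere, retention ramps linearly from zero at the threshold
contrast to full at twice threshold (soft thresholding, the default). A
binary keep/zero variant exists, but its discontinuity fragments band
content along the threshold contour and measurably destabilizes the edge
positions Canny finds downstream; the soft ramp preserves the intended
monotone loss of content with worsening vision. The filter operates on
linear luminance; a log-luminance mode is available.

Idempotence: one-step idempotence is impossible for any threshold filter —
oscillatory band content always has subthreshold slivers at its zero
crossings, so a second pass always perturbs retained content. The filter
is exactly idempotent on its fixed points (uniform images; images whose
oscillatory content is entirely subthreshold) and iterated application
contracts toward a fixed point; the tests check exactly that.

## Boundary extraction

Canny on the max-normalized luminance grid (Gaussian sigma 1 px; hysteresis
at 0.1/0.2 of the gradient reference — the 99.5th-percentile Sobel
gradient magnitude of the smoothed normalized image). A high percentile
rather than the absolute maximum makes the reference robust to isolated
photometric hot spots (a light's closest approach to a surface), which
would otherwise push the thresholds past genuinely high-contrast
boundaries. Normalizing by the maximum luminance makes the edge map
invariant to global luminance scaling. When detecting boundaries on a
*filtered* image the pipeline passes the unfiltered render as the gradient
reference: the detection criterion then stays fixed as vision worsens, so
filtering can only remove boundaries. (With self-referenced thresholds,
removing the strongest content would lower the adaptive thresholds and
re-admit weak edges — worse vision could paradoxically yield more edges.)

## Scene synthesis

The stimulus family is a 30 ft walkway, 4 ft wide, one of five targets at
10 ft (flat, ±1 in, ±7 in steps), five lighting arrangements, five
viewpoints; 5×5×5×2 repetitions = 250 trials. Scenes are ray-cast against
the piecewise-planar model through a perspective pinhole camera (focal
length ppd·180/π pixels, i.e. the nominal pixels-per-degree holds on
axis) and shaded with direct Lambertian reflection from one point light
(optionally coned for the spotlight variants) plus an ambient term — no
global illumination, no cast shadows, no interreflections. Reflectances
(walkway 0.45, surrounding ground 0.18, wall 0.30) create the stable
border contrast; the step riser shares the walkway material so its
visibility is carried by shading geometry and varies across lighting, as
intended. Absolute luminances are arbitrary (the whole chain is invariant
to luminance scale); only the structural contrast pattern matters.

Defaults: eye height 5 ft, image 512×512 at 20 ppd (25.6° field of view),
camera pitched −20° so a floor-level target 10 ft ahead is framed.
Viewpoints: pivot-left/right orbit the eye ±15° about the vertical axis
through the target (re-aimed at the step — pure camera yaw would push the
22.6°-wide step out of the 25.6° field); rotate-down/up change pitch ±5°.
Note the riser's projected height follows its oblique subtense from the
eye (≈2.7° for the 7-inch riser seen from 5 ft up, ≈55 px at 20 ppd), not
the frontal approximation (3.3°): scene checks compare against the oblique
projection.

Ground-truth geometric edges are extracted from the per-pixel surface-id
and depth maps (marking the nearer side of every id transition), so they
are exactly light-independent and handle occlusion (e.g. a step-down riser
is invisible and contributes no edge). ROI masks derive from the projected
step footprint: `whole-step` dilates the step discontinuity (for the flat
target, the projected line where the step would be — every trial of the
design therefore has a scoreable region containing at least the border
crossings); `corners` is the outer 15% of the step width per side;
`central-edge` the rest; `walkway` dilates all geometry edges. The
dilation radius is angular (0.2°).

## Visibility scoring

Distances are the exact Euclidean distance transform of the boundary map
sampled at geometry pixels (+∞ when no boundary exists). The
distance-to-score kernel is linear: score = max(0, 1 − d/d_max), with
d_max = 0.5° of visual angle converted to pixels, so scores do not depend
on image resolution. The published form of this mapping is not available;
the linear kernel with angular falloff is this package's documented
stand-in, and both kernel and d_max are configurable so a different
mapping can be dropped in. A Gaussian kernel is provided. The HVS of an
ROI is the mean score over geometry∩ROI; an empty intersection raises an
explicit error rather than returning a silent 0.

## Simulated observers and statistics

A simulated observer answers correctly with probability
g + (1−g)·logistic(A·X + B), X the trial's HVS, g the guessing floor
(chance in a five-alternative choice, 0.2). Group defaults mirror the two
blur conditions of the validation experiments: moderate VA 1.2 (SD 0.085),
CS 0.68; severe VA 1.62 (SD 0.028), CS inferred from acuity; generating
slopes 3.02 and 1.54 (the reported group fits). The intercepts are not
reported anywhere; B = −1.5 (moderate) and −2.0 (severe) were chosen once
so that simulated accuracy spans roughly 0.35 → 0.86 (moderate) and
0.30 → 0.50 (severe) over the HVS range, matching the qualitative
accuracy ranges described for those groups.

Fitting is plain maximum-likelihood logistic regression (statsmodels GLM,
binomial/logit): ln(P/(1−P)) = A·X + B, with deviances against the
saturated model, the reduced deviance ratio (D0 − Dr)/D0, Wald 95% CIs,
and a chi-square likelihood-ratio test against the intercept-only null.
The guessing floor exists only in the simulator, not in the fitted model,
matching the validation analyses this mirrors. Pooled-group fits are
fixed-effect only; the original aggregated analyses used a random-effects
model whose structure is unstated, so pooled fixed-effect fits are the
default and per-subject fits carry the individual-level statistics.
Separation is flagged (|A| > 10³ or exploding standard errors) rather than
silently diverging.

The Chow coefficient-equality test between two groups runs, by default, on
linear-probability (OLS) fits of correctness on HVS — the textbook RSS
formulation with k = 2 and df (2, n1+n2−4). A variant on squared Pearson
residuals of the logistic fits is included for comparison but is nearly
powerless (Pearson residuals are standardized by each model's own fitted
variance, so pooled-model misfit barely inflates their sum of squares);
at the reported group slope pair (3.02 vs 1.54, n = 1750 each) the LPM
form rejects at α = 0.001 essentially always, the Pearson form almost
never.

Trial binning uses ten half-open bins [0,0.1), …, [0.9,1.0] with the last
bin closed.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the stimulus family (geometry,
factorial design, lighting-dependent edge contrast, viewpoint variation)
but not its photometry: no global illumination, no material texture, no
calibrated luminances. Passing tests therefore demonstrate that the
scoring chain behaves correctly and that the statistics recover known
generating parameters — they do not certify agreement with human
psychophysics on real renders. The simulated observer responds through
the same logistic law later fitted to it (plus a guessing floor the fit
omits), so parameter-recovery results are internal-consistency checks,
not external validation.

## Numerical choices and problem sizes

* Luminance floor for contrast denominators: 10⁻⁶ cd/m²; filter output
  clamped at 0 cd/m².
* Band bank: top center at half Nyquist, down to ~4 cycles/image; centers
  outside that range raise configuration errors.
* Distance sentinel: +∞ maps to score 0.
* Degenerate inputs: constant images yield empty edge maps (not errors);
  constant predictors, single-class outcomes and empty ROIs raise typed
  errors.
* Tests run scenes at 128 px/5 ppd and 256 px/10 ppd (same 25.6° field of
  view as the 512 px/20 ppd default) — at coarser grids single-pixel edge
  shifts move the HVS by several percent, which is why the
  vision-loss-monotonicity sweep runs at the full default resolution.
* Simulation sizes follow the design they mirror: 250 trials per subject,
  1750 per pooled group; calibration checks use 2000 null replicates of
  250 trials.

## Known limitations

* Visual-field loss, glare, diagnosis-specific factors and temporal
  presentation effects are outside the model, as is any color processing.
* The distance-to-score kernel is a stand-in (see above).
* Strict per-scene monotonicity of HVS under worsening vision is an
  empirical property of the default configuration at full resolution, not
  a theorem: blur can shift a detected edge *toward* the geometry, and at
  coarse resolutions (≤384 px) isolated scenes show the moderate-blur
  score marginally above the normal-vision score.
* The Chow test on binary outcomes is itself unusual; both implemented
  formulations are documented and neither claims exact finite-sample F
  distribution under heteroscedastic binary noise.
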