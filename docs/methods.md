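# Methods

## Signal model

GFP-aequorin bioluminescence yields no excitation-based ΔF/F; the
measured quantity is the photon count rate inside a region of interest.
The acquisition model is a point process on the sensor: each photon is a
triple (x, y, t) with integer pixel coordinates and a continuous time
stamp, collected at 120 frames s⁻¹ (8.3 ms frame period). All analysis
operates on 1-s integrations ("1 Hz") of the photons inside hand-drawn
ROI polygons; no pixel binning is applied.

Time bins are half-open, `[k·w, (k+1)·w)`, so a photon is never counted
twice; ROI membership is boundary-inclusive (any consistent rule works
for hand-drawn polygons, and inclusivity makes rectangular test fixtures
exact). Overlapping ROIs are allowed and each keeps its own photon
total, matching per-ROI reporting.

## Evoked-response detection

Within one fly × ROI series, the evoked-response epoch runs from the
stimulant application to the KCl control application. The series is
normalized by its maximum rate inside that epoch (the "response peak"),
so the terminal KCl surge can never set the peak. The detection rules on
the normalized signal are:

- **onset** — first bin of a run at/above the threshold (default 0.10 of
  peak) starting at or after the stimulant time, where the run must last
  at least the sustain time (default 2 s = 2 bins at 1 Hz);
- **offset** — first bin after onset falling back below the threshold;
  if the signal never re-crosses before the epoch end the offset is
  clamped there and the window flagged `truncated`;
- **multiple runs** — the run containing the epoch peak is reported
  (features are anchored on the response peak); the earliest-run
  alternative is available via `prefer_peak_run=False`;
- **peak ties** — the earliest bin attaining the maximum wins.

No baseline subtraction is applied by default: the photon-counting
background is near zero relative to evoked peaks, and the 10 % rule is
defined on the raw normalized rate. An optional subtraction mode exists
(`subtract_baseline`) for recordings with appreciable background.

**Degenerate-signal guard.** When a series contains no real response,
its epoch maximum is just the largest baseline fluctuation and the
normalized baseline sits near 1, so a threshold-on-normalized-signal
rule would trivially "detect" noise. `detect_response` therefore warns
when more than half of the pre-stimulus bins already exceed the
threshold, and can reject such series outright (`reject_degenerate`).
The pipeline's detection stage enables rejection by default; the
low-level function defaults to warn-only. This guard is what keeps the
false-positive rate on response-free synthetic recordings below a few
percent.

Features are computed from **raw** counts: latency = onset − stimulant
time; duration = offset − onset; total photons = Σ counts over
[onset, offset); peak rate and peak time from the window maximum.
Average profiles align each series on its own peak over ±100 s (201
one-second offsets) and average per offset over the series that have
data there.

## Mixed-effects model suite

The response Y_ij is modelled per 1-s bin within the evoked window
(rows = fly × ROI × bin) with predictors ROI (factor, 5 or 3 levels),
condition (factor: with/without dopamine) and time within the window
(continuous), plus a random per-fly intercept. Six fixed-effect
structures are compared (interaction; interaction + time; ROI only;
additive; three-way; condition only). A secondary response mode models
per-fly × ROI latency summaries, which have no within-window time axis,
so the suite drops to the four time-free models there.

Choices that matter:

- **ML, not REML** — the structures differ in their fixed effects, and
  REML likelihoods are not comparable across fixed-effect structures.
- **BIC** = −2·logLik + df·ln(n) with n = number of rows and
  df = fixed-effect columns + 2 variance components (random-intercept
  and residual variance). This convention reproduces lme4's `BIC()`
  exactly, which the test suite verifies against `lmer(..., REML=FALSE)`
  through Rscript.
- **Bayes factor** — BF = e^(ΔBIC/2) with ΔBIC = BIC(other) − BIC(best);
  overflow is reported as `inf` with the log-scale value available.
  Ranking ties are broken toward smaller df.
- **Coding** — treatment coding with the EB as the ROI reference and
  the no-dopamine condition as the condition reference; post hoc
  results are expressed as condition differences within each ROI
  (estimated-marginal-mean differences, holding time at its sample
  mean), so the coding is not user-visible.
- **Bonferroni family** — the set of condition-within-ROI contrasts
  actually computed (m = number of ROI levels); adjusted
  p = min(m·p, 1).
- **Parametric bootstrap** — simulate Y* = Xβ̂ + Zu* + ε* with
  u* ~ N(0, σ̂²_fly), ε* ~ N(0, σ̂²_res), refit, keep the central
  percentile interval. The 97.5 % level is interpreted literally as
  2.5 % total tail mass (1.25 % per tail) and is configurable; the
  default replicate count is 10 000, reducible for interactive runs.
  Replicates whose refit fails are dropped and counted.

Fitting is delegated to `statsmodels` MixedLM behind the module surface;
design matrices are materialized with `patsy`, which is also how
`count_parameters` obtains exact fixed-effect column counts (12, 13, 7,
8, 22, 4 for the 5×2+time suite) without fitting anything.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- **protocol** — 600 s baseline, stimulant application, 600 s evoked
  recording, KCl 600 s after the stimulant, plus 60 s post-KCl; with
  dopamine, the application precedes the stimulant by exactly 600 s
  (enforced by the protocol type). Shorter epochs are available for
  small runs.
- **rate model** — per ROI,
  r(t) = baseline + f·A·K(t−onset)/K_max + A_KCl·K_KCl(t−t_KCl)/K_max,
  with the double-exponential kernel
  K(t) = (1 − e^(−t/τ_rise))·e^(−t/τ_decay) (defaults τ_rise = 5 s,
  τ_decay = 40 s; KCl: 2 s / 15 s). The kernel peaks at
  τ_rise·ln(1 + τ_decay/τ_rise) and is normalized so A is the evoked
  *peak* rate. No kinetic model is claimed for the real reporter; this
  is the simplest rise-and-decay shape consistent with observed profile
  shapes, and all tests treat it as generative truth only.
- **fly heterogeneity** — a log-normal multiplier f = e^(N(0, σ_fly)),
  σ_fly = 0.3, on every evoked amplitude of a fly: the generative
  counterpart of the random fly intercept.
- **event sampling** — exact inhomogeneous-Poisson thinning with
  per-1-s-bin rate bounds computed from the kernel's unimodality;
  events are placed uniformly inside the emitting ROI polygon
  (bounding-box rejection) and floored to integer pixels. A sensor-wide
  uniform background (default 2 photons s⁻¹) and single-frame cosmic-ray
  bursts (default 0.5 min⁻¹, 200 photons at one pixel, snapped to the
  frame grid so a burst can never straddle a 1-s bin edge) complete the
  stream.
- **magnitudes** — baseline ≈ 50 photons s⁻¹ and evoked EB peaks ≈ 2000
  photons s⁻¹ (others a few hundred). True in vivo rates are not
  tabulated anywhere; "thousands of photons per second" for strong
  responses is the only magnitude cue, so these defaults are explicit
  assumptions.
- **presets** — R2 (nicotine; dopamine raises the EB peak 2000→3000 and
  shortens EB latency by 5 s), R5 (picrotoxin; dopamine lowers
  2000→1200 and lengthens latency by 10 s), EPG (EB-only 1500→2250),
  and RNAi variants that neutralize (Dop1R1) or invert (Dop1R2) the
  dopamine effect. Cohort arms share every parameter except the
  condition-keyed maps; per-fly seeds are `seed + fly_index`.

What the generator does **not** emulate: aequorin consumption/photo-
chemistry, optics and PSF, spatial structure within an ROI (no
heading-bump), slow drift, or correlated noise. Passing recovery tests
therefore demonstrate correctness of the analysis chain under the
assumed point-process model, not performance on real recordings.

## Problem sizes in the test suite

Tests run on reduced problem sizes chosen so relative effect sizes (and
hence every recovery property) are preserved: photon rates scaled to
10 % of defaults, epochs shortened (60–120 s baseline, 120–180 s evoked
window), 12–15 flies per arm and 50 seeds for the recovery studies,
bootstrap replicates reduced to 200 for calibration checks (100
replicate datasets). Model-structure recovery cohorts are drawn from the
cell-means + random-intercept model itself, since that is the setting in
which the interaction model is the true one; the photon-level generator
has a genuine within-window time course, so on its output the
time-bearing specifications legitimately win the BIC comparison.

## Known limitations

- Onset resolution is 1 s (the integration width); no sub-second
  latency estimation and no Ca²⁺-kinetics deconvolution.
- The detector reports a single response window; multiple discrete
  bouts are not merged (the run containing the peak is reported).
- The LME suite assumes iid Gaussian residuals within fly; photon shot
  noise is Poisson, which is acceptable at the default rates (counts of
  tens to thousands per bin) but the homoscedasticity assumption is
  knowingly approximate, as in the original analysis.
- `bootstrap_ci` refits with the same optimizer as the original fit;
  on near-boundary variance estimates individual replicates may sit at
  zero fly variance, which is correct behaviour for a percentile
  interval but widens it slightly.
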