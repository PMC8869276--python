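# Methods

## Experimental structure assumed

A recording is a thermal video of a seated subject at a fixed frame rate
(default 10 Hz), divided into contiguous phases: an acclimation **baseline**
(default 300 s), three exercise **sets** performed to exhaustion separated by
**rests** (default 180 s), and a final **recovery** (default 300 s). Four
rectangular ROIs are analysed: Exercised Leg, Nonexercised Leg, Nose Tip and
Corrugator. One perceived-exertion rating (RPE, integer 1–10) is recorded per
set; by default the final-set value represents the subject (configurable to
mean or max), since a single rating per subject enters the correlation
analysis.

All analysis windows are anchored to the timeline:

| window | extent | purpose |
|---|---|---|
| `dt_baseline` | [t_rep1 − 20 s, t_rep1 − 10 s] | pre-exercise 10-s mean |
| `dt_final` | [t_end − 10 s, t_end] | end-of-recovery 10-s mean |
| `psd_pre` | [t_rep1 − 300 s, t_rep1] | baseline spectral window |
| `psd_post` | [t_end − 300 s, t_end] | recovery spectral window |

The spectral windows must lie wholly inside their anchoring phase: a 5-min
spectral window requires a ≥ 5-min baseline/recovery, otherwise exercise
motion artefacts would contaminate a resting-state estimate. Subjects whose
timelines violate this are excluded with a logged reason, never silently;
if the shared timeline itself is infeasible the pipeline aborts at the
features stage.

## ROI tracking

Frame-to-frame normalised cross-correlation (NCC) template matching: the
template is the ROI pixel content, searched within ±10 px (configurable) of
the previous position; the template is refreshed from the tracked position
every 50 frames so slow radiometric change (the skin warming/cooling) does
not starve the correlation. Matching operates on whole pixels and is fully
deterministic — adequate because the seated subject produces rigid, slow ROI
motion. Frames whose best NCC score falls below 0.5, including degenerate
featureless frames where NCC is undefined, hold the previous position and
are flagged; flags propagate into the run manifest. Trace extraction is the
arithmetic mean of all pixels in the rectangular box (no mask shape),
0-based coordinates, x indexing columns.

On synthetic scenes with a Gaussian-edged patch, NETD-scale pixel noise and
a 5-px drift across 600 frames, the recovered path matches the ground-truth
path with RMSE ≤ 1 px (measured 0 px), and a static scene yields exactly
zero displacement.

## Spectral estimation and band powers

The PSD of each 300-s window (3000 samples at 10 Hz; exact length enforced,
no silent padding) is a Welch average of Hann-tapered 150-s segments at 50%
overlap, each segment linearly detrended. One deliberate departure from
textbook Welch: each segment's periodogram is **rescaled so its integral
over [0, fs/2] equals that segment's detrended sample variance**. The
conventional taper-power normalisation preserves variance only in
expectation; for deterministic tones the estimate can exceed the signal's
variance by several percent depending on phase alignment with the taper.
The exact per-segment normalisation makes Parseval hold by construction, so
band powers can never exceed the variance budget of the analysed signal,
while leaving the spectral shape and all relative band comparisons
untouched. All estimator settings are recorded in every estimate.

Band powers are trapezoidal integrals of the density over each band, with
linear interpolation at band edges between grid points — making the
integral exactly additive over any partition of a band. ΔPSD is the raw
post-minus-pre difference of band areas (°C²); a constant offset changes no
band power (detrending removes DC), and swapping the two epochs exactly
flips every ΔPSD sign.

**Resolution limit.** With 150-s segments the grid spacing is ≈ 0.0067 Hz,
above the metabolic band's 0.003 Hz lower edge (one full cycle at 0.003 Hz
lasts ~333 s, longer than the whole window). The metabolic band is
therefore integrated from the first nonzero grid point and every output
carries a `resolution_limited:metabolic` flag; metabolic band powers should
be interpreted as [0.0067, 0.02] Hz areas. For the same reason, the
Parseval verification uses multi-tone signals whose tones sit on the
analysis grid (bins ≥ 4, neurogenic–cardiac) plus a slow linear drift: for
grid-aligned tones the closed-form expectations (A²/2 per tone) are exact
and the variance bound is a theorem rather than an approximation.

## Statistics

Per feature (ΔT and five ΔPSD bands), the omnibus test across the four ROIs
is the classical within-subject decomposition
`F = MS_conditions / MS_error` with subject blocking. Sphericity is not
assumed: degrees of freedom are multiplied by the Greenhouse–Geisser ε
estimated from the sample covariance of condition scores (bounded in
[1/(k−1), 1]; Huynh–Feldt available by option; uncorrected results are also
retained in the report). The implementation is cross-checked in the test
suite against an independent brute-force oracle (explicit sums of squares;
ε from the eigenvalues of the double-centred covariance) to 1e-8 and
against pingouin.

GG correction is conservative at this design size: under a true null with
exchangeable ROIs (n = 8, k = 4) the measured rejection rate at α = 0.05 is
≈ 0.030–0.035 (4000 simulated cohorts). The calibration study runs at
feature level — the statistics layer is the unit under test there; the
trace-to-feature chain is validated by its own closed-form checks.

Post hoc comparisons follow the common software reading of Fisher LSD for
repeated measures: all 6 pairwise paired t-tests, two-sided, unadjusted,
each with its own pair error term (recorded in the report so the pooled
alternative is auditable). Normality failures are logged warnings, not
automatic switches to nonparametric tests. Feature–RPE association is
Pearson's r with the two-sided p from the t transform on n − 2 d.f.; the
24-cell feature × ROI matrix is reported without multiplicity adjustment
and the report footnotes this. Degenerate cells (zero variance) are flagged
NaN rather than errors.

## Synthetic-data generator

The generator is statistical, not biophysical: it emulates the *shape* of
such recordings, not thermoregulation. Each ROI trace is

  trend(t) + Σ oscillators + N(0, noise_sd²),  clamped to [20, 45] °C

* **Trend**: continuous piecewise-linear, one slope per phase label. The
  injected ΔT is spread over the exercise sets, so the baseline and
  recovery windows sit on plateaus and the injected value is recovered
  exactly by the window logic.
* **Oscillators**: band-limited sinusoids, independently specifiable for
  the baseline and recovery epochs, so per-band ΔPSD ground truth
  (A_post² − A_pre²)/2 is directly injectable. Default frequency is the
  band's geometric centre, away from edges, minimising leakage ambiguity.
* **Noise**: i.i.d. Gaussian, SD 0.03 °C — the camera's noise-equivalent
  temperature difference (< 30 mK). No spatial or temporal correlation is
  modelled.
* **Frames**: ROI patches (uniform or Gaussian-edged) over an ambient
  background, pixel weights normalised so the in-box mean equals the
  driving trace exactly before pixel noise; integer-pixel motion paths
  (linear drift, sinusoidal sway) with the ground-truth path returned for
  tracker validation.
* **RPE**: a noisy linear readout of chosen true features, rounded and
  clamped to 1–10. A target correlation ρ maps to slope ρ·σ_RPE/σ_feature
  and residual SD σ_RPE·√(1−ρ²); with σ_RPE = 1.5 the rounding attenuates
  an injected ρ = 0.8 to ≈ 0.79 empirically.

The default `study_default` scenario: 8 subjects; exercised leg warms
(+1.5 ± 0.5 °C) and gains myogenic power (0.03 → 0.10 °C amplitude); nose
tip warms mildly; both facial ROIs gain neurogenic and lose myogenic power;
the contralateral leg and corrugator cool slightly; RPE is coupled at
ρ = −0.8 to the exercised leg's ΔT. Passing tests on this scenario
demonstrates that the chain recovers what was injected — it says nothing
about real physiology, inter-subject variability structure, emissivity or
motion artefacts of real recordings.

## Pipeline and reproducibility

A single YAML config drives simulate → features → stats; CLI flags override
config values. Synthetic mode requires a seed and is bit-deterministic:
identical config + seed reproduce byte-identical traces, feature tables and
reports (verified by checksum). The manifest records the config hash,
per-output SHA-256 checksums and every warning (excluded subjects,
resolution-limited bands, low-confidence tracking frames). The synthetic
pipeline operates at trace level; frame rendering and tracking are exercised
by the `extract` stage on stacks (real or simulated) and by their dedicated
tests — rendering full-length 640×480 cohorts would add runtime, not
information.

Config validation returns *all* schema violations with JSON-path locators
rather than failing on the first.

## Known limitations

* The metabolic band is resolution-limited (above); its ΔPSD is reported
  but flagged.
* NCC tracking assumes rigid, slow motion and whole-pixel displacements;
  deformable or fast motion would need a different tracker.
* The generator's between-subject variation is Gaussian and independent
  across parameters; real cohorts are neither.
* Correlations at n = 8 are extremely noisy (sampling SD of r ≈ 0.2–0.35);
  single-cohort correlation values in the demo report should be read
  accordingly.
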