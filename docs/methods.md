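# Methods

## Signal model and preprocessing

A VOT recording couples uniformly sampled channel streams — NIRS
chromophores O₂Hb/HHb at 50 Hz, a DCS blood-flow index (BFI) at ~38.5 Hz —
with cuff annotations (inflation, release, optional pre-occlusion light
contraction). The physiological dynamics of interest live well below
0.2 Hz; the cardiac pulse rides on every optical channel at 1–2 Hz.

**Low-pass filter.** Every channel is filtered with a Kaiser-window FIR
designed per sampling rate for a 1.0 → 1.3 Hz transition band and ≥ 60 dB
stopband attenuation (designed with a 6 dB margin; ~675 taps at 50 Hz). The
odd-length symmetric taps are normalized to unit sum (DC gain exactly 1)
and applied by centred convolution, which is exactly zero-phase — feature
*times* are meaningful only if filtering adds no lag. Edges are handled by
reflecting one filter length of signal at each end; streams shorter than
one filter length are rejected. Missing samples are linearly interpolated
before filtering and re-masked afterwards, so gaps do not spread.

The measured contract (also recomputed by `scripts/acceptance.py`): DC gain
1 within 10⁻³, ≥ 74 dB attenuation at 1.4 Hz, zero peak shift on a slow
Gaussian bump.

**DCS averaging.** BFI is additionally bin-averaged into non-overlapping
1-s bins aligned to the stream start (bin centres become the timestamps),
because DCS shot-to-shot noise is far larger than NIRS noise. Bins average
their non-missing samples; fully missing bins stay missing.

**TSI.** The tissue saturation index is computed sample-wise as
100·O₂Hb/(O₂Hb+HHb) from the *filtered* chromophores (configurable to
pre-filter computation via `tsi_stage`). Samples with non-positive total
hemoglobin are marked missing. Because TSI is a ratio, it is invariant to
a common rescaling of both chromophores.

## Phase segmentation and feature extraction

With inflation at t_i and release at t_r: OC = [t_i, t_r],
HY = [t_r, t_r + 180 s], and BA is a 60-s window that ends 15 s before t_i
when a pre-occlusion light contraction is annotated (so its transient stays
out of the baseline) and at t_i otherwise; both the guard and the window
lengths are configurable.

Baselines are arithmetic means over BA (failing if > 20% of the window is
missing). Delta streams subtract the baseline mean; rBF = 100·BFI/BA-BFI
(failing on non-positive baseline flow).

* **Slopes** are ordinary-least-squares fits of value against time over
  closed windows: the first 20 s of occlusion and the first 10 s after
  release for NIRS deltas; release-to-peak for rBF. At least 5 samples are
  required (3 for the 1 Hz rBF window).
* **Extrema** are extremal *samples* over the full phase window, ties
  broken to the earliest occurrence; times are reported relative to t_r, so
  occlusion times are ≤ 0 and hyperemic times ≥ 0.
* **rBF floor** is the mean of the last 10 s of occlusion (not an extremal
  sample — a mean is the robust choice on the noisiest channel).
* **HTR** (half-time to recovery): with v₀ the first non-missing sample
  at/after release and h = peak − v₀ the hyperemic height, HTR is the first
  crossing of v₀ + h/2 moving toward the peak (a downward crossing for
  HHb), linearly interpolated between the bracketing samples; by
  construction HTR ≤ time-to-peak. A height indistinguishable from zero
  (relative 10⁻⁹) means there was no hyperemic response: the HTR is
  recorded missing and the subject flagged, never dropped silently.

NIRS features are extracted on the native 50 Hz streams; all rBF features
on the 1 Hz stream. A recording lacking the NIRS pair or the BFI stream
yields the corresponding features as missing values with a finding.

The feature set has 30 entries (4 baseline, 10 occlusion, 16 hyperemia).

## Statistics

Planned comparisons are controlled per variable family: OC NIRS (9
variables), HY NIRS (12), HY DCS (4). Each family gets a two-sample
Hotelling's T²; with pooled covariance S,

T² = (n₁n₂/(n₁+n₂)) (x̄₁−x̄₂)ᵀ S⁻¹ (x̄₁−x̄₂),
F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2)) on (p, n₁+n₂−p−1) df,
partial η² = T²/(T²+n₁+n₂−2).

For p = 1 this reduces exactly to the squared pooled t (verified to 10⁻¹⁰
relative). The single OC DCS variable (rBF floor) gets a lone Student's t.
Pairwise comparisons within each family use pooled-variance t-tests with
Bonferroni correction at the family size m (9/12/4); baselines are reported
uncorrected since they are descriptive rather than planned hypothesis
tests. Right-skewed magnitudes (rBF floor, rBF peak, ∆TSI peak, rBF slope)
are log-transformed before testing, and Cohen's d is computed on the tested
(transformed) scale; the rBF half-time resists transformation and falls to
the Mann–Whitney U test (exact when n₁+n₂ ≤ 20 and tie-free, normal
approximation otherwise), which carries no d. When a log transform is
undefined on a particular data set (non-positive values occur in synthetic
cohorts), the analysis falls back to the rank test and records it. Missing
features are dropped per-variable in pairwise tests and listwise within a
family for T².

## Synthetic ground truth

The generator builds recordings whose controlled parameters *are* the true
feature values, so extraction can be tested by round trip:

* **Baseline**: constant level + cardiac sinusoid (default 1.2 Hz, 1 µM on
  O₂Hb, half on HHb, 10% multiplicative on BFI) + white noise, plus an
  optional 5-s contraction transient just before inflation (it sits inside
  the baseline guard, so no feature sees it). The pulsatility envelope
  vanishes during occlusion (no flow, no pulse) and returns early in
  hyperemia through 8-s raised-cosine ramps — sharp amplitude gating of a
  1.2 Hz carrier would put modulation sidebands below the filter passband
  edge and leak into the physiology.
* **Occlusion chromophores**: an exact linear segment at the prescribed
  20-s slope, then an exponential, slope-continuous drift toward a shoulder
  one nadir-depth short of the prescribed extremum, and a raised-cosine
  nadir (zenith for HHb, half-width 4 s, depth 5% of the channel's dynamic
  range) centred on the prescribed time-to-extremum. This realizes the
  drawn slope, extremum value and extremum time simultaneously — a single
  ramp-and-plateau cannot, since slope × duration would fix the extremum —
  while keeping the extremum identifiable under noise.
* **Occlusion BFI** decays exponentially (4-s constant) to the prescribed
  floor, so the last-10-s mean equals the floor exactly.
* **Hyperemia**: a saturating-exponential rise
  r(t) = (1−e^(−t/τ))/(1−e^(−t_peak/τ)) from the release value to the
  prescribed peak at the prescribed time, with τ solved (bracketed root,
  10⁻⁶ s tolerance) so the half-height crossing lands exactly at the
  prescribed HTR; HTR → t_peak/2 degenerates to the linear rise (τ → ∞),
  returned with a flag. After the peak, exponential relaxation toward
  baseline with a fixed 60-s constant (not a measured quantity). The BFI
  upstroke starts one second after release — the arterial transit latency
  of reperfusion — which also keeps the zero-phase filter from smearing the
  enormous (~8-fold) flow overshoot backward into the pre-release floor
  window.
* **TSI and the hyperemic slopes are emergent**, not drawn: TSI is a ratio
  of the generated chromophores, and the 10-s/release-to-peak slopes are
  fixed by the rise geometry. Their ground truth is measured on the clean
  noise-free trace (the rBF slope on the clean 1 Hz stream, whose peak bin
  is the analysis-level truth). Round-trip tests for these features
  therefore check the pipeline's filtering and windowing, not the
  generator's arithmetic.

Cohorts draw each subject's controlled parameters as independent truncated
normals from per-group (mean, SD) tables, defaulting to the observed
climber (n=17) and non-climber (n=15) summaries; draws are resampled until
mutually consistent (e.g. extremum beyond the 20-s ramp, HTR below half the
time-to-peak). Truncation shifts the realized means of heavily clipped
parameters (occlusion times, rBF HTR) away from the table values; recovery
tests always compare against the realized per-subject truth, not the table.
Cross-feature correlations are unknown (only marginals are published), so
independent draws are a documented simplification; real traces also carry
motion artifacts, probe-coupling drifts and 1/f physiological noise that
the generator does not emulate, so passing recovery tests demonstrate
correctness of the *algorithms*, not robustness to every field artifact.

## Tolerances and measured behaviour

Noise-free round trip (both group parameter sets): slopes and extremal
values recover within 1%, times and half-times within 1 s — one sample of
the 1 Hz analysis base. Sub-sample agreement at 50 Hz is not a meaningful
target after low-pass filtering: any 1 Hz smoothing shifts the argmax of an
asymmetric peak by O(0.1 s).

Under the realistic-noise conditions (white noise at 5% of each channel's
dynamic range, 1.2 Hz cardiac), cohort-level bias over 50 cohorts stays
below 5% of the generator mean for 29 of 30 features (median ~0.4%). The
exception is the hyperemic HHb minimum (~8%): its published kinetics
(HTR 7.1 s ≪ time-to-minimum 32 s) force the rise to flatten ~10 s before
the minimum, and the post-minimum relaxation is equally flat, so the
extremal-sample estimator systematically picks the deepest noise excursion
over a very broad valley (≈1.9 residual-noise SDs). This is a property of
extremal-sample peak picking on band-limited noisy data — the same bias is
embedded in any measured table of such values — and is reported honestly
rather than patched by redefining the estimator.

## Known limitations

* Absolute BFI is not fitted from autocorrelation curves; BFI is consumed
  as provided and only relative blood flow is analysed.
* Cuff events come from annotations; no automatic release detection.
* No motion-artifact detection or correction.
* The on-disk format is the package's own CSV+JSON layout; vendor-native
  device exports need an import adapter written against the actual files.
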