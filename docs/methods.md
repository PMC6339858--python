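# Methods

This note documents the models, numerical choices and known limitations of
`scalefd`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Curve-length estimator

The estimator down-samples a series `X(1..N)` at stride `k` from each of the
`k` possible offsets `m`, sums absolute increments, and normalizes by
`(N−1)/(n_m·k)` with `n_m = ⌊(N−m)/k⌋` so that every offset's length is
expressed per unit of (original) time, then divides by `k` once more to
convert the stride-`k` length to a curve length at that scale.  Offsets with
`n_m = 0` (possible when `k > N/2`) carry no increments; they are excluded
from the mean over offsets and their count is recorded on the profile.

The dimension is the OLS slope of `log⟨L(k)⟩` against `log(1/k)` over every
integer scale in the fit window (windows here are at most 131 scales wide,
so no logarithmic sub-sampling of large `k` is used).  Natural logarithms;
the slope is base-invariant.  `r²` is always reported and never used as an
automatic rejection rule.  Design rules enforced as typed errors rather than
silent behavior:

* any scale `k ≥ N` — scale-too-large;
* a zero mean length in the fit window (constant segment) — degenerate
  signal; callers that tabulate (e.g. the epoch-length diagnostics) catch
  this and emit a missing-value marker instead;
* fewer than three scales, or a missing integer scale inside the window —
  insufficient scales.  Fits never interpolate missing scales.
* amplitude invariance is exact by construction: `aX + b` changes every
  `L_m(k)` by `|a|`, which moves the intercept only.

## Band-to-scale mapping

`k_min = ⌊fs/f_high⌋` (clamped to the minimum usable scale 2) and
`k_max = ⌊fs/f_low⌋`, floor ("Gauss bracket") semantics.  Windows narrower
than 10 scales produce visibly noisy dimension-vs-`k_min` curves (the
sliding-window diagnostic demonstrates this), so such ranges are flagged
`narrow` rather than rejected; this is why the canonical table uses three
broad bands plus the entire range instead of the usual five-band division.
At 200 Hz the canonical fast window is an explicit override (`3–25` rather
than the generic `3–15`): it shares the alpha window's upper bound so the
beta/gamma fit spans 10+ scales.  The override is marked on the returned
range, and both the generic mapping and explicit `k_min/k_max` overrides are
available in run configurations.

## Epoch preparation and PSD

The canonical preparation takes the leading 60 s of a recording and trims
5 s from each end — the segments contaminated by the acquisition band-pass
filter's edge response — leaving 10,000 samples at 200 Hz for fractal
estimation.  Trim is expressed in seconds so the rule generalizes across
sampling rates.  The companion PSD is computed on the *untrimmed* 60 s
window: one Hanning-windowed FFT (Welch averaging available but off by
default), density scaled by the window power so broadband variance is
conserved (Parseval within 1%), expressed in dB/Hz re 1, floored at 1e-30
before the log.  Re-binning averages density on the linear scale over
half-open 1-Hz bins starting at 5 Hz; the final bin starts at 60 Hz, giving
56 bins and hence the 896-entry (56 × 16 channels) PSD comparison family.
The fractal/PSD epoch asymmetry is deliberate and mirrors the acquisition
protocol the pipeline emulates; it is visible in the run log.

## Group statistics

Fractal dimensions are log-transformed (natural log) before group tests —
their sampling distribution is right-skewed — and the transform is marked on
the table so a double application errors.  Sensor-wise comparisons use the
classical pooled-variance two-sample t (Welch variant by config); positive t
means the first group is larger.  BH-FDR families mirror the analysis
groupings: 16 (entire-band channels), 48 (three band-specific dimensions
pooled over channels), 56 × channels for the PSD grid.  The mixed
repeated-measures ANOVA (group between, channel within) is computed from the
textbook sums-of-squares partition; the group × channel interaction's
degrees of freedom are multiplied by the Greenhouse–Geisser epsilon
`ε = tr(CSC)² / ((b−1)·tr((CSC)²))` with `S` the pooled within-group
covariance of the channel measures and `C` the centering matrix (bounded in
`[1/(b−1), 1]`).  It is implemented in-package because the available mixed
ANOVA routines do not GG-adjust the interaction term; the implementation is
cross-checked against `pingouin.mixed_anova`'s uncorrected F values in the
test suite.  Huynh–Feldt is not implemented.  Covariate (MMSE-like)
correlations are Pearson r per channel, computed within one group on
*untransformed* dimensions.

## Synthetic data

Three generators provide ground truth without any external recordings:

* **fBm** (`gen_fbm`): exact fractional Gaussian noise by circulant
  (Davies–Harte) embedding, cumulatively summed.  Dimension oracle
  `D = 2 − H`.  If the embedding is not positive semidefinite (rare extreme
  cases) negative eigenvalues are clipped — an approximate spectral
  synthesis — and a runtime warning is issued.
* **Weierstrass cosine function** (`gen_weierstrass`): `λ = 5`, term count
  chosen so `λ^M ≥ n`, optional seeded random phases; analytic graph
  dimension equals the target parameter.
* **Cohorts** (`gen_cohort`): two groups of multichannel recordings
  (defaults: 18 vs 16 subjects, 16 standard 10-20 channels, 200 Hz, 60 s).
  Each channel is Gaussian noise with a piecewise power-law spectrum: within
  each segment the density falls as `f^−(2H+1)` (the fBm spectral law), so a
  band's Hurst exponent sets the signal's roughness at that band's temporal
  scales.  Segment *placement* was calibrated against the estimator: a scale
  window `[k_min, k_max]` responds to spectral content roughly a factor 2–5
  below the nominal `fs/k` band, so the slow segment occupies 0–1.2 Hz, the
  alpha segment 1.2–4 Hz and the fast segment 4 Hz–Nyquist, each with its
  variance over the window's sensitivity core pinned to a common `1/f^1.7`
  reference law (tilting one band then leaves the power seen by the other
  windows unchanged).  A 3% 1/f background is mixed in.  Per-subject Hurst
  exponents are drawn around group means (between-subject SD 0.02 / 0.03 /
  0.08 for slow / alpha / fast; per-channel jitter 0.01); the second group's
  *fast* exponent is offset by +0.2 (raising H lowers D — reduced fast-scale
  complexity), and an integer 0–30 covariate is drawn jointly with the
  fast-band Hurst so that its correlation with fast-scale dimension is the
  design coupling (default 0.6) before discretization.

What the generator does and does not emulate.  It reproduces: realistic
`1/f`-type spectra and dimension values near 1.7; a group complexity loss
expressed at fast temporal scales (detectable by the fast window, invisible
to the alpha window); covariate coupling to fast-scale fractality; and the
group/channel covariance structure the statistics assume.  It does **not**
produce oscillatory alpha peaks, artifacts (EOG/EMG), non-Gaussian
waveforms, or physiologically detailed dynamics — passing tests demonstrate
correctness of the estimator and calibration of the statistics, not
clinical validity.  Two further limitations are intrinsic and documented
rather than hidden: (i) the analysis windows overlap in their spectral
sensitivity (the fast window contains the alpha window by design), so the
generator's slow- and alpha-band dials influence the measured dimensions
only weakly and partly across windows; large slow-band offsets are
therefore not part of the default design, and the default group difference
is carried by the fast dial (which also lowers the entire-range dimension).
(ii) Spectral shaping exists only inside the generator — the analysis path
never filters, since filtering before curve-length estimation perturbs the
scale profile it measures.

## Simulation studies (`scalefd.calibration`)

Three protocols quantify operating characteristics end to end: fBm
dimension recovery (mean over 20 seeds within 0.05 of `2 − H` for
H ∈ {0.3, 0.5, 0.7}, N = 10,000, window [3, 133]); the per-family
false-positive rate of the t + BH battery on 200 null cohorts (≤ the
nominal q = 0.05); and fast-band effect detection on 50 offset cohorts
(≥ 80%).  Repeated-cohort studies run on 30 s epochs rather than the
canonical 50 s to keep the suite affordable; 30 s is also the shortest
epoch these studies use, because at materially shorter epochs the dimension
estimates' error distribution grows heavy tails that visibly distort the
t-test calibration (the estimator remains unbiased; only the group-level
error rates suffer).  All studies are seeded and deterministic.

## Numerical notes

* Curve lengths are computed per scale with a single vectorized
  pad-and-reshape pass over the increment sequence; equality with a literal
  nested-loop transcription is asserted to 1e-10 relative tolerance.
* The circulant embedding draws Hermitian-symmetrized complex normals so
  the synthesized covariance is exact, and the generator consumes a fixed
  number of variates per call for reproducibility.
* Recordings are exchanged as delimited matrices (header row of channel
  labels, one sample per row) written at 10 significant digits; EDF files
  are read through `mne` with non-EEG channels dropped by label pattern.
  EDF export is not provided.
* Pipeline runs are deterministic given inputs and configuration; the run
  log records package/library versions, the resolved band table, exclusion
  accounting (subjects in = analyzed + excluded) and input checksums.
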