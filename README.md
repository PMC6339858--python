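# scalefd

Temporal-scale-specific Higuchi fractal dimension analysis for multichannel
neurophysiological time series.

## The problem

The complexity of resting-state EEG is a candidate marker of
neurodegeneration: cortical signals in dementia are reproducibly *less*
irregular than in healthy ageing.  A single fractal dimension collapses that
irregularity across all time scales, discarding exactly the information —
*which* scales lose complexity — that distinguishes physiological processes
(slow coupling-driven rhythms vs. fast local dynamics).  The obvious repair,
band-pass filtering before fractal estimation, distorts the increment
structure the estimator measures and can erase real group differences.

`scalefd` implements the alternative: estimate the curve-length power law of
the **raw broadband signal**, but fit its exponent only over the window of
temporal scales that corresponds to a physiological frequency band.  No
filtering touches the analysis path.

## The estimator

For a series `X(1..N)` sampled at `fs`, scale `k` and offset `m ∈ 1..k`, the
normalized curve length is

```
L_m(k) = (1/k) · [ Σ_{i=1}^{n_m} |X(m+ik) − X(m+(i−1)k)| ] · (N−1)/(n_m·k),
n_m = ⌊(N−m)/k⌋
```

and `⟨L(k)⟩` is the mean over offsets.  A fractal signal obeys
`⟨L(k)⟩ ∝ k^(−D)`; `D` is the slope of the ordinary least-squares line
through `(log 1/k, log⟨L(k)⟩)`, with `D = 2 − H` for fractional Brownian
motion of Hurst exponent `H`.

A band `[f_low, f_high]` maps to the scale window
`k_min = ⌊fs/f_high⌋`, `k_max = ⌊fs/f_low⌋`.  At 200 Hz the canonical
four-window table is

| band   | frequencies  | k window |
|--------|--------------|----------|
| entire | 1.5–60 Hz    | 3–133    |
| slow   | 2–8 Hz       | 25–100   |
| alpha  | 8–13 Hz      | 15–25    |
| fast   | 13–60 Hz     | 3–25     |

(the fast window's upper bound deliberately extends to the alpha bound so
the fit spans at least 10 scales).

Around the estimator the package provides the full study pipeline: epoch
preparation (leading 60 s, 5 s trimmed per end → 10,000 samples at 200 Hz),
Hanning-windowed PSD in 1-Hz bins over 5–60 Hz, sensor-wise pooled-variance
t tests with Benjamini–Hochberg FDR (families of 16 / 48 / 896), a mixed
repeated-measures ANOVA with Greenhouse–Geisser adjustment, Pearson
correlations with a cognitive covariate, epoch-length diagnostics, and a
synthetic-cohort generator whose signals have analytically known fractal
structure (fractional Brownian motion, the Weierstrass cosine function, and
piecewise power-law cohort spectra).

## Worked example

Simulate a 34-subject two-group cohort (16 channels, 200 Hz, 60 s; the
second group carries a fast-band Hurst offset of +0.2 and an MMSE-like
covariate coupled to fast-scale fractality at r = 0.6), then analyze it:

```sh
scalefd simulate --out cohort --seed 1 --subjects 18,16
scalefd analyze cohort --out results --seed 1
```

Per-channel estimates for one subject (`scalefd fd cohort/A01.tsv`):

```
channel band  k_min k_max   D      r^2
Fp1     entire    3   133  1.707  0.9998
Fp1     slow     25   100  1.700  0.9998
Fp1     alpha    15    25  1.725  1.0000
Fp1     fast      3    25  1.720  1.0000
```

`D ≈ 1.7` is the design value (base Hurst 0.3 → dimension 2 − 0.3), and the
near-unit `r²` says the curve-length power law holds tightly in every
window.  The group battery (`results/anova.tsv`, `results/ttests.tsv`)
prints, for the fast band:

```
fast  group            F=51.36  df=(1, 32)        p=3.9e-08
fast  group_x_channel  F=1.14   df=(9.77, 312.7)  p=0.33    (GG ε=0.651)
```

with all 16 fast-band channels surviving the FDR criterion (mean t = 5.67,
q < 0.05) while the slow-band group effect stays null (F = 0.55, p = 0.46)
— the simulated complexity loss is confined to fast temporal scales, and
the scale-specific estimator localizes it there.

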