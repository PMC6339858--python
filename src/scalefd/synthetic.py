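"""Synthetic signals with known fractal dimension and full synthetic cohorts.

Two oracle generators and a cohort generator:

* :func:`gen_fbm` — exact fractional Brownian motion via circulant embedding
  of fractional Gaussian noise.  The graph of fBm with Hurst exponent ``H``
  has fractal dimension ``2 - H``, giving a closed-form oracle for the
  curve-length estimator.
* :func:`gen_weierstrass` — the Weierstrass cosine function, the classical
  deterministic validation signal whose box dimension is known analytically.
* :func:`gen_cohort` — multichannel resting-state-like recordings for two
  groups.  Each channel superposes band-limited fractional components (slow,
  alpha, fast), realized as a single Gaussian signal with a piecewise
  power-law spectrum whose per-band slope encodes that band's Hurst exponent,
  plus a weak 1/f background.  One group's Hurst exponents are offset in
  selected bands (raising H lowers the fractal dimension, emulating reduced
  signal complexity), and a cognitive-score-like covariate is drawn jointly
  with the fast-band Hurst.

Spectral shaping happens *only inside the generator*; the analysis path
never filters, because filtering a signal before curve-length estimation
distorts its scale profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Epoch
from .errors import InputError
from .io import Recording, STANDARD_1020_16

__all__ = ["CohortSpec", "gen_fbm", "gen_weierstrass", "gen_cohort", "fgn"]


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    Exact (Davies-Harte) when the embedding is positive semidefinite; for the
    rare non-PSD case the negative eigenvalues are clipped, which degrades the
    construction to an approximate spectral synthesis, and a warning is
    issued.
    """
    if not (0.0 < hurst < 1.0):
        raise InputError("Hurst exponent must lie in (0, 1)")
    if n < 2:
        raise InputError("need n >= 2")
    h2 = 2.0 * hurst
    lag = np.arange(n + 1, dtype=float)
    rho = 0.5 * ((lag + 1) ** h2 - 2 * lag**h2 + np.abs(lag - 1) ** h2)
    # circulant first row of size 2n: rho(0..n), rho(n-1..1)
    row = np.concatenate([rho, rho[-2:0:-1]])
    m = row.size
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn(
            f"circulant embedding not PSD for H={hurst}, n={n}; "
            "falling back to approximate spectral synthesis",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = np.maximum(lam, 0.0)
    half = m // 2
    z = np.zeros(m, dtype=complex)
    z[0] = rng.standard_normal() * np.sqrt(lam[0])
    z[half] = rng.standard_normal() * np.sqrt(lam[half])
    a = rng.standard_normal(half - 1)
    b = rng.standard_normal(half - 1)
    z[1:half] = np.sqrt(lam[1:half] / 2.0) * (a + 1j * b)
    z[half + 1 :] = np.conj(z[1:half][::-1])
    x = np.fft.fft(z).real / np.sqrt(m)
    return x[:n]


def gen_fbm(n: int, hurst: float, seed: int, fs: float = 200.0, label: str = "fbm") -> Epoch:
    """Fractional Brownian motion path of ``n`` samples (fractal dimension 2-H).

    The path is the cumulative sum of exact fractional Gaussian noise;
    reproducible given ``seed``.
    """
    if n < 64:
        raise InputError("need n >= 64 for a meaningful fractal estimate")
    rng = np.random.default_rng(seed)
    return Epoch(np.cumsum(fgn(n, hurst, rng)), fs, label)


def gen_weierstrass(
    n: int,
    target_d: float,
    seed: int | None = None,
    fs: float = 200.0,
    lam: float = 5.0,
    label: str = "weierstrass",
) -> Epoch:
    """Weierstrass cosine function with graph dimension ``target_d``.

    ``W(t) = sum_j lam**(-j*(2-target_d)) * cos(2*pi*lam**j * t/n + phi_j)``
    with the term count chosen so ``lam**M`` exceeds ``n``.  Deterministic
    with zero phases; a seed randomizes the per-term phases.
    """
    if not (1.0 < target_d < 2.0):
        raise InputError("target dimension must lie in (1, 2)")
    m_terms = int(np.ceil(np.log(n) / np.log(lam))) + 1
    t = np.arange(n, dtype=float)
    if seed is None:
        phases = np.zeros(m_terms)
    else:
        phases = np.random.default_rng(seed).uniform(0, 2 * np.pi, m_terms)
    w = np.zeros(n)
    for j in range(m_terms):
        w += lam ** (-j * (2.0 - target_d)) * np.cos(2 * np.pi * lam**j * t / n + phases[j])
    return Epoch(w, fs, label)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    spec[1:] /= np.sqrt(f[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


# Piecewise-spectrum segments: (band, f_low, f_high, pin_low, pin_high).
# A curve-length window [k_min, k_max] does not probe the nominal band
# frequencies fs/k: the variogram kernel reads roughly fs/(2*pi*k) and below,
# so each band's fractional component is placed at the (much lower)
# frequencies its scale window actually responds to, as established by
# spectral break-point scans of the estimator.  The slow segment extends to
# DC and the fast one to Nyquist.  Each segment's variance is pinned over its
# window's sensitivity core [pin_low, pin_high]: tilting one band's exponent
# then redistributes power within that core without changing the total power
# the neighbouring windows see.
_GEN_SEGMENTS = (
    ("slow", 0.0, 1.2, 0.5, 1.2),
    ("alpha", 1.2, 4.0, 1.2, 4.0),
    ("fast", 4.0, None, 4.0, 30.0),
)

#: spectral exponent of the reference 1/f law that sets the segment levels
_GEN_REF_EXPONENT = 1.7


def _piecewise_fractal_noise(
    n: int, fs: float, hurst: dict[str, float], rng: np.random.Generator,
    background: float = 0.03,
) -> np.ndarray:
    """Gaussian signal whose spectrum is a piecewise power law per band.

    Within each segment the power density falls as ``f**-(2*H_band + 1)`` —
    the spectral law of fractional Brownian motion with Hurst exponent H —
    so the scale-windowed fractal dimension responds to that band's Hurst
    exponent.  Segment variances over their sensitivity cores follow a common
    ``1/f**1.7`` reference law, so one band's exponent does not rescale the
    power read by the neighbouring windows.  A weak 1/f background (power
    fraction ``background``) is mixed in.
    """
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    dens = np.zeros_like(f)
    for band, f_lo, f_hi, pin_lo, pin_hi in _GEN_SEGMENTS:
        expo = 2.0 * hurst[band] + 1.0
        hi = fs / 2 if f_hi is None else min(f_hi, fs / 2)
        seg = (f > max(f_lo, 0.0)) & (f <= hi)
        pin = (f > pin_lo) & (f <= min(pin_hi, fs / 2))
        if not seg.any() or not pin.any():
            continue
        ref_power = (f[pin] ** -_GEN_REF_EXPONENT).sum()
        dens[seg] = f[seg] ** -expo * (ref_power / (f[pin] ** -expo).sum())
    nz = f > 0
    if background > 0:
        # 1/f floor carrying `background` of the pre-normalization power
        total = dens[nz].sum()
        shape = f[nz] ** -1.0
        dens[nz] += background * total * shape / shape.sum()
    spec = np.fft.rfft(rng.standard_normal(n)) * np.sqrt(dens)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _default_band_effects() -> dict[str, float]:
    return {"slow": 0.0, "alpha": 0.0, "fast": 0.2}


def _default_base_hurst() -> dict[str, float]:
    return {"slow": 0.30, "alpha": 0.40, "fast": 0.30}


def _default_subject_sd() -> dict[str, float]:
    return {"slow": 0.02, "alpha": 0.03, "fast": 0.08}


def _default_weights() -> dict[str, float]:
    return {"background": 0.03}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-group cohort.

    Defaults mirror the emulated study design: 18 vs 16 subjects, 16
    channels (Fp1..O2), 200 Hz, 60 s eyes-closed-like recordings, the second
    group's fast-band Hurst exponent offset by +0.2 (lower fast-scale fractal
    dimension), and a covariate correlated at 0.6 with fast-band fractality.
    Slow- and alpha-band offsets are available through ``band_effects`` but
    exert only a weak, partly cross-window influence on the measured
    dimensions; see the methods documentation.

    ``covariate_coupling`` is the target Pearson correlation between the
    fast-band fractal dimension (D = 2 - H direction) and the covariate,
    defined before the covariate is discretized to its 0-30 integer range.
    ``subject_sd`` may be a single number or a per-band mapping of
    between-subject Hurst standard deviations.
    """

    n_group_a: int = 18
    n_group_b: int = 16
    n_channels: int = 16
    fs: float = 200.0
    duration_s: float = 60.0
    band_effects: dict[str, float] = field(default_factory=_default_band_effects)
    covariate_coupling: float = 0.6
    seed: int = 0
    base_hurst: dict[str, float] = field(default_factory=_default_base_hurst)
    subject_sd: dict[str, float] | float = field(default_factory=_default_subject_sd)
    channel_sd: float = 0.01
    weights: dict[str, float] = field(default_factory=_default_weights)
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b) < 2:
            raise InputError("need at least 2 subjects per group")
        if not (1 <= self.n_channels <= len(STANDARD_1020_16)):
            raise InputError(f"n_channels must be in [1, {len(STANDARD_1020_16)}]")
        if abs(self.covariate_coupling) > 1:
            raise InputError("|covariate coupling| must be <= 1")
        for band, h0 in self.base_hurst.items():
            h1 = h0 + self.band_effects.get(band, 0.0)
            if not (0.0 < h0 < 1.0 and 0.0 < h1 < 1.0):
                raise InputError(
                    f"band {band!r}: Hurst {h0} with offset yields {h1}, outside (0, 1)"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def gen_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a synthetic cohort.

    Returns the recordings and a metadata frame with columns
    ``subject, group, covariate`` plus the latent per-band Hurst exponents
    (columns ``hurst_slow/alpha/fast``) for oracle-style checks.
    Identical spec and seed give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels = STANDARD_1020_16[: spec.n_channels]
    n = spec.n_samples
    rho = spec.covariate_coupling
    recs: list[Recording] = []
    meta_rows = []
    for g_idx, (g_label, n_subj) in enumerate(
        zip(spec.group_labels, (spec.n_group_a, spec.n_group_b))
    ):
        for s in range(n_subj):
            sid = f"{g_label}{s + 1:02d}"
            z_fast = rng.standard_normal()
            # covariate tracks fast-band fractal dimension (-H direction)
            z_cov = -rho * z_fast + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
            hurst = {}
            for band, h0 in spec.base_hurst.items():
                off = spec.band_effects.get(band, 0.0) if g_idx == 1 else 0.0
                z = z_fast if band == "fast" else rng.standard_normal()
                sd = (
                    spec.subject_sd.get(band, 0.0)
                    if isinstance(spec.subject_sd, dict)
                    else spec.subject_sd
                )
                hurst[band] = float(np.clip(h0 + off + sd * z, 0.01, 0.99))
            center = 18.0 if g_idx == 1 else 28.0
            scale = 4.7 if g_idx == 1 else 1.5
            covariate = int(np.clip(round(center + scale * z_cov), 0, 30))
            chans = []
            for ch in labels:
                ch_hurst = {
                    b: float(np.clip(h + spec.channel_sd * rng.standard_normal(), 0.01, 0.99))
                    for b, h in hurst.items()
                }
                x = _piecewise_fractal_noise(
                    n, spec.fs, ch_hurst, rng,
                    background=spec.weights.get("background", 0.03),
                )
                chans.append(Epoch(x, spec.fs, ch))
            recs.append(
                Recording(tuple(chans), subject_id=sid, group=g_label, covariate=covariate)
            )
            meta_rows.append(
                {
                    "subject": sid,
                    "group": g_label,
                    "covariate": covariate,
                    **{f"hurst_{b}": h for b, h in hurst.items()},
                }
            )
    return recs, pd.DataFrame(meta_rows)
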