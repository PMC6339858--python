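"""Higuchi curve-length profiles and scale-specific fractal dimension estimation.

The central quantity is the mean curve length ``<L(k)>`` of a uniformly
sampled series at temporal scale ``k``.  For a series ``X(1..N)`` (1-based
here, stored 0-based) and offset ``m`` in ``1..k``::

    L_m(k) = (1/k) * [ sum_{i=1..n_m} |X(m+i*k) - X(m+(i-1)*k)| ] * (N-1) / (n_m * k)

with ``n_m = floor((N-m)/k)``.  ``<L(k)>`` is the arithmetic mean of the
``L_m(k)`` over offsets with ``n_m >= 1``.  A signal with fractal dimension
``D`` obeys the power law ``<L(k)> ~ k**(-D)``, so ``D`` is the slope of the
ordinary least-squares line through ``(log(1/k), log <L(k)>)``.

Restricting the fit window ``[k_min, k_max]`` to the scales spanned by a
physiological frequency band yields a *temporal-scale-specific* fractal
dimension: fractality of the raw broadband signal assessed only at the time
scales of that band, without any band-pass filtering of the signal itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .bands import BandScaleRange
from .errors import (
    DegenerateSignalError,
    InputError,
    InsufficientScalesError,
    ScaleTooLargeError,
)

__all__ = [
    "Epoch",
    "CurveLengthProfile",
    "FractalEstimate",
    "curve_length_profile",
    "fit_dimension",
    "scale_specific_dimension",
    "sliding_dimension_curve",
    "epoch_length_diagnostics",
]


@dataclass(frozen=True)
class Epoch:
    """One channel's uniformly sampled series.

    Parameters
    ----------
    samples : array-like of float
        Signal values, arbitrary amplitude units.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Channel name (free text, e.g. a 10-20 electrode label).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise InputError("epoch needs a 1-d series of length >= 2")
        if not np.all(np.isfinite(x)):
            raise InputError(f"epoch {self.label!r} contains non-finite samples")
        if not (self.fs > 0):
            raise InputError("sampling rate must be positive")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.samples.size / self.fs

    def slice_seconds(self, start_s: float, stop_s: float) -> "Epoch":
        """Sub-epoch covering ``[start_s, stop_s)`` seconds."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not (0 <= i0 < i1 <= len(self)):
            raise InputError(
                f"slice [{start_s}, {stop_s}) s outside epoch of {self.duration} s"
            )
        return Epoch(self.samples[i0:i1], self.fs, self.label)


@dataclass(frozen=True)
class CurveLengthProfile:
    """Mean curve lengths ``<L(k)>`` over a set of scales with per-offset detail.

    ``per_offset_lengths[i]`` holds the ``k_values[i]`` offset-specific lengths
    ``L_m(k)``; offsets with no usable increment (``floor((N-m)/k) = 0``) are
    stored as NaN and excluded from the mean.
    """

    k_values: np.ndarray
    mean_lengths: np.ndarray
    per_offset_lengths: tuple[np.ndarray, ...]
    n_excluded_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=int)
        if np.any(np.diff(k) <= 0) or np.any(k < 1):
            raise InputError("k_values must be strictly increasing positive integers")
        if self.n_excluded_offsets is None:
            object.__setattr__(
                self,
                "n_excluded_offsets",
                np.array([int(np.isnan(p).sum()) for p in self.per_offset_lengths]),
            )

    def window(self, k_min: int, k_max: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(k, <L(k)>)`` for every integer scale in ``[k_min, k_max]``.

        Raises if any integer in the window is absent: fits never silently
        interpolate missing scales.
        """
        wanted = np.arange(k_min, k_max + 1)
        idx = np.searchsorted(self.k_values, wanted)
        ok = (idx < self.k_values.size) & (self.k_values[np.minimum(idx, self.k_values.size - 1)] == wanted)
        if not np.all(ok):
            missing = wanted[~ok]
            raise InsufficientScalesError(
                f"profile is missing scales {missing.tolist()} in window [{k_min}, {k_max}]"
            )
        return wanted, self.mean_lengths[idx]


@dataclass(frozen=True)
class FractalEstimate:
    """Slope-fit result of the curve-length power law.

    ``dimension`` is dimensionless; for non-degenerate fractal signals it
    typically lies in [1, 2] but is reported unclamped.
    """

    dimension: float
    intercept: float
    k_min: int
    k_max: int
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.k_min >= self.k_max:
            raise InputError("k_min must be < k_max")


def curve_length_profile(epoch: Epoch, k_values: Iterable[int]) -> CurveLengthProfile:
    """Compute Higuchi curve lengths of ``epoch`` at each scale in ``k_values``.

    Parameters
    ----------
    epoch : Epoch
    k_values : iterable of int
        Scales; each must satisfy ``k < len(epoch)``.

    Returns
    -------
    CurveLengthProfile

    Raises
    ------
    ScaleTooLargeError
        If any ``k >= len(epoch)``.
    """
    x = epoch.samples
    n = x.size
    ks = np.unique(np.asarray(list(k_values), dtype=int))
    if ks.size == 0:
        raise InputError("empty scale set")
    if np.any(ks < 1):
        raise InputError("scales must be positive integers")
    if ks[-1] >= n:
        raise ScaleTooLargeError(
            f"scale k={int(ks[-1])} requires series length > {int(ks[-1])}, got {n}"
        )

    means = np.empty(ks.size)
    per_offset: list[np.ndarray] = []
    for j, k in enumerate(ks):
        k = int(k)
        d = np.abs(x[k:] - x[:-k])  # |X(t+k) - X(t)|, t = 1..N-k (1-based)
        # column m-1 of the zero-padded (rows, k) view collects the increments
        # of offset m; row i is stride step i+1.
        rows = -(-d.size // k)
        pad = np.zeros(rows * k)
        pad[: d.size] = d
        sums = pad.reshape(rows, k).sum(axis=0)
        m = np.arange(1, k + 1)
        n_m = (n - m) // k
        lm = np.full(k, np.nan)
        valid = n_m >= 1
        lm[valid] = sums[valid] * (n - 1) / (n_m[valid] * k * k)
        per_offset.append(lm)
        means[j] = np.nanmean(lm)
    return CurveLengthProfile(ks, means, tuple(per_offset))


def fit_dimension(profile: CurveLengthProfile, k_min: int, k_max: int) -> FractalEstimate:
    """Estimate ``D`` by OLS on ``(log(1/k), log <L(k)>)`` over ``[k_min, k_max]``.

    Natural logarithms are used; the slope is base-invariant.

    Raises
    ------
    DegenerateSignalError
        If any ``<L(k)>`` in the window is zero (constant segment).
    InsufficientScalesError
        If fewer than 3 scales fall in the window.
    """
    k, L = profile.window(k_min, k_max)
    if k.size < 3:
        raise InsufficientScalesError(
            f"need >= 3 scales for a slope fit, window [{k_min}, {k_max}] has {k.size}"
        )
    if np.any(L <= 0) or np.any(~np.isfinite(L)):
        raise DegenerateSignalError(
            f"non-positive curve length in window [{k_min}, {k_max}]"
        )
    res = sstats.linregress(np.log(1.0 / k), np.log(L))
    return FractalEstimate(
        dimension=float(res.slope),
        intercept=float(res.intercept),
        k_min=int(k_min),
        k_max=int(k_max),
        r_squared=float(res.rvalue**2),
        n_points=int(k.size),
    )


def scale_specific_dimension(epoch: Epoch, band: BandScaleRange) -> FractalEstimate:
    """Fractal dimension of ``epoch`` restricted to a band's scale window.

    Composes :func:`curve_length_profile` over all integer scales in
    ``[band.k_min, band.k_max]`` with :func:`fit_dimension` on that window.
    """
    ks = range(band.k_min, band.k_max + 1)
    profile = curve_length_profile(epoch, ks)
    return fit_dimension(profile, band.k_min, band.k_max)


def sliding_dimension_curve(
    epoch: Epoch,
    window_width: int,
    k_min_range: Sequence[int] | range,
) -> list[tuple[int, FractalEstimate]]:
    """Dimension estimates from a scale window slid across ``k_min`` values.

    For each ``k_min`` in ``k_min_range`` the fit covers
    ``[k_min, k_min + window_width]``.  Plotting ``D`` against ``k_min``
    diagnoses how wide a window must be before the estimate varies smoothly;
    widths of at least 10 scales give smooth curves on EEG-like signals.
    """
    if window_width < 2:
        raise InputError("window_width must be >= 2")
    kmins = sorted(int(k) for k in k_min_range)
    if not kmins:
        raise InputError("empty k_min range")
    if kmins[0] < 1:
        raise InputError("k_min must be positive")
    k_all = range(kmins[0], kmins[-1] + window_width + 1)
    profile = curve_length_profile(epoch, k_all)
    return [(km, fit_dimension(profile, km, km + window_width)) for km in kmins]


def epoch_length_diagnostics(
    epoch: Epoch,
    lengths_s: Sequence[float],
    bands: Sequence[BandScaleRange],
    mode: Literal["averaged-segments", "leading-prefix"] = "averaged-segments",
) -> pd.DataFrame:
    """Scale-specific dimensions as a function of evaluation epoch length.

    ``averaged-segments`` tiles the epoch into non-overlapping segments of the
    requested length and averages ``D`` over all segments in which the band is
    computable; ``leading-prefix`` uses only the first ``length_s`` seconds.
    A band whose ``k_max`` is not smaller than the segment sample count gets a
    missing-value marker (NaN) rather than an exception.

    Returns a tidy frame with columns ``length_s, band, D, n_segments``.
    """
    if mode not in ("averaged-segments", "leading-prefix"):
        raise InputError(f"unknown mode {mode!r}")
    rows = []
    for length_s in lengths_s:
        n_seg_samples = int(round(length_s * epoch.fs))
        if n_seg_samples > len(epoch):
            raise InputError(
                f"requested length {length_s} s exceeds epoch duration {epoch.duration} s"
            )
        if mode == "leading-prefix":
            starts = [0]
        else:
            n_tiles = len(epoch) // n_seg_samples
            starts = [t * n_seg_samples for t in range(n_tiles)]
        for band in bands:
            ds = []
            for s0 in starts:
                seg = Epoch(epoch.samples[s0 : s0 + n_seg_samples], epoch.fs, epoch.label)
                if band.k_max >= len(seg):
                    continue  # scale window does not fit in this segment
                try:
                    ds.append(scale_specific_dimension(seg, band).dimension)
                except (DegenerateSignalError, InsufficientScalesError):
                    continue
            rows.append(
                {
                    "length_s": float(length_s),
                    "band": band.label,
                    "D": float(np.mean(ds)) if ds else np.nan,
                    "n_segments": len(ds),
                }
            )
    return pd.DataFrame(rows)
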