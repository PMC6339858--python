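"""Mapping physiological frequency bands to Higuchi scale windows.

A scale ``k`` corresponds to the period of ``fs/k`` Hz, so a band
``[f_low, f_high]`` maps to the window ``k_min = [fs/f_high]``,
``k_max = [fs/f_low]`` with ``[.]`` the Gauss bracket (floor).  Windows
narrower than 10 scales yield noisy slope fits and are flagged rather than
rejected, which is why the canonical analysis uses three broad bands (slow,
alpha, fast) instead of the usual five-band delta..gamma division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError, InvalidBandError

__all__ = ["BandScaleRange", "band_to_scales", "default_band_table", "MIN_ANALYSIS_WIDTH"]

#: minimum k-window width for a smooth dimension-vs-k_min dependency
MIN_ANALYSIS_WIDTH = 10


@dataclass(frozen=True)
class BandScaleRange:
    """A named frequency band and its derived scale window.

    Attributes
    ----------
    label : str
    f_low, f_high : float
        Band edges in Hz.
    k_min, k_max : int
        Scale window (samples).
    narrow : bool
        True when ``k_max - k_min < 10`` (slope fit flagged as noisy).
    override : bool
        True when the window was set explicitly rather than derived from the
        band edges by the reciprocal mapping.
    """

    label: str
    f_low: float
    f_high: float
    k_min: int
    k_max: int
    narrow: bool = False
    override: bool = False

    def __post_init__(self) -> None:
        if not (self.f_low < self.f_high):
            raise InputError("f_low must be < f_high")
        if not (self.k_min < self.k_max):
            raise InvalidBandError(
                f"band {self.label!r}: scale window [{self.k_min}, {self.k_max}] is empty"
            )

    @property
    def width(self) -> int:
        return self.k_max - self.k_min


def band_to_scales(fs: float, f_low: float, f_high: float, label: str = "") -> BandScaleRange:
    """Derive the scale window of a frequency band at sampling rate ``fs``.

    ``k_min = floor(fs / f_high)`` (clamped to the minimum usable scale 2) and
    ``k_max = floor(fs / f_low)``.

    Raises
    ------
    InvalidBandError
        If the resulting window is empty (``k_min >= k_max``).
    """
    if not (0 < f_low < f_high <= fs / 2):
        raise InputError(
            f"band [{f_low}, {f_high}] Hz must satisfy 0 < f_low < f_high <= fs/2 = {fs / 2}"
        )
    k_min = max(2, math.floor(fs / f_high))
    k_max = math.floor(fs / f_low)
    if k_min >= k_max:
        raise InvalidBandError(
            f"band [{f_low}, {f_high}] Hz at fs={fs} maps to empty window "
            f"[{k_min}, {k_max}]"
        )
    return BandScaleRange(
        label=label or f"{f_low:g}-{f_high:g}Hz",
        f_low=float(f_low),
        f_high=float(f_high),
        k_min=k_min,
        k_max=k_max,
        narrow=(k_max - k_min) < MIN_ANALYSIS_WIDTH,
    )


# canonical band edges: entire analysis range plus slow (delta/theta),
# alpha, and fast (beta/gamma)
CANONICAL_BANDS: tuple[tuple[str, float, float], ...] = (
    ("entire", 1.5, 60.0),
    ("slow", 2.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("fast", 13.0, 60.0),
)


def default_band_table(fs: float = 200.0) -> list[BandScaleRange]:
    """The canonical four-band table.

    At ``fs = 200`` Hz this reproduces the reference configuration exactly:
    entire 1.5-60 Hz -> [3, 133], slow 2-8 Hz -> [25, 100], alpha 8-13 Hz ->
    [15, 25], fast 13-60 Hz -> [3, 25].  The fast band's upper scale bound is
    a deliberate override of the reciprocal mapping (which would give 15): it
    extends the fast window up to the alpha band's upper bound so that the
    beta/gamma window is 10+ scales wide.  At other sampling rates the generic
    mapping is used for all four bands.
    """
    out = []
    for label, f_low, f_high in CANONICAL_BANDS:
        rng = band_to_scales(fs, f_low, f_high, label=label)
        if label == "fast" and fs == 200.0:
            rng = BandScaleRange(
                label=label,
                f_low=f_low,
                f_high=f_high,
                k_min=rng.k_min,
                k_max=25,
                narrow=False,
                override=True,
            )
        out.append(rng)
    return out
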