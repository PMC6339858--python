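"""Reading and writing multichannel recordings and cohort metadata.

Two on-disk formats are supported: EDF (read via :mod:`mne`, which must be
installed) and a delimited numeric matrix — header row of channel labels, one
sample per row, tab- or comma-separated.  The delimited format is the
package's native interchange format and what the cohort generator writes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Epoch
from .errors import InputError

__all__ = ["Recording", "read_recording", "write_recording", "STANDARD_1020_16"]

#: the 16-electrode 10-20 montage used by the emulated study design
STANDARD_1020_16 = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8", "C3",
    "C4", "P3", "Pz", "P4", "T5", "T6", "O1", "O2",
)

# labels dropped when loading clinical exports
_NON_EEG = re.compile(r"(EOG|ECG|EKG|EMG|STI|TRIG|STATUS|MARKER)", re.IGNORECASE)


@dataclass(frozen=True)
class Recording:
    """A subject's multichannel recording plus its cohort metadata.

    All channels share the sampling rate and length; labels are unique.
    """

    channels: tuple[Epoch, ...]
    subject_id: str
    group: str | None = None
    covariate: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise InputError("recording needs at least one channel")
        fs = {ch.fs for ch in self.channels}
        ns = {len(ch) for ch in self.channels}
        if len(fs) != 1 or len(ns) != 1:
            raise InputError("all channels must share fs and length")
        labels = [ch.label for ch in self.channels]
        if len(set(labels)) != len(labels):
            raise InputError(f"duplicate channel labels in {self.subject_id!r}")

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    @property
    def n_samples(self) -> int:
        return len(self.channels[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({ch.label: ch.samples for ch in self.channels})


def _read_delimited(path: Path, fs: float) -> Recording:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns.duplicated().any() or any(c.endswith((".1", ".2")) for c in df.columns):
        raise InputError(f"duplicate channel labels in {path}")
    epochs = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        if np.isnan(vals).any():
            raise InputError(f"non-numeric cells in column {col!r} of {path}")
        epochs.append(Epoch(vals, fs, str(col)))
    return Recording(tuple(epochs), subject_id=path.stem)


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise InputError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    keep = [ch for ch in raw.ch_names if not _NON_EEG.search(ch)]
    if not keep:
        raise InputError(f"no EEG channels found in {path}")
    raw.pick(keep)
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    epochs = tuple(Epoch(data[i], fs, ch) for i, ch in enumerate(raw.ch_names))
    return Recording(epochs, subject_id=path.stem)


def read_recording(path: str | Path, fmt: str = "auto", fs: float | None = None) -> Recording:
    """Load one subject's recording.

    Parameters
    ----------
    path : path to an EDF file or a delimited matrix.
    fmt : {"auto", "edf", "delimited"}
        ``auto`` dispatches on the ``.edf`` suffix.
    fs : float, optional
        Sampling rate in Hz; required for delimited files (EDF carries its
        own header rate).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        if fs is None:
            raise InputError("sampling rate fs is required for delimited input")
        return _read_delimited(path, fs)
    raise InputError(f"unknown format {fmt!r}")


def write_recording(recording: Recording, path: str | Path, sep: str = "\t") -> Path:
    """Write a recording as a delimited matrix (header row, samples as rows)."""
    path = Path(path)
    recording.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path
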