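"""Typed errors raised across the package."""


class ScaleFDError(Exception):
    """Base class for all package errors."""


class InputError(ScaleFDError):
    """Malformed input data (non-finite samples, bad shapes, bad labels)."""


class ScaleTooLargeError(ScaleFDError):
    """A requested scale k is not smaller than the series length."""


class DegenerateSignalError(ScaleFDError):
    """Curve length vanished at some scale (constant or near-constant segment)."""


class InsufficientScalesError(ScaleFDError):
    """Fewer than three scales available for the log-log slope fit."""


class InvalidBandError(ScaleFDError):
    """A frequency band maps to an empty or inverted scale window."""
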