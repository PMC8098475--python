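"""Exception hierarchy shared across the package."""


class IcemapError(Exception):
    """Base class for all errors raised by this package."""


class CalibrationError(IcemapError):
    """Unknown calibration key or method mismatch."""


class InvalidMeasurementError(IcemapError):
    """Non-positive or otherwise unusable intensity measurement."""


class InsufficientDataError(IcemapError):
    """Not enough usable samples to estimate a constant."""


class PairingError(IcemapError):
    """Per-hole inputs could not be matched by id."""


class FormatError(IcemapError):
    """Unreadable or unsupported image file."""


class AlignmentError(IcemapError):
    """Image registration failed or shift out of bounds."""


class LatticeError(IcemapError):
    """No periodic hole lattice could be found."""
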