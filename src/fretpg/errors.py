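"""Exception hierarchy.

All package errors derive from :class:`FretpgError` so callers (and the CLI)
can distinguish data problems from programming errors with one ``except``.
"""


class FretpgError(Exception):
    """Base class for all errors raised by fretpg."""


class SpectrumFormatError(FretpgError):
    """A spectrum file or array violates the format contract (e.g. non-monotone wavelengths)."""


class InsufficientDataError(FretpgError):
    """Too few data points to proceed."""


class GridRangeError(FretpgError):
    """A requested wavelength grid extends beyond the measured range (no extrapolation)."""


class AlignmentError(FretpgError):
    """Two spectra that must share a grid/excitation channel do not."""


class ManifestError(FretpgError):
    """An experiment manifest is incomplete or inconsistent."""


class WeakReferenceError(FretpgError):
    """A reference scan has too little signal above its noise floor to define a shape."""


class DegenerateReferenceError(FretpgError):
    """A reference spectrum is identically zero (or yields a non-finite crosstalk ratio)."""


class CollinearityError(FretpgError):
    """The unmixing basis is numerically collinear (condition number above the guard)."""


class UnderdeterminedError(FretpgError):
    """Fewer grid points than basis columns."""


class UndefinedEfficiencyError(FretpgError):
    """FRET efficiency is undefined because no directly excited acceptor signal is present."""


class InsufficientReplicatesError(FretpgError):
    """A statistical operation needs more replicates than were provided."""


class ClassificationError(FretpgError):
    """A muropeptide row carries an unknown oligomer class."""


class ConfigError(FretpgError):
    """Invalid simulation or run configuration."""


class DomainError(FretpgError, ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""
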