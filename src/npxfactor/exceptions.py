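"""Exception hierarchy.

All package errors derive from :class:`NpxFactorError` so callers can catch
one base class; subclasses distinguish malformed files, inconsistent data,
bad parameters and degenerate fits.
"""


class NpxFactorError(Exception):
    """Base class for all npxfactor errors."""


class FormatError(NpxFactorError):
    """A file does not match the expected schema (missing/unknown columns)."""


class IntegrityError(NpxFactorError):
    """Data are internally inconsistent (duplicates, empty intersections)."""


class MappingError(NpxFactorError):
    """A subject map references sample IDs that do not exist."""


class ParameterError(NpxFactorError, ValueError):
    """An argument is outside its documented range."""


class DegenerateFitError(NpxFactorError):
    """A regression cannot be fit (zero predictor variance, too few pairs)."""


class UsageError(NpxFactorError):
    """Operations combined inconsistently (e.g. wrong transform direction)."""
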