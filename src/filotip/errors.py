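"""Exception hierarchy for the filotip pipeline.

Every stage raises a subclass of :class:`FilotipError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class FilotipError(Exception):
    """Base class for all filotip errors."""


class ArgumentError(FilotipError, ValueError):
    """An argument violates a documented precondition."""


class SceneSizeError(FilotipError):
    """The requested cell body plus filopodia do not fit in the image."""


class CalibrationError(FilotipError):
    """Pixel size / frame interval missing and not supplied explicitly."""


class ParseError(FilotipError):
    """A CSV/YAML input is malformed; the message names the offending row."""


class ConstantImageError(FilotipError):
    """Normalization is undefined because the image has no dynamic range."""


class EmptyMaskError(FilotipError):
    """A cell mask is empty (no cell detected) — distinct from zero spots."""


class UndefinedRatioError(FilotipError):
    """An enrichment ratio has a zero shaft denominator."""


class DegenerateAmplitudeError(FilotipError):
    """A titration's free and bound signals coincide; no binding amplitude."""


class NoBindingError(FilotipError):
    """The titration signal is flat relative to its noise; no Kd is fitted."""


class ConfigError(FilotipError):
    """A run configuration contains unknown or invalid keys."""
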