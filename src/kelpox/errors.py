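"""Exception hierarchy for the kelpox package."""


class KelpoxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KelpoxError):
    """Input file is structurally malformed (missing columns, no header)."""


class EmptyInputError(KelpoxError):
    """No usable rows / samples / files were found."""


class GridError(KelpoxError):
    """Timestamps are incompatible with the requested uniform grid."""


class ValidationError(KelpoxError):
    """A domain invariant was violated (duplicate ids, out-of-range values)."""


class InsufficientDataError(KelpoxError):
    """Too few observations for the requested statistic."""


class ConfigError(KelpoxError):
    """An analysis configuration is unusable for the given record."""


class BandResolutionError(KelpoxError):
    """A frequency band lies outside the resolved spectral range."""


class UndefinedDominanceError(KelpoxError):
    """Dominant band requested but every band variance is zero."""
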