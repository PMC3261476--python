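"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
configuration problems (the user asked for something invalid) and data
problems (the input bytes/tables are wrong or insufficient).
"""


class PulsecamError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PulsecamError):
    """Invalid parameter, threshold, band, or config file."""


class DataError(PulsecamError):
    """Invalid or insufficient input data."""


class CorruptStreamError(DataError):
    """Raw frame file size does not match its metadata."""


class InvalidMetadataError(ConfigurationError):
    """Sidecar metadata violates nv21 constraints (odd dims, fps<=0, ...)."""


class EmptyInputError(DataError):
    """Operation requires a nonempty input."""


class InsufficientSignalError(DataError):
    """Signal too short or too degraded to analyse."""


class InsufficientBeatsError(DataError):
    """Too few beats for the requested rolling window."""


class DegenerateInputError(DataError):
    """Statistic undefined on this input (zero variance, one subject, ...)."""


class IncompleteStudyError(DataError):
    """Study table is missing a required condition or device."""
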