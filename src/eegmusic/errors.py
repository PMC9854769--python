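"""Exception hierarchy used across the pipeline.

Every stage raises a subclass of :class:`EEGMusicError` so callers (and the
CLI) can distinguish user-facing failures from programming errors.
"""


class EEGMusicError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EEGMusicError):
    """A file could not be parsed or written in the requested format."""


class DataError(EEGMusicError):
    """Input data violate a precondition (non-finite, empty, too short...)."""


class MetadataError(EEGMusicError):
    """Labels/metadata are inconsistent with the data they describe."""


class SpecError(EEGMusicError):
    """A configuration or synthetic-data specification is invalid."""


class ConfigError(SpecError):
    """An estimator/training configuration is invalid."""


class NumericalError(EEGMusicError):
    """A numerical operation failed (singular or ill-conditioned system)."""
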