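"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`ParastormError`, so callers (notably the CLI) can distinguish
pipeline failures from programming errors.
"""


class ParastormError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ParastormError):
    """Input file is not a readable movie/table of the expected format."""


class MetadataError(ParastormError):
    """Required camera metadata is absent and no override was supplied."""


class BoundsError(ParastormError):
    """Frame or pixel index outside the valid range."""


class SchemaError(ParastormError):
    """A table or calibration file has unknown or missing columns/keys."""


class ParseError(ParastormError):
    """A cell in a CSV could not be interpreted; carries the row number."""


class ConfigError(ParastormError):
    """Invalid run/simulation/postprocessing configuration."""


class DegenerateInputError(ParastormError):
    """An ROI or data set carries no usable signal (e.g. constant patch)."""


class InsufficientDataError(ParastormError):
    """Too few observations to fit the requested model."""


class DegenerateCalibrationError(ParastormError):
    """Defocus curves do not encode z (coincident foci or flat widths)."""


class DomainError(ParastormError):
    """A closed-form expression was evaluated outside its domain."""


class PlanError(ParastormError):
    """Invalid worker plan (e.g. more workers than frames)."""


class MergeError(ParastormError):
    """Worker tables overlap in frame coverage and cannot be merged."""


class RunError(ParastormError):
    """A parallel worker failed; names the worker and its frame subset."""


class DriftError(ParastormError):
    """Drift estimation impossible (e.g. a temporal bin is nearly empty)."""


class SettingsError(ParastormError):
    """Invalid rendering settings."""


class ModeError(ParastormError):
    """Operation requested on a table of the wrong dimensionality."""
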