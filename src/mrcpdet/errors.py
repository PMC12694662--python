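"""Exception hierarchy used across the pipeline."""


class MrcpDetError(Exception):
    """Base class for all package errors."""


class ConfigError(MrcpDetError):
    """Invalid configuration value; the message names the offending field."""


class SizingError(MrcpDetError):
    """Requested structure does not fit in the available signal length."""


class ShapeError(MrcpDetError):
    """Array or epoch shape does not match the expected layout."""


class SchemaError(MrcpDetError):
    """Channel sets or column conventions of two objects disagree."""


class BalanceError(MrcpDetError):
    """Class balancing impossible (one class empty)."""


class TemplateError(MrcpDetError):
    """Template construction impossible (empty training set)."""


class FoldError(MrcpDetError):
    """A cross-validation fold cannot be trained (e.g. single-class)."""


class GroupingError(MrcpDetError):
    """Cohort grouping violated (mixed or empty condition groups)."""


class InsufficientDataError(MrcpDetError):
    """Too few epochs to build a cross-validation plan."""


class MetricError(MrcpDetError):
    """Evaluation metric undefined for the given inputs."""
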