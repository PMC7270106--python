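"""Exception hierarchy.

Validation problems (bad files, bad configuration, impossible requests)
derive from :class:`ValidationError`; conditions where a metric is
mathematically undefined derive from :class:`UndefinedMetricError`.
The CLI maps the former to exit code 1 and everything else to 2.
"""


class CtevalError(Exception):
    """Base class for all package errors."""


class ValidationError(CtevalError):
    """Input violates a documented invariant (bad file, bad config)."""


class TranscriptParseError(ValidationError):
    """A transcript file could not be parsed; message names the line."""


class PairingModeError(ValidationError):
    """The requested pairing mode lacks required timing information."""


class EmptyGroupError(ValidationError):
    """A per-group metric was requested for a group with no members."""


class AnnotationError(ValidationError):
    """A harm annotation points at a nonexistent session or utterance."""


class ConfigError(ValidationError):
    """An evaluation configuration references missing inputs."""


class UndefinedMetricError(CtevalError):
    """The metric is undefined for this input (e.g. empty reference)."""
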