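"""Exception hierarchy shared across the package.

Distinct exception classes map onto distinct CLI exit codes (see cli.py),
so analysis failures, malformed inputs and bad configuration can be told
apart by calling scripts.
"""


class DndMotionError(Exception):
    """Base class for all package errors."""


class ParameterError(DndMotionError, ValueError):
    """A parameter violates its documented bounds (names the bound)."""


class ParseError(DndMotionError, ValueError):
    """A session file or config file could not be parsed."""


class ConfigError(DndMotionError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class SegmentationError(DndMotionError, RuntimeError):
    """The phase structure of a timed-up-and-go recording is undetectable."""


class InsufficientDataError(DndMotionError, RuntimeError):
    """Too little signal to analyse (e.g. a walk shorter than 4 steps)."""
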