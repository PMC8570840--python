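"""Exception hierarchy.

Every failure mode the pipeline can signal deliberately derives from
:class:`PeflowError`, so callers (and the CLI) can distinguish expected
analysis failures from programming errors.
"""


class PeflowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PeflowError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(PeflowError):
    """A file could not be parsed in the declared format."""


class UnsupportedScaleError(FormatError):
    """An FCS parameter uses log amplification; only linear is supported."""


class EmptyInputError(PeflowError):
    """An input holds zero events."""


class EmptyGateError(PeflowError):
    """A gate excluded every event."""


class NoPeaksError(PeflowError):
    """Peak detection found no usable peaks."""


class FitError(PeflowError):
    """A single-Gaussian fit was degenerate or failed to converge."""


class AssignmentError(PeflowError):
    """Detected peaks could not be reconciled with standard + 2C + k*P roles."""


class OverlapError(AssignmentError):
    """Standard and sample 2C peaks overlap; a secondary standard is advised."""


class InsufficientPeaksError(PeflowError):
    """Fewer sample peaks than the estimator requires (P needs at least two)."""


class ModelViolationError(PeflowError):
    """The fitted peak series contradicts the 2C + k*P model (negative slope)."""


class EmptySetError(PeflowError):
    """A selection (e.g. inferred diploids) is empty."""


class LabelingError(PeflowError):
    """A measurement carries a missing or unknown group label."""


class ConfigError(PeflowError):
    """Invalid or unknown pipeline configuration."""
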