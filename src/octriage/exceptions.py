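"""Exception taxonomy for the pipeline.

All errors derive from :class:`OctriageError` so callers can catch the whole
family; most also derive from ``ValueError`` so they behave conventionally.
"""


class OctriageError(Exception):
    """Base class for all package errors."""


class DomainError(OctriageError, ValueError):
    """An argument is outside the operation's domain."""


class SchemaError(OctriageError, ValueError):
    """A manifest or table is missing a required column."""


class IntegrityError(OctriageError, ValueError):
    """A manifest violates a uniqueness or referential invariant."""


class FormatError(OctriageError, ValueError):
    """An image file has an unsupported layout (channels / bit depth)."""


class DegenerateInputError(OctriageError, ValueError):
    """Input carries no usable signal (constant series, identical samples)."""


class ModelFitError(OctriageError, RuntimeError):
    """A statistical model could not be fitted (e.g. rank-deficient corpus)."""


class TraceFailureError(OctriageError, RuntimeError):
    """Surface tracing failed on too many columns."""


class ScoreFailureError(OctriageError, RuntimeError):
    """Too few columns produced a finite decay slope."""


class StratificationError(OctriageError, ValueError):
    """A stratum is too small to split into train and cv sides."""


class TrainingError(OctriageError, RuntimeError):
    """Classifier training is impossible (e.g. single-class input)."""


class CutoffError(OctriageError, RuntimeError):
    """ROC cut-off selection failed (degenerate scores or labels)."""


class AlignmentError(OctriageError, ValueError):
    """Predictions and truth refer to different site sets."""


class ConfigurationError(OctriageError, ValueError):
    """A pipeline stage is missing or inconsistently configured."""


class RegistrationError(OctriageError, ValueError):
    """An embedding backend violates its contract."""
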