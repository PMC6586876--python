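"""Exception hierarchy for the prepexec pipeline.

Every analytic failure mode gets its own class so that the pipeline can
convert them into auditable exclusion records instead of crashes.
"""


class PrepexecError(Exception):
    """Base class for all package errors."""


class SchemaError(PrepexecError):
    """A session bundle is missing a required field or group."""


class SessionValidationError(PrepexecError):
    """An in-memory session violates a structural invariant."""


class ArgumentError(PrepexecError):
    """An argument is outside its documented domain."""


class EmptySelectionError(PrepexecError):
    """A trial filter removed every trial."""


class DetectionError(PrepexecError):
    """Movement-onset detection failed (flat or truncated trajectory)."""


class BehaviorError(PrepexecError):
    """A behavioral quantity is undefined for this trial/condition."""


class FitError(PrepexecError):
    """A sigmoid fit did not converge or the data carry no transition."""


class DatasetExclusionError(PrepexecError):
    """The dataset fails an inclusion rule (e.g. too few units)."""


class TrainingError(PrepexecError):
    """Classifier training failed (e.g. a single class present)."""


class DimensionError(PrepexecError):
    """A dimensionality rule or subspace/session shape check failed."""


class OptimizationError(PrepexecError):
    """The subspace optimizer failed to converge on every start."""


class AlignmentError(PrepexecError):
    """Two traces do not share a time grid or alignment event."""


class StatisticsError(PrepexecError):
    """A statistical test's preconditions are not met."""
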