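"""Typed exceptions and warnings shared across the package.

Every validation failure raises one of these instead of a bare ValueError so
that callers (and tests) can distinguish a malformed file from a bad
parameter or a degenerate computation.
"""


class NeocouplingError(Exception):
    """Base class for all package errors."""


class FormatError(NeocouplingError):
    """A container or sidecar file is missing or structurally wrong."""


class CorruptionError(NeocouplingError):
    """File contents contradict their declared metadata (e.g. size mismatch)."""


class ValidationError(NeocouplingError):
    """Data violate a documented invariant (NaNs, unsorted times, ...)."""


class ParameterError(NeocouplingError, ValueError):
    """An argument is outside its documented domain."""


class LengthError(NeocouplingError):
    """Input is too short for the requested operation."""


class FitError(NeocouplingError):
    """A model fit failed (rank deficiency, singular covariance, ...)."""


class DetectionError(NeocouplingError):
    """An automatic detection step found no (or an ambiguous) answer.

    Carries a ``diagnostics`` attribute with the intermediate quantities the
    decision was based on, so failures can be inspected.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class QualityError(NeocouplingError):
    """Too much of the data failed internal quality checks to continue."""


class UndefinedValueError(NeocouplingError):
    """A ratio-type index is undefined (zero denominator)."""


class SampleSizeError(NeocouplingError):
    """A statistical routine received fewer observations than it requires."""


class ConfigError(NeocouplingError):
    """A configuration value is inconsistent or would produce invalid data."""


class StageError(NeocouplingError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class DegenerateSignalWarning(UserWarning):
    """Emitted when a signal is constant and phase is undefined."""


class UnstableModelWarning(UserWarning):
    """Emitted when a fitted autoregressive model is unstable."""
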