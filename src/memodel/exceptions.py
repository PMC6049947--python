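"""Exception hierarchy for memodel.

All package errors derive from :class:`MEModelError` so callers can catch a
single base class. Names mirror the failure they signal, not the module that
raises them.
"""


class MEModelError(Exception):
    """Base class for every error raised by memodel."""


class DomainError(MEModelError, ValueError):
    """A numeric argument is outside its mathematical domain (e.g. mu < 0)."""


class DuplicateIdError(MEModelError):
    """Two different records were registered under the same identifier."""


class InvalidCodonError(MEModelError):
    """A codon is ambiguous or not part of the configured codon table."""


class EmptySequenceError(MEModelError):
    """An operation requires a non-empty nucleotide sequence."""


class AlphabetError(MEModelError):
    """A sequence contains characters outside the expected alphabet."""


class UnlinkedDataError(MEModelError):
    """A reaction's required ProcessData link does not resolve."""


class UnknownMetaboliteError(MEModelError):
    """A small molecule referenced by a reaction is absent from the model."""


class ModeError(MEModelError):
    """The model is in the wrong coupling mode for the requested operation."""


class MissingGeneError(MEModelError):
    """A gene referenced by the build inputs is absent from the annotation."""


class UnbalancedReactionError(MEModelError):
    """A compiled reaction fails the elemental balance check."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or {}


class DanglingReferenceError(MEModelError):
    """Build inputs reference an entity that was never defined."""


class CompositionError(MEModelError):
    """An amino-acid composition is invalid (bad keys or fractions)."""


class SolverBackendError(MEModelError):
    """The LP backend failed numerically (distinct from true infeasibility)."""


class InfeasibleAtMinError(MEModelError):
    """The lower end of the growth-rate bracket is already infeasible."""


class NonConvergenceError(MEModelError):
    """Bisection hit its iteration cap before reaching the tolerance."""


class InfeasibleError(MEModelError):
    """The LP at the requested growth rate has no feasible flux state."""


class UnknownGeneError(MEModelError):
    """A knockout was requested for a gene the model does not contain."""


class EmptyMatrixError(MEModelError):
    """A confusion matrix with zero total has no defined metrics."""


class InsufficientDataError(MEModelError):
    """Too few shared entries to compute a comparison statistic."""


class ParameterError(MEModelError):
    """A generator or builder parameter is out of range."""


class SchemaVersionError(MEModelError):
    """A serialized model declares an unsupported schema major version."""


class ValidationError(MEModelError):
    """A serialized model failed validation; message carries a JSON pointer."""
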