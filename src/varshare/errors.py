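"""Exception hierarchy shared across the package."""


class VarShareError(Exception):
    """Base class for all package-specific errors."""


class NonVariantError(VarShareError):
    """Raised when ref and alt describe no change after trimming."""


class ReferenceMismatchError(VarShareError):
    """Raised when a variant's ref allele disagrees with the reference sequence."""


class OutsideTranscriptError(VarShareError):
    """Raised when a genomic position falls outside a transcript span."""


class NoCandidateTranscriptError(VarShareError):
    """Raised when a gene contributes no usable candidate transcript."""


class UnknownConsequenceError(VarShareError):
    """Raised when a consequence term is absent from the severity ranking."""


class SubmissionRejectedError(VarShareError):
    """All-or-nothing dataset rejection carrying row-level diagnostics."""

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class MetadataError(VarShareError):
    """Dataset metadata failed validation."""


class PseudonymSpaceExhaustedError(VarShareError):
    """The pseudonym namespace for a kind has no free codes left."""


class CohortTooSmallError(VarShareError):
    """Too few samples to define the outlier fences."""


class ManualReviewRequiredError(VarShareError):
    """A resolution situation the planner does not automate."""


class InfeasibleProfileError(VarShareError):
    """A fixture recipe with mutually inconsistent requested counts."""
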