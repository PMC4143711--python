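"""Exception hierarchy shared across the package."""


class FamrareError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(FamrareError):
    """Structural problem in a pedigree (unresolved parent, cycle, ...)."""


class FormatError(FamrareError):
    """Malformed input file (VCF without GT, ragged kinship TSV, ...)."""


class ValidationError(FamrareError):
    """Input values violate a documented precondition."""


class ParameterError(FamrareError):
    """Invalid user-supplied parameter (bounds, budgets, sizes)."""


class AlignmentError(FamrareError):
    """Sample identifiers disagree between inputs that must align."""


class DegenerateDesignError(FamrareError):
    """The case/control design is degenerate (all-case or all-control)."""


class InsufficientDataError(FamrareError):
    """Too little data for the requested summary (e.g. <3 complete genes)."""
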