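"""Exception hierarchy shared across the package."""


class PrsGxeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PrsGxeError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidInputError(PrsGxeError, ValueError):
    """An input table or array violates a precondition."""


class InvalidCategoryError(InvalidInputError):
    """A raw categorical measure contains an unknown label."""


class MissingVariantError(InvalidInputError):
    """Weight-table variants absent from the genotype matrix."""

    def __init__(self, missing):
        self.missing = list(missing)
        shown = ", ".join(self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"variants in weight table absent from genotypes: {shown}{more}")


class DegenerateScoreError(InvalidInputError):
    """Score vector has zero variance (cannot standardize or rank)."""


class DegenerateDesignError(PrsGxeError, ValueError):
    """Rank-deficient design matrix or an empty design cell."""

    def __init__(self, message, aliased=()):
        self.aliased = list(aliased)
        if self.aliased:
            message = f"{message}: aliased columns {self.aliased}"
        super().__init__(message)


class InsufficientDataError(PrsGxeError, ValueError):
    """Too few complete cases to fit the requested model."""


class SeparationError(PrsGxeError, ValueError):
    """Perfect separation in a logistic fit."""


class SearchFailedError(PrsGxeError, RuntimeError):
    """Every candidate cut-off in the grid search was skipped."""


class PipelineStageError(PrsGxeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
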