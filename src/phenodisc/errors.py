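"""Named exceptions raised across the pipeline."""


class PhenodiscError(Exception):
    """Base class for all pipeline errors."""


class UnreadableFileError(PhenodiscError):
    """The input file does not exist or cannot be parsed."""


class DuplicateColumnError(PhenodiscError):
    """Two columns share the same name after group-label stripping."""


class MissingDependentError(PhenodiscError):
    """No column matches the declared dependent variable."""


class GroupLabelError(PhenodiscError):
    """A column header carries a malformed group label."""


class DegenerateDependentError(PhenodiscError):
    """The dependent variable has fewer than two observed levels."""


class ZeroVarianceError(PhenodiscError):
    """A quantitative column has zero variance at the scaling stage."""


class EmptyStratumError(PhenodiscError):
    """A conditioning stratum has no observed values for a variable."""


class ImputationError(PhenodiscError):
    """Imputation preconditions violated (e.g. fewer complete cases than K)."""


class FactorError(PhenodiscError):
    """Mixed-data factor analysis cannot be run on the given input."""


class ConfigError(PhenodiscError):
    """Invalid run configuration."""


class ConvergenceError(PhenodiscError):
    """A classifier failed to converge within its iteration budget."""


class StageError(PhenodiscError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
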