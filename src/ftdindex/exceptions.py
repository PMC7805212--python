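"""Exception hierarchy for the ftdindex pipeline."""


class FTDIndexError(Exception):
    """Base class for all ftdindex errors."""


class InvalidInputError(FTDIndexError, ValueError):
    """A numeric input violates a physical precondition (e.g. ICV <= 0)."""


class SchemaError(FTDIndexError, ValueError):
    """Tabular input is missing a required column, structure or lobe."""


class ConfigError(FTDIndexError, ValueError):
    """A simulation or pipeline configuration is incomplete or inconsistent."""


class MatchingError(FTDIndexError, ValueError):
    """Subjects do not form complete matched NC/AD/FTD triplets."""

    def __init__(self, message: str, triplet_ids=()):
        super().__init__(message)
        self.triplet_ids = tuple(triplet_ids)


class NoSignalError(FTDIndexError, RuntimeError):
    """No measure differs between AD and FTD; the index cannot be fitted."""


class ZeroRangeError(FTDIndexError, ValueError):
    """A training measure column is constant, so min-max normalization is undefined."""


class ModelSchemaError(FTDIndexError, ValueError):
    """A persisted model document violates the model schema or its invariants."""


class UndefinedROCError(FTDIndexError, ValueError):
    """ROC analysis requested with only one class present."""


class IncompleteInputError(FTDIndexError, ValueError):
    """The decision rule reached a stage whose required input is missing."""


class PipelineStageError(FTDIndexError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
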