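"""Exception hierarchy for the logBB toolkit.

Every failure mode named in a module contract gets its own class so callers
can catch precisely; all inherit from :class:`LogBBError`.
"""


class LogBBError(Exception):
    """Base class for all toolkit errors."""


class SmilesParseError(LogBBError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class MissingColumnError(LogBBError):
    """A required column is absent from an input table."""


class EmptyDatasetError(LogBBError):
    """No usable records remain after parsing/filtering."""


class DegenerateInputError(LogBBError):
    """Input is degenerate for the requested statistic (e.g. constant vector)."""


class UnknownLearnerError(LogBBError):
    """Learner name not present in the registry."""


class SchemaError(LogBBError):
    """Feature matrix does not match the model's expected schema."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing required feature columns: {self.missing}")


class ModelFormatError(LogBBError):
    """Persisted model archive is unreadable or version-incompatible."""


class ConfigError(LogBBError):
    """Pipeline configuration violates the expected schema."""
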