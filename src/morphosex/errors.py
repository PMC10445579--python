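"""Exception hierarchy for the package."""


class MorphosexError(Exception):
    """Base class for all package-specific errors."""


class ScoreParseError(MorphosexError):
    """A rating or recorded-sex file violates the expected format.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TableLookupError(MorphosexError, KeyError):
    """An observer, cranium, or trait is not present in a table."""


class MissingScoreError(MorphosexError):
    """A discriminant function was evaluated with a required score absent."""


class DegenerateInputError(MorphosexError):
    """Too few raters or items for the requested statistic."""


class UndefinedStatisticError(MorphosexError):
    """The statistic's denominator vanishes for this input."""


class ConfigError(MorphosexError):
    """A synthetic-data configuration violates its invariants."""
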