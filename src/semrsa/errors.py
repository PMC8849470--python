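"""Exception types shared across the package."""


class SemRsaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SemRsaError):
    """A configuration value violates a precondition."""


class DegeneratePatternError(SemRsaError):
    """A pattern (or residual) has zero variance, so a correlation is undefined."""


class AlignmentError(SemRsaError):
    """Condition labels or grids of two objects do not match."""


class CollinearityError(SemRsaError):
    """A control design is rank deficient."""


class MissingWordError(SemRsaError, KeyError):
    """A requested word has no vector / norm / value."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class DependencyError(SemRsaError):
    """A pipeline stage is missing an upstream artifact."""
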