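"""Exception hierarchy for the microstates package."""


class MicrostatesError(Exception):
    """Base class for all package-specific errors."""


class InvalidDataError(MicrostatesError, ValueError):
    """Input data violates a precondition (non-finite values, bad shape...)."""


class MontageError(MicrostatesError, ValueError):
    """Montage is invalid or incompatible between operands."""


class UndefinedStatisticError(MicrostatesError, ValueError):
    """A statistic is undefined for this input (e.g. zero-variance map)."""


class GenerationError(MicrostatesError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class NumericalError(MicrostatesError, RuntimeError):
    """A numerical procedure failed (e.g. singular interpolation system)."""


class ConfigError(MicrostatesError, ValueError):
    """Run configuration is invalid; carries the full list of problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in self.problems))
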