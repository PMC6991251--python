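"""Exception types raised across the package."""


class ConfigError(ValueError):
    """A simulation or analysis configuration is invalid."""


class SchemaError(KeyError):
    """An input table is missing a required column."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return self.args[0] if self.args else ""


class InputError(ValueError):
    """Raw study data violate a precondition (negative days, overlaps, ...)."""


class SeparationError(RuntimeError):
    """A logistic fit is degenerate (constant response or perfect separation)."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


class EmptyStratumError(RuntimeError):
    """A (quarter, regimen) stratum needed for reporting has no at-risk weight."""
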