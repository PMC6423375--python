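"""Exception hierarchy shared across the package."""


class BoolcellError(Exception):
    """Base class for all package errors."""


class NetworkParseError(BoolcellError):
    """A network file is malformed or not in the declared dialect."""


class UnsupportedModelError(BoolcellError):
    """The model uses features outside the Boolean restriction (e.g. multivalued nodes)."""


class NetworkValidationError(BoolcellError):
    """A network or mutation profile violates a structural invariant."""


class RuleSyntaxError(BoolcellError):
    """A Boolean rule expression could not be parsed."""


class ConfigError(BoolcellError):
    """A simulation configuration is inconsistent or incomplete."""


class CapacityError(BoolcellError):
    """More cells requested than the lattice can hold."""


class StabilityError(BoolcellError):
    """An explicit diffusion step would violate the FTCS stability bound."""

    def __init__(self, alpha: float, alpha_max: float, suggested_substeps: int):
        self.alpha = alpha
        self.alpha_max = alpha_max
        self.suggested_substeps = suggested_substeps
        super().__init__(
            f"FTCS step unstable: alpha={alpha:.4g} exceeds the bound "
            f"{alpha_max:.4g}; split the step into at least "
            f"{suggested_substeps} substeps"
        )


class SizeError(BoolcellError):
    """Exhaustive enumeration refused because the state space is too large."""
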