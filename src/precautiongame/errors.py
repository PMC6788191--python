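"""Exception hierarchy for the liability-game package."""


class PrecautionGameError(Exception):
    """Base class for all package errors."""


class ParameterError(PrecautionGameError, ValueError):
    """A model parameter lies outside its admissible domain."""


class ConfigError(PrecautionGameError, ValueError):
    """A run-configuration file is malformed or out of domain."""


class InfeasibleGainsError(PrecautionGameError, ValueError):
    """A sign pattern of the corner net gains that no valid parameter set can produce.

    pi2 - pi1 = (1-a)p + b*cs >= 0 for every valid parameter set, so
    pi1 > 0 together with pi2 < 0 can only arise from hand-built,
    inconsistent gain values.
    """


class DegenerateEquilibriumError(PrecautionGameError, ZeroDivisionError):
    """A denominator of the interior-equilibrium formula vanishes."""


class NumericalError(PrecautionGameError, RuntimeError):
    """Numerical integration produced a non-finite state or failed to step."""
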