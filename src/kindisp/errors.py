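"""Exception hierarchy shared across the package."""


class KindispError(Exception):
    """Base class for all package-specific errors."""

    category = "error"


class DomainError(KindispError, ValueError):
    """A parameter lies outside its mathematical domain."""

    category = "domain"


class DegenerateError(KindispError, ZeroDivisionError):
    """A formula denominator vanishes for the supplied parameters."""

    category = "degenerate"


class ConsistencyError(KindispError, ArithmeticError):
    """Two algebraically equivalent forms disagree beyond tolerance."""

    category = "consistency"


class ExtinctionError(KindispError, RuntimeError):
    """The simulated population lost all juveniles in one generation."""

    category = "extinction"


class ConfigError(KindispError, ValueError):
    """A configuration file failed to parse or validate."""

    category = "config"


class InconclusiveBracketError(KindispError, RuntimeError):
    """Bisection endpoints classify in the same selection direction."""

    category = "inconclusive-bracket"
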