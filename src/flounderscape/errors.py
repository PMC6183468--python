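"""Exception types shared across the package."""


class FlounderscapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FlounderscapeError, ValueError):
    """A model or configuration parameter is outside its valid range."""


class NoCoalescenceError(FlounderscapeError, RuntimeError):
    """A genealogy could not reach a common ancestor.

    Raised when the structured coalescent has zero total event rate
    (isolated lineages in separate demes with no migration) or when the
    configured maximum time is exceeded.
    """


class SimulationFailureError(FlounderscapeError, RuntimeError):
    """Locus re-simulation exhausted its attempt budget.

    Carries the realized acceptance rate so the caller can diagnose an
    over-strict minor-allele-frequency cutoff for the sample size.
    """

    def __init__(self, message: str, acceptance_rate: float | None = None):
        super().__init__(message)
        self.acceptance_rate = acceptance_rate


class EmptyResultError(FlounderscapeError, ValueError):
    """A filtering step removed every individual or every locus."""


class UndefinedDistanceError(FlounderscapeError, ZeroDivisionError):
    """A genetic distance is undefined (e.g. all individuals homozygous)."""


class VcfParseError(FlounderscapeError, ValueError):
    """A VCF file could not be parsed; reports the offending line."""
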