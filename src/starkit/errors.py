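"""Exception hierarchy shared across the package."""


class StarkitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StarkitError, ValueError):
    """A model/noise/design parameter violates its invariant.

    ``field`` names the offending parameter.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class IntegrationError(StarkitError, RuntimeError):
    """ODE integration produced a non-finite state or failed to converge."""


class CircuitError(StarkitError, ValueError):
    """Invalid circuit topology or unresolvable reference."""


class PlateError(StarkitError, ValueError):
    """Plate dataset violates the layout/role contract."""


class UndefinedStatisticError(StarkitError, ValueError):
    """A requested statistic is undefined for the given data (zero variance,
    non-positive denominator, degenerate design)."""


class IdentifiabilityError(StarkitError, ValueError):
    """Requested free-parameter subset is not identifiable from the design."""


class AssemblyError(StarkitError, ValueError):
    """Part validation or junction overhang failure during assembly."""
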