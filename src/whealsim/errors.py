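"""Exception types shared across the package."""


class WhealSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WhealSimError):
    """A solver or run configuration violates a stability or validity constraint."""


class InstabilityError(WhealSimError):
    """The explicit integration produced NaN or negative concentrations."""


class AnalysisNotApplicableError(WhealSimError):
    """An analytic result (e.g. the wave-speed bound) requires an equilibrium
    that does not exist for the given parameters."""


class NeverDevelopsError(WhealSimError):
    """Wheals cannot develop for these kinetics (release rate below decay rate),
    so a minimal stimulus threshold does not exist."""


class BracketFailureError(WhealSimError):
    """A bisection bracket could not be established."""


class WhealAbsentError(WhealSimError):
    """The point-source solution is below the wheal threshold everywhere at the
    requested time."""


class UnidentifiablePairError(WhealSimError):
    """A pair of dose series carries no information about the diffusion
    coefficient (degenerate pairwise equation)."""


class EstimationError(WhealSimError):
    """No dose pair yielded a diffusion-coefficient estimate."""


class EmptyTraceError(WhealSimError):
    """No threshold crossing was found in any snapshot of a trajectory."""
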