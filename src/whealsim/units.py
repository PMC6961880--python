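"""Conversions between dimensional and dimensionless model quantities.

The simulation runs on the unit square with unit time; physically this
corresponds to a 27.4 cm x 27.4 cm patch of skin and a 250 s time unit.
Only length, time and speed are converted — the printed dimensional rate
constants are not used because their ratios to the dimensionless column are
mutually inconsistent, so a single rate scaling cannot reproduce them.
Concentration enters through the injection dose scaling ``u_nd`` (ml/ug).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScaleSet",
    "TABLE_SCALES",
    "diffusion_to_dimensionless",
    "diffusion_to_dimensional",
    "diffusion_unit_convert",
    "speed_to_dimensional",
    "conc_scale_from_injection",
]


@dataclass(frozen=True)
class ScaleSet:
    """Physical scales of the dimensionless model.

    Attributes
    ----------
    length_cm
        Edge length L of the square simulation domain, in cm.
    time_s
        Duration T of one dimensionless time unit, in seconds.
    conc_scale
        Concentration normalization u_nd in ml/ug (dimensionless dose =
        u_nd x dose in ug/ml).
    """

    length_cm: float = 27.4
    time_s: float = 250.0
    conc_scale: float = 0.03

    def __post_init__(self) -> None:
        for name in ("length_cm", "time_s", "conc_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: The scales of the reference simulations.
TABLE_SCALES = ScaleSet()

# exact unit algebra: factors to cm^2/sec
_DIFF_FACTORS = {
    "cm2/s": 1.0,
    "cm2/sec": 1.0,
    "mm2/s": 1e-2,
    "mm2/sec": 1e-2,
    "mm2/min": 1e-2 / 60.0,
}


def diffusion_to_dimensionless(d_dim: float, s: ScaleSet = TABLE_SCALES) -> float:
    """Convert a diffusivity in cm^2/sec to model units: ``d * T / L^2``."""
    if d_dim <= 0:
        raise ValueError("diffusivity must be positive")
    return d_dim * s.time_s / s.length_cm**2


def diffusion_to_dimensional(d_nd: float, s: ScaleSet = TABLE_SCALES) -> float:
    """Inverse of :func:`diffusion_to_dimensionless` (returns cm^2/sec)."""
    if d_nd <= 0:
        raise ValueError("diffusivity must be positive")
    return d_nd * s.length_cm**2 / s.time_s


def diffusion_unit_convert(d: float, from_units: str, to_units: str) -> float:
    """Exact unit conversion between cm2/s, mm2/s and mm2/min."""
    try:
        f = _DIFF_FACTORS[from_units]
    except KeyError:
        raise ValueError(f"unknown diffusivity unit {from_units!r}") from None
    try:
        t = _DIFF_FACTORS[to_units]
    except KeyError:
        raise ValueError(f"unknown diffusivity unit {to_units!r}") from None
    return d * f / t


def speed_to_dimensional(c_nd: float, s: ScaleSet = TABLE_SCALES) -> float:
    """Convert a dimensionless front speed to mm/hr.

    One length unit is ``10 * length_cm`` millimetres and one time unit is
    ``time_s / 3600`` hours.
    """
    if c_nd < 0:
        raise ValueError("speed must be >= 0")
    return c_nd * (10.0 * s.length_cm) * 3600.0 / s.time_s


def conc_scale_from_injection(u0_nd: float, dose: float) -> float:
    """Concentration scale u_nd = u0 / dose (ml/ug) from an injection.

    ``u0_nd`` is the dimensionless initial amount used in the point-source
    model and ``dose`` the injected concentration in ug/ml.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    return u0_nd / dose
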