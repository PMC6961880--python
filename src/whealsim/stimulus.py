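"""Initial stimulus fields and the minimal developing stimulus P_min.

The initial condition perturbs the resting histamine state ``u0*`` by a
mixture of per-cell uniform random noise ``phi`` and a smooth cosine weight
``psi`` fixing the large-scale spatial distribution of the stimulus::

    u(x, 0) = u0* + r (phi(x) + s psi(x)) / (1 + s)
    psi(x)  = (cos(n pi x / L) cos(m pi y / L) + 1) / 2

``r`` is the maximal perturbation amplitude (stimulus size), ``s`` the
weight strength; ``s = 0`` gives pure noise and ``s -> inf`` the
deterministic weight.  Stimulus strength is reported as the percentage
``P_r = 100 r / c_max`` of a reference histamine concentration, and
``P_min`` is the smallest strength at which a wheal develops, located by
bisection on ``r`` at a fixed random seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rdsolver
from .errors import BracketFailureError, NeverDevelopsError
from .kinetics import KineticParams, equilibria, no_pattern_condition
from .rdsolver import SolverConfig, WhealParams

__all__ = [
    "StimulusSpec",
    "weight_field",
    "initial_condition",
    "radial_bump",
    "stimulus_strength",
    "develops",
    "find_p_min",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Perturbation magnitude ``r``, weight strength ``s``, cosine mode
    numbers ``(n, m)`` and the RNG seed for the noise field."""

    r: float
    s: float = 0.0
    n: int = 0
    m: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 0 or self.s < 0:
            raise ValueError("r and s must be >= 0")
        if self.n < 0 or self.m < 0 or self.n != int(self.n) or self.m != int(self.m):
            raise ValueError("n and m must be nonnegative integers")


def weight_field(n: int, m: int, grid: tuple[np.ndarray, np.ndarray],
                 length: float = 1.0) -> np.ndarray:
    """Cosine weight psi on [0, L]^2, pointwise in [0, 1]; psi(0, 0) = 1."""
    x, y = grid
    return (np.cos(n * np.pi * np.asarray(x) / length)
            * np.cos(m * np.pi * np.asarray(y) / length) + 1.0) / 2.0


def initial_condition(u0_star: float, spec: StimulusSpec,
                      grid: tuple[np.ndarray, np.ndarray],
                      length: float = 1.0) -> np.ndarray:
    """Perturbed initial field; values lie in [u0*, u0* + r].

    The noise field phi is i.i.d. uniform[0, 1) per grid cell from
    ``spec.seed`` (the field is therefore resolution-dependent; the seed and
    grid size identify it exactly).
    """
    x, _ = grid
    rng = np.random.default_rng(spec.seed)
    phi = rng.random(np.shape(x))
    psi = weight_field(spec.n, spec.m, grid, length)
    return u0_star + spec.r * (phi + spec.s * psi) / (1.0 + spec.s)


def radial_bump(u0_star: float, amplitude: float, width: float,
                r: np.ndarray) -> np.ndarray:
    """Gaussian stimulus centred at the origin of a radial grid."""
    r = np.asarray(r, dtype=float)
    return u0_star + amplitude * np.exp(-((r / width) ** 2))


def stimulus_strength(r: float, c_max: float = 1.0) -> float:
    """Stimulus strength P_r = 100 r / c_max (percent)."""
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    return 100.0 * r / c_max


def develops(p: KineticParams, spec: StimulusSpec, wp: WhealParams,
             cfg: SolverConfig, t_burn: float = 1.0,
             u0_star: float | None = None) -> bool:
    """Whether the stimulus triggers a wheal.

    A wheal "develops" when the spatial maximum of ``u`` exceeds the wheal
    threshold ``u_r`` at any time in ``(t_burn, t_end]``; the burn-in skips
    the initial transient, during which the perturbation itself may sit
    above threshold.
    """
    if u0_star is None:
        eq = equilibria(p, chi=1)
        u0_star = eq.u0_star if eq.u0_star is not None else 0.0
    grid = rdsolver.grid_2d(cfg)
    u0 = initial_condition(u0_star, spec, grid, cfg.length)
    dt = cfg.dt if cfg.dt is not None else rdsolver.stable_dt(p, cfg)
    state = rdsolver.make_state(u0, wp)
    n_steps = int(round(cfg.t_end / dt))
    check_every = max(1, int(round(0.1 / dt)))
    for k in range(1, n_steps + 1):
        rdsolver._step_raw(state, p, cfg, wp, dt, update_wheal=False)
        if state.t > t_burn and k % check_every == 0:
            if state.u.max() > wp.u_r:
                return True
    return state.t > t_burn and state.u.max() > wp.u_r


def find_p_min(p: KineticParams, spec: StimulusSpec, wp: WhealParams,
               cfg: SolverConfig, c_max: float = 1.0, r_hi: float = 2.0,
               rtol: float = 0.01, t_burn: float = 1.0) -> float:
    """Minimal stimulus strength P_min (percent) at which a wheal develops.

    Bisection on the perturbation amplitude ``r`` at a fixed seed, so the
    map r -> develops is deterministic; the result is the midpoint of the
    final bracket, converted via :func:`stimulus_strength`.  ``spec.r`` is
    ignored (the template fixes s, n, m and the seed).

    Raises
    ------
    NeverDevelopsError
        When ``gamma - alpha0 < 0``: no stimulus can ignite release.
    BracketFailureError
        When even ``r_hi`` fails to develop a wheal.

    Notes
    -----
    When the kinetics have no positive equilibrium at all (e.g. no
    inhibition, ``alpha2 = 0``, with ``gamma > alpha0``) the base state
    already grows without bound and P_min is 0.
    """
    if no_pattern_condition(p):
        raise NeverDevelopsError(
            f"gamma - alpha0 = {p.gamma - p.alpha0:g} < 0: wheals never develop"
        )
    eq = equilibria(p, chi=1)
    if eq.u0_star is None:
        # unbounded kinetics: any stimulus (even none) develops
        return 0.0

    def dev(r: float) -> bool:
        s = StimulusSpec(r=r, s=spec.s, n=spec.n, m=spec.m, seed=spec.seed)
        return develops(p, s, wp, cfg, t_burn=t_burn, u0_star=eq.u0_star)

    if not dev(r_hi):
        raise BracketFailureError(
            f"no wheal develops even at r_hi={r_hi:g}; increase r_hi or t_end"
        )
    lo, hi = 0.0, r_hi
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if dev(mid):
            hi = mid
        else:
            lo = mid
    return stimulus_strength(0.5 * (lo + hi), c_max)
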