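"""Space-free histamine kinetics of the wheal model.

A single field ``u`` represents extracellular histamine released by dermal
mast cells.  The local reaction rate combines four processes:

* **store-limited self-activation** ``chi * gamma * u`` — histamine triggers
  further release from nearby mast cells at rate ``gamma``; the indicator
  ``chi`` drops to 0 once a cell's finite granule store is exhausted,
* **bell-shaped self-inhibition** ``alpha2 * u / (alpha1 + u**2)`` — an
  inhibitory loop that is strongest at intermediate concentrations
  (peak at ``u = sqrt(alpha1)``, maximal level set by ``alpha2``),
* **basal secretion** ``mu``,
* **first-order decay** ``alpha0 * u``.

With ``chi = 1`` the equilibria of ``R(u) = 0`` are the nonnegative real
roots of the cubic::

    (gamma - alpha0) u^3 + mu u^2 + ((gamma - alpha0) alpha1 - alpha2) u
        + mu alpha1 = 0

For the reference parameter regime the kinetics are excitable: a small
stable resting state ``u0*`` coexists with an unstable ignition threshold
``ul*``; pushing ``u`` above ``ul*`` triggers runaway release that is only
terminated by store depletion.  All quantities here are dimensionless; see
:mod:`whealsim.units` for the physical scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisNotApplicableError

__all__ = [
    "KineticParams",
    "EquilibriumSet",
    "SET_I",
    "reaction_rate",
    "reaction_jacobian",
    "equilibria",
    "no_pattern_condition",
    "wave_speed_bound",
]

#: tolerance below which a residual counts as an equilibrium (dimensionless)
ROOT_TOL = 1e-8
#: imaginary parts below this are treated as numerical noise of real roots
IMAG_TOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the histamine reaction-diffusion model.

    All values are dimensionless.  Defaults are the reference set used for
    the representative simulations ("Set I").

    Parameters
    ----------
    gamma
        Histamine release rate of the self-activation loop.
    alpha0
        Basal first-order decay rate.
    alpha1
        Concentration parameter of the inhibition loop; the inhibitory
        effect peaks at ``u = sqrt(alpha1)``.
    alpha2
        Maximal level of the inhibition loop.
    mu
        Basal secretion rate.
    u_tot
        Total histamine store per mast cell (concentration x time); once the
        cumulative release exceeds this the cell stops releasing.
    d_u
        Diffusion coefficient (length^2 / time in dimensionless units).
    """

    gamma: float = 4.0
    alpha0: float = 0.7
    alpha1: float = 0.4
    alpha2: float = 4.5
    mu: float = 1.5
    u_tot: float = 150.0
    d_u: float = 4.7e-6

    def __post_init__(self) -> None:
        for name in ("gamma", "alpha0", "alpha1", "alpha2", "mu", "u_tot", "d_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.alpha2 > 0 and self.alpha1 <= 0:
            raise ValueError(
                "alpha1 must be > 0 when alpha2 > 0 (inhibition term must be "
                "finite at u = 0)"
            )


#: Reference ("Set I") dimensionless parameters.
SET_I = KineticParams()


@dataclass(frozen=True)
class EquilibriumSet:
    """Nonnegative equilibria of the space-free kinetics, sorted ascending.

    Attributes
    ----------
    roots
        All nonnegative real roots of the reaction rate.
    stability
        Per-root label, ``"stable"`` or ``"unstable"``, from the sign of
        dR/du at the root (non-positive slope counts as stable).
    u0_star
        Minimal strictly positive equilibrium (the resting state), or None.
    ul_star
        Smallest unstable equilibrium above ``u0_star`` (the ignition
        threshold), or None if the kinetics are not excitable.
    """

    roots: tuple[float, ...]
    stability: tuple[str, ...]
    u0_star: float | None = field(default=None)
    ul_star: float | None = field(default=None)


def reaction_rate(u, chi, p: KineticParams):
    """Reaction rate R(u) = chi*gamma*u - alpha2*u/(alpha1+u^2) + mu - alpha0*u.

    ``u`` may be a scalar or array; ``chi`` is 0/1 (scalar or array).
    Negative concentrations are a domain error.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("histamine concentration u must be >= 0")
    if p.alpha2 == 0.0:
        inhib = np.zeros_like(u)
    else:
        inhib = p.alpha2 * u / (p.alpha1 + u * u)
    out = np.asarray(chi, dtype=float) * p.gamma * u - inhib + p.mu - p.alpha0 * u
    return out if out.ndim else float(out)


def reaction_jacobian(u, chi, p: KineticParams):
    """dR/du.  The inhibition term contributes -alpha2*(alpha1-u^2)/(alpha1+u^2)^2."""
    u = np.asarray(u, dtype=float)
    if p.alpha2 == 0.0:
        dinhib = np.zeros_like(u)
    else:
        dinhib = p.alpha2 * (p.alpha1 - u * u) / (p.alpha1 + u * u) ** 2
    out = np.asarray(chi, dtype=float) * p.gamma - dinhib - p.alpha0
    return out if out.ndim else float(out)


def equilibria(p: KineticParams, chi: int = 1, tol: float = ROOT_TOL) -> EquilibriumSet:
    """All nonnegative real equilibria of the space-free kinetics.

    With ``chi = 1`` the equilibria are roots of the cubic above; with
    ``chi = 0`` (stores exhausted) the same cubic with ``gamma`` replaced by
    zero.  Roots are found from the polynomial companion matrix and filtered
    to real nonnegative values; stability follows the sign of dR/du.

    An empty root list is returned when no nonnegative equilibrium exists
    (e.g. ``alpha2 = 0`` with ``gamma > alpha0`` and ``mu > 0``: the rate is
    positive for all u >= 0).
    """
    if chi not in (0, 1):
        raise ValueError("chi must be 0 or 1")
    g = chi * p.gamma
    coeffs = np.array(
        [g - p.alpha0, p.mu, (g - p.alpha0) * p.alpha1 - p.alpha2, p.mu * p.alpha1]
    )
    nz = np.nonzero(np.abs(coeffs) > 0)[0]
    if len(nz) == 0:
        # rate identically zero: every u is a (marginal) equilibrium;
        # report the origin and label it stable by the <=0 slope convention
        return EquilibriumSet(roots=(0.0,), stability=("stable",), u0_star=None)
    coeffs = coeffs[nz[0]:]
    if len(coeffs) == 1:
        raw = np.array([])
    else:
        raw = np.roots(coeffs)
    roots: list[float] = []
    for z in raw:
        if abs(z.imag) > IMAG_TOL:
            continue
        x = float(z.real)
        if x < -IMAG_TOL:
            continue
        x = max(x, 0.0)
        if abs(reaction_rate(x, chi, p)) > max(tol, 1e-12 * max(1.0, abs(x))) * 10:
            # companion-matrix roots are accurate well below ROOT_TOL for
            # these low-order polynomials; this guards pathological scaling
            continue
        if not any(abs(x - r) < 1e-9 for r in roots):
            roots.append(x)
    roots.sort()
    stability = tuple(
        "stable" if reaction_jacobian(r, chi, p) <= 0 else "unstable" for r in roots
    )
    positive = [r for r in roots if r > 1e-12]
    u0_star = positive[0] if positive else None
    ul_star = None
    if u0_star is not None:
        for r, s in zip(roots, stability):
            if r > u0_star and s == "unstable":
                ul_star = r
                break
    return EquilibriumSet(
        roots=tuple(roots), stability=stability, u0_star=u0_star, ul_star=ul_star
    )


def no_pattern_condition(p: KineticParams) -> bool:
    """True iff wheal emergence is impossible regardless of stimulus.

    This is the strict condition ``gamma - alpha0 < 0``: the self-activation
    loop cannot outpace basal decay, so no stimulus can ignite runaway
    release.  It includes the activation-absent case ``gamma = 0``.
    """
    return p.gamma - p.alpha0 < 0


def wave_speed_bound(p: KineticParams, ul_star: float | None = None) -> float | None:
    """Linear-spreading lower bound on the traveling-front speed.

    ``c_min = 2 sqrt(D_u (gamma - alpha2 (alpha1 - ul*^2)/(alpha1 + ul*^2)^2
    - alpha0))`` — twice the geometric mean of diffusivity and the kinetic
    growth rate linearized at the unstable equilibrium ``ul*``.  The bound
    is monotone increasing in ``gamma`` and decreasing in ``alpha0``.

    Parameters
    ----------
    ul_star
        Evaluation point; computed from :func:`equilibria` when omitted.

    Returns
    -------
    float or None
        The bound, or None when the bracketed term is negative (no positive
        bound exists).

    Raises
    ------
    AnalysisNotApplicableError
        If ``ul_star`` is omitted and the kinetics have no unstable
        equilibrium above the resting state.
    """
    if ul_star is None:
        eq = equilibria(p, chi=1)
        ul_star = eq.ul_star
        if ul_star is None:
            raise AnalysisNotApplicableError(
                "no unstable equilibrium ul* exists for these parameters; "
                "pass ul_star explicitly to evaluate the formula elsewhere"
            )
    radicand = p.d_u * reaction_jacobian(ul_star, 1, p)
    if radicand < 0:
        return None
    return 2.0 * float(np.sqrt(radicand))
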