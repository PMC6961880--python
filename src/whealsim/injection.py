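"""Intradermal-injection analytics: point-source diffusion and D estimation.

A histamine bolus injected into the dermis disperses by diffusion alone
(self-activation and -inhibition are negligible for a localized stimulus),
so the concentration follows the 2-D point-source solution

    u(r, t) = u0 / (4 pi D t) * exp(-r^2 / (4 D t)),

and the visible wheal edge is the radius where ``u`` crosses the wheal
threshold ``u_r``:

    r*(t) = sqrt(4 D t log(u0 / (4 pi D u_r t)))          (+ r0 with offset)

``r*`` rises, peaks at ``t* = u0 / (4 pi D u_r e)`` with value
``2 sqrt(D t*)``, and would then recede; the measured wheal radius includes
the initial bleb radius ``r0`` set by the injected volume.

The diffusion coefficient is estimated from three doses by (A) fitting each
radius time course with the saturating exponential
``Y = Y0 + (P - Y0)(1 - exp(-alpha t))``, (B) locating the stopping time
``t*`` where the fitted expansion speed drops below ``epsilon`` and the
radius ``r*max`` there, and (C) solving, for each dose pair, the condition
that the point-source concentration at ``(r*max - r0, t*)`` is the same
threshold ``u_r`` for both doses — a one-dimensional root-finding problem
in D.  The per-dose estimates are averaged.

A fixture generator stands in for clinical time series: it produces
saturating radius curves that follow the threshold-radius law up to each
dose's own maximum and plateau there (wheals persist once expanded; skin
recovery is much slower than histamine decay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import EstimationError, UnidentifiablePairError, WhealAbsentError

__all__ = [
    "InjectionModel",
    "S2_MODEL",
    "DoseSeries",
    "SaturatingFit",
    "EstimationResult",
    "gaussian_solution",
    "threshold_radius",
    "time_of_max_radius",
    "expansion_velocity",
    "mean_initial_velocity",
    "fit_saturating",
    "extract_tstar_rmax",
    "estimate_diffusion",
    "make_fixtures",
    "read_dose_series_csv",
    "write_dose_series_csv",
]


@dataclass(frozen=True)
class InjectionModel:
    """Point-source model parameters.

    ``u0``: scaled initial dose (dimensionless, u_nd x dose in ug/ml);
    ``d``: diffusion coefficient in mm^2/min; ``u_r``: wheal threshold
    (same scale as u0); ``r0``: initial wheal (bleb) radius in mm.
    """

    u0: float = 0.3
    d: float = 0.08474977
    u_r: float = 0.003748
    r0: float = 3.20875

    def __post_init__(self) -> None:
        if self.u0 <= 0 or self.d <= 0 or self.u_r <= 0:
            raise ValueError("u0, d and u_r must be positive")
        if self.r0 < 0:
            raise ValueError("r0 must be >= 0")


#: The printed fit of the 10 ug/ml injection experiment.
S2_MODEL = InjectionModel()


def gaussian_solution(r, t: float, m: InjectionModel):
    """Point-source concentration u(r, t); integrates to u0 over the plane."""
    if t <= 0:
        raise ValueError("t must be positive")
    r = np.asarray(r, dtype=float)
    out = m.u0 / (4.0 * np.pi * m.d * t) * np.exp(-(r * r) / (4.0 * m.d * t))
    return out if out.ndim else float(out)


def _log_radicand(t, m: InjectionModel):
    return np.log(m.u0 / (4.0 * np.pi * m.d * m.u_r * np.asarray(t, dtype=float)))


def threshold_radius(t, m: InjectionModel, offset: bool = True):
    """Radius where the point-source solution equals the wheal threshold.

    ``r*(t) = sqrt(4 D t log(u0 / (4 pi D u_r t)))``, plus ``r0`` when
    ``offset`` is true.  For scalar ``t`` outside the wheal-visible window
    (non-positive radicand) :class:`WhealAbsentError` is raised; for array
    input those entries are NaN.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    rad = 4.0 * m.d * t * _log_radicand(t, m)
    if scalar and rad <= 0:
        raise WhealAbsentError(f"wheal absent at t={float(t):g} min")
    with np.errstate(invalid="ignore"):
        core = np.sqrt(np.where(rad > 0, rad, np.nan))
    out = core + (m.r0 if offset else 0.0)
    return float(out) if scalar else out


def time_of_max_radius(m: InjectionModel) -> float:
    """Maximizer t* = u0 / (4 pi D u_r e) of the threshold radius (min)."""
    return m.u0 / (4.0 * np.pi * m.d * m.u_r * np.e)


def expansion_velocity(t, m: InjectionModel):
    """Analytic d r*/dt = 2 D (log-term - 1) / (r* - r0), in mm/min.

    Monotone decreasing over the early window, zero at ``t*``, and only
    defined inside the wheal-visible window (scalar input outside raises
    :class:`WhealAbsentError`).
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    core = threshold_radius(t, m, offset=False)
    ell = _log_radicand(t, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = 2.0 * m.d * (ell - 1.0) / np.asarray(core, dtype=float)
    return float(v) if scalar else v


def mean_initial_velocity(m: InjectionModel, window_min: float = 15.0) -> float:
    """Mean expansion velocity over the first ``window_min`` minutes.

    Since the radius starts at ``r0`` (the core -> 0 as t -> 0), this is
    ``(r*(T) - r0) / T`` in mm/min.
    """
    return threshold_radius(window_min, m, offset=False) / window_min


# --------------------------------------------------------------------------
# dose series, fitting and extraction

@dataclass(frozen=True)
class SaturatingFit:
    """Parameters of Y = Y0 + (P - Y0)(1 - exp(-alpha t)) plus diagnostics."""

    y0: float
    p: float
    alpha: float
    residual_norm: float
    alpha_identifiable: bool = True

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.y0 + (self.p - self.y0) * (1.0 - np.exp(-self.alpha * t))
        return out if out.ndim else float(out)

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        out = self.alpha * (self.p - self.y0) * np.exp(-self.alpha * t)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseSeries:
    """One injection time course: dose (ug/ml), times (min), radii (mm).

    ``r0`` is the measured initial wheal radius (the bleb made by the
    injected volume) — a direct observation, not a fitted quantity.
    """

    dose: float
    times: np.ndarray
    radii: np.ndarray
    r0: float
    fit: SaturatingFit | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "radii", r)
        if t.shape != r.shape:
            raise ValueError("times and radii must have the same shape")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("radii must be >= 0")

    def fitted(self) -> "DoseSeries":
        return self if self.fit is not None else replace(
            self, fit=fit_saturating(self.times, self.radii))


def fit_saturating(times, radii) -> SaturatingFit:
    """Nonlinear least-squares fit of the saturating exponential.

    Constant series are returned as ``P = Y0 = const`` with ``alpha``
    flagged unidentifiable.  Non-convergence raises with diagnostics.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(radii, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit the saturating curve")
    if np.ptp(r) < 1e-12:
        return SaturatingFit(float(r[0]), float(r[0]), np.nan, 0.0,
                             alpha_identifiable=False)

    def f(tt, y0, p, a):
        return y0 + (p - y0) * (1.0 - np.exp(-a * tt))

    p0 = (float(r[0]), float(r.max()), 0.15)
    try:
        popt, _ = curve_fit(
            f, t, r, p0=p0,
            bounds=([0.0, 0.0, 1e-4], [np.inf, np.inf, 10.0]),
            maxfev=50000,
        )
    except RuntimeError as exc:
        raise EstimationError(
            f"saturating fit failed to converge (n={len(t)}, "
            f"radius range {r.min():.3g}..{r.max():.3g}): {exc}"
        ) from exc
    resid = float(np.linalg.norm(r - f(t, *popt)))
    return SaturatingFit(float(popt[0]), float(popt[1]), float(popt[2]), resid)


def extract_tstar_rmax(series: DoseSeries, epsilon: float = 0.005,
                       clip_to_window: bool = False,
                       r_from: str = "fit") -> tuple[float, float]:
    """Stopping time t* and maximal radius r*max of a fitted series.

    ``t*`` is the first time the fitted curve's expansion speed drops to
    ``epsilon`` (mm/min); since the derivative is ``alpha (P - Y0)
    exp(-alpha t)``, the closed form is ``t* = log(alpha (P - Y0) /
    epsilon) / alpha``.  ``r*max`` is the fitted curve at ``t*``
    (``r_from="fit"``) or the observed series read there (``r_from="data"``:
    the fitted value corrected by the mean data-minus-fit residual within
    +-2.5 min of ``t*``, which tracks the observed curve while averaging
    measurement noise).  With ``clip_to_window`` the stopping time is
    clamped into the observed time range — the variant used inside
    :func:`estimate_diffusion`, where extrapolating beyond the observation
    window is not meaningful.

    A boundary case ``epsilon >= alpha (P - Y0)`` (the curve never expands
    faster than epsilon) yields ``t* = 0`` with a warning.
    """
    series = series.fitted()
    fit = series.fit
    assert fit is not None
    if not fit.alpha_identifiable:
        warnings.warn("constant series: t* undefined, returning t*=0")
        tstar = 0.0
    else:
        v0 = fit.alpha * (fit.p - fit.y0)
        if v0 <= epsilon:
            warnings.warn(
                f"initial fitted speed {v0:.3g} <= epsilon={epsilon:g}; "
                "t* clamped to 0"
            )
            tstar = 0.0
        else:
            tstar = float(np.log(v0 / epsilon) / fit.alpha)
    if clip_to_window:
        tstar = float(np.clip(tstar, series.times[0], series.times[-1]))
    if r_from == "fit":
        rmax = float(fit(tstar))
    elif r_from == "data":
        resid = series.radii - fit(series.times)
        near = np.abs(series.times - tstar) <= 2.5
        corr = resid[near].mean() if near.any() else \
            np.interp(tstar, series.times, resid)
        rmax = float(fit(tstar)) + float(corr)
    else:
        raise ValueError("r_from must be 'fit' or 'data'")
    return tstar, rmax


@dataclass(frozen=True)
class EstimationResult:
    """Three-dose diffusion estimate.

    ``t_star``/``r_max`` per dose; ``d_pairwise`` maps dose pairs to the D
    solving that pair's threshold equality (NaN where the pair failed);
    ``d_mean`` is the mean of the successful pairs, in mm^2/min.
    """

    t_star: dict[float, float]
    r_max: dict[float, float]
    d_pairwise: dict[tuple[float, float], float]
    d_mean: float


def _pair_mismatch(d: float, u0_i, t_i, r_i, u0_j, t_j, r_j) -> float:
    # log u(r_i, t_i; d) - log u(r_j, t_j; d) for the point-source solution
    return (np.log(u0_i / t_i) - r_i**2 / (4.0 * d * t_i)) \
        - (np.log(u0_j / t_j) - r_j**2 / (4.0 * d * t_j))


def estimate_diffusion(series_by_dose: dict[float, DoseSeries],
                       epsilon: float = 0.005, u_nd: float = 0.03,
                       shared_r: bool = False,
                       bracket: tuple[float, float] = (1e-4, 10.0),
                       subtract_r0: bool = True) -> EstimationResult:
    """Estimate the histamine diffusion coefficient from dose series.

    For each dose the stopping point ``(t*, r*max)`` is extracted (t*
    clipped to the observation window, r*max read off the observed series),
    the initial bleb radius ``r0`` subtracted, and for every dose pair the
    equality of threshold concentrations ``u(r_i, t_i; D) = u(r_j, t_j; D)``
    (dose scaling ``u0 = u_nd x dose``) is solved for D by bracketed
    root-finding.  ``shared_r=True`` reproduces the variant where a single
    radius (the mean of the pair) enters both sides.

    Pairs without a sign change in the bracket are skipped with a warning;
    a pair with identical (t*, r*) carries no information and is skipped as
    unidentifiable.  All pairs failing raises :class:`EstimationError`.
    """
    doses = sorted(series_by_dose)
    if len(doses) < 2:
        raise ValueError("need at least two doses")
    t_star: dict[float, float] = {}
    r_max: dict[float, float] = {}
    r_core: dict[float, float] = {}
    for d in doses:
        s = series_by_dose[d].fitted()
        ts, rm = extract_tstar_rmax(s, epsilon, clip_to_window=True,
                                    r_from="data")
        t_star[d] = ts
        r_max[d] = rm
        r_core[d] = rm - (s.r0 if subtract_r0 else 0.0)
        if r_core[d] < 0:
            raise EstimationError(f"negative core radius for dose {d} ug/ml")
    d_pairwise: dict[tuple[float, float], float] = {}
    for a in range(len(doses)):
        for b in range(a + 1, len(doses)):
            i, j = doses[a], doses[b]
            ri, rj = r_core[i], r_core[j]
            if shared_r:
                ri = rj = 0.5 * (ri + rj)
            args = (u_nd * i, t_star[i], ri, u_nd * j, t_star[j], rj)
            # D enters only through (r_j^2/t_j - r_i^2/t_i)/(4D); the pair is
            # informative iff the D-free part log(u0_j t_i / (u0_i t_j)) is
            # nonzero (identical doses/stopping points carry no signal)
            den = np.log((u_nd * j * t_star[i]) / (u_nd * i * t_star[j]))
            num = rj**2 / t_star[j] - ri**2 / t_star[i]
            if abs(den) < 1e-8 or abs(num) < 1e-12:
                warnings.warn(
                    f"dose pair ({i}, {j}): degenerate (identical doses or "
                    "stopping points); unidentifiable", stacklevel=2)
                d_pairwise[(i, j)] = np.nan
                continue
            glo = _pair_mismatch(bracket[0], *args)
            ghi = _pair_mismatch(bracket[1], *args)
            if glo * ghi > 0:
                warnings.warn(
                    f"dose pair ({i}, {j}): no root in bracket {bracket}; "
                    "pair skipped", stacklevel=2)
                d_pairwise[(i, j)] = np.nan
                continue
            d_pairwise[(i, j)] = float(brentq(
                _pair_mismatch, bracket[0], bracket[1], args=args))
    vals = [v for v in d_pairwise.values() if np.isfinite(v)]
    if not vals:
        raise EstimationError("no dose pair yielded a diffusion estimate")
    return EstimationResult(t_star, r_max, d_pairwise, float(np.mean(vals)))


# --------------------------------------------------------------------------
# synthetic fixtures

def make_fixtures(d_true: float = 0.08474977, u_r: float = 0.003748,
                  doses: tuple[float, ...] = (3.0, 10.0, 30.0),
                  u_nd: float = 0.03, r0: float = 3.20875,
                  times: np.ndarray | None = None, noise_sd: float = 0.0,
                  seed: int = 0) -> dict[float, DoseSeries]:
    """Synthetic dose series standing in for the clinical time courses.

    Radii follow the threshold-radius law ``r0 + r*(t)`` of the point-source
    model up to each dose's stopping time ``t*`` and plateau there: once the
    histamine wave recedes below threshold the wheal stops expanding, and
    the already-formed wheal persists on the observation timescale (skin
    recovery is slow).  Gaussian noise of ``noise_sd`` mm is added to every
    point except the measured t=0 radius, which equals ``r0`` exactly (it is
    set by the injected volume).

    Default sampling is minutes 0..20, the clinical observation window.
    """
    if times is None:
        times = np.arange(0.0, 21.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[float, DoseSeries] = {}
    for dose in doses:
        m = InjectionModel(u0=u_nd * dose, d=d_true, u_r=u_r, r0=r0)
        tstar = time_of_max_radius(m)
        t_eff = np.minimum(np.maximum(times, 1e-12), tstar)
        with np.errstate(invalid="ignore"):
            core = np.asarray(threshold_radius(t_eff, m, offset=False))
        core = np.nan_to_num(core, nan=0.0)
        core[times == 0.0] = 0.0  # the wave has not spread at injection time
        radii = r0 + core
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, radii.shape)
            noise[times == 0.0] = 0.0
            radii = np.maximum(radii + noise, 0.0)
        out[dose] = DoseSeries(dose=dose, times=times, radii=radii, r0=r0)
    return out


def write_dose_series_csv(series_by_dose: dict[float, DoseSeries], path) -> None:
    """Write dose series as CSV (dose_ug_per_ml, time_min, radius_mm)."""
    import pandas as pd

    frames = [
        {"dose_ug_per_ml": s.dose, "time_min": t, "radius_mm": r}
        for s in series_by_dose.values()
        for t, r in zip(s.times, s.radii)
    ]
    pd.DataFrame(frames).to_csv(path, index=False)


def read_dose_series_csv(path) -> dict[float, DoseSeries]:
    """Read dose series from CSV; r0 is the radius at the earliest time."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[float, DoseSeries] = {}
    for dose, g in df.groupby("dose_ug_per_ml"):
        g = g.sort_values("time_min")
        t = g["time_min"].to_numpy(dtype=float)
        r = g["radius_mm"].to_numpy(dtype=float)
        out[float(dose)] = DoseSeries(float(dose), t, r, r0=float(r[0]))
    return out
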