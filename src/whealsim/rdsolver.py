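"""Explicit finite-difference integration of the histamine field.

The model is a single reaction-diffusion equation on a square skin patch
with zero-flux (Neumann) boundaries::

    du/dt = D_u lap(u) + chi(U) gamma u - alpha2 u/(alpha1 + u^2) + mu - alpha0 u

where ``U(x, t)`` is the cumulative histamine released at ``x`` up to time
``t`` and ``chi`` switches off self-activation, irreversibly, once ``U``
exceeds the per-cell store ``u_tot`` (no histamine resynthesis).  A second,
purely diagnostic layer turns the concentration into a wheal state through
a hysteretic sigmoid ``H(u) = 1/(1 + exp(-beta (u - u_r)))`` whose steepness
``beta`` depends on whether ``u`` is rising or falling at that point
(``beta_fall > beta_rise``: skin recovery is sharper in threshold than wheal
appearance, and the wheal state does not feed back on ``u``).

Two geometries are supported: the full 2-D square (5-point Laplacian,
mirrored ghost cells) and a 1-D axisymmetric reduction (finite-volume
cylindrical Laplacian on cell-centred radii) used for front-speed work,
where the front width of ~1e-3 domain lengths demands fine radial grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, EmptyTraceError, InstabilityError
from .kinetics import KineticParams

__all__ = [
    "SolverConfig",
    "WhealParams",
    "SimulationState",
    "Trajectory",
    "FrontTrace",
    "stable_dt",
    "make_state",
    "step",
    "run",
    "wheal_state",
    "track_front",
    "fit_constant_speed",
    "save_trajectory_h5",
    "save_mask_png",
]

RISING, FALLING = 1, -1


@dataclass(frozen=True)
class WhealParams:
    """Hysteretic wheal readout parameters.

    ``u_r`` is the histamine threshold above which a wheal is visible;
    ``beta_rise``/``beta_fall`` are the sigmoid steepnesses while the local
    concentration is rising/falling (``beta_fall > beta_rise``).
    """

    u_r: float = 0.5
    beta_rise: float = 30.0
    beta_fall: float = 150.0

    def __post_init__(self) -> None:
        if self.u_r <= 0:
            raise ValueError("u_r must be positive")
        if not self.beta_rise < self.beta_fall:
            raise ValueError("beta_rise must be < beta_fall (hysteresis asymmetry)")


@dataclass(frozen=True)
class SolverConfig:
    """Grid and time-stepping configuration.

    ``grid_n`` is the number of cells per edge (2-D) or along the radius
    (radial mode); ``length`` the domain edge (2-D) or the maximal radius
    (radial), both in dimensionless length.  ``dt=None`` selects a stable
    step automatically.
    """

    grid_n: int = 512
    dt: float | None = None
    t_end: float = 10.0
    snapshot_interval: float = 1.0
    radial_mode: bool = False
    length: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_n < 4:
            raise ConfigurationError("grid_n must be >= 4")
        if self.t_end < 0:
            raise ConfigurationError("t_end must be >= 0")
        if self.snapshot_interval <= 0:
            raise ConfigurationError("snapshot_interval must be positive")
        if self.length <= 0:
            raise ConfigurationError("length must be positive")

    @property
    def h(self) -> float:
        return self.length / self.grid_n


def _kinetic_rate_bound(p: KineticParams) -> float:
    # conservative bound on |dR/du|: growth gamma-alpha0 plus the steepest
    # inhibition slope alpha2/alpha1 (attained at u=0) plus decay
    g = p.gamma + p.alpha0
    if p.alpha2 > 0:
        g += p.alpha2 / p.alpha1
    return max(g, 1e-12)


def stable_dt(p: KineticParams, cfg: SolverConfig, safety: float = 0.8) -> float:
    """Largest time step satisfying both stability guards.

    Diffusion (explicit 5-point / cylindrical): ``dt <= h^2 / (4 D_u)``;
    kinetics accuracy: ``dt * max|dR/du| <= 0.1``.
    """
    h = cfg.h
    dt_diff = h * h / (4.0 * p.d_u) if p.d_u > 0 else np.inf
    dt_kin = 0.1 / _kinetic_rate_bound(p)
    return safety * min(dt_diff, dt_kin)


def _validate_dt(p: KineticParams, cfg: SolverConfig, dt: float) -> None:
    h = cfg.h
    if p.d_u > 0 and dt > h * h / (4.0 * p.d_u) * (1 + 1e-12):
        raise ConfigurationError(
            f"dt={dt:g} violates the diffusion stability limit "
            f"h^2/(4 D_u) = {h * h / (4 * p.d_u):g} at grid_n={cfg.grid_n}"
        )
    if dt * _kinetic_rate_bound(p) > 0.1 * (1 + 1e-12):
        raise ConfigurationError(
            f"dt={dt:g} violates the kinetic accuracy guard "
            f"0.1/max-rate = {0.1 / _kinetic_rate_bound(p):g}"
        )


@dataclass
class SimulationState:
    """Full per-cell state of a simulation at time ``t``.

    ``chi`` is boolean (store not yet exhausted); ``direction`` is +1 where
    the concentration last rose, -1 where it last fell; ``wheal`` is the
    hysteretic readout H(u).
    """

    u: np.ndarray
    cum_release: np.ndarray
    chi: np.ndarray
    direction: np.ndarray
    wheal: np.ndarray
    t: float = 0.0

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.u.copy(), self.cum_release.copy(), self.chi.copy(),
            self.direction.copy(), self.wheal.copy(), self.t,
        )


def make_state(u0: np.ndarray, wp: WhealParams) -> SimulationState:
    """Fresh state from an initial concentration field (stores full,
    direction initialized to rising)."""
    u0 = np.asarray(u0, dtype=float)
    if np.any(u0 < 0):
        raise ValueError("initial concentration must be >= 0")
    direction = np.full(u0.shape, RISING, dtype=np.int8)
    wheal = wheal_state(u0, direction, wp)
    return SimulationState(
        u=u0.copy(),
        cum_release=np.zeros_like(u0),
        chi=np.ones(u0.shape, dtype=bool),
        direction=direction,
        wheal=np.asarray(wheal),
        t=0.0,
    )


def wheal_state(u, direction, wp: WhealParams):
    """Hysteretic wheal readout H(u).

    A logistic sigmoid centred at ``u_r``; steepness ``beta_rise`` where the
    concentration is rising (direction +1), ``beta_fall`` where falling.
    H(u_r) = 1/2 for either branch; the falling branch is the sharper one.
    """
    u = np.asarray(u, dtype=float)
    beta = np.where(np.asarray(direction) == RISING, wp.beta_rise, wp.beta_fall)
    out = expit(beta * (u - wp.u_r))
    return out if out.ndim else float(out)


def _laplacian_2d(u: np.ndarray, h: float) -> np.ndarray:
    # 5-point stencil with mirrored ghost cells (zero normal flux)
    p = np.pad(u, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u) / (h * h)


def _laplacian_radial(u: np.ndarray, h: float, r_faces: np.ndarray,
                      r_centers: np.ndarray) -> np.ndarray:
    # finite-volume (1/r) d/dr (r du/dr) on cell-centred radii; the r=0 face
    # carries zero flux geometrically and the outer face is zero-flux
    flux = r_faces[1:-1] * np.diff(u) / h
    lap = np.empty_like(u)
    lap[0] = flux[0] / (r_centers[0] * h)
    lap[-1] = -flux[-1] / (r_centers[-1] * h)
    lap[1:-1] = np.diff(flux) / (r_centers[1:-1] * h)
    return lap


def radial_grid(cfg: SolverConfig) -> np.ndarray:
    """Cell-centre radii of the axisymmetric grid."""
    h = cfg.h
    return (np.arange(cfg.grid_n) + 0.5) * h


def grid_2d(cfg: SolverConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinate arrays (X, Y) of the 2-D grid."""
    h = cfg.h
    c = (np.arange(cfg.grid_n) + 0.5) * h
    return np.meshgrid(c, c, indexing="ij")


def step(state: SimulationState, p: KineticParams, cfg: SolverConfig,
         wp: WhealParams, dt: float | None = None) -> SimulationState:
    """Advance the state by one explicit Euler step (in place).

    Cumulative release is accumulated by the rectangle rule with the
    pre-step concentration; the depletion switch is one-way.  Raises
    :class:`InstabilityError` on NaN or negative concentrations.
    """
    if dt is None:
        dt = cfg.dt if cfg.dt is not None else stable_dt(p, cfg)
    _validate_dt(p, cfg, dt)
    _step_raw(state, p, cfg, wp, dt)
    return state


def _step_raw(state: SimulationState, p: KineticParams, cfg: SolverConfig,
              wp: WhealParams, dt: float,
              aux: tuple[np.ndarray, np.ndarray] | None = None,
              update_wheal: bool = True) -> None:
    u = state.u
    if cfg.radial_mode:
        if aux is None:
            h = cfg.h
            rf = np.arange(cfg.grid_n + 1) * h
            rc = radial_grid(cfg)
        else:
            rf, rc = aux
        lap = _laplacian_radial(u, cfg.h, rf, rc)
    else:
        lap = _laplacian_2d(u, cfg.h)
    chi = state.chi
    if p.alpha2 > 0:
        react = np.where(chi, p.gamma * u, 0.0) - p.alpha2 * u / (p.alpha1 + u * u) \
            + p.mu - p.alpha0 * u
    else:
        react = np.where(chi, p.gamma * u, 0.0) + p.mu - p.alpha0 * u
    state.cum_release += np.where(chi, p.gamma * u * dt, 0.0)
    du = dt * (p.d_u * lap + react)
    u_new = u + du
    lo = u_new.min()
    if not np.isfinite(lo) or lo < -1e-9:
        raise InstabilityError(
            f"integration unstable at t={state.t + dt:g} (min u = {lo!r}); "
            f"reduce dt={dt:g}"
        )
    np.copyto(state.direction, np.where(du > 0, RISING,
                                        np.where(du < 0, FALLING, state.direction)))
    state.u = u_new
    state.chi &= state.cum_release <= p.u_tot
    if update_wheal:
        state.wheal = np.asarray(wheal_state(u_new, state.direction, wp))
    state.t += dt


@dataclass
class Trajectory:
    """Snapshots of a simulation run."""

    times: np.ndarray
    u: list[np.ndarray]
    wheal: list[np.ndarray]
    cum_release: list[np.ndarray]
    final_state: SimulationState
    cfg: SolverConfig

    def wheal_mask(self, i: int = -1) -> np.ndarray:
        """Binary wheal mask of snapshot ``i`` (H >= 0.5)."""
        return self.wheal[i] >= 0.5


def run(p: KineticParams, u0: np.ndarray, wp: WhealParams,
        cfg: SolverConfig) -> Trajectory:
    """Integrate from an initial field, collecting snapshots.

    Snapshots are taken at t=0, every ``snapshot_interval``, and at
    ``t_end``.  With ``t_end = 0`` the trajectory holds the initial
    condition only.
    """
    dt = cfg.dt if cfg.dt is not None else stable_dt(p, cfg)
    _validate_dt(p, cfg, dt)
    state = make_state(u0, wp)
    aux = None
    if cfg.radial_mode:
        if state.u.ndim != 1 or len(state.u) != cfg.grid_n:
            raise ConfigurationError(
                f"radial mode expects a 1-D field of length grid_n={cfg.grid_n}"
            )
        aux = (np.arange(cfg.grid_n + 1) * cfg.h, radial_grid(cfg))
    elif state.u.shape != (cfg.grid_n, cfg.grid_n):
        raise ConfigurationError(
            f"expected a ({cfg.grid_n}, {cfg.grid_n}) field, got {state.u.shape}"
        )
    times = [0.0]
    us = [state.u.copy()]
    wheals = [state.wheal.copy()]
    cums = [state.cum_release.copy()]
    n_steps = int(round(cfg.t_end / dt))
    every = max(1, int(round(cfg.snapshot_interval / dt)))
    for k in range(1, n_steps + 1):
        # update the hysteretic readout only at snapshots: H is diagnostic
        # (no feedback on u) but direction memory is maintained every step
        at_snap = (k % every == 0) or (k == n_steps)
        _step_raw(state, p, cfg, wp, dt, aux=aux, update_wheal=at_snap)
        if at_snap:
            times.append(state.t)
            us.append(state.u.copy())
            wheals.append(state.wheal.copy())
            cums.append(state.cum_release.copy())
    return Trajectory(np.array(times), us, wheals, cums, state, cfg)


@dataclass
class FrontTrace:
    """Threshold-crossing radius of an expanding wheal over time.

    ``speed`` is the least-squares slope over ``speed_window`` (the longest
    interval on which a linear fit leaves residuals below 5% of the radius
    range); NaN when no such window exists.
    """

    times: np.ndarray
    radii: np.ndarray
    radii_sd: np.ndarray
    speed: float
    speed_window: tuple[float, float] | None

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time": self.times, "radius": self.radii, "radius_sd": self.radii_sd}
        ).to_csv(path, index=False)


def _outermost_crossing(r: np.ndarray, u: np.ndarray, level: float) -> float | None:
    above = np.nonzero(u >= level)[0]
    if len(above) == 0:
        return None
    i = above[-1]
    if i == len(u) - 1:
        return float(r[i])
    frac = (u[i] - level) / (u[i] - u[i + 1])
    return float(r[i] + frac * (r[i + 1] - r[i]))


def fit_constant_speed(times: np.ndarray, radii: np.ndarray,
                       min_points: int = 5, resid_frac: float = 0.05
                       ) -> tuple[float, tuple[float, float] | None]:
    """Slope of the maximal near-linear window of a radius trace.

    Scans all contiguous windows of at least ``min_points`` snapshots and
    keeps the longest one whose linear-fit residuals stay below
    ``resid_frac`` of the radius range within the window; ties go to the
    later window (fronts establish after a transient).
    """
    n = len(times)
    best = None
    for i in range(n - min_points + 1):
        for j in range(n, i + min_points - 1, -1):
            t, r = times[i:j], radii[i:j]
            rng = r.max() - r.min()
            if rng <= 0:
                if j - i >= min_points and best is None:
                    best = (i, j, 0.0)  # stationary front: speed 0
                continue
            a, b = np.polyfit(t, r, 1)
            resid = np.abs(r - (a * t + b)).max()
            if resid < resid_frac * rng:
                if best is None or (j - i) > (best[1] - best[0]) or (
                    (j - i) == (best[1] - best[0]) and i >= best[0]
                ):
                    best = (i, j, float(a))
                break  # longer windows from this i already failed? no: j decreasing, first success is longest for this i
    if best is None:
        return float("nan"), None
    i, j, speed = best
    return speed, (float(times[i]), float(times[j - 1]))


def track_front(traj: Trajectory, u_r: float,
                center: tuple[float, float] | None = None,
                n_rays: int = 32) -> FrontTrace:
    """Radius of the outermost ``u = u_r`` crossing around ``center``.

    In radial mode the single 1-D crossing is used; in 2-D the radius is the
    angular mean over ``n_rays`` rays (bilinear sampling at half-cell
    spacing), with the per-snapshot standard deviation across rays reported.
    Snapshots with no crossing anywhere are dropped; an entirely empty trace
    raises :class:`EmptyTraceError`.
    """
    cfg = traj.cfg
    times, radii, sds = [], [], []
    if cfg.radial_mode:
        r = radial_grid(cfg)
        for t, u in zip(traj.times, traj.u):
            c = _outermost_crossing(r, u, u_r)
            if c is not None:
                times.append(t)
                radii.append(c)
                sds.append(0.0)
    else:
        from scipy.ndimage import map_coordinates

        if center is None:
            center = (cfg.length / 2.0, cfg.length / 2.0)
        h = cfg.h
        cx, cy = center
        r_max = min(cx, cy, cfg.length - cx, cfg.length - cy)
        r_samp = np.arange(0.0, r_max, h / 2.0)
        angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
        for t, u in zip(traj.times, traj.u):
            ray_radii = []
            for a in angles:
                xs = cx + r_samp * np.cos(a)
                ys = cy + r_samp * np.sin(a)
                prof = map_coordinates(
                    u, [xs / h - 0.5, ys / h - 0.5], order=1, mode="nearest"
                )
                c = _outermost_crossing(r_samp, prof, u_r)
                if c is not None:
                    ray_radii.append(c)
            if ray_radii:
                times.append(t)
                radii.append(float(np.mean(ray_radii)))
                sds.append(float(np.std(ray_radii)))
    if not times:
        raise EmptyTraceError("no u = u_r crossing found in any snapshot")
    times = np.array(times)
    radii = np.array(radii)
    speed, window = fit_constant_speed(times, radii)
    return FrontTrace(times, radii, np.array(sds), speed, window)


def save_trajectory_h5(traj: Trajectory, path, config: dict | None = None,
                       seed: int | None = None) -> None:
    """Write snapshots to an HDF5 container (groups /u, /U, /wheal)."""
    import json

    import h5py

    from . import __version__

    with h5py.File(path, "w") as f:
        for name, frames in (("u", traj.u), ("U", traj.cum_release),
                             ("wheal", traj.wheal)):
            g = f.create_group(name)
            for i, arr in enumerate(frames):
                g.create_dataset(f"snap_{i:05d}", data=arr)
        f.create_dataset("times", data=traj.times)
        f.attrs["code_version"] = __version__
        if config is not None:
            f.attrs["config"] = json.dumps(config)
        if seed is not None:
            f.attrs["seed"] = seed


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary wheal mask as a PNG (white = wheal)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def load_mask_png(path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img >= 128


def convergence_ratio(p: KineticParams, u0: np.ndarray, wp: WhealParams,
                      cfg: SolverConfig, dt: float) -> float:
    """Max-norm relative change of the final field when dt is halved."""
    t1 = run(p, u0, wp, replace(cfg, dt=dt))
    t2 = run(p, u0, wp, replace(cfg, dt=dt / 2.0))
    a, b = t1.u[-1], t2.u[-1]
    return float(np.max(np.abs(a - b)) / max(np.max(np.abs(b)), 1e-300))
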