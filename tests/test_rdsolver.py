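"""Reaction-diffusion integration: conservation, oracles, fronts, hysteresis."""

import numpy as np
import pytest

from whealsim.errors import ConfigurationError, InstabilityError
from whealsim.kinetics import KineticParams, equilibria
from whealsim.rdsolver import (
    FrontTrace,
    SolverConfig,
    Trajectory,
    WhealParams,
    _step_raw,
    convergence_ratio,
    fit_constant_speed,
    grid_2d,
    make_state,
    radial_grid,
    run,
    stable_dt,
    step,
    track_front,
    wheal_state,
)
from whealsim.stimulus import StimulusSpec, initial_condition, radial_bump

PURE_DIFFUSION = KineticParams(gamma=0.0, alpha0=0.0, alpha1=0.0, alpha2=0.0,
                               mu=0.0, d_u=1e-3)


class TestStep:
    def test_equilibrium_is_fixed_point(self, set_i, wheal):
        cfg = SolverConfig(grid_n=16, t_end=1.0)
        u0 = np.full((16, 16), equilibria(set_i).u0_star)
        state = make_state(u0, wheal)
        for _ in range(20):
            step(state, set_i, cfg, wheal)
        assert np.max(np.abs(state.u - u0)) < 20 * 1e-12

    def test_zero_flux_mass_conservation(self, wheal, rng):
        cfg = SolverConfig(grid_n=64, t_end=1.0)
        u0 = rng.random((64, 64))
        state = make_state(u0, wheal)
        dt = stable_dt(PURE_DIFFUSION, cfg)
        m0 = state.u.sum()
        for _ in range(1000):
            step(state, PURE_DIFFUSION, cfg, wheal, dt=dt)
        assert abs(state.u.sum() / m0 - 1) < 1e-10

    def test_pure_diffusion_matches_gaussian_oracle(self, wheal):
        """A Gaussian initial profile evolves per the point-source solution."""
        n = 128
        cfg = SolverConfig(grid_n=n, t_end=1.0)
        X, Y = grid_2d(cfg)
        D = PURE_DIFFUSION.d_u
        t0, t1 = 1.0, 3.0
        r2 = (X - 0.5) ** 2 + (Y - 0.5) ** 2
        u0 = np.exp(-r2 / (4 * D * t0)) / (4 * np.pi * D * t0)
        state = make_state(u0, wheal)
        dt = stable_dt(PURE_DIFFUSION, cfg)
        n_steps = int(round((t1 - t0) / dt))
        dt = (t1 - t0) / n_steps
        for _ in range(n_steps):
            step(state, PURE_DIFFUSION, cfg, wheal, dt=dt)
        exact = np.exp(-r2 / (4 * D * t1)) / (4 * np.pi * D * t1)
        mask = exact > 0.01 * exact.max()
        err = np.abs(state.u - exact)[mask] / exact[mask]
        # kernel sigma spans ~14 cells at t1
        assert err.max() < 0.02

    def test_cfl_violation_is_a_configuration_error(self, set_i, wheal):
        cfg = SolverConfig(grid_n=512, t_end=1.0)
        state = make_state(np.full((512, 512), 0.3), wheal)
        bad_dt = 2.0 * (cfg.h ** 2) / (4 * set_i.d_u)
        with pytest.raises(ConfigurationError, match="dt"):
            step(state, set_i, cfg, wheal, dt=bad_dt)

    def test_unstable_step_raises(self, set_i, wheal):
        cfg = SolverConfig(grid_n=64, t_end=1.0)
        u0 = np.zeros((64, 64))
        u0[32, 32] = 50.0
        state = make_state(u0, wheal)
        with pytest.raises(InstabilityError):
            for _ in range(200):  # grossly too large dt, bypassing validation
                _step_raw(state, set_i, cfg, wheal, dt=5.0)

    def test_depletion_switch_is_one_way(self, set_i, wheal):
        cfg = SolverConfig(grid_n=24, t_end=6.0, snapshot_interval=0.2)
        u0 = initial_condition(equilibria(set_i).u0_star,
                               StimulusSpec(r=0.8, seed=1), grid_2d(cfg))
        state = make_state(u0, wheal)
        dt = stable_dt(set_i, cfg)
        prev_chi = state.chi.copy()
        prev_cum = state.cum_release.copy()
        for _ in range(int(6.0 / dt)):
            step(state, set_i, cfg, wheal, dt=dt)
            assert not np.any(state.chi & ~prev_chi), "chi returned to 1"
            assert np.all(state.cum_release >= prev_cum - 1e-15)
            prev_chi = state.chi.copy()
            prev_cum = state.cum_release.copy()
        assert np.any(~state.chi), "strong stimulus should deplete some cells"
        assert np.all(state.chi == (state.cum_release <= set_i.u_tot))


class TestRun:
    def test_zero_time_returns_initial_condition(self, set_i, wheal, rng):
        cfg = SolverConfig(grid_n=16, t_end=0.0)
        u0 = rng.random((16, 16))
        traj = run(set_i, u0, wheal, cfg)
        assert len(traj.times) == 1
        assert np.array_equal(traj.u[0], u0)

    def test_no_inhibition_grows_uniformly(self, wheal):
        """alpha2=0, gamma>alpha0: exponential growth, no spatial structure."""
        p = KineticParams(alpha2=0.0, alpha1=0.0, u_tot=np.inf)
        cfg = SolverConfig(grid_n=16, t_end=2.0, snapshot_interval=0.5, dt=5e-4)
        u_start = 0.3
        traj = run(p, np.full((16, 16), u_start), wheal, cfg)
        lam = p.gamma - p.alpha0
        for t, u in zip(traj.times, traj.u):
            assert u.std() / u.mean() < 1e-6
            exact = (u_start + p.mu / lam) * np.exp(lam * t) - p.mu / lam
            assert u.mean() == pytest.approx(exact, rel=0.02)
        assert traj.u[-1].mean() > 100 * u_start

    def test_set_i_random_stimulus_develops_pattern(self, set_i, wheal):
        cfg = SolverConfig(grid_n=64, t_end=10.0, snapshot_interval=2.0)
        u0 = initial_condition(equilibria(set_i).u0_star,
                               StimulusSpec(r=0.6, seed=0), grid_2d(cfg))
        traj = run(set_i, u0, wheal, cfg)
        late = traj.u[-1]
        assert late.max() / late.min() > 10

    def test_halving_dt_changes_little(self, set_i, wheal):
        """Convergence at Set I in the smooth (subthreshold) regime."""
        cfg = SolverConfig(grid_n=256, length=0.25, radial_mode=True, t_end=2.0,
                           snapshot_interval=1.0)
        u0 = radial_bump(equilibria(set_i).u0_star, 0.3, 0.02, radial_grid(cfg))
        dt = stable_dt(set_i, cfg)
        assert convergence_ratio(set_i, u0, wheal, cfg, dt) < 0.005


class TestWhealState:
    def test_midpoint_half_on_both_branches(self, wheal):
        assert wheal_state(wheal.u_r, 1, wheal) == pytest.approx(0.5)
        assert wheal_state(wheal.u_r, -1, wheal) == pytest.approx(0.5)

    def test_saturation(self, wheal):
        assert wheal_state(wheal.u_r + 1.0, 1, wheal) > 0.999
        assert wheal_state(max(wheal.u_r - 1.0, 0), 1, wheal) < 1e-3

    def test_falling_branch_is_sharper_not_lower(self, wheal):
        """Near threshold the falling sigmoid is closer to a step."""
        du = 0.1 / wheal.beta_rise
        below_r = wheal_state(wheal.u_r - du, 1, wheal)
        below_f = wheal_state(wheal.u_r - du, -1, wheal)
        assert below_f < below_r  # sharper, not uniformly smaller
        above_r = wheal_state(wheal.u_r + du, 1, wheal)
        above_f = wheal_state(wheal.u_r + du, -1, wheal)
        assert above_f > above_r

    def test_invalid_hysteresis_order_rejected(self):
        with pytest.raises(ValueError):
            WhealParams(beta_rise=100.0, beta_fall=50.0)

    def test_direction_memory_follows_concentration(self, wheal):
        p = KineticParams(gamma=0.0, alpha0=1.0, alpha1=0.0, alpha2=0.0,
                          mu=0.5, d_u=0.0)
        cfg = SolverConfig(grid_n=4, t_end=1.0)
        state = make_state(np.full((4, 4), 2.0), wheal)  # decays toward 0.5
        step(state, p, cfg, wheal, dt=0.01)
        assert np.all(state.direction == -1)
        state2 = make_state(np.full((4, 4), 0.1), wheal)  # grows toward 0.5
        step(state2, p, cfg, wheal, dt=0.01)
        assert np.all(state2.direction == 1)


class TestTrackFront:
    def _disk_trajectory(self, speed, n=128, r0=0.1, steps=11):
        cfg = SolverConfig(grid_n=n, t_end=float(steps - 1))
        X, Y = grid_2d(cfg)
        rr = np.hypot(X - 0.5, Y - 0.5)
        times = np.arange(steps, dtype=float)
        us = [np.where(rr <= r0 + speed * t, 1.0, 0.0) for t in times]
        wheals = [u.copy() for u in us]
        state = make_state(us[-1], WhealParams())
        return Trajectory(times, us, wheals, [u * 0 for u in us], state, cfg)

    def test_constant_speed_disk_recovered(self):
        c = 0.02
        traj = self._disk_trajectory(c)
        trace = track_front(traj, u_r=0.5)
        assert trace.speed == pytest.approx(c, abs=1.5 / 128)

    def test_stationary_disk_zero_speed(self):
        traj = self._disk_trajectory(0.0)
        trace = track_front(traj, u_r=0.5)
        assert trace.speed == pytest.approx(0.0, abs=1e-12)

    def test_radial_and_2d_front_speeds_agree(self, set_i, wheal):
        """Axisymmetric reduction reproduces the 2-D front at matched h."""
        n2, length = 128, 1.0
        h = length / n2
        cfg2 = SolverConfig(grid_n=n2, length=length, t_end=20.0,
                            snapshot_interval=2.0)
        u0s = equilibria(set_i).u0_star
        X, Y = grid_2d(cfg2)
        rr = np.hypot(X - 0.5, Y - 0.5)
        u02 = u0s + 1.0 * np.exp(-((rr / 0.02) ** 2))
        traj2 = run(set_i, u02, wheal, cfg2)
        c2 = track_front(traj2, wheal.u_r).speed

        cfgr = SolverConfig(grid_n=n2 // 2, length=length / 2,
                            radial_mode=True, t_end=20.0, snapshot_interval=2.0)
        assert cfgr.h == pytest.approx(h)
        u0r = radial_bump(u0s, 1.0, 0.02, radial_grid(cfgr))
        trajr = run(set_i, u0r, wheal, cfgr)
        cr = track_front(trajr, wheal.u_r).speed
        assert c2 == pytest.approx(cr, rel=0.10)

    def test_fit_rejects_nonlinear_trace(self):
        t = np.linspace(0, 10, 21)
        r = 0.01 * t**2
        speed, window = fit_constant_speed(t, r)
        if window is not None:  # only a sub-window may be near-linear
            assert window[1] - window[0] < 10.0


class TestIO:
    def test_h5_round_trip(self, set_i, wheal, tmp_path):
        import h5py

        from whealsim.rdsolver import save_trajectory_h5

        cfg = SolverConfig(grid_n=8, t_end=0.5, snapshot_interval=0.25)
        traj = run(set_i, np.full((8, 8), 0.2), wheal, cfg)
        path = tmp_path / "traj.h5"
        save_trajectory_h5(traj, path, config={"grid_n": 8}, seed=11)
        with h5py.File(path) as f:
            assert f.attrs["seed"] == 11
            snaps = sorted(f["u"])
            assert len(snaps) == len(traj.times)
            np.testing.assert_array_equal(f["u"][snaps[-1]][...], traj.u[-1])

    def test_mask_png_round_trip(self, tmp_path, rng):
        from whealsim.rdsolver import load_mask_png, save_mask_png

        mask = rng.random((32, 32)) > 0.6
        save_mask_png(mask, tmp_path / "m.png")
        assert np.array_equal(load_mask_png(tmp_path / "m.png"), mask)
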