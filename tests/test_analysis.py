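"""Line profiles, comparison statistics, synthetic thermometry, probes."""

import numpy as np
import pytest

from thermoembo import (
    InjectionSchedule,
    LineProfile,
    ParameterSet,
    SimConfig,
    Simulator,
    compare_profiles,
    line_profile,
    make_box_mesh,
    probe_timeseries,
    synthesize_thermometry,
)
from thermoembo.chemistry import fit_hydrolysis_rate


class TestLineProfile:
    def test_uniform_field(self, mesh_2d):
        prof = line_profile(np.full(64, 21.0), mesh_2d,
                            (0.001, 0.001), (0.019, 0.019), 10)
        np.testing.assert_allclose(prof.values, 21.0)
        assert len(prof.positions_mm) == 10
        assert prof.positions_mm[-1] == pytest.approx(
            np.hypot(0.018, 0.018) * 1e3
        )

    def test_multilinear_reproduces_linear_fields(self):
        mesh = make_box_mesh((0.02,), (40,))
        field = 5.0 + 300.0 * mesh.cell_centers[:, 0]
        prof = line_profile(field, mesh, (0.00025,), (0.01975,), 15)
        x = np.linspace(0.00025, 0.01975, 15)
        np.testing.assert_allclose(prof.values, 5.0 + 300.0 * x, rtol=1e-12)

    def test_nearest_vs_multilinear_within_one_cell_bound(self, mesh_2d):
        x = mesh_2d.cell_centers
        field = np.sin(200.0 * x[:, 0]) + np.cos(150.0 * x[:, 1])
        a = line_profile(field, mesh_2d, (0.002, 0.003), (0.018, 0.017), 30,
                         mode="multilinear")
        b = line_profile(field, mesh_2d, (0.002, 0.003), (0.018, 0.017), 30,
                         mode="nearest")
        # brute-force bound: largest neighbor-to-neighbor field jump
        bound = np.abs(np.diff(field.reshape(8, 8), axis=0)).max() + np.abs(
            np.diff(field.reshape(8, 8), axis=1)
        ).max()
        assert np.abs(a.values - b.values).max() <= bound

    def test_segment_outside_domain_rejected(self, mesh_2d):
        with pytest.raises(ValueError):
            line_profile(np.zeros(64), mesh_2d, (0.0, 0.0), (0.03, 0.0), 5)


class TestCompareProfiles:
    def make(self, values):
        return LineProfile(
            positions_mm=np.arange(len(values), dtype=float),
            values=np.asarray(values, dtype=float),
            start=(0.0,), end=(0.001,),
        )

    def test_identical_profiles(self):
        a = self.make([21.0, 30.0, 45.0, 40.0, 25.0])
        rep = compare_profiles(a, self.make([21.0, 30.0, 45.0, 40.0, 25.0]))
        assert rep.mean_abs_diff == 0.0 and rep.max_abs_diff == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        vals = [21.0, 30.0, 45.0, 40.0, 25.0]
        rep = compare_profiles(self.make(vals),
                               self.make([v + 2.0 for v in vals]))
        assert rep.mean_abs_diff == pytest.approx(2.0)
        assert rep.max_abs_diff == pytest.approx(2.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_pearson_matches_hand_formula(self):
        a = np.array([23.0, 31.0, 44.0, 39.0, 27.0])
        b = np.array([25.0, 29.0, 41.0, 42.0, 24.0])
        rep = compare_profiles(self.make(a), self.make(b))
        r_hand = float(
            ((a - a.mean()) * (b - b.mean())).sum()
            / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert rep.pearson_r == pytest.approx(r_hand, rel=1e-12)
        assert rep.n == 5

    def test_mismatched_positions_rejected(self):
        a = self.make([1.0, 2.0, 3.0, 2.0, 1.0])
        b = LineProfile(np.arange(5) * 2.0, np.ones(5), (0.0,), (0.002,))
        with pytest.raises(ValueError):
            compare_profiles(a, b)

    def test_zero_variance_rejected(self):
        a = self.make([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            compare_profiles(a, a)


class _Checkpoint:
    """Minimal stand-in trajectory node (time + temperature field)."""

    def __init__(self, time, u):
        self.time = time
        self.thermal = type("T", (), {"u": np.asarray(u, dtype=float)})()


class TestSyntheticThermometry:
    def traj(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(21.0, 60.0, 50)
        return [_Checkpoint(t, base + 0.01 * t) for t in
                np.arange(0.0, 200.0, 22.3)]

    def test_infinite_snr_limit(self):
        traj = self.traj()
        t, frames, sigma = synthesize_thermometry(traj, snr=1e12, seed=0)
        np.testing.assert_allclose(frames[0], traj[0].thermal.u, atol=1e-9)

    def test_seed_reproducibility(self):
        traj = self.traj()
        _, f1, _ = synthesize_thermometry(traj, snr=40.0, seed=123)
        _, f2, _ = synthesize_thermometry(traj, snr=40.0, seed=123)
        np.testing.assert_array_equal(f1, f2)
        _, f3, _ = synthesize_thermometry(traj, snr=40.0, seed=124)
        assert not np.array_equal(f1, f3)

    def test_noise_moments(self):
        field = np.zeros(10_000)
        traj = [_Checkpoint(0.0, field), _Checkpoint(22.3, field)]
        _, frames, sigma = synthesize_thermometry(traj, snr=40.0, seed=5)
        assert sigma == pytest.approx(1.0)
        draws = frames.ravel()
        assert len(draws) >= 1e5 / 10
        assert np.std(draws) == pytest.approx(sigma, rel=0.01)
        assert np.mean(draws) == pytest.approx(0.0, abs=0.02)


class TestProbeTimeseries:
    def test_constant_trajectory(self, mesh_2d):
        traj = [_Checkpoint(t, np.full(64, 33.0)) for t in (0.0, 10.0, 20.0)]
        df = probe_timeseries(traj, [(0.01, 0.01)], mesh_2d)
        assert list(df["time_s"]) == [0.0, 10.0, 20.0]
        np.testing.assert_allclose(df.iloc[:, 1], 33.0)

    def test_duplicate_points_give_identical_columns(self, mesh_2d):
        rng = np.random.default_rng(2)
        traj = [_Checkpoint(t, rng.uniform(20, 90, 64)) for t in (0.0, 5.0)]
        df = probe_timeseries(traj, [(0.003, 0.007), (0.003, 0.007)], mesh_2d)
        np.testing.assert_array_equal(df.iloc[:, 1], df.iloc[:, 2])

    def test_point_outside_domain_rejected(self, mesh_2d):
        with pytest.raises(ValueError):
            probe_timeseries([_Checkpoint(0.0, np.zeros(64))],
                             [(0.5, 0.5)], mesh_2d)

    def test_reacting_insulated_probe_is_nondecreasing(self):
        cfg = SimConfig(
            extents=(0.004,), cells=(4,), vessel=None,
            schedule=InjectionSchedule(duration=0.0),
            dt=1.0, t_end=200.0, checkpoint_interval=20.0,
            solve_flow=False, sealed_far=True,
        )
        sim = Simulator(cfg)
        state = sim.initialize(s_bolus=np.full(4, 0.8))
        traj = [state]
        while state.time < cfg.t_end:
            state = sim.step(state)
            traj.append(state)
        df = probe_timeseries(traj, [(0.002,)], sim.mesh)
        series = df.iloc[:, 1].to_numpy()
        assert np.all(np.diff(series) > 0)


class TestPipelineClosure:
    def test_fitted_rate_matches_effective_decay_rate(self):
        """End-to-end: fitting the first-order rise model to a probe series
        from a well-mixed reacting run recovers the effective bolus decay
        rate gamma*eps*rho_DCACl/rho_bolus within 10%."""
        par = ParameterSet()
        cfg = SimConfig(
            extents=(0.004,), cells=(4,), vessel=None, params=par,
            schedule=InjectionSchedule(duration=0.0),
            dt=1.0, t_end=3000.0, checkpoint_interval=22.3,
            solve_flow=False, sealed_far=True,
        )
        sim = Simulator(cfg)
        state = sim.initialize(s_bolus=np.ones(4))
        traj = [state]
        while state.time < cfg.t_end:
            state = sim.step(state)
            traj.append(state)
        df = probe_timeseries(traj, [(0.002,)], sim.mesh)
        fit = fit_hydrolysis_rate(
            df["time_s"].to_numpy(), df.iloc[:, 1].to_numpy(), baseline=21.0
        )
        geff = par.gamma * par.epsilon * par.rho_dcacl / par.rho_bolus
        assert fit.gamma_hat == pytest.approx(geff, rel=0.10)
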