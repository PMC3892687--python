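import numpy as np
import pytest
from hypothesis import given, strategies as st

from topaug.model_core import (DynModel, Dataset, FixedNoise, ProportionalNoise,
                               generate_observations, promote_parameter_to_state,
                               reformulate_as_sde, simulate_ode, simulate_sde)
from topaug.casestudies import pk_model


def scalar_decay(rate_param: bool = True):
    return DynModel(
        name="decay",
        state_names=["x"],
        param_names=["a"],
        drift=lambda x, u, th, t: -th[0] * x,
        output_map=lambda x: x[:1],
        observable_names=["x"],
        initial_state=np.array([1.0]),
    )


class TestSimulateOde:
    def test_exponential_decay_closed_form(self):
        traj = simulate_ode(scalar_decay(), np.array([1.0]), np.linspace(0, 1, 11))
        assert traj.states[0, 0] == 1.0
        assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), rel=1e-7)

    def test_zero_drift_constant(self):
        m = scalar_decay()
        m.drift = lambda x, u, th, t: np.zeros(1)
        m.initial_state = np.array([3.5])
        traj = simulate_ode(m, np.array([0.0]), np.linspace(0, 5, 6))
        assert np.allclose(traj.states, 3.5)

    def test_pk_matches_high_accuracy_oracle(self):
        from scipy.integrate import solve_ivp
        b = pk_model("truth")
        theta = b.theta_array()
        grid = np.linspace(0, 10, 21)
        traj = simulate_ode(b.model, theta, grid)
        # independent high-order integrator at much tighter tolerance
        ref = solve_ivp(lambda t, x: b.model.f(x, theta, t), (0, 10),
                        b.model.x0(theta), t_eval=grid, method="DOP853",
                        rtol=1e-12, atol=1e-12)
        scale = np.abs(ref.y.T).max()
        assert np.max(np.abs(traj.states - ref.y.T)) / scale < 1e-6

    def test_nonfinite_drift_reports_state_and_time(self):
        m = scalar_decay()
        m.drift = lambda x, u, th, t: np.array([np.nan])
        with pytest.raises(Exception, match="x"):
            simulate_ode(m, np.array([1.0]), np.linspace(0, 1, 5))


class TestSimulateSde:
    def test_zero_sigma_reduces_to_ode(self):
        m = reformulate_as_sde(scalar_decay())
        theta = np.array([1.0, 0.0])
        grid = np.linspace(0, 2, 21)
        paths = simulate_sde(m, theta, grid, n_paths=3, seed=1, substeps=40)
        ode = simulate_ode(m, theta, grid)
        # Euler step error bound: compare against half-step simulation
        half = simulate_sde(m, theta, grid, n_paths=1, seed=1, substeps=80)
        step_err = np.max(np.abs(paths[0].states - half[0].states))
        for p in paths:
            assert np.array_equal(p.states, paths[0].states)
        assert np.max(np.abs(paths[0].states - ode.states)) < 10 * step_err + 1e-12

    def test_pure_diffusion_variance_grows_linearly(self):
        m = DynModel(name="wiener", state_names=["x"], param_names=["s"],
                     drift=lambda x, u, th, t: np.zeros(1),
                     output_map=lambda x: x[:1], observable_names=["x"],
                     initial_state=np.zeros(1), diffusion_params=["s"])
        sigma = 0.7
        paths = simulate_sde(m, np.array([sigma]), np.linspace(0, 2, 5),
                             n_paths=10_000, seed=3)
        xs = np.stack([p.states[:, 0] for p in paths])
        t = np.linspace(0, 2, 5)[1:]
        var = xs.var(axis=0)[1:]
        mc_se = var * np.sqrt(2 / 10_000)
        assert np.all(np.abs(var - sigma ** 2 * t) < 3 * mc_se + 3 * sigma**2 * t / np.sqrt(10_000))

    def test_ou_stationary_variance(self):
        m = reformulate_as_sde(scalar_decay())
        m.initial_state = np.array([0.0])
        sigma = 0.5
        grid = np.linspace(0, 12, 13)
        # fine substeps keep the Euler-Maruyama bias well under the MC error
        paths = simulate_sde(m, np.array([1.0, sigma]), grid, n_paths=4000,
                             seed=5, substeps=40)
        final = np.array([p.states[-1, 0] for p in paths])
        target = sigma ** 2 / 2.0
        mc_se = target * np.sqrt(2 / 4000)
        assert abs(final.var() - target) < 3 * mc_se

    def test_negative_sigma_rejected(self):
        m = reformulate_as_sde(scalar_decay())
        with pytest.raises(ValueError, match=">= 0"):
            simulate_sde(m, np.array([1.0, -0.1]), np.linspace(0, 1, 3), seed=0)

    def test_reproducible_per_seed(self):
        m = reformulate_as_sde(scalar_decay())
        a = simulate_sde(m, np.array([1.0, 0.3]), np.linspace(0, 1, 5), 2, seed=9)
        b = simulate_sde(m, np.array([1.0, 0.3]), np.linspace(0, 1, 5), 2, seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.states, pb.states)


class TestStructuralTransforms:
    def test_reformulate_appends_one_sigma_per_state(self):
        b = pk_model("linear")
        sde = reformulate_as_sde(b.model)
        assert sde.param_names == ["k_A", "C_L", "V", "sigma_Q", "sigma_C"]
        assert sde.diffusion_params == ["sigma_Q", "sigma_C"]
        assert sde.drift is b.model.drift

    def test_reformulate_single_state(self):
        sde = reformulate_as_sde(scalar_decay())
        assert len(sde.sigma_names) == 1

    def test_reformulate_twice_rejected(self):
        sde = reformulate_as_sde(scalar_decay())
        with pytest.raises(ValueError, match="already stochastic"):
            reformulate_as_sde(sde)

    def test_promote_pk_gives_three_sigmas(self):
        b = pk_model("extended")
        assert b.model.n_states == 3
        assert b.model.state_names[-1] == "k_A"
        assert set(b.model.sigma_names) == {"sigma_Q", "sigma_C", "sigma_k_A"}
        assert "k_A" not in b.model.param_names
        assert "k_A0" in b.model.param_names

    def test_promote_unknown_parameter(self):
        sde = reformulate_as_sde(scalar_decay())
        with pytest.raises(KeyError):
            promote_parameter_to_state(sde, "nope", 1.0)

    def test_promoted_state_with_zero_sigma_is_constant(self):
        b = pk_model("extended")
        m = b.model
        # C_L, V, sigma_Q, sigma_C, k_A0, sigma_k_A
        theta = np.array([5.0, 15.0, 0.0, 0.0, 0.4, 0.0])
        traj = simulate_ode(m, theta, np.linspace(0, 5, 11))
        assert np.allclose(traj.states[:, 2], 0.4, atol=1e-9)
        # matches the unpromoted linear model at k_A = 0.4
        lin = pk_model("linear").model
        ref = simulate_ode(lin, np.array([0.4, 5.0, 15.0]), np.linspace(0, 5, 11))
        assert np.allclose(traj.states[:, :2], ref.states, atol=1e-7)

    def test_promote_cost_invariance_with_zero_sigma(self, pk_dataset):
        """Promoting a parameter and freezing its diffusion must not change
        the filter cost relative to the unpromoted model at matched theta."""
        from topaug.ekf import cost
        lin_sde = pk_model("linear_sde").model
        ext = pk_model("extended").model
        th_lin = np.array([0.4, 5.0, 15.0, 0.05, 0.02])
        th_ext = np.array([5.0, 15.0, 0.05, 0.02, 0.4, 0.0])
        c_lin = cost(lin_sde, th_lin, pk_dataset).value
        c_ext = cost(ext, th_ext, pk_dataset).value
        assert c_ext == pytest.approx(c_lin, abs=1e-8)


class TestStoichiometry:
    def test_conservation_along_trajectory(self):
        # A -> B -> C chain given as N v: total mass is a left null vector of N
        N = np.array([[-1, 0], [1, -1], [0, 1]])

        def v(x, u, th, t):
            return np.array([th[0] * x[0], th[1] * x[1]])

        m = DynModel(
            name="chain", state_names=["A", "B", "C"], param_names=["k1", "k2"],
            drift=lambda x, u, th, t: N @ v(x, u, th, t),
            output_map=lambda x: x, observable_names=["A", "B", "C"],
            initial_state=np.array([1.0, 0.2, 0.0]), stoichiometry=(N, v))
        traj = simulate_ode(m, np.array([0.7, 0.3]), np.linspace(0, 5, 20))
        total = traj.states.sum(axis=1)
        assert np.max(np.abs(total - total[0])) < 1e-7


class TestGenerateObservations:
    def test_zero_rho_noiseless(self):
        b = pk_model("truth")
        traj = simulate_ode(b.model, b.theta_array(), np.linspace(0.5, 10, 20))
        ds = generate_observations(traj, b.model, ProportionalNoise(0.0), seed=1)
        expected = np.array([b.model.h(x) for x in traj.states])
        assert np.allclose(ds.values, expected)

    def test_proportional_sd_calibration(self):
        m = DynModel(name="const", state_names=["x"], param_names=[],
                     drift=lambda x, u, th, t: np.zeros(1),
                     output_map=lambda x: x[:1], observable_names=["y"],
                     initial_state=np.array([1.0]))
        traj = simulate_ode(m, np.array([]), np.arange(10_001, dtype=float))
        ds = generate_observations(traj, m, ProportionalNoise(0.1), seed=2)
        sd = ds.values.std()
        mc_se = 0.1 / np.sqrt(2 * 10_000)
        assert abs(sd - 0.1) < 3 * mc_se

    def test_fixed_noise_sds_stored(self):
        b = pk_model("truth")
        traj = simulate_ode(b.model, b.theta_array(), np.linspace(0.5, 10, 20))
        ds = generate_observations(traj, b.model, FixedNoise(0.05), seed=0)
        assert np.allclose(ds.sds, 0.05)


class TestDataset:
    def test_csv_round_trip(self, tmp_path, pk_dataset):
        path = tmp_path / "ds.csv"
        pk_dataset.to_csv(path)
        back = Dataset.from_csv(path)
        assert np.allclose(back.times, pk_dataset.times)
        assert np.allclose(back.values, pk_dataset.values, equal_nan=True)
        assert np.allclose(back.sds, pk_dataset.sds, equal_nan=True)

    def test_csv_round_trip_with_missing_cells(self, tmp_path, gln_dataset):
        path = tmp_path / "gln.csv"
        gln_dataset.to_csv(path)
        back = Dataset.from_csv(path)
        assert back.n_points == gln_dataset.n_points == 37

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Dataset(np.array([0.0, 0.0, 1.0]), np.zeros((3, 1)),
                    np.ones((3, 1)), ["y"])

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            Dataset(np.array([0.0, 1.0]), np.ones((2, 1)),
                    np.array([[1.0], [0.0]]), ["y"])

    @given(st.integers(min_value=1, max_value=6))
    def test_n_points_counts_observed_cells(self, k):
        times = np.arange(k, dtype=float)
        values = np.ones((k, 2))
        values[0, 0] = np.nan
        sds = np.full((k, 2), 0.1)
        sds[0, 0] = np.nan
        ds = Dataset(times, values, sds, ["a", "b"])
        assert ds.n_points == 2 * k - 1
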