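import numpy as np
import pytest

from topaug.model_core import simulate_ode
from topaug.casestudies import (GLN_VARIANTS, PK_VARIANTS, gln_generate,
                                gln_model, gln_phi, pk_generate, pk_model)
import topaug.casestudies.constants as C


class TestPkModels:
    def test_variant_registry_has_eight_m_models(self):
        m_series = [v for v in PK_VARIANTS if v.startswith("M")]
        assert len(m_series) == 8
        for v in m_series:
            pk_model(v)

    def test_mass_balance_of_truth_model(self):
        b = pk_model("truth")
        theta = b.theta_array()
        grid = np.linspace(0, 10, 50)
        traj = simulate_ode(b.model, theta, grid)
        V, CL = theta[3], theta[2]
        # d(Q + V C)/dt = -C_L * C along the trajectory
        for x, t in zip(traj.states, grid):
            f = b.model.f(x, theta, t)
            assert f[0] + V * f[1] == pytest.approx(-CL * x[1], abs=1e-8)

    def test_linear_matches_truth_in_low_dose_limit(self):
        b = pk_model("truth")
        lin = pk_model("linear")
        theta = b.theta_array()
        k_a = theta[0] / theta[1]  # V_max / K_m
        grid = np.linspace(0, 10, 30)
        devs = []
        for q0 in [3.0, 0.3, 0.03]:
            mt = b.model
            mt.initial_state = np.array([q0, 0.0])
            lin.model.initial_state = np.array([q0, 0.0])
            t1 = simulate_ode(mt, theta, grid)
            t2 = simulate_ode(lin.model, np.array([k_a, theta[2], theta[3]]), grid)
            devs.append(np.max(np.abs(t1.states - t2.states)) / q0)
        b.model.initial_state = np.array([C.PK_Q0, C.PK_C0])
        lin.model.initial_state = np.array([C.PK_Q0, C.PK_C0])
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 5e-3

    def test_m_series_sigma_structure(self):
        assert pk_model("M1").model.sigma_names == ["sigma_Q", "sigma_C"]
        assert pk_model("M2").model.sigma_names == ["sigma_Q"]
        assert pk_model("M3").model.sigma_names == ["sigma_C"]
        assert pk_model("M4").model.sigma_names == []
        assert not pk_model("M4").model.is_stochastic
        assert pk_model("M8").model.param_names == ["V_max", "K_m", "C_L", "V"]

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown"):
            pk_model("M9")


class TestPkGenerator:
    def test_twenty_points_on_plasma_concentration(self):
        ds = pk_generate(seed=0)
        assert ds.n_points == 20
        assert ds.observable_names == ["C"]

    def test_bit_reproducible_per_seed(self):
        a, b = pk_generate(seed=3), pk_generate(seed=3)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.sds, b.sds)
        c = pk_generate(seed=4)
        assert not np.array_equal(a.values, c.values)

    def test_zero_rho_noiseless(self):
        ds = pk_generate(seed=0, rho=0.0)
        b = pk_model("truth")
        traj = simulate_ode(b.model, b.theta_array(),
                            np.concatenate([[0.0], ds.times]))
        assert np.allclose(ds.values[:, 0], traj.states[1:, 1])

    def test_truth_recovered_inside_viable_region(self):
        """Fitting the final MM model must place the generating parameters
        within five likelihood orders of the fitted optimum."""
        from topaug.ekf import cost
        from topaug.sampling import nm_polish
        b = pk_model("M8")
        theta = pk_model("truth").theta_array()
        ok = 0
        for seed in range(5):
            ds = pk_generate(seed=seed)

            def f(z):
                v = cost(b.model, 10 ** np.asarray(z), ds).value
                return v if np.isfinite(v) else 1e300

            z = nm_polish(f, np.log10(theta) + 0.3, maxfev=250, restarts=1,
                          step=0.3)
            ok += cost(b.model, theta, ds).value <= f(z) + 5 * np.log(10)
        assert ok >= 4


class TestGlnModels:
    def test_gate_keeps_w_at_zero_above_threshold(self):
        for hard in (False, True):
            b = gln_model("rmm", hard_gate=hard)
            theta = b.theta_array()
            # huge external pool: Q never drops near K within the window
            b.model.initial_state = np.array([300.0, C.GLN_C0, 0.0])
            traj = simulate_ode(b.model, theta, np.linspace(-60, 100, 30))
            assert np.max(np.abs(traj.states[:, 2])) < 1e-6

    def test_rmm_with_zero_v2_reduces_to_mm(self):
        rmm = gln_model("rmm")
        mm = gln_model("mm")
        th_r = rmm.theta_array()
        i_v2 = rmm.model.param_names.index("V_2")
        th_r[i_v2] = 0.0
        th_m = np.array([th_r[rmm.model.param_names.index(p)]
                         for p in mm.model.param_names])
        grid = np.linspace(-60, 160, 45)
        tr = simulate_ode(rmm.model, th_r, grid)
        tm = simulate_ode(mm.model, th_m, grid)
        assert np.allclose(tr.states[:, :2], tm.states, atol=1e-7)

    def test_parameter_counts_are_nested(self):
        counts = {v: gln_model(v).model.n_params
                  for v in ("mm", "rmm", "e1rmm", "e2rmm")}
        assert counts["mm"] < counts["rmm"] < counts["e1rmm"] < counts["e2rmm"]

    def test_capped_activation_variant(self):
        b = gln_model("rmm", capped_w=True)
        traj = simulate_ode(b.model, b.theta_array(), np.linspace(-60, 160, 60))
        assert np.max(traj.states[:, 2]) <= 1.0 + 1e-6

    def test_growth_input_is_positive_and_increasing(self):
        t = np.linspace(-60, 160, 50)
        phi = gln_phi(t)
        assert np.all(phi > 0)
        assert np.all(np.diff(phi) > 0)

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown"):
            gln_model("qqq")


class TestGlnGenerator:
    def test_schedule_sizes(self):
        ds = gln_generate(seed=0)
        n_extra = int(np.sum(~np.isnan(ds.values[:, 0])))
        n_intra = int(np.sum(~np.isnan(ds.values[:, 1])))
        assert (n_intra, n_extra) == (14, 23)

    def test_bit_reproducible_per_seed(self):
        a, b = gln_generate(seed=9), gln_generate(seed=9)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_noiseless_external_glutamine_nonincreasing(self):
        b = gln_model("rmm")
        traj = simulate_ode(b.model, b.theta_array(), np.linspace(-60, 160, 100))
        assert np.all(np.diff(traj.states[:, 0]) <= 1e-9)

    def test_shift_lands_near_time_zero(self):
        # external glutamine crosses the activation threshold K just after 0
        b = gln_model("rmm")
        grid = np.linspace(-60, 160, 441)
        traj = simulate_ode(b.model, b.theta_array(), grid)
        K = C.GLN_THETA_TRUE["K"]
        crossing = grid[np.argmax(traj.states[:, 0] < K)]
        assert -5.0 <= crossing <= 20.0

    def test_activation_rises_after_the_shift(self):
        b = gln_model("rmm")
        grid = np.linspace(-60, 160, 100)
        traj = simulate_ode(b.model, b.theta_array(), grid)
        W = traj.states[:, 2]
        assert np.max(np.abs(W[grid < -5])) < 0.02
        assert W[-1] > 0.5


class TestRegistryAndSpecs:
    def test_register_case_plugin_hook(self):
        from topaug.casestudies import REGISTRY, register_case
        try:
            register_case("toy", lambda v: pk_model("linear"), variants=("only",))
            assert "toy" in REGISTRY
            with pytest.raises(ValueError, match="already registered"):
                register_case("toy", lambda v: None)
        finally:
            REGISTRY.pop("toy", None)

    def test_load_model_spec_with_box_override(self, tmp_path):
        import json
        from topaug.casestudies import load_model_spec
        spec = tmp_path / "m.json"
        spec.write_text(json.dumps({"case": "pk", "variant": "linear_sde",
                                    "box": {"k_A": [-2, 2]}}))
        bundle = load_model_spec(spec)
        assert bundle.model.name == "pk_linear_sde"
        assert bundle.box["k_A"] == (-2, 2)

    def test_load_model_spec_rejects_unknown_keys(self, tmp_path):
        import json
        from topaug.casestudies import load_model_spec
        spec = tmp_path / "bad.json"
        spec.write_text(json.dumps({"case": "pk", "variant": "linear",
                                    "typo": 1}))
        with pytest.raises(ValueError, match="unknown model-spec keys"):
            load_model_spec(spec)


class TestBundleRoundTrip:
    def test_dataset_regenerates_identically_from_id_and_seed(self):
        for gen, seed in ((pk_generate, 5), (gln_generate, 5)):
            a, b = gen(seed=seed), gen(seed=seed)
            assert np.array_equal(a.values, b.values, equal_nan=True)
            assert a.meta["seed"] == b.meta["seed"] == seed
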