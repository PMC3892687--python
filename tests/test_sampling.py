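import numpy as np
import pytest

from topaug.model_core import Dataset
from topaug.sampling import (EllipsoidRegion, ExploreSettings, ViableSample,
                             characterize, estimate_viable_fraction, explore,
                             project, weighted_prediction)
from topaug.viability import ViabilityRule

QUAD_SETTINGS = ExploreSettings(n_chains=3, n_steps=200, n_anneal=60, n_init=48,
                                polish_evals=120)


def quad_cost(z):
    return float(np.sum(np.asarray(z) ** 2))


def two_well_cost(z):
    z = np.asarray(z)
    if abs(z[0]) < 0.4:
        return np.inf
    c = np.sign(z[0])
    return float(((z[0] - c) / 0.2) ** 2 + np.sum((z[1:] / 0.2) ** 2))


BOX3 = np.array([[-1.5, 1.5]] * 3)


class TestExplore:
    def test_same_seed_identical_sample(self):
        a = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=5)
        b = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=5)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.costs, b.costs)

    def test_viable_flags_respect_cutoff(self):
        rule = ViabilityRule("sde-relative", delta_orders=0.0)
        s = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=1, rule=rule)
        assert s.n_viable >= 1
        assert np.all(s.costs[s.viable_flags] <= s.rule.threshold + 1e-12)

    def test_quadratic_viable_set_inside_unit_ball(self):
        # cutoff 1 above the (zero) optimum: viable iff sum z^2 <= 1
        rule = ViabilityRule("sde-relative", delta_orders=1.0 / np.log(10.0))
        s = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=2, rule=rule)
        vp = s.viable_points()
        assert vp.shape[0] > 10
        assert np.all(np.sum(vp ** 2, axis=1) <= 1.0 + 1e-9)

    def test_volume_fraction_matches_ball_volume(self):
        frac = estimate_viable_fraction(quad_cost, BOX3, threshold=1.0,
                                        n=20_000, seed=3)
        exact = (4.0 * np.pi / 3.0) / 27.0
        assert abs(frac - exact) / exact < 0.2

    def test_infinite_cost_everywhere_reports_status(self):
        s = explore(lambda z: np.inf, BOX3,
                    ExploreSettings(n_chains=2, n_steps=20, n_init=16,
                                    polish_evals=0), seed=0)
        assert s.n_viable == 0
        assert "no viable points" in s.status

    def test_all_points_inside_box(self):
        s = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=9)
        assert np.all(s.points >= BOX3[:, 0] - 1e-12)
        assert np.all(s.points <= BOX3[:, 1] + 1e-12)


class TestCharacterize:
    def test_spherical_cost_gives_one_roundish_region(self):
        rule = ViabilityRule("sde-relative", delta_orders=1.0 / np.log(10.0))
        s = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=4, rule=rule)
        regions = characterize(s, quad_cost, seed=4)
        assert len(regions) == 1
        w = np.linalg.eigvalsh(regions[0].shape)
        ratio = np.sqrt(w.max() / w.min())  # >= 1 by construction
        assert ratio <= 1.4

    def test_two_wells_give_two_regions(self):
        rule = ViabilityRule("sde-relative", delta_orders=2.0 / np.log(10.0))
        s = explore(two_well_cost, BOX3,
                    ExploreSettings(n_chains=6, n_steps=250, n_anneal=80,
                                    n_init=64, polish_evals=100), seed=6, rule=rule)
        regions = characterize(s, two_well_cost, gap=0.5, seed=6)
        assert len(regions) == 2

    def test_too_few_viable_points_empty_list(self):
        s = ViableSample(param_names=["a", "b", "c"],
                         points=np.zeros((2, 3)), costs=np.array([0.0, 0.1]),
                         box=BOX3)
        s.rule = ViabilityRule("sde-relative", threshold=1.0)
        s.viable_flags = np.array([True, False])
        regions = characterize(s, quad_cost)
        assert regions == []
        assert "too few" in s.status

    def test_merged_points_reclassify_consistently(self):
        rule = ViabilityRule("sde-relative", delta_orders=1.0 / np.log(10.0))
        s = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=8, rule=rule)
        characterize(s, quad_cost, seed=8)
        # every flagged point re-evaluates below the cutoff, bit-identically
        for z, c, flag in zip(s.points, s.costs, s.viable_flags):
            assert quad_cost(z) == c
            if flag:
                assert c <= s.rule.threshold

    def test_ellipsoid_volume_formula(self):
        reg = EllipsoidRegion(np.zeros(3), np.eye(3), radius=2.0)
        assert reg.volume() == pytest.approx(4 * np.pi / 3 * 8, rel=1e-12)


class TestProject:
    def make_sample(self):
        rule = ViabilityRule("sde-relative", delta_orders=1.0 / np.log(10.0))
        return explore(quad_cost, BOX3, QUAD_SETTINGS, seed=10, rule=rule,
                       param_names=["a", "b", "c"])

    def test_projection_onto_all_dims_is_identity(self):
        s = self.make_sample()
        out = project(s, ["a", "b", "c"])
        assert np.allclose(out["table"][["a", "b", "c"]].values, s.viable_points())

    def test_unknown_dimension_raises(self):
        with pytest.raises(KeyError, match="unknown parameter"):
            project(self.make_sample(), ["a", "zz"])

    def test_occupancy_grid_marks_viable_cells(self):
        s = self.make_sample()
        out = project(s, ["a", "b"], bins=6)
        assert out["occupancy"].shape == (6, 6)
        assert out["occupancy"].any()
        # centre cell must be occupied (the optimum is at the origin)
        assert out["occupancy"][2:4, 2:4].any()


class TestWeightedPrediction:
    def test_single_point_band_collapses(self, pk_dataset):
        from topaug.casestudies import pk_model
        b = pk_model("linear")
        s = ViableSample(param_names=list(b.model.param_names),
                         points=np.log10([[0.4, 5.0, 15.0]]),
                         costs=np.array([0.0]),
                         box=np.array([[-4, 4]] * 3))
        s.viable_flags = np.array([True])
        s.weights = np.array([1.0])
        grid = np.linspace(1, 9, 5)
        band = weighted_prediction(b.model, s, grid)
        assert np.allclose(band["se"], 0.0)

    def test_two_equal_points_average(self, pk_dataset):
        from topaug.casestudies import pk_model
        b = pk_model("linear")
        pts = np.log10([[0.3, 5.0, 15.0], [0.5, 5.0, 15.0]])
        s = ViableSample(param_names=list(b.model.param_names), points=pts,
                         costs=np.array([0.0, 0.0]), box=np.array([[-4, 4]] * 3))
        s.viable_flags = np.array([True, True])
        s.weights = np.array([0.5, 0.5])
        grid = np.linspace(1, 9, 5)
        band = weighted_prediction(b.model, s, grid)
        from topaug.model_core import simulate_ode
        g2 = np.concatenate([[0.0], grid])
        ha = simulate_ode(b.model, np.array([0.3, 5.0, 15.0]), g2).states[1:, 1]
        hb = simulate_ode(b.model, np.array([0.5, 5.0, 15.0]), g2).states[1:, 1]
        assert np.allclose(band["mean"].values, 0.5 * (ha + hb), rtol=1e-6)

    def test_empty_sample_rejected(self):
        from topaug.casestudies import pk_model
        b = pk_model("linear")
        s = ViableSample(param_names=list(b.model.param_names),
                         points=np.zeros((1, 3)), costs=np.array([np.inf]),
                         box=np.array([[-4, 4]] * 3))
        with pytest.raises(ValueError, match="no viable points"):
            weighted_prediction(b.model, s, np.linspace(1, 5, 3))


class TestSerialization:
    def test_csv_and_sidecar_round_trip(self, tmp_path):
        rule = ViabilityRule("sde-relative", delta_orders=1.0)
        s = explore(quad_cost, BOX3, QUAD_SETTINGS, seed=11, rule=rule,
                    param_names=["a", "b", "c"])
        s.to_csv(tmp_path / "s.csv", tmp_path / "s.json")
        import json
        import pandas as pd
        df = pd.read_csv(tmp_path / "s.csv")
        assert list(df.columns) == ["a", "b", "c", "cost", "viable", "weight", "chain"]
        meta = json.loads((tmp_path / "s.json").read_text())
        assert meta["seed"] == 11
        assert meta["rule"]["mode"] == "sde-relative"
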