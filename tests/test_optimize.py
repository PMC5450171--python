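import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsmextract import datasets
from rsmextract.factors import FactorSpec
from rsmextract.model import QuadraticModel
from rsmextract.optimize import (
    DesirabilitySpec,
    default_desirability_specs,
    desirability,
    grid_export,
    joint_optimize,
    maximize_in_box,
    predict,
    stationary_point,
)

from conftest import brute_force_quadratic, grid_max_oracle


def _model(k, intercept=0.0, linear=None, quadratic=None, interaction=None, name="m"):
    factors = [FactorSpec(f"f{i}", -1.0, 0.0, 1.0) for i in range(k)]
    return QuadraticModel(
        response_name=name,
        factors=factors,
        intercept=intercept,
        linear=np.zeros(k) if linear is None else np.asarray(linear, float),
        interaction=np.zeros((k, k)) if interaction is None else np.asarray(interaction, float),
        quadratic=np.zeros(k) if quadratic is None else np.asarray(quadratic, float),
    )


class TestPredict:
    def test_center_prediction_is_the_intercept(self, kwz_models):
        model = kwz_models["yield"]
        assert predict(model, np.zeros(4)) == pytest.approx(model.intercept)

    def test_vertex_equals_signed_coefficient_sum(self):
        model = _model(3, intercept=2.0, linear=[1, -2, 3], quadratic=[0.5, 0.5, 0.5],
                       interaction=np.triu(np.ones((3, 3)), 1))
        x = np.array([1.0, -1.0, 1.0])
        expected = (2.0 + (1 - -2 + 3) + 3 * 0.5
                    + (1 * -1) + (1 * 1) + (-1 * 1))
        assert predict(model, x) == pytest.approx(expected)

    def test_matches_brute_force_oracle_at_random_points(self, kwz_models):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-1, 1, size=(1000, 4))
        for model in kwz_models.values():
            assert np.max(np.abs(model.predict(pts) - brute_force_quadratic(model, pts))) < 1e-10


class TestStationaryPoint:
    def test_separable_concave_maximum(self):
        model = _model(3, linear=[1, 1, 1], quadratic=[-1, -1, -1])
        sp = stationary_point(model)
        assert sp.kind == "maximum"
        assert np.allclose(sp.point, 0.5)

    def test_pure_bowl_minimum_at_origin(self):
        sp = stationary_point(_model(3, quadratic=[1, 1, 1]))
        assert sp.kind == "minimum"
        assert np.allclose(sp.point, 0.0)

    def test_fitted_tpc_surface_is_a_saddle(self, kwz_models):
        # its temperature^2 coefficient is positive while others are negative
        assert stationary_point(kwz_models["tpc"]).kind == "saddle"

    def test_singular_hessian_reported_degenerate(self):
        sp = stationary_point(_model(3, linear=[1, 0, 0]))
        assert sp.kind == "degenerate"
        assert sp.point is None


class TestMaximizeInBox:
    def test_one_factor_parabola(self):
        model = _model(1, intercept=1.0, quadratic=[-1.0])
        res = maximize_in_box(model)
        assert res.value == pytest.approx(1.0, abs=1e-8)
        assert res.coded_point[0] == pytest.approx(0.0, abs=1e-6)
        assert not any(res.boundary)

    def test_interior_optimum_matches_stationary_point(self):
        model = _model(4, linear=[0.4, -0.2, 0.1, 0.3], quadratic=[-1, -2, -1.5, -1])
        res = maximize_in_box(model)
        assert np.allclose(res.coded_point, stationary_point(model).point, atol=1e-6)

    def test_yield_surface_matches_dense_grid_oracle(self, kwz_models):
        model = kwz_models["yield"]
        res = maximize_in_box(model)
        grid_best, _ = grid_max_oracle(model, n=21)
        assert res.value >= grid_best - 1e-9
        assert res.value - grid_best < 0.02

    def test_never_below_design_point_predictions(self, kwz, kwz_models):
        design, _ = kwz
        for model in kwz_models.values():
            res = maximize_in_box(model)
            assert np.all(np.abs(res.coded_point) <= 1 + 1e-9)
            assert res.value >= np.max(model.predict(design.coded)) - 1e-9

    def test_natural_point_decodes_coded_point(self, kwz_models):
        res = maximize_in_box(kwz_models["abts"])
        for f, x in zip(kwz_models["abts"].factors, res.coded_point):
            assert res.natural_point[f.name] == pytest.approx(f.decode(x))

    def test_restricted_box_respected(self, kwz_models):
        box = [(-0.5, 0.5)] * 4
        res = maximize_in_box(kwz_models["tpc"], box=box)
        assert np.all(res.coded_point >= -0.5 - 1e-9)
        assert np.all(res.coded_point <= 0.5 + 1e-9)


class TestDesirability:
    SPEC = {
        "a": DesirabilitySpec(goal="maximize", low=0.0, high=10.0),
        "b": DesirabilitySpec(goal="maximize", low=0.0, high=10.0),
    }

    def test_all_at_upper_anchor_gives_one(self):
        assert desirability({"a": 10.0, "b": 12.0}, self.SPEC) == 1.0

    def test_single_zero_annihilates(self):
        assert desirability({"a": 0.0, "b": 10.0}, self.SPEC) == 0.0

    def test_geometric_mean_of_quarter_and_one(self):
        assert desirability({"a": 2.5, "b": 10.0}, self.SPEC) == pytest.approx(0.5)

    def test_minimize_and_target_goals(self):
        spec = {"m": DesirabilitySpec(goal="minimize", low=0.0, high=10.0)}
        assert desirability({"m": 0.0}, spec) == 1.0
        assert desirability({"m": 10.0}, spec) == 0.0
        tgt = {"t": DesirabilitySpec(goal="target", low=0.0, high=10.0, target=5.0)}
        assert desirability({"t": 5.0}, tgt) == 1.0
        assert desirability({"t": 2.5}, tgt) == pytest.approx(0.5)

    @given(
        y=st.floats(0.0, 10.0),
        delta=st.floats(0.0, 5.0),
        other=st.floats(0.5, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_each_response(self, y, delta, other):
        d0 = desirability({"a": y, "b": other}, self.SPEC)
        d1 = desirability({"a": y + delta, "b": other}, self.SPEC)
        assert d1 >= d0 - 1e-12

    def test_weight_exponent(self):
        spec = {"a": DesirabilitySpec(goal="maximize", low=0.0, high=1.0, weight=2.0)}
        assert desirability({"a": 0.5}, spec) == pytest.approx(0.25)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            DesirabilitySpec(goal="maximize", low=1.0, high=1.0)
        with pytest.raises(ValueError):
            DesirabilitySpec(goal="maximize", low=0.0, high=1.0, weight=0.0)


class TestJointOptimize:
    def test_identical_surfaces_reduce_to_single_optimum(self):
        model = _model(3, linear=[0.5, -0.3, 0.2], quadratic=[-1, -1, -1], name="y1")
        single = maximize_in_box(model)
        joint = joint_optimize({"y1": model, "y2": model})
        assert np.allclose(joint.coded_point, single.coded_point, atol=1e-4)

    def test_symmetric_tradeoff_lands_between_optima(self):
        # two concave surfaces with mirrored optima at +/-0.5 on axis 0
        up = _model(3, linear=[1.0, 0, 0], quadratic=[-1, -1, -1], name="up")
        down = _model(3, linear=[-1.0, 0, 0], quadratic=[-1, -1, -1], name="down")
        joint = joint_optimize({"up": up, "down": down})
        assert joint.coded_point[0] == pytest.approx(0.0, abs=1e-4)

    def test_default_anchor_range_over_box(self, kwz_models):
        specs = default_desirability_specs({"yield": kwz_models["yield"]})
        grid_best, _ = grid_max_oracle(kwz_models["yield"], n=21)
        assert specs["yield"].high == pytest.approx(grid_best, abs=0.02)

    def test_study_joint_optimum_reports_all_responses(self, kwz_models):
        joint = joint_optimize(kwz_models)
        assert set(joint.response_values) == set(kwz_models)
        assert 0.0 < joint.value <= 1.0
        assert np.all(np.abs(joint.coded_point) <= 1 + 1e-9)

    def test_mismatched_factors_rejected(self):
        a = _model(3, name="a")
        b = QuadraticModel(
            response_name="b",
            factors=[FactorSpec(f"g{i}", -1.0, 0.0, 1.0) for i in range(3)],
            intercept=0.0, linear=np.zeros(3),
            interaction=np.zeros((3, 3)), quadratic=np.zeros(3),
        )
        with pytest.raises(ValueError, match="same factor"):
            joint_optimize({"a": a, "b": b})


def test_grid_export_lattice(kwz_models):
    df = grid_export(kwz_models["yield"], n=5)
    assert len(df) == 5**4
    assert list(df.columns) == ["ethanol", "temperature", "ratio", "time", "predicted"]
    # lattice predictions agree with direct evaluation
    pts = df[["ethanol", "temperature", "ratio", "time"]].to_numpy()
    assert np.allclose(df["predicted"], kwz_models["yield"].predict(pts))
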