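import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelmsm.model_core import (
    BaselineDef,
    ConstantHazard,
    DerivedBaselineDef,
    ModelSpec,
    ParameterVector,
    PiecewiseHazard,
    SpecificationError,
    StateGraph,
    Term,
    TransitionModel,
    WeibullHazard,
    baseline_hazard,
    intensity_matrix,
    resolve_parameters,
)


class TestStateGraph:
    def test_absorbing_has_no_outgoing(self):
        g = StateGraph(("a", "b"), (("a", "b"),))
        assert g.absorbing == frozenset({"b"})

    def test_self_transition_rejected(self):
        with pytest.raises(SpecificationError):
            StateGraph(("a", "b"), (("a", "a"),))

    def test_unknown_state_rejected(self):
        with pytest.raises(SpecificationError):
            StateGraph(("a", "b"), (("a", "c"),))

    def test_duplicate_transition_rejected(self):
        with pytest.raises(SpecificationError):
            StateGraph(("a", "b"), (("a", "b"), ("a", "b")))


class TestBaselineHazard:
    def test_weibull_shape_one_is_constant(self):
        assert baseline_hazard(WeibullHazard(0.5, 1.0), 3.0) == pytest.approx(0.5)

    def test_weibull_direct_evaluation(self):
        assert baseline_hazard(WeibullHazard(0.5, 2.0), 2.0) == pytest.approx(2.0)

    def test_piecewise_right_continuous_at_cutpoint(self):
        h = PiecewiseHazard((15.0,), (0.1, 0.3))
        assert baseline_hazard(h, 14.9) == pytest.approx(0.1)
        assert baseline_hazard(h, 15.0) == pytest.approx(0.3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            baseline_hazard(ConstantHazard(0.5), -1.0)

    def test_weibull_cumhaz_closed_form(self):
        h = WeibullHazard(0.5, 2.0)
        assert h.cumhaz(1.0, 3.0) == pytest.approx(0.5 * (9 - 1))

    def test_piecewise_cumhaz(self):
        h = PiecewiseHazard((15.0,), (0.1, 0.3))
        assert h.cumhaz(0.0, 20.0) == pytest.approx(0.1 * 15 + 0.3 * 5)

    def test_nonpositive_weibull_params_rejected(self):
        with pytest.raises(SpecificationError):
            WeibullHazard(0.0, 1.0)
        with pytest.raises(SpecificationError):
            WeibullHazard(1.0, -1.0)


def _ratio_spec(k):
    """lam5 = lam1*lam6 / (k*lam2) on a toy graph."""
    graph = StateGraph(
        ("a", "b", "c", "d"),
        (("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")),
    )
    return ModelSpec(
        graph=graph,
        transitions={
            ("a", "b"): TransitionModel(("a", "b"), "lam1"),
            ("a", "c"): TransitionModel(("a", "c"), "lam2"),
            ("a", "d"): TransitionModel(("a", "d"), "lam6"),
            ("b", "c"): TransitionModel(("b", "c"), "lam5"),
        },
        baselines={
            "lam1": BaselineDef("lam1", "weibull"),
            "lam2": BaselineDef("lam2", "weibull"),
            "lam6": BaselineDef("lam6", "weibull"),
            "lam5": DerivedBaselineDef(
                "lam5", "ratio_product", ("lam1", "lam6", "lam2"), n_num=2, k=k
            ),
        },
    )


class TestConstraints:
    def test_shared_baseline_name_is_identical(self):
        graph = StateGraph(("a", "b", "c"), (("a", "c"), ("b", "c")))
        spec = ModelSpec(
            graph=graph,
            transitions={
                ("a", "c"): TransitionModel(("a", "c"), "lam3"),
                ("b", "c"): TransitionModel(("b", "c"), "lam3"),
            },
            baselines={"lam3": BaselineDef("lam3", "weibull")},
        )
        res = resolve_parameters(spec, {"lam3.a": 0.4, "lam3.b": 1.7})
        assert res[("a", "c")].baseline is res[("b", "c")].baseline

    def test_ratio_rule_symmetry(self):
        # k=1 and lam1 == lam2 implies lam5 == lam6 pointwise
        spec = _ratio_spec(1.0)
        p = {"lam1.a": 0.3, "lam1.b": 1.4, "lam2.a": 0.3, "lam2.b": 1.4,
             "lam6.a": 0.2, "lam6.b": 1.1}
        res = resolve_parameters(spec, p)
        t = np.linspace(0.1, 10, 25)
        np.testing.assert_allclose(
            res[("b", "c")].baseline.hazard(t), res[("a", "d")].baseline.hazard(t)
        )

    def test_doubling_k_halves_derived_rate(self):
        p = {"lam1.a": 0.3, "lam1.b": 1.4, "lam2.a": 0.25, "lam2.b": 1.2,
             "lam6.a": 0.2, "lam6.b": 1.1}
        r1 = resolve_parameters(_ratio_spec(1.0), p)
        r2 = resolve_parameters(_ratio_spec(2.0), p)
        t = np.linspace(0.1, 10, 25)
        np.testing.assert_allclose(
            r2[("b", "c")].baseline.hazard(t), 0.5 * r1[("b", "c")].baseline.hazard(t)
        )

    def test_exp_offset_rule(self):
        graph = StateGraph(("a", "b", "c"), (("a", "b"), ("b", "c")))
        spec = ModelSpec(
            graph=graph,
            transitions={
                ("a", "b"): TransitionModel(("a", "b"), "lam"),
                ("b", "c"): TransitionModel(("b", "c"), "lam2"),
            },
            baselines={
                "lam": BaselineDef("lam"),
                "lam2": DerivedBaselineDef("lam2", "exp_offset", ("lam",), offset_param="g"),
            },
        )
        res = resolve_parameters(spec, {"lam": 0.2, "g": 0.7})
        assert res[("b", "c")].baseline.rate == pytest.approx(0.2 * math.exp(0.7))
        # zero offset: identity
        res0 = resolve_parameters(spec, {"lam": 0.2, "g": 0.0})
        assert res0[("b", "c")].baseline.rate == pytest.approx(0.2)

    def test_resolution_idempotent(self):
        spec = _ratio_spec(1.5)
        p = {"lam1.a": 0.3, "lam1.b": 1.4, "lam2.a": 0.25, "lam2.b": 1.2,
             "lam6.a": 0.2, "lam6.b": 1.1}
        r1 = resolve_parameters(spec, p)
        r2 = resolve_parameters(spec, p)
        assert r1[("b", "c")].baseline == r2[("b", "c")].baseline

    def test_cyclic_constraint_rejected(self):
        graph = StateGraph(("a", "b", "c"), (("a", "b"), ("b", "c")))
        with pytest.raises(SpecificationError):
            ModelSpec(
                graph=graph,
                transitions={
                    ("a", "b"): TransitionModel(("a", "b"), "x"),
                    ("b", "c"): TransitionModel(("b", "c"), "y"),
                },
                baselines={
                    "x": DerivedBaselineDef("x", "exp_offset", ("y",), offset_param="g1"),
                    "y": DerivedBaselineDef("y", "exp_offset", ("x",), offset_param="g2"),
                },
            )

    def test_missing_parameter_errors(self, two_state_spec):
        with pytest.raises(SpecificationError):
            resolve_parameters(two_state_spec, {})

    def test_equal_groups_unify_labels(self):
        graph = StateGraph(("a", "b", "c"), (("a", "b"), ("b", "c")))
        spec = ModelSpec(
            graph=graph,
            transitions={
                ("a", "b"): TransitionModel(("a", "b"), "l1", (Term("x", "b1"),)),
                ("b", "c"): TransitionModel(("b", "c"), "l2", (Term("x", "b2"),)),
            },
            baselines={"l1": BaselineDef("l1"), "l2": BaselineDef("l2")},
            equal=(("b1", "b2"),),
        )
        pv = spec.parameters()
        assert "b1" in pv.names and "b2" not in pv.names
        res = resolve_parameters(spec, {"l1": 0.1, "l2": 0.2, "b1": 0.9})
        assert dict(res[("b", "c")].coefs)["x"] == pytest.approx(0.9)


class TestIntensityMatrix:
    def test_three_state_example(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        Q = intensity_matrix(three_state_spec, res, {}, 0.0)
        expected = np.array([[-0.2, 0.2, 0.0], [0.1, -0.4, 0.3], [0.0, 0.4, -0.4]])
        np.testing.assert_allclose(Q, expected)

    def test_covariate_multiplies_single_entry(self, three_state_spec, three_state_params):
        spec = three_state_spec
        spec.transitions[("1", "2")] = TransitionModel(
            ("1", "2"), "lam12", (Term("x", "beta"),)
        )
        res = resolve_parameters(spec, {**three_state_params, "beta": math.log(2.0)})
        Q = intensity_matrix(spec, res, {"x": 1.0}, 0.0)
        assert Q[0, 1] == pytest.approx(0.4)
        assert Q[1, 2] == pytest.approx(0.3)

    def test_disallowed_entry_is_zero(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        for x in (0.0, 1.0, 5.0):
            Q = intensity_matrix(three_state_spec, res, {"x": x}, 1.0)
            assert Q[0, 2] == 0.0

    def test_missing_covariate_errors(self, two_state_covariate_spec):
        res = resolve_parameters(two_state_covariate_spec, {"lam": 0.5, "beta": 1.0})
        with pytest.raises(SpecificationError):
            intensity_matrix(two_state_covariate_spec, res, {}, 0.0)

    @given(
        rates=st.lists(st.floats(1e-4, 10.0), min_size=4, max_size=4),
        t=st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_zero(self, rates, t):
        trs = (("1", "2"), ("2", "1"), ("2", "3"), ("3", "2"))
        graph = StateGraph(("1", "2", "3"), trs)
        spec = ModelSpec(
            graph=graph,
            transitions={tr: TransitionModel(tr, f"l{tr[0]}{tr[1]}") for tr in trs},
            baselines={f"l{a}{b}": BaselineDef(f"l{a}{b}") for a, b in trs},
        )
        params = dict(zip(("l12", "l21", "l23", "l32"), rates))
        Q = intensity_matrix(spec, resolve_parameters(spec, params), {}, t)
        assert np.all(Q - np.diag(np.diag(Q)) >= 0)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_frailty_scales_linearly(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        Q1 = intensity_matrix(three_state_spec, res, {}, 0.0, frailty=1.0)
        Qu = intensity_matrix(three_state_spec, res, {}, 0.0, frailty=2.5)
        np.testing.assert_allclose(Qu, 2.5 * Q1)


class TestParameterVector:
    @given(st.lists(st.floats(-8, 8), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, working):
        pv = ParameterVector(("a", "b", "c"), ("log", "identity", "logit"))
        nat = pv.to_natural(np.array(working))
        back = pv.to_working(nat)
        np.testing.assert_allclose(back, working, rtol=1e-10, atol=1e-10)

    def test_scales_enforced(self):
        with pytest.raises(SpecificationError):
            ParameterVector(("a",), ("bogus",))
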