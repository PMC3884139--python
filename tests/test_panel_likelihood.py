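import math

import numpy as np
import pytest

from panelmsm.model_core import (
    BaselineDef,
    ModelSpec,
    PiecewiseHazard,
    StateGraph,
    Term,
    TransitionModel,
    resolve_parameters,
)
from panelmsm.panel_likelihood import (
    ObservationRecord,
    PanelData,
    PanelDesign,
    Subject,
    length_of_stay,
    state_occupancy,
    subject_loglik,
    total_loglik,
    transition_probability,
)


def _rec(t, states, exact=False, **cov):
    if isinstance(states, str):
        states = (states,)
    return ObservationRecord(t, tuple(states), exact=exact, covariates=cov)


class TestTransitionProbability:
    def test_two_state_closed_form(self, two_state_spec):
        res = resolve_parameters(two_state_spec, {"lam": 0.5})
        P = transition_probability(two_state_spec, res, {}, 0.0, 2.0)
        assert P[0, 0] == pytest.approx(math.exp(-1.0), abs=1e-12)
        assert P[0, 1] == pytest.approx(1 - math.exp(-1.0), abs=1e-12)

    def test_piecewise_product_of_survivals(self):
        graph = StateGraph(("1", "2"), (("1", "2"),))
        spec = ModelSpec(
            graph=graph,
            transitions={("1", "2"): TransitionModel(("1", "2"), "lam")},
            baselines={"lam": BaselineDef("lam", "piecewise", (1.0,))},
        )
        res = resolve_parameters(spec, {"lam.1": 0.5, "lam.2": 1.0})
        P = transition_probability(spec, res, {}, 0.0, 2.0)
        assert P[0, 0] == pytest.approx(math.exp(-1.5), abs=1e-12)

    def test_chapman_kolmogorov(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        P03 = transition_probability(three_state_spec, res, {}, 0.0, 3.0)
        prod = np.eye(3)
        for a, b in ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)):
            prod = prod @ transition_probability(three_state_spec, res, {}, a, b)
        np.testing.assert_allclose(P03, prod, atol=1e-10)

    def test_identity_at_zero_length(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        np.testing.assert_allclose(
            transition_probability(three_state_spec, res, {}, 2.0, 2.0), np.eye(3)
        )

    def test_rows_sum_to_one(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        P = transition_probability(three_state_spec, res, {}, 0.0, 7.0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0) and np.all(P <= 1)

    def test_time_homogeneous_depends_on_gap_only(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        P1 = transition_probability(three_state_spec, res, {}, 0.0, 1.5)
        P2 = transition_probability(three_state_spec, res, {}, 4.0, 5.5)
        np.testing.assert_allclose(P1, P2, atol=1e-12)

    def test_interior_split_invariance(self, three_state_spec, three_state_params):
        res = resolve_parameters(three_state_spec, three_state_params)
        whole = transition_probability(three_state_spec, res, {}, 0.0, 4.0)
        split = transition_probability(
            three_state_spec, res, {}, 0.0, 1.234
        ) @ transition_probability(three_state_spec, res, {}, 1.234, 4.0)
        np.testing.assert_allclose(whole, split, atol=1e-10)


class TestSubjectLoglik:
    def test_survival(self, two_state_spec):
        s = Subject(0, [_rec(0.0, "1"), _rec(1.0, "1")])
        assert subject_loglik(two_state_spec, s, {"lam": 0.5}) == pytest.approx(-0.5)

    def test_exact_death(self, two_state_spec):
        s = Subject(0, [_rec(0.0, "1"), _rec(1.0, "2", exact=True)])
        assert subject_loglik(two_state_spec, s, {"lam": 0.5}) == pytest.approx(
            -0.5 + math.log(0.5)
        )

    def test_censoring_set_sums_to_one(self, two_state_spec):
        s = Subject(0, [_rec(0.0, "1"), _rec(1.0, ("1", "2"))])
        assert subject_loglik(two_state_spec, s, {"lam": 0.5}) == pytest.approx(0.0, abs=1e-12)

    def test_impossible_sequence_is_minus_inf(self, two_state_spec):
        s = Subject(0, [_rec(0.0, "2"), _rec(1.0, "1")])
        with pytest.warns(RuntimeWarning):
            assert subject_loglik(two_state_spec, s, {"lam": 0.5}) == -np.inf

    @pytest.mark.parametrize("n_states", [2, 3])
    def test_fully_observed_path_matches_sojourn_product(self, n_states):
        # progressive chain, exact records at every jump plus a final censored
        # observation: the likelihood must equal the analytic product of
        # sojourn densities and jump intensities
        from panelmsm.simulate import simulate_path, subject_rng

        if n_states == 2:
            trs = (("1", "2"),)
            rates = {("1", "2"): 0.5}
        else:
            # a pure chain: every recorded jump then pins its pre-state
            trs = (("1", "2"), ("2", "3"))
            rates = {("1", "2"): 0.3, ("2", "3"): 0.4}
        graph = StateGraph(tuple(str(i) for i in range(1, n_states + 1)), trs)
        spec = ModelSpec(
            graph=graph,
            transitions={tr: TransitionModel(tr, f"l{tr[0]}{tr[1]}") for tr in trs},
            baselines={f"l{a}{b}": BaselineDef(f"l{a}{b}") for a, b in trs},
        )
        params = {f"l{a}{b}": r for (a, b), r in rates.items()}
        res = resolve_parameters(spec, params)
        out = {s: sum(r for (a, _), r in rates.items() if a == s) for s in graph.states}
        horizon = 6.0
        for trial in range(8):
            rng = subject_rng(42, n_states, trial)
            path = simulate_path(spec, res, [(0.0, {})], "1", horizon, rng)
            recs = [_rec(0.0, "1")] + [_rec(t, s, exact=True) for t, s in path[1:]]
            if path[-1][1] not in graph.absorbing:
                recs.append(_rec(horizon, path[-1][1]))
            s = Subject(trial, recs)
            got = subject_loglik(spec, s, params)
            expected = 0.0
            full = list(path)
            if path[-1][1] not in graph.absorbing:
                full.append((horizon, None))
            for (t0, s0), (t1, s1) in zip(full, full[1:]):
                expected -= out[s0] * (t1 - t0)
                if s1 is not None:
                    expected += math.log(rates[(s0, s1)])
            assert got == pytest.approx(expected, abs=1e-8)


class TestTotalLoglik:
    def test_additivity(self, two_state_spec):
        s = Subject(0, [_rec(0.0, "1"), _rec(1.0, "1")])
        s2 = Subject(1, [_rec(0.0, "1"), _rec(1.0, "1")])
        one = total_loglik(two_state_spec, PanelData([s]), {"lam": 0.5})
        two = total_loglik(two_state_spec, PanelData([s, s2]), {"lam": 0.5})
        assert two == pytest.approx(2 * one)

    def test_empty_data(self, two_state_spec):
        assert total_loglik(two_state_spec, PanelData([]), {"lam": 0.5}) == 0.0

    def test_generating_parameters_beat_perturbed(self, three_state_spec, three_state_params):
        # Monte-Carlo likelihood comparison: the generating parameters should
        # out-score a doubled rate in nearly every replicate
        from panelmsm.simulate import simulate_path, state_at, subject_rng

        res = resolve_parameters(three_state_spec, three_state_params)
        wrong = dict(three_state_params)
        wrong["lam12"] = 2 * wrong["lam12"]
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            subjects = []
            for i in range(50):
                rng = subject_rng(rep, i)
                path = simulate_path(three_state_spec, res, [(0.0, {})], "1", 5.0, rng)
                recs = [_rec(float(t), state_at(path, t)) for t in range(0, 6)]
                subjects.append(Subject(i, recs))
            data = PanelData(subjects)
            if total_loglik(three_state_spec, data, three_state_params) > total_loglik(
                three_state_spec, data, wrong
            ):
                wins += 1
        assert wins >= 0.95 * n_rep


class TestOccupancyAndLengthOfStay:
    def test_absorbing_initial_state(self, two_state_spec):
        occ = state_occupancy(two_state_spec, {}, {"lam": 0.5}, "2", [0.0, 1.0, 5.0])
        np.testing.assert_allclose(occ[:, 1], 1.0)

    def test_two_state_closed_form(self, two_state_spec):
        occ = state_occupancy(two_state_spec, {}, {"lam": 0.5}, "1", [0.0, 2.0])
        np.testing.assert_allclose(occ[1], [math.exp(-1), 1 - math.exp(-1)], atol=1e-10)

    def test_consistency_with_transition_probability(
        self, three_state_spec, three_state_params
    ):
        grid = np.linspace(0.0, 8.0, 9)
        occ = state_occupancy(three_state_spec, {}, three_state_params, "1", grid)
        res = resolve_parameters(three_state_spec, three_state_params)
        P = transition_probability(three_state_spec, res, {}, 0.0, 8.0)
        np.testing.assert_allclose(occ[-1], P[0], atol=1e-10)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-10)

    def test_length_of_stay_closed_form(self, two_state_spec):
        los = length_of_stay(two_state_spec, {}, {"lam": 0.5}, "1", 2.0)
        assert los[0] == pytest.approx((1 - math.exp(-1)) / 0.5, abs=1e-8)
        assert los[1] == pytest.approx(2.0 - (1 - math.exp(-1)) / 0.5, abs=1e-8)

    def test_length_of_stay_absorbing(self, two_state_spec):
        los = length_of_stay(two_state_spec, {}, {"lam": 0.5}, "2", 40.0)
        assert los[1] == pytest.approx(40.0, abs=1e-10)

    def test_length_of_stay_conservation(self, three_state_spec, three_state_params):
        los = length_of_stay(three_state_spec, {}, three_state_params, "1", 40.0)
        assert los.sum() == pytest.approx(40.0, abs=1e-6)

    def test_invalid_horizon(self, two_state_spec):
        with pytest.raises(ValueError):
            length_of_stay(two_state_spec, {}, {"lam": 0.5}, "1", 0.0)


class TestPanelDesign:
    def test_matches_subject_loop(self, three_state_spec, three_state_params):
        from panelmsm.simulate import simulate_path, state_at, subject_rng

        res = resolve_parameters(three_state_spec, three_state_params)
        subjects = []
        for i in range(25):
            rng = subject_rng(5, i)
            path = simulate_path(three_state_spec, res, [(0.0, {})], "1", 6.0, rng)
            recs = [_rec(float(t), state_at(path, t)) for t in range(0, 7)]
            subjects.append(Subject(i, recs))
        # one subject with a censoring set triggers the fallback path
        subjects.append(Subject("set", [_rec(0.0, "1"), _rec(2.0, ("1", "2"))]))
        # one subject with an exact transition
        subjects.append(Subject("ex", [_rec(0.0, "1"), _rec(1.5, "2", exact=True)]))
        data = PanelData(subjects)
        design = PanelDesign(three_state_spec, data)
        fast = design.loglik(res)
        slow = total_loglik(three_state_spec, data, three_state_params)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_covariate_patterns_separate_tables(self, two_state_covariate_spec):
        params = {"lam": 0.3, "beta": 0.8}
        subs = [
            Subject(0, [_rec(0.0, "1", x=0.0), _rec(1.0, "1", x=0.0)]),
            Subject(1, [_rec(0.0, "1", x=1.0), _rec(1.0, "1", x=1.0)]),
        ]
        data = PanelData(subs)
        design = PanelDesign(two_state_covariate_spec, data)
        got = design.loglik(resolve_parameters(two_state_covariate_spec, params))
        expected = -0.3 - 0.3 * math.exp(0.8)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_multi_frailty_consistency(self, three_state_spec, three_state_params):
        from panelmsm.simulate import simulate_path, state_at, subject_rng

        res = resolve_parameters(three_state_spec, three_state_params)
        subjects = []
        for i in range(10):
            rng = subject_rng(11, i)
            path = simulate_path(three_state_spec, res, [(0.0, {})], "1", 4.0, rng)
            recs = [_rec(float(t), state_at(path, t)) for t in range(0, 5)]
            subjects.append(Subject(i, recs, cluster=i % 3))
        design = PanelDesign(three_state_spec, PanelData(subjects))
        us = np.array([0.4, 1.0, 3.0])
        multi = design.cluster_logliks_multi(res, us)
        for i, u in enumerate(us):
            np.testing.assert_allclose(
                multi[i], design.cluster_logliks(res, frailty=float(u)), atol=1e-9
            )


class TestValidation:
    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            Subject(0, [_rec(1.0, "1"), _rec(1.0, "1")])

    def test_entry_after_first_record_rejected(self):
        with pytest.raises(ValueError):
            Subject(0, [_rec(1.0, "1")], entry_time=2.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            Subject(0, [])

    def test_exact_set_rejected(self):
        with pytest.raises(ValueError):
            ObservationRecord(1.0, ("1", "2"), exact=True)
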