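"""Hidden-state (misclassification) models and the remission workflow.

The observed code at a visit may differ from the underlying state; emission
probabilities are fixed structural constants or visit-level logistic terms.
Likelihood evaluation uses the standard forward recursion, alternating
transition-probability steps over inter-visit gaps with per-visit emission
weighting.

The remission application recodes zero/nonzero activity-count sequences into
codes O1 (nonzero count), O2 (first or second zero of a run) and O3 (third or
later consecutive zero); the three-state hidden model (Model A) allows O2
visits to arise from active disease, while Models B and C are two-state
recodings fitted without misclassification.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np

from .model_core import (
    BaselineDef,
    ModelSpec,
    SpecificationError,
    StateGraph,
    Term,
    TransitionModel,
    intensity_matrix,
    resolve_parameters,
)
from .panel_likelihood import (
    ObservationRecord,
    PanelData,
    Subject,
    length_of_stay,
    subject_loglik,
    transition_probability,
)

__all__ = [
    "EmissionModel",
    "RemissionCoding",
    "recode_zero_runs",
    "emission_matrix",
    "forward_loglik",
    "HMMLikelihood",
    "build_remission_model",
    "build_two_state_model",
    "misclassification_posterior",
    "remission_length_of_stay",
    "posterior_table",
    "panel_from_counts",
    "simulate_remission_scenario",
    "simulate_remission_counts",
]

INTERCEPT = "1"  # emission covariate name meaning a constant 1


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmissionModel:
    """Matrix of Pr{O(t)=code | S(t)=hidden}.

    Each entry is a float (structural 0/1), ``("logit", terms)`` for a
    logistic term in visit-level covariates, or ``"rest"`` for one minus the
    sum of the other entries in the row.
    """

    hidden: tuple[str, ...]
    codes: tuple[str, ...]
    entries: tuple[tuple[Any, ...], ...]

    def __post_init__(self):
        if len(self.entries) != len(self.hidden):
            raise SpecificationError("one emission row per hidden state required")
        for row in self.entries:
            if len(row) != len(self.codes):
                raise SpecificationError("emission row length mismatch")
            if sum(1 for e in row if e == "rest") > 1:
                raise SpecificationError("at most one 'rest' entry per row")

    def param_scales(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for row in self.entries:
            for e in row:
                if isinstance(e, tuple) and e[0] == "logit":
                    for term in e[1]:
                        out[term.label] = "identity"
        return out

    @property
    def covariate_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for row in self.entries:
            for e in row:
                if isinstance(e, tuple) and e[0] == "logit":
                    for term in e[1]:
                        if term.covariate not in (INTERCEPT,) and term.covariate not in seen:
                            seen.append(term.covariate)
        return tuple(seen)

    def bind(self, natural: Mapping[str, float]) -> "BoundEmission":
        values = {}
        for label in self.param_scales():
            values[label] = float(natural[label])
        return BoundEmission(self, values)


@dataclass(frozen=True)
class BoundEmission:
    model: EmissionModel
    values: Mapping[str, float]

    @property
    def codes(self) -> tuple[str, ...]:
        return self.model.codes

    def row(self, hidden_state: str, covariates: Mapping[str, float]) -> np.ndarray:
        r = self.model.hidden.index(hidden_state)
        row = self.model.entries[r]
        out = np.zeros(len(self.model.codes))
        rest_idx = None
        for c, e in enumerate(row):
            if e == "rest":
                rest_idx = c
            elif isinstance(e, tuple) and e[0] == "logit":
                lp = 0.0
                for term in e[1]:
                    x = 1.0 if term.covariate == INTERCEPT else float(
                        covariates.get(term.covariate, 0.0)
                    )
                    lp += self.values[term.label] * x
                out[c] = 1.0 / (1.0 + math.exp(-lp))
            else:
                out[c] = float(e)
        if rest_idx is not None:
            out[rest_idx] = 1.0 - (out.sum() - out[rest_idx])
        return out

    def matrix(self, covariates: Mapping[str, float]) -> np.ndarray:
        return np.vstack([self.row(h, covariates) for h in self.model.hidden])


def emission_matrix(
    emission: EmissionModel, natural: Mapping[str, float], covariates: Mapping[str, float]
) -> np.ndarray:
    """Stochastic emission matrix for one visit's covariates; rows sum to 1."""
    return emission.bind(natural).matrix(covariates)


# ---------------------------------------------------------------------------
# Zero-run recoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemissionCoding:
    codes: tuple[str, ...]
    z: tuple[Any, ...]  # first-zero indicator, defined only at O2 visits
    model_b: tuple[str, ...]  # "1" active / "2" remission
    model_c: tuple[str, ...]


def recode_zero_runs(counts: Sequence[int]) -> RemissionCoding:
    """Recode an active-joint-count sequence into observed codes and the
    Model B / Model C two-state sequences.

    O1 marks a nonzero count; O2 the first or second zero of a run; O3 the
    third or later consecutive zero.  Model B assigns remission from the
    third visit of a run of >=3 zeros; Model C assigns remission to every
    visit of such a run.  Runs of <=2 zeros stay active in both.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("at least one visit required")
    if any((not float(c).is_integer()) or c < 0 for c in counts):
        raise ValueError("counts must be nonnegative integers")
    codes: list[str] = []
    z: list[Any] = []
    run = 0
    for c in counts:
        if c > 0:
            run = 0
            codes.append("O1")
            z.append(None)
        else:
            run += 1
            if run <= 2:
                codes.append("O2")
                z.append(1 if run == 1 else 0)
            else:
                codes.append("O3")
                z.append(None)
    model_b = ["1"] * len(counts)
    model_c = ["1"] * len(counts)
    i = 0
    while i < len(counts):
        if counts[i] == 0:
            j = i
            while j < len(counts) and counts[j] == 0:
                j += 1
            if j - i >= 3:
                for p in range(i, j):
                    model_c[p] = "2"
                for p in range(i + 2, j):
                    model_b[p] = "2"
            i = j
        else:
            i += 1
    return RemissionCoding(tuple(codes), tuple(z), tuple(model_b), tuple(model_c))


# ---------------------------------------------------------------------------
# Forward likelihood
# ---------------------------------------------------------------------------


def _code_mask(emission: EmissionModel, states: Sequence[str]) -> np.ndarray:
    m = np.zeros(len(emission.codes))
    for s in states:
        m[emission.codes.index(s)] = 1.0
    return m


def forward_loglik(
    spec: ModelSpec,
    subject: Subject,
    params: Mapping[str, float],
    resolved: Mapping | None = None,
    bound: BoundEmission | None = None,
    cache: dict | None = None,
) -> float:
    """Forward-recursion log-likelihood for a subject observed through the
    spec's emission model.

    The hidden-state distribution at the first visit is the occupancy row
    from ``spec.initial_state`` at the subject's entry time (delayed entry),
    weighted by the first visit's emission.
    """
    emission: EmissionModel = spec.emission
    if emission is None:
        raise SpecificationError("spec has no emission model")
    if resolved is None:
        resolved = resolve_parameters(spec, params)
    if bound is None:
        bound = emission.bind(params)
    init_state = spec.initial_state or spec.graph.states[0]
    recs = subject.records
    cov = dict(recs[0].covariates)
    M = bound.matrix(cov)
    P0 = transition_probability(
        spec, resolved, cov, subject.entry_time, recs[0].time, cache=cache
    )
    alpha = P0[spec.graph.index(init_state)] * (M @ _code_mask(emission, recs[0].states))
    loglik = 0.0
    t_prev = recs[0].time
    for rec in recs[1:]:
        tot = float(alpha.sum())
        if tot <= 0 or not np.isfinite(tot):
            warnings.warn(f"subject {subject.id}: zero forward vector", RuntimeWarning)
            return -np.inf
        loglik += math.log(tot)
        alpha = alpha / tot
        P = transition_probability(spec, resolved, cov, t_prev, rec.time, cache=cache)
        cov.update(rec.covariates)
        M = bound.matrix(cov)
        alpha = (alpha @ P) * (M @ _code_mask(emission, rec.states))
        t_prev = rec.time
    tot = float(alpha.sum())
    if tot <= 0 or not np.isfinite(tot):
        warnings.warn(f"subject {subject.id}: zero forward vector", RuntimeWarning)
        return -np.inf
    return loglik + math.log(tot)


class HMMLikelihood:
    """Vectorized forward likelihood over a panel dataset.

    Subjects sharing a visit schedule and transition-covariate sequence are
    propagated together (one matrix product per step for the whole group);
    emission weights vary freely by subject and visit.  Subjects with
    censoring-set observations fall back to the per-subject recursion.
    """

    def __init__(self, spec: ModelSpec, data: PanelData):
        if spec.emission is None:
            raise SpecificationError("spec has no emission model")
        self.spec = spec
        self.emission: EmissionModel = spec.emission
        covs = spec.covariates
        ecovs = self.emission.covariate_names
        groups: dict[tuple, list] = {}
        self._loop: list[Subject] = []
        for subj in data.subjects:
            if any(len(r.states) != 1 for r in subj.records):
                self._loop.append(subj)
                continue
            times = (float(subj.entry_time),) + tuple(float(r.time) for r in subj.records)
            covseq = []
            cov: dict[str, float] = {}
            for r in subj.records:
                cov.update(r.covariates)
                covseq.append(tuple(float(cov.get(c, 0.0)) for c in covs))
            groups.setdefault((times, tuple(covseq)), []).append(subj)
        self._groups = []
        code_index = {c: i for i, c in enumerate(self.emission.codes)}
        for (times, covseq), subjects in groups.items():
            obs = np.array(
                [[code_index[r.states[0]] for r in s.records] for s in subjects], dtype=np.intp
            )
            E = np.zeros((len(subjects), len(times) - 1, len(ecovs)))
            for si, s in enumerate(subjects):
                for vi, r in enumerate(s.records):
                    for ei, c in enumerate(ecovs):
                        E[si, vi, ei] = float(r.covariates.get(c, 0.0))
            self._groups.append((times, covseq, obs, E))
        self._covs = covs
        self._ecovs = ecovs
        self._init_idx = spec.graph.index(spec.initial_state or spec.graph.states[0])

    def _emission_tensor(self, natural, E: np.ndarray) -> np.ndarray:
        """(n_subj, n_visits, n_hidden, n_codes) emission probabilities."""
        em = self.emission
        S, V, _ = E.shape
        M = np.zeros((S, V, len(em.hidden), len(em.codes)))
        for r, row in enumerate(em.entries):
            rest_c = None
            for c, e in enumerate(row):
                if e == "rest":
                    rest_c = c
                elif isinstance(e, tuple) and e[0] == "logit":
                    lp = np.zeros((S, V))
                    for term in e[1]:
                        coef = float(natural[term.label])
                        if term.covariate == INTERCEPT:
                            lp += coef
                        else:
                            lp += coef * E[:, :, self._ecovs.index(term.covariate)]
                    M[:, :, r, c] = 1.0 / (1.0 + np.exp(-lp))
                else:
                    M[:, :, r, c] = float(e)
            if rest_c is not None:
                M[:, :, r, rest_c] = 1.0 - (M[:, :, r].sum(axis=-1) - M[:, :, r, rest_c])
        return M

    def loglik(self, natural: Mapping[str, float]) -> float:
        resolved = resolve_parameters(self.spec, natural)
        bound = self.emission.bind(natural)
        cache: dict = {}
        total = 0.0
        for times, covseq, obs, E in self._groups:
            S, V = obs.shape
            M = self._emission_tensor(natural, E)
            # W[s, v, r] = emission probability of the observed code under hidden r
            W = np.take_along_axis(M, obs[:, :, None, None], axis=3)[:, :, :, 0]
            cov0 = dict(zip(self._covs, covseq[0]))
            P0 = transition_probability(
                self.spec, resolved, cov0, times[0], times[1], cache=cache
            )
            alpha = P0[self._init_idx][None, :] * W[:, 0, :]
            ll = np.zeros(S)
            for v in range(1, V):
                tot = alpha.sum(axis=1)
                if np.any(tot <= 0):
                    return -np.inf
                ll += np.log(tot)
                alpha = alpha / tot[:, None]
                cov = dict(zip(self._covs, covseq[v - 1]))
                P = transition_probability(
                    self.spec, resolved, cov, times[v], times[v + 1], cache=cache
                )
                alpha = (alpha @ P) * W[:, v, :]
            tot = alpha.sum(axis=1)
            if np.any(tot <= 0):
                return -np.inf
            total += float((ll + np.log(tot)).sum())
        for subj in self._loop:
            ll1 = forward_loglik(
                self.spec, subj, natural, resolved=resolved, bound=bound, cache=cache
            )
            if ll1 == -np.inf:
                return -np.inf
            total += ll1
        return total


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def remission_emission(extra_terms: Sequence[Term] = ()) -> EmissionModel:
    """Emission structure of the three-state remission model: only the active
    state can be misclassified, as a zero count coded O2."""
    terms = (Term(INTERCEPT, "gamma0"), Term("Z", "gammaZ")) + tuple(extra_terms)
    return EmissionModel(
        hidden=("S1", "S2", "S3"),
        codes=("O1", "O2", "O3"),
        entries=(
            ("rest", ("logit", terms), 0.0),
            (0.0, 1.0, 0.0),
            (0.0, 0.0, 1.0),
        ),
    )


def build_remission_model(
    cutpoints: Sequence[float] = (15.0,),
    covariate_terms: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    emission_terms: Sequence[Term] = (),
    use_z_term: bool = True,
) -> ModelSpec:
    """Three-state hidden remission model (Model A).

    States S1 (active) -> S2 (early remission) -> S3 (established remission)
    -> S1; S2 and S3 are both reported as remission.  ``covariate_terms``
    maps "12"/"31"/"23" to (covariate, label) pairs.
    """
    graph = StateGraph(
        ("S1", "S2", "S3"),
        (("S1", "S2"), ("S2", "S3"), ("S3", "S1")),
        unobservable=frozenset({"S2"}),
    )
    cutpoints = tuple(float(c) for c in cutpoints)
    kind = "piecewise" if cutpoints else "constant"
    baselines = {
        name: BaselineDef(name, kind, cutpoints)
        for name in ("lam12", "lam23", "lam31")
    }
    ct = {k: tuple(v) for k, v in (covariate_terms or {}).items()}
    transitions = {
        ("S1", "S2"): TransitionModel(
            ("S1", "S2"), "lam12", tuple(Term(c, l) for c, l in ct.get("12", ()))
        ),
        ("S2", "S3"): TransitionModel(
            ("S2", "S3"), "lam23", tuple(Term(c, l) for c, l in ct.get("23", ()))
        ),
        ("S3", "S1"): TransitionModel(
            ("S3", "S1"), "lam31", tuple(Term(c, l) for c, l in ct.get("31", ()))
        ),
    }
    if use_z_term:
        emission = remission_emission(tuple(emission_terms))
    else:
        terms = (Term(INTERCEPT, "gamma0"),) + tuple(emission_terms)
        emission = EmissionModel(
            hidden=("S1", "S2", "S3"),
            codes=("O1", "O2", "O3"),
            entries=(
                ("rest", ("logit", terms), 0.0),
                (0.0, 1.0, 0.0),
                (0.0, 0.0, 1.0),
            ),
        )
    return ModelSpec(
        graph=graph,
        transitions=transitions,
        baselines=baselines,
        emission=emission,
        state_groups={"active": ("S1",), "remission": ("S2", "S3")},
        initial_state="S1",
    )


def build_two_state_model(
    cutpoints: Sequence[float] = (15.0,),
    covariate_terms: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> ModelSpec:
    """Two alternating states (1 active, 2 remission) with no misclassification;
    used for the recoded Model B / Model C sequences."""
    graph = StateGraph(("1", "2"), (("1", "2"), ("2", "1")))
    cutpoints = tuple(float(c) for c in cutpoints)
    kind = "piecewise" if cutpoints else "constant"
    ct = {k: tuple(v) for k, v in (covariate_terms or {}).items()}
    return ModelSpec(
        graph=graph,
        transitions={
            ("1", "2"): TransitionModel(
                ("1", "2"), "lam12", tuple(Term(c, l) for c, l in ct.get("12", ()))
            ),
            ("2", "1"): TransitionModel(
                ("2", "1"), "lam21", tuple(Term(c, l) for c, l in ct.get("21", ()))
            ),
        },
        baselines={
            "lam12": BaselineDef("lam12", kind, cutpoints),
            "lam21": BaselineDef("lam21", kind, cutpoints),
        },
        state_groups={"active": ("1",), "remission": ("2",)},
        initial_state="1",
    )


def misclassification_posterior(p_o2_given_s1: float, pi1: float, pi2: float) -> float:
    """Bayes posterior Pr(S1 | O2) from Pr(O2|S1), using Pr(O2|S2)=1 and
    occupancy proportions pi1, pi2 for S1 and S2."""
    if pi1 < 0 or pi2 < 0:
        raise ValueError("occupancy proportions must be nonnegative")
    if pi1 + pi2 <= 0:
        raise ValueError("pi1 + pi2 must be positive")
    if not 0.0 <= p_o2_given_s1 <= 1.0:
        raise ValueError("probability out of range")
    num = p_o2_given_s1 * pi1
    return num / (num + pi2)


def remission_length_of_stay(
    spec: ModelSpec,
    params: Mapping[str, float],
    covariates: Mapping[str, float],
    horizon: float = 40.0,
    t0: float = 0.0,
) -> dict[str, float]:
    """Expected years per reporting group (active/remission) over [t0, t0+horizon]."""
    init = spec.initial_state or spec.graph.states[0]
    los = length_of_stay(spec, covariates, params, init, horizon, t0=t0)
    groups = spec.state_groups or {s: (s,) for s in spec.graph.states}
    out = {}
    for name, members in groups.items():
        out[name] = float(sum(los[spec.graph.index(s)] for s in members))
    out["_per_state"] = {s: float(los[i]) for i, s in enumerate(spec.graph.states)}
    return out


def posterior_table(
    spec: ModelSpec,
    params: Mapping[str, float],
    horizon: float = 40.0,
    covariates: Mapping[str, float] | None = None,
):
    """Posterior Pr(S1 | O2) by first/second-zero indicator and baseline period.

    Occupancy proportions for S1 and S2 are approximated by the proportions
    of expected length of stay within each piecewise-baseline period,
    renormalized over {S1, S2}.
    """
    import pandas as pd

    covariates = dict(covariates or {})
    init = spec.initial_state or spec.graph.states[0]
    cuts: list[float] = []
    for bd in spec.baselines.values():
        cuts.extend(c for c in getattr(bd, "cutpoints", ()) if 0.0 < c < horizon)
    edges = [0.0] + sorted(set(cuts)) + [horizon]
    bound = spec.emission.bind(params)
    i1, i2 = spec.graph.index("S1"), spec.graph.index("S2")
    o2 = spec.emission.codes.index("O2")
    rows = []
    los_cum = {0.0: np.zeros(spec.graph.n_states)}
    for b in edges[1:]:
        los_cum[b] = length_of_stay(spec, covariates, params, init, b)
    for a, b in zip(edges, edges[1:]):
        seg = los_cum[b] - los_cum[a]
        pi1, pi2 = float(seg[i1]), float(seg[i2])
        tot = pi1 + pi2
        for z in (1.0, 0.0):
            p_o2_s1 = float(bound.row("S1", {**covariates, "Z": z})[o2])
            rows.append(
                {
                    "period_start": a,
                    "period_end": b,
                    "Z": z,
                    "p_o2_given_s1": p_o2_s1,
                    "pi1": pi1 / tot if tot > 0 else math.nan,
                    "pi2": pi2 / tot if tot > 0 else math.nan,
                    "posterior_s1_given_o2": misclassification_posterior(
                        p_o2_s1, pi1, pi2
                    )
                    if tot > 0
                    else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Data plumbing and simulation
# ---------------------------------------------------------------------------


def panel_from_counts(counts_by_subject, model: str, covariates=None) -> PanelData:
    """Build PanelData from per-subject (times, counts) sequences.

    ``model`` is "A" (observed codes O1/O2/O3 with the Z covariate), "B" or
    "C" (recoded two-state sequences).
    """
    subjects = []
    for sid, (times, counts) in counts_by_subject.items():
        coding = recode_zero_runs(counts)
        cov = dict((covariates or {}).get(sid, {}))
        recs = []
        for i, t in enumerate(times):
            if model == "A":
                c = dict(cov)
                c["Z"] = float(coding.z[i]) if coding.z[i] is not None else 0.0
                recs.append(ObservationRecord(float(t), (coding.codes[i],), covariates=c))
            elif model == "B":
                recs.append(ObservationRecord(float(t), (coding.model_b[i],), covariates=dict(cov)))
            elif model == "C":
                recs.append(ObservationRecord(float(t), (coding.model_c[i],), covariates=dict(cov)))
            else:
                raise ValueError("model must be 'A', 'B' or 'C'")
        subjects.append(Subject(sid, recs, entry_time=0.0))
    return PanelData(subjects)


def simulate_remission_scenario(
    n: int = 400,
    n_visits: int = 12,
    seed: int = 0,
    truth: Mapping[str, float] | None = None,
    cutpoints: Sequence[float] = (),
):
    """Hidden three-state scenario with exogenous first-zero indicator Z.

    Observed codes are drawn from the emission matrix given the simulated
    hidden state; Z is a visit-level binary covariate entering the
    misclassification logit.  Returns (spec, truth, PanelData).
    """
    from .simulate import simulate_path, state_at, subject_rng

    spec = build_remission_model(cutpoints=cutpoints)
    if truth is None:
        truth = {
            "lam12": 0.15,
            "lam23": 0.8,
            "lam31": 0.35,
            "gamma0": -1.2,
            "gammaZ": 1.0,
        }
    resolved = resolve_parameters(spec, truth)
    bound = spec.emission.bind(truth)
    subjects = []
    visit_times = np.arange(1.0, n_visits + 1.0)
    for i in range(n):
        rng = subject_rng(seed, i)
        path = simulate_path(spec, resolved, [(0.0, {})], "S1", visit_times[-1] + 1.0, rng)
        recs = []
        for vt in visit_times:
            hidden = state_at(path, vt)
            z = float(rng.integers(0, 2))
            probs = bound.row(hidden, {"Z": z})
            code = spec.emission.codes[rng.choice(len(probs), p=probs)]
            recs.append(ObservationRecord(float(vt), (code,), covariates={"Z": z}))
        subjects.append(Subject(i, recs, entry_time=0.0))
    return spec, dict(truth), PanelData(subjects)


def simulate_remission_counts(
    n: int = 200,
    n_visits: int = 12,
    seed: int = 0,
    rates: Mapping[str, float] | None = None,
    p_zero_active: float = 0.25,
    visit_gap: float = 1.0,
):
    """Count-sequence scenario for the Model A/B/C comparison.

    The hidden state evolves through the three-state cycle; at visits the
    active state emits a zero count with probability ``p_zero_active`` and a
    positive count otherwise, while both remission states emit zero counts.
    Returns {subject: (times, counts)}.
    """
    from .simulate import simulate_path, state_at, subject_rng

    spec = build_remission_model(cutpoints=())
    if rates is None:
        rates = {"lam12": 0.12, "lam23": 0.9, "lam31": 0.3}
    full = dict(rates)
    full.update({"gamma0": 0.0, "gammaZ": 0.0})
    resolved = resolve_parameters(spec, full)
    out = {}
    horizon = visit_gap * (n_visits + 1)
    for i in range(n):
        rng = subject_rng(seed, i, 7)
        path = simulate_path(spec, resolved, [(0.0, {})], "S1", horizon, rng)
        times = [visit_gap * (v + 1) for v in range(n_visits)]
        counts = []
        for t in times:
            s = state_at(path, t)
            if s == "S1":
                counts.append(0 if rng.random() < p_zero_active else int(1 + rng.poisson(2.0)))
            else:
                counts.append(0)
        out[i] = (times, counts)
    return spec, dict(rates), out
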