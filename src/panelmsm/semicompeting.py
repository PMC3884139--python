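"""Five-state semi-competing-risks model with informative loss to follow-up.

States: H (event-free), NF (observed non-fatal event), LTF (lost to follow-up
for the non-fatal process), NFL (a non-fatal event occurring after LTF —
never observed) and F (fatal event, absorbing).  Transition intensities are
Weibull proportional hazards:

    lam1: H->NF   lam2: H->F   lam3: NF->F   lam4: H->LTF
    lam5: LTF->NFL   lam6: LTF->F   lam7: NFL->F

Identifiability requires lam7 = lam3 (risk of death after a non-fatal event
does not depend on censoring status) and the ratio constraint
lam1/lam2 = k * lam5/lam6, so lam5(t) = lam1(t)*lam6(t)/(k*lam2(t)) with the
sensitivity constant k fixed, never estimated.

Pre-LTF events are exactly timed, so their likelihood contributions are
closed-form survival/hazard products.  After an exact LTF time the state is
marginalized over {LTF, NFL} by numerically solving the occupancy equations
of the progressive three-state sub-chain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    BaselineDef,
    DerivedBaselineDef,
    ModelSpec,
    SpecificationError,
    StateGraph,
    Term,
    TransitionModel,
    intensity_matrix,
    resolve_parameters,
)
from .panel_likelihood import ObservationRecord, PanelData, Subject

__all__ = [
    "STATES",
    "build_semicompeting_model",
    "SubjectHistory",
    "parse_history",
    "post_ltf_occupancy",
    "subject_loglik",
    "dataset_loglik",
    "occupancy_grid",
    "cumulative_incidence",
    "simulate_semicompeting_scenario",
]

STATES = ("H", "NF", "LTF", "NFL", "F")

_TRANSITIONS = (
    ("H", "NF"),
    ("H", "F"),
    ("NF", "F"),
    ("H", "LTF"),
    ("LTF", "NFL"),
    ("LTF", "F"),
    ("NFL", "F"),
)

_BASELINE_OF = {
    ("H", "NF"): "lam1",
    ("H", "F"): "lam2",
    ("NF", "F"): "lam3",
    ("H", "LTF"): "lam4",
    ("LTF", "NFL"): "lam5",
    ("LTF", "F"): "lam6",
    ("NFL", "F"): "lam3",  # lam7 = lam3 structurally
}


def build_semicompeting_model(
    k: float = 1.0,
    covariate_terms: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    share_death_effects: bool = False,
) -> ModelSpec:
    """Model spec with the structural constraints lam7=lam3 and
    lam5 = lam1*lam6/(k*lam2).

    ``covariate_terms`` maps baseline names ("lam1".."lam6") to (covariate,
    label) pairs; with ``share_death_effects`` the labels of all transitions
    into F are unified (one effect per covariate for lam2, lam3, lam6).
    """
    if k <= 0:
        raise SpecificationError("sensitivity parameter k must be positive")
    ct = {key: tuple(v) for key, v in (covariate_terms or {}).items()}
    transitions = {}
    for tr in _TRANSITIONS:
        name = _BASELINE_OF[tr]
        terms = tuple(Term(c, l) for c, l in ct.get(name, ()))
        if tr == ("NFL", "F"):
            terms = tuple(Term(c, l) for c, l in ct.get("lam3", ()))
        transitions[tr] = TransitionModel(tr, name, terms)
    baselines: dict[str, Any] = {
        name: BaselineDef(name, "weibull") for name in ("lam1", "lam2", "lam3", "lam4", "lam6")
    }
    baselines["lam5"] = DerivedBaselineDef(
        "lam5", "ratio_product", sources=("lam1", "lam6", "lam2"), n_num=2, k=float(k)
    )
    equal: list[tuple[str, ...]] = []
    if share_death_effects:
        death = ("lam2", "lam3", "lam6")
        by_cov: dict[str, list[str]] = {}
        for name in death:
            for c, l in ct.get(name, ()):
                by_cov.setdefault(c, []).append(l)
        for labels in by_cov.values():
            if len(labels) > 1:
                equal.append(tuple(labels))
    graph = StateGraph(STATES, _TRANSITIONS, unobservable=frozenset({"NFL"}))
    return ModelSpec(
        graph=graph,
        transitions=transitions,
        baselines=baselines,
        equal=tuple(equal),
        metadata={"k": float(k)},
        initial_state="H",
    )


# ---------------------------------------------------------------------------
# Subject histories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectHistory:
    """Flattened event history: exact NF/LTF/death times (or None) and the
    administrative end-of-study time."""

    id: Any
    t_nf: float | None
    t_ltf: float | None
    t_death: float | None
    t_end: float
    covariates: Mapping[str, float]

    def __post_init__(self):
        if self.t_nf is not None and self.t_ltf is not None:
            raise ValueError(f"subject {self.id}: NF and LTF both observed")
        times = [t for t in (self.t_nf, self.t_ltf, self.t_death) if t is not None]
        if any(t > self.t_end for t in times):
            raise ValueError(f"subject {self.id}: event after end of study")
        if self.t_death is not None and any(
            t >= self.t_death for t in (self.t_nf, self.t_ltf) if t is not None
        ):
            raise ValueError(f"subject {self.id}: event at or after death")


def parse_history(subject: Subject) -> SubjectHistory:
    """Interpret panel records as a semi-competing-risks history.

    Exact records name NF, LTF or F events; the final record gives the
    administrative end (its state or state set is not otherwise used, since
    the pre-LTF state is fully determined by the exact events)."""
    t_nf = t_ltf = t_death = None
    cov: dict[str, float] = dict(subject.records[0].covariates)
    t_end = subject.records[-1].time
    for rec in subject.records:
        if not rec.exact:
            continue
        state = rec.states[0]
        if state == "NF":
            if t_ltf is not None:
                raise ValueError(f"subject {subject.id}: NF observed after LTF")
            t_nf = rec.time
        elif state == "LTF":
            t_ltf = rec.time
        elif state == "F":
            t_death = rec.time
        else:
            raise ValueError(f"subject {subject.id}: unexpected exact state {state}")
    return SubjectHistory(subject.id, t_nf, t_ltf, t_death, t_end, cov)


# ---------------------------------------------------------------------------
# Post-LTF marginalization
# ---------------------------------------------------------------------------


def post_ltf_occupancy(
    lam5, lam6, lam7, t_ltf, t, m5=1.0, m6=1.0, m7=1.0, n_quad: int = 60
):
    """Occupancy (p_LTF, p_NFL) at times ``t`` given LTF entry at ``t_ltf``.

    Solves the progressive sub-chain LTF -> NFL -> F, LTF -> F by exploiting
    its structure: survival in LTF is a closed-form cumulative hazard and the
    NFL occupancy is a single time integral, evaluated by Gauss-Legendre
    quadrature.  ``m*`` are covariate multipliers on the baseline hazards;
    ``t_ltf``, ``t`` and the multipliers broadcast elementwise.
    """
    t = np.asarray(t, dtype=float)
    t_ltf = np.broadcast_to(np.asarray(t_ltf, dtype=float), t.shape)
    m5, m6, m7 = (np.broadcast_to(np.asarray(m, dtype=float), t.shape) for m in (m5, m6, m7))
    p_ltf = np.exp(-(m5 * lam5.cumhaz(t_ltf, t) + m6 * lam6.cumhaz(t_ltf, t)))
    x, w = np.polynomial.legendre.leggauss(n_quad)
    # nodes on [t_ltf, t] for every requested time
    half = (t - t_ltf) / 2.0
    mid = (t + t_ltf) / 2.0
    s = mid[..., None] + half[..., None] * x  # (..., n_quad)
    lo = t_ltf[..., None]
    surv_ltf = np.exp(
        -(m5[..., None] * lam5.cumhaz(lo, s) + m6[..., None] * lam6.cumhaz(lo, s))
    )
    dens = surv_ltf * m5[..., None] * lam5.hazard(s)
    surv_nfl = np.exp(-m7[..., None] * lam7.cumhaz(s, t[..., None]))
    p_nfl = half * np.sum(w * dens * surv_nfl, axis=-1)
    return p_ltf, p_nfl


def _multipliers(resolved, cov):
    return {tr: math.exp(rt.linear_predictor(cov)) for tr, rt in resolved.items()}


def subject_loglik(
    spec: ModelSpec, subject: Subject | SubjectHistory, params: Mapping[str, float], resolved=None
) -> float:
    """Log-likelihood of one subject's history under the five-state model."""
    if resolved is None:
        resolved = resolve_parameters(spec, params)
    h = subject if isinstance(subject, SubjectHistory) else parse_history(subject)
    m = _multipliers(resolved, h.covariates)
    lam = {i: resolved[tr].baseline for i, tr in enumerate(_TRANSITIONS, start=1)}
    mu = {i: m[tr] for i, tr in enumerate(_TRANSITIONS, start=1)}
    ll = 0.0
    t_exit_h = min(t for t in (h.t_nf, h.t_ltf, h.t_death, h.t_end) if t is not None)
    for j in (1, 2, 4):  # competing exits from H
        ll -= mu[j] * float(lam[j].cumhaz(0.0, t_exit_h))
    if h.t_nf is not None:
        ll += math.log(mu[1] * float(lam[1].hazard(h.t_nf)))
        t_stop = h.t_death if h.t_death is not None else h.t_end
        ll -= mu[3] * float(lam[3].cumhaz(h.t_nf, t_stop))
        if h.t_death is not None:
            ll += math.log(mu[3] * float(lam[3].hazard(h.t_death)))
    elif h.t_ltf is not None:
        ll += math.log(mu[4] * float(lam[4].hazard(h.t_ltf)))
        t_stop = h.t_death if h.t_death is not None else h.t_end
        p_ltf, p_nfl = post_ltf_occupancy(
            lam[5], lam[6], lam[7], h.t_ltf, np.asarray([t_stop]), mu[5], mu[6], mu[7]
        )
        if h.t_death is not None:
            dens = p_ltf[0] * mu[6] * float(lam[6].hazard(h.t_death)) + p_nfl[0] * mu[7] * float(
                lam[7].hazard(h.t_death)
            )
            ll += math.log(dens)
        else:
            ll += math.log(p_ltf[0] + p_nfl[0])
    elif h.t_death is not None:
        ll += math.log(mu[2] * float(lam[2].hazard(h.t_death)))
    return ll


def dataset_loglik(
    spec: ModelSpec, histories: Sequence[SubjectHistory], params: Mapping[str, float]
) -> float:
    """Total log-likelihood over parsed histories, vectorized across subjects."""
    resolved = resolve_parameters(spec, params)
    lam = {i: resolved[tr].baseline for i, tr in enumerate(_TRANSITIONS, start=1)}
    n = len(histories)
    nan = math.nan
    t_nf = np.array([nan if h.t_nf is None else h.t_nf for h in histories])
    t_ltf = np.array([nan if h.t_ltf is None else h.t_ltf for h in histories])
    t_death = np.array([nan if h.t_death is None else h.t_death for h in histories])
    t_end = np.array([h.t_end for h in histories])
    mu = np.empty((8, n))
    for j, tr in enumerate(_TRANSITIONS, start=1):
        rt = resolved[tr]
        mu[j] = np.array([math.exp(rt.linear_predictor(h.covariates)) for h in histories])
    t_exit_h = np.nanmin(np.vstack([t_nf, t_ltf, t_death, t_end]), axis=0)
    ll = np.zeros(n)
    has_nf = ~np.isnan(t_nf)
    has_ltf = ~np.isnan(t_ltf)
    has_death = ~np.isnan(t_death)
    t_stop = np.where(has_death, t_death, t_end)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for j in (1, 2, 4):
            ll -= mu[j] * lam[j].cumhaz(0.0, t_exit_h)
        if has_nf.any():
            i = has_nf
            ll[i] += np.log(mu[1, i] * lam[1].hazard(t_nf[i]))
            ll[i] -= mu[3, i] * lam[3].cumhaz(t_nf[i], t_stop[i])
            d = i & has_death
            ll[d] += np.log(mu[3, d] * lam[3].hazard(t_death[d]))
        if has_ltf.any():
            i = has_ltf
            ll[i] += np.log(mu[4, i] * lam[4].hazard(t_ltf[i]))
            p_ltf, p_nfl = post_ltf_occupancy(
                lam[5], lam[6], lam[7], t_ltf[i], t_stop[i], mu[5, i], mu[6, i], mu[7, i]
            )
            d = has_death[i]
            contrib = np.empty(i.sum())
            contrib[d] = np.log(
                p_ltf[d] * mu[6, i][d] * lam[6].hazard(t_death[i][d])
                + p_nfl[d] * mu[7, i][d] * lam[7].hazard(t_death[i][d])
            )
            contrib[~d] = np.log(p_ltf[~d] + p_nfl[~d])
            ll[i] += contrib
        direct = has_death & ~has_nf & ~has_ltf
        if direct.any():
            ll[direct] += np.log(mu[2, direct] * lam[2].hazard(t_death[direct]))
    total = float(ll.sum())
    return total if np.isfinite(total) else -np.inf


def histories(data: PanelData) -> list[SubjectHistory]:
    return [parse_history(s) for s in data.subjects]


# ---------------------------------------------------------------------------
# Occupancy, cumulative incidence
# ---------------------------------------------------------------------------


def occupancy_grid(
    spec: ModelSpec,
    covariates: Mapping[str, float],
    params: Mapping[str, float],
    grid: Sequence[float],
    rtol: float = 1e-10,
) -> np.ndarray:
    """Occupancy probabilities over the five states from H at grid[0], by
    integrating the forward occupancy equations dp/dt = p Q(t)."""
    grid = np.asarray(grid, dtype=float)
    resolved = resolve_parameters(spec, params)
    n = spec.graph.n_states
    p0 = np.zeros(n)
    p0[spec.graph.index("H")] = 1.0

    def rhs(t, p):
        Q = intensity_matrix(spec, resolved, covariates, max(t, 1e-12))
        return p @ Q

    sol = solve_ivp(
        rhs, (grid[0], grid[-1]), p0, t_eval=grid, rtol=rtol, atol=1e-12, method="RK45"
    )
    if not sol.success:
        raise RuntimeError(f"occupancy integration failed: {sol.message}")
    return sol.y.T


def cumulative_incidence(
    spec: ModelSpec,
    covariates: Mapping[str, float],
    params: Mapping[str, float],
    grid: Sequence[float],
) -> np.ndarray:
    """Probability that the first event of interest (entry into NF, NFL or
    directly into F) has occurred by each grid time.

    Every exit from {H, LTF} other than H->LTF is a first event, so the
    cumulative incidence is 1 - p_H(t) - p_LTF(t)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("grid must start at 0")
    occ = occupancy_grid(spec, covariates, params, grid)
    iH, iL = spec.graph.index("H"), spec.graph.index("LTF")
    cif = 1.0 - occ[:, iH] - occ[:, iL]
    return np.clip(cif, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Simulation scenario
# ---------------------------------------------------------------------------


def simulate_semicompeting_scenario(
    n: int = 2000,
    horizon: float = 15.0,
    seed: int = 0,
    k: float = 1.0,
    truth: Mapping[str, float] | None = None,
    covariate_terms: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    covariate_sampler=None,
):
    """Exact-time scenario: NF, LTF and death times observed exactly before
    LTF; after LTF only the death time (if any) is recorded.

    Returns (spec, truth, PanelData); the panel encoding uses exact records
    for events and a final record at the administrative end giving the set of
    states compatible with the observed history.
    """
    from .simulate import simulate_path, subject_rng

    spec = build_semicompeting_model(k=k, covariate_terms=covariate_terms)
    if truth is None:
        truth = {
            "lam1.a": 0.030, "lam1.b": 1.2,
            "lam2.a": 0.015, "lam2.b": 1.3,
            "lam3.a": 0.060, "lam3.b": 1.1,
            "lam4.a": 0.025, "lam4.b": 1.0,
            "lam6.a": 0.020, "lam6.b": 1.3,
        }
    resolved = resolve_parameters(spec, truth)
    subjects = []
    for i in range(n):
        rng = subject_rng(seed, i)
        cov = dict(covariate_sampler(rng)) if covariate_sampler else {}
        path = simulate_path(spec, resolved, [(0.0, cov)], "H", horizon, rng)
        recs = [ObservationRecord(0.0, ("H",), covariates=cov)]
        ltf = False
        for t, s in path[1:]:
            if s in ("NF", "LTF", "F"):
                recs.append(ObservationRecord(t, (s,), exact=True, covariates=cov))
            if s == "LTF":
                ltf = True
            if s == "F":
                break
        died = path[-1][1] == "F"
        if not died:
            final_states = ("LTF", "NFL") if ltf else (path[-1][1],)
            recs.append(ObservationRecord(horizon, final_states, covariates=cov))
        subjects.append(Subject(i, recs))
    return spec, dict(truth), PanelData(subjects)
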