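"""Clustered progressive four-state damage processes with gamma frailty.

Each unit process (a paired joint location) moves on S1 (neither side
damaged) -> S2 (right damaged) / S3 (left damaged) -> S4 (both damaged);
damage is irreversible, the two sides never jump simultaneously.  All unit
processes of a subject share one gamma random effect with unit mean and
variance theta, acting multiplicatively on every transition rate; the
marginal likelihood integrates the product of conditional unit-process
likelihoods over the frailty by generalized Gauss-Laguerre quadrature.

Symmetry of damage is parameterized by offsets: lam024 = lam013*exp(gamma24)
and lam034 = lam012*exp(gamma34); positive offsets mean a joint becomes
damaged faster once its contralateral partner is damaged.
"""
from __future__ import annotations

import math
import warnings
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp, roots_genlaguerre

from .model_core import (
    BaselineDef,
    DerivedBaselineDef,
    FrailtySpec,
    ModelSpec,
    StateGraph,
    Term,
    TransitionModel,
    resolve_parameters,
)
from .panel_likelihood import (
    ObservationRecord,
    PanelData,
    PanelDesign,
    Subject,
    subject_loglik,
)

__all__ = [
    "build_damage_model",
    "conditional_cluster_loglik",
    "marginal_cluster_loglik",
    "MarginalLikelihood",
    "symmetry_estimates",
    "simulate_damage_scenario",
]

_STATES = ("S1", "S2", "S3", "S4")
_TRANSITIONS = (("S1", "S2"), ("S1", "S3"), ("S2", "S4"), ("S3", "S4"))


def build_damage_model(
    include_activity: bool = True,
    include_past_activity: bool = False,
    quadrature_order: int = 30,
) -> ModelSpec:
    """Four-state damage model with symmetry offsets and shared frailty.

    Activity covariates (A/T/E for left and right) follow the parsimony
    constraints: the same coefficient applies to the mirrored transition of
    the other hand.  Only the undamaged joint's activity enters transitions
    into S4.
    """
    terms: dict[tuple[str, str], tuple[Term, ...]] = {tr: () for tr in _TRANSITIONS}
    if include_activity:
        terms[("S1", "S2")] = (
            Term("A_L", "alpha_out"),
            Term("T_R", "tau_out"),
            Term("E_R", "eps_out"),
        )
        terms[("S1", "S3")] = (
            Term("A_R", "alpha_out"),
            Term("T_L", "tau_out"),
            Term("E_L", "eps_out"),
        )
        terms[("S2", "S4")] = (Term("T_L", "tau_in"), Term("E_L", "eps_in"))
        terms[("S3", "S4")] = (Term("T_R", "tau_in"), Term("E_R", "eps_in"))
    if include_past_activity:
        terms[("S1", "S2")] += (Term("P_L", "past_out"),)
        terms[("S1", "S3")] += (Term("P_R", "past_out"),)
        terms[("S2", "S4")] += (Term("P_L", "past_in"),)
        terms[("S3", "S4")] += (Term("P_R", "past_in"),)
    baselines: dict[str, Any] = {
        "lam012": BaselineDef("lam012", "constant"),
        "lam013": BaselineDef("lam013", "constant"),
        "lam024": DerivedBaselineDef("lam024", "exp_offset", ("lam013",), offset_param="gamma24"),
        "lam034": DerivedBaselineDef("lam034", "exp_offset", ("lam012",), offset_param="gamma34"),
    }
    transitions = {
        ("S1", "S2"): TransitionModel(("S1", "S2"), "lam012", terms[("S1", "S2")]),
        ("S1", "S3"): TransitionModel(("S1", "S3"), "lam013", terms[("S1", "S3")]),
        ("S2", "S4"): TransitionModel(("S2", "S4"), "lam024", terms[("S2", "S4")]),
        ("S3", "S4"): TransitionModel(("S3", "S4"), "lam034", terms[("S3", "S4")]),
    }
    return ModelSpec(
        graph=StateGraph(_STATES, _TRANSITIONS),
        transitions=transitions,
        baselines=baselines,
        frailty=FrailtySpec(theta_param="theta", quadrature_order=quadrature_order),
        initial_state="S1",
    )


# ---------------------------------------------------------------------------
# Conditional and marginal likelihoods
# ---------------------------------------------------------------------------


def conditional_cluster_loglik(
    spec: ModelSpec,
    subjects: Sequence[Subject],
    params: Mapping[str, float],
    u: float,
    resolved=None,
    cache: dict | None = None,
) -> float:
    """Sum of unit-process log-likelihoods given the frailty value u."""
    if u <= 0:
        raise ValueError("frailty value must be positive")
    if resolved is None:
        resolved = resolve_parameters(spec, params)
    return sum(
        subject_loglik(spec, s, resolved=resolved, frailty=u, cache=cache) for s in subjects
    )


def _quadrature(theta: float, order: int):
    """Nodes/log-weights integrating f against the Gamma(1/theta, 1/theta) law."""
    alpha = 1.0 / theta
    x, w = roots_genlaguerre(order, alpha - 1.0)
    u = theta * x
    logw = np.log(w) - gammaln(alpha)
    return u, logw


_THETA_FLOOR = 1e-6

_PROBE_U = (0.5, 1.0, 1.5)


def _fit_tilt(ell_probes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match ell(u) ~ a + b*log(u) - c*u from probes at u = 0.5, 1.0, 1.5.

    Returns (b, c) per cluster, clipped to sane ranges; used only to place
    quadrature nodes, so the marginal stays exact in the probe model and
    unbiased otherwise.
    """
    d21 = ell_probes[1] - ell_probes[0]
    d32 = ell_probes[2] - ell_probes[1]
    l21 = math.log(2.0)
    l32 = math.log(1.5)
    b = (d21 - d32) / (l21 - l32)
    c = (b * l21 - d21) * 2.0
    bad = ~(np.isfinite(b) & np.isfinite(c))
    b = np.where(bad, 0.0, np.clip(np.round(b), 0.0, 500.0))
    c = np.where(bad, 0.0, np.clip(c, 0.0, None))
    return b, c


_ROOT_CACHE: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}


def _cached_roots(order: int, q: float):
    # q is alpha + integer tilt; alpha repeats across quadrature calls within
    # an optimizer run, so a plain dict cache is effective
    key = (order, float(q))
    if key not in _ROOT_CACHE:
        if len(_ROOT_CACHE) > 4096:
            _ROOT_CACHE.clear()
        _ROOT_CACHE[key] = roots_genlaguerre(order, q - 1.0)
    return _ROOT_CACHE[key]


def _tilted_rule(alpha: float, beta: float, ell_probes: np.ndarray, order: int):
    """Cluster-specific quadrature nodes and log-weights for the unit-mean
    gamma mixture, exponentially and power tilted by the probed shape of the
    conditional log-likelihood.

    Returns (u_nodes, logw_base) of shape (order, n_cluster); the caller adds
    ell(u_nodes) to logw_base and log-sum-exps over axis 0.
    """
    b, c = _fit_tilt(np.asarray(ell_probes))
    q = alpha + b
    nc = b.shape[0]
    u_nodes = np.empty((order, nc))
    logw = np.empty((order, nc))
    rate = beta + c
    const = alpha * math.log(beta) - gammaln(alpha)
    for q_int in np.unique(q):
        sel = q == q_int
        x, w = _cached_roots(order, float(q_int))
        u = x[:, None] / rate[sel][None, :]
        u_nodes[:, sel] = u
        logw[:, sel] = (
            np.log(w)[:, None]
            + (alpha - q_int) * np.log(u)
            + c[sel][None, :] * u
            + const
            - q_int * np.log(rate[sel])[None, :]
        )
    return u_nodes, logw


def marginal_cluster_loglik(
    spec: ModelSpec,
    subjects: Sequence[Subject],
    params: Mapping[str, float],
    theta: float | None = None,
    order: int | None = None,
) -> float:
    """log integral of the conditional cluster likelihood over the gamma
    frailty; theta=0 degenerates to the conditional value at u=1.

    The quadrature is exponentially tilted by the (probed) slope of the
    conditional log-likelihood in u, which makes pure-survival clusters exact
    at any order and sharpens accuracy when theta * total-hazard is large.
    """
    if theta is None:
        theta = float(params[spec.frailty.theta_param])
    if order is None:
        order = spec.frailty.quadrature_order if spec.frailty else 30
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    resolved = resolve_parameters(spec, params)
    if theta < _THETA_FLOOR:
        return conditional_cluster_loglik(spec, subjects, params, 1.0, resolved=resolved)
    cache: dict = {}

    def ell(u: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return conditional_cluster_loglik(
                spec, subjects, params, u, resolved=resolved, cache=cache
            )

    alpha = beta = 1.0 / theta
    probes = np.array([[ell(u)] for u in _PROBE_U])
    u_nodes, logw = _tilted_rule(alpha, beta, probes[:, :], order)
    vals = np.array([ell(float(ui)) for ui in u_nodes[:, 0]])
    if not np.any(np.isfinite(vals)):
        warnings.warn("conditional likelihood non-finite at all quadrature nodes", RuntimeWarning)
        return -np.inf
    return float(logsumexp(logw[:, 0] + vals))


class MarginalLikelihood:
    """Marginal log-likelihood over all clusters, vectorized via PanelDesign.

    The per-cluster conditional log-likelihood is evaluated at each frailty
    quadrature node (transition-probability tables are shared across clusters
    within a node) and combined by log-sum-exp.
    """

    def __init__(self, spec: ModelSpec, data: PanelData, order: int | None = None):
        self.spec = spec
        self.design = PanelDesign(spec, data)
        self.order = order or (spec.frailty.quadrature_order if spec.frailty else 30)

    def cluster_logliks(self, natural: Mapping[str, float]) -> np.ndarray:
        theta = float(natural[self.spec.frailty.theta_param])
        resolved = resolve_parameters(self.spec, natural)
        if theta < _THETA_FLOOR:
            return self.design.cluster_logliks(resolved, frailty=1.0)
        with warnings.catch_warnings():
            # extreme quadrature nodes can underflow transition probabilities;
            # their weighted contribution is negligible
            warnings.simplefilter("ignore", RuntimeWarning)
            return self._tilted_logliks(resolved, theta)

    def _tilted_logliks(self, resolved, theta: float) -> np.ndarray:
        """Per-cluster marginals with a cluster-specific exponential tilt.

        The slope of the conditional log-likelihood in u (probed at u=0.5 and
        1.5) is absorbed into the gamma weight, so each cluster integrates
        against nodes concentrated where its integrand has mass.
        """
        design = self.design
        nc = design.n_clusters
        probes = design.cluster_logliks_multi(resolved, np.array(_PROBE_U))
        alpha = beta = 1.0 / theta
        u_nodes, base_logw = _tilted_rule(alpha, beta, probes, self.order)
        P, PQ = design._tables_multi(resolved, u_nodes.ravel())
        n = self.spec.graph.n_states
        P = P.reshape(self.order, nc, -1, n, n)
        vals = np.zeros((self.order, nc))
        with np.errstate(divide="ignore"):
            if len(design._plain):
                rows = design._plain
                logs = np.log(P[:, rows[:, 3], rows[:, 0], rows[:, 1], rows[:, 2]])
                order_ix = np.argsort(rows[:, 3], kind="stable")
                cl = rows[order_ix, 3]
                starts = np.flatnonzero(np.r_[True, np.diff(cl) > 0])
                vals[:, cl[starts]] += np.add.reduceat(logs[:, order_ix], starts, axis=1)
            for ki, s0, s1, ci in design._exact:
                pq = PQ[int(ki)].reshape(self.order, nc, n, n)[:, ci, int(s0), int(s1)]
                vals[:, ci] += np.log(np.clip(pq, 0.0, None))
        if design._loop_subjects:
            cache: dict = {}
            for i in range(self.order):
                for subj, ci in design._loop_subjects:
                    vals[i, ci] += subject_loglik(
                        self.spec,
                        subj,
                        resolved=resolved,
                        frailty=float(u_nodes[i, ci]),
                        cache=cache,
                    )
        return logsumexp(base_logw + vals, axis=0)

    def loglik(self, natural: Mapping[str, float]) -> float:
        vals = self.cluster_logliks(natural)
        total = float(vals.sum())
        return total if np.isfinite(total) else -np.inf


def symmetry_estimates(fitted) -> dict[str, dict[str, float]]:
    """Point estimates and 95% Wald intervals for the symmetry offsets."""
    out = {}
    for name in ("gamma24", "gamma34"):
        est = fitted.estimate(name)
        se = fitted.se_of(name)
        lo, hi = fitted.ci(name)
        out[name] = {"estimate": est, "se": se, "ci_lower": lo, "ci_upper": hi}
    return out


# ---------------------------------------------------------------------------
# Simulation scenario
# ---------------------------------------------------------------------------


def simulate_damage_scenario(
    n: int = 300,
    n_locations: int = 14,
    n_visits: int = 10,
    seed: int = 0,
    theta: float = 0.5,
    truth: Mapping[str, float] | None = None,
    include_activity: bool = False,
    p_active: float = 0.3,
):
    """Clustered damage scenario: every subject contributes ``n_locations``
    unit processes starting in S1, all sharing one gamma frailty draw.

    With ``include_activity`` the binary activity covariates are redrawn at
    each visit (piecewise constant in between).  Returns (spec, truth,
    PanelData) where unit processes appear as subjects with a shared cluster
    id.
    """
    from .simulate import simulate_path, state_at, subject_rng

    spec = build_damage_model(include_activity=include_activity)
    if truth is None:
        truth = {
            "lam012": 0.05,
            "lam013": 0.06,
            "gamma24": 1.0,
            "gamma34": 0.8,
            "theta": theta,
        }
        if include_activity:
            truth.update(
                {"alpha_out": 0.6, "tau_out": 0.4, "eps_out": 0.9, "tau_in": 0.5, "eps_in": 0.7}
            )
    else:
        truth = dict(truth)
        truth.setdefault("theta", theta)
    resolved = resolve_parameters(spec, truth)
    th = float(truth["theta"])
    cov_names = ("A_L", "A_R", "T_L", "T_R", "E_L", "E_R") if include_activity else ()
    subjects = []
    visit_times = np.arange(1.0, n_visits + 1.0)
    for i in range(n):
        rng = subject_rng(seed, i)
        u = rng.gamma(1.0 / th, th) if th > 0 else 1.0
        for loc in range(n_locations):
            loc_rng = subject_rng(seed, i, loc + 1)
            if include_activity:
                segs = []
                for vt in [0.0] + list(visit_times[:-1]):
                    tender = {s: float(loc_rng.random() < p_active) for s in ("L", "R")}
                    effused = {
                        s: float(tender[s] > 0 and loc_rng.random() < 0.5) for s in ("L", "R")
                    }
                    segs.append(
                        (
                            float(vt),
                            {
                                "A_L": tender["L"],
                                "A_R": tender["R"],
                                "T_L": tender["L"] * (1 - effused["L"]),
                                "T_R": tender["R"] * (1 - effused["R"]),
                                "E_L": effused["L"],
                                "E_R": effused["R"],
                            },
                        )
                    )
            else:
                segs = [(0.0, {})]
            path = simulate_path(
                spec, resolved, segs, "S1", visit_times[-1] + 0.5, loc_rng, frailty=u
            )
            recs = []
            prev_cov: Mapping[str, float] = segs[0][1]
            recs.append(ObservationRecord(0.0, ("S1",), covariates=dict(prev_cov)))
            for vi, vt in enumerate(visit_times):
                # the covariates recorded at a visit are those in force until the next one
                cov = segs[vi + 1][1] if include_activity and vi + 1 < len(segs) else {}
                recs.append(
                    ObservationRecord(float(vt), (state_at(path, vt),), covariates=dict(cov))
                )
            subjects.append(Subject(f"{i}:{loc}", recs, cluster=i, unit=loc))
    return spec, dict(truth), PanelData(subjects)
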