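"""Panel-data likelihood for multi-state models without misclassification.

Observations are intermittent: the state is recorded at visit times only, so
transition times are interval censored.  Under piecewise-constant intensities
the transition-probability matrix over an interval is an ordered product of
matrix exponentials, one per sub-interval on which the generator is constant.
Exactly observed transitions (e.g. death times) contribute a density term:
the probability of reaching the pre-jump state times the jump intensity.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .model_core import (
    ModelSpec,
    ResolvedTransition,
    SpecificationError,
    intensity_matrix,
    resolve_parameters,
)

__all__ = [
    "ObservationRecord",
    "Subject",
    "PanelData",
    "transition_probability",
    "subject_loglik",
    "total_loglik",
    "state_occupancy",
    "length_of_stay",
    "PanelDesign",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class ObservationRecord:
    """One visit: time, the observed state (or a set of possible states) and
    the covariate values in force from this time until the next record."""

    time: float
    states: tuple[str, ...]
    exact: bool = False
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("negative observation time")
        if not self.states:
            raise ValueError("observation must allow at least one state")
        if self.exact and len(self.states) != 1:
            raise ValueError("an exact transition must name a single state")


@dataclass
class Subject:
    id: Any
    records: list[ObservationRecord]
    cluster: Any = None
    unit: Any = None
    entry_time: float = 0.0

    def __post_init__(self):
        if not self.records:
            raise ValueError(f"subject {self.id}: no records")
        times = [r.time for r in self.records]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError(f"subject {self.id}: times not strictly increasing")
        if self.entry_time > times[0]:
            raise ValueError(f"subject {self.id}: entry time after first record")


@dataclass
class PanelData:
    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    def clusters(self) -> dict[Any, list[Subject]]:
        out: dict[Any, list[Subject]] = {}
        for s in self.subjects:
            key = s.cluster if s.cluster is not None else s.id
            out.setdefault(key, []).append(s)
        return out


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

_WEIBULL_STEP = 1.0 / 64.0


def _is_step_hazard(h) -> bool:
    from .model_core import ConstantHazard, PiecewiseHazard

    return isinstance(h, (ConstantHazard, PiecewiseHazard))


def _segment_points(resolved, t0: float, t1: float) -> list[float]:
    pts = {t0, t1}
    for rt in resolved.values():
        for c in rt.baseline.cutpoints:
            if t0 < c < t1:
                pts.add(float(c))
    return sorted(pts)


def transition_probability(
    spec: ModelSpec,
    resolved: Mapping[tuple[str, str], ResolvedTransition],
    covariates: Mapping[str, float],
    t0: float,
    t1: float,
    frailty: float = 1.0,
    cache: dict | None = None,
    weibull_step: float = _WEIBULL_STEP,
) -> np.ndarray:
    """Stochastic matrix P(t0, t1) for fixed covariates.

    Exact under constant/piecewise baselines (the interval is split at every
    cutpoint); Weibull baselines are approximated by midpoint-rate sub-steps
    of width ``weibull_step``.
    """
    if t1 < t0:
        raise ValueError("t1 < t0 in transition_probability")
    n = spec.graph.n_states
    if t1 == t0:
        return np.eye(n)
    if cache is not None:
        key = (tuple(sorted(covariates.items())), float(t0), float(t1), float(frailty))
        hit = cache.get(key)
        if hit is not None:
            return hit
    time_varying = not all(_is_step_hazard(rt.baseline) for rt in resolved.values())
    P = np.eye(n)
    pts = _segment_points(resolved, t0, t1)
    for a, b in zip(pts, pts[1:]):
        if time_varying:
            nsub = max(1, int(math.ceil((b - a) / weibull_step)))
        else:
            nsub = 1
        h = (b - a) / nsub
        for i in range(nsub):
            mid = a + (i + 0.5) * h
            Q = intensity_matrix(spec, resolved, covariates, mid, frailty)
            P = P @ expm(Q * h)
    np.clip(P, 0.0, 1.0, out=P)
    if cache is not None:
        cache[key] = P
    return P


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _state_indicator(spec: ModelSpec, states: Sequence[str]) -> np.ndarray:
    v = np.zeros(spec.graph.n_states)
    for s in states:
        v[spec.graph.index(s)] = 1.0
    return v


def _offdiag_column(Q: np.ndarray, j: int) -> np.ndarray:
    col = Q[:, j].copy()
    col[j] = 0.0
    return col


def subject_loglik(
    spec: ModelSpec,
    subject: Subject,
    params: Mapping[str, float] | None = None,
    frailty: float = 1.0,
    resolved: Mapping | None = None,
    cache: dict | None = None,
) -> float:
    """Log-likelihood contribution of one subject.

    The recursion conditions on the state (or state set) at the first record,
    which is how left truncation is handled: nothing before the first visit
    contributes.
    """
    if resolved is None:
        resolved = resolve_parameters(spec, params)
    recs = subject.records
    first = recs[0]
    alpha = _state_indicator(spec, first.states)
    cov = dict(first.covariates)
    t_prev = first.time
    loglik = 0.0
    for rec in recs[1:]:
        P = transition_probability(spec, resolved, cov, t_prev, rec.time, frailty, cache)
        v = alpha @ P
        if rec.exact:
            j = spec.graph.index(rec.states[0])
            Q = intensity_matrix(spec, resolved, cov, rec.time, frailty)
            dens = float(v @ _offdiag_column(Q, j))
            alpha = np.zeros_like(v)
            alpha[j] = dens
        else:
            alpha = v * _state_indicator(spec, rec.states)
        tot = float(alpha.sum())
        if tot <= 0.0 or not np.isfinite(tot):
            warnings.warn(
                f"subject {subject.id}: zero-probability observation at t={rec.time}",
                RuntimeWarning,
            )
            return -np.inf
        loglik += math.log(tot)
        alpha = alpha / tot
        cov.update(rec.covariates)
        t_prev = rec.time
    return loglik


def total_loglik(
    spec: ModelSpec,
    data: PanelData,
    params: Mapping[str, float],
    frailty: float = 1.0,
) -> float:
    """Sum of subject contributions; -inf propagates."""
    resolved = resolve_parameters(spec, params)
    cache: dict = {}
    out = 0.0
    for subj in data.subjects:
        ll = subject_loglik(spec, subj, resolved=resolved, frailty=frailty, cache=cache)
        if ll == -np.inf:
            return -np.inf
        out += ll
    return out


# ---------------------------------------------------------------------------
# Occupancy and length of stay
# ---------------------------------------------------------------------------


def state_occupancy(
    spec: ModelSpec,
    covariates: Mapping[str, float],
    params: Mapping[str, float],
    initial_state: str,
    grid: Sequence[float],
    resolved: Mapping | None = None,
) -> np.ndarray:
    """Occupancy probabilities P(state at t | initial state at grid[0])."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be nondecreasing")
    if resolved is None:
        resolved = resolve_parameters(spec, params)
    p = _state_indicator(spec, [initial_state])
    out = np.empty((len(grid), spec.graph.n_states))
    out[0] = p
    for i in range(1, len(grid)):
        P = transition_probability(spec, resolved, covariates, grid[i - 1], grid[i])
        p = p @ P
        out[i] = p
    return out


def _expm_with_integral(Q: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    # Van Loan block trick: expm([[Q, I], [0, 0]]*dt) holds both e^{Q dt}
    # and the integral of e^{Q s} over [0, dt].
    n = Q.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = Q * dt
    M[:n, n:] = np.eye(n) * dt
    E = expm(M)
    return E[:n, :n], E[:n, n:]


def length_of_stay(
    spec: ModelSpec,
    covariates: Mapping[str, float],
    params: Mapping[str, float],
    initial_state: str,
    horizon: float,
    t0: float = 0.0,
    resolved: Mapping | None = None,
    weibull_step: float = _WEIBULL_STEP,
) -> np.ndarray:
    """Expected time in each state on [t0, t0+horizon], starting in initial_state.

    Exact for constant/piecewise intensities (blockwise matrix-exponential
    integrals); Weibull intensities use midpoint sub-steps.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if resolved is None:
        resolved = resolve_parameters(spec, params)
    t1 = t0 + horizon
    time_varying = not all(_is_step_hazard(rt.baseline) for rt in resolved.values())
    pts = _segment_points(resolved, t0, t1)
    p = _state_indicator(spec, [initial_state])
    los = np.zeros(spec.graph.n_states)
    for a, b in zip(pts, pts[1:]):
        nsub = max(1, int(math.ceil((b - a) / weibull_step))) if time_varying else 1
        h = (b - a) / nsub
        for i in range(nsub):
            mid = a + (i + 0.5) * h
            Q = intensity_matrix(spec, resolved, covariates, mid)
            P, J = _expm_with_integral(Q, h)
            los += p @ J
            p = p @ P
    return los


# ---------------------------------------------------------------------------
# Vectorized likelihood design (hot path for fitting)
# ---------------------------------------------------------------------------


class PanelDesign:
    """Pre-compiled panel dataset for repeated likelihood evaluation.

    Intervals whose endpoints are single observed states are evaluated by
    table lookup into transition-probability matrices computed once per
    distinct (covariate pattern, t0, t1); subjects with censoring sets fall
    back to the generic recursion.  Exactly observed transitions use the
    density (P @ Q_offdiag) term.
    """

    def __init__(self, spec: ModelSpec, data: PanelData):
        self.spec = spec
        covs = spec.covariates
        key_index: dict[tuple, int] = {}
        self._keys: list[tuple] = []
        rows_plain: list[tuple[int, int, int, int]] = []  # key, s0, s1, cluster
        rows_exact: list[tuple[int, int, int, int]] = []
        self._loop_subjects: list[tuple[Subject, int]] = []
        cluster_index: dict[Any, int] = {}
        self._cluster_keys: list[Any] = []

        for subj in data.subjects:
            ckey = subj.cluster if subj.cluster is not None else subj.id
            if ckey not in cluster_index:
                cluster_index[ckey] = len(cluster_index)
                self._cluster_keys.append(ckey)
            ci = cluster_index[ckey]
            simple = all(len(r.states) == 1 for r in subj.records)
            if not simple:
                self._loop_subjects.append((subj, ci))
                continue
            cov = dict(subj.records[0].covariates)
            t_prev = subj.records[0].time
            s_prev = spec.graph.index(subj.records[0].states[0])
            for rec in subj.records[1:]:
                kv = tuple(float(cov.get(c, 0.0)) for c in covs)
                key = (kv, float(t_prev), float(rec.time))
                ki = key_index.get(key)
                if ki is None:
                    ki = key_index[key] = len(self._keys)
                    self._keys.append(key)
                s_cur = spec.graph.index(rec.states[0])
                if rec.exact:
                    rows_exact.append((ki, s_prev, s_cur, ci))
                else:
                    rows_plain.append((ki, s_prev, s_cur, ci))
                cov.update(rec.covariates)
                t_prev = rec.time
                s_prev = s_cur

        self._covs = covs
        self._plain = np.asarray(rows_plain, dtype=np.intp).reshape(-1, 4)
        self._exact = np.asarray(rows_exact, dtype=np.intp).reshape(-1, 4)
        self._exact_keyset = sorted(set(self._exact[:, 0].tolist()))
        self.n_clusters = len(cluster_index)

    def _tables(self, resolved, frailty: float):
        n = self.spec.graph.n_states
        P = np.empty((len(self._keys), n, n))
        for i, (kv, t0, t1) in enumerate(self._keys):
            covariates = dict(zip(self._covs, kv))
            P[i] = transition_probability(
                self.spec, resolved, covariates, t0, t1, frailty
            )
        PQ = {}
        for ki in self._exact_keyset:
            kv, t0, t1 = self._keys[ki]
            covariates = dict(zip(self._covs, kv))
            Q = intensity_matrix(self.spec, resolved, covariates, t1, frailty)
            np.fill_diagonal(Q, 0.0)
            PQ[ki] = P[ki] @ Q
        return P, PQ

    def cluster_logliks(self, resolved, frailty: float = 1.0) -> np.ndarray:
        """Per-cluster log-likelihoods at the given resolved parameters."""
        P, PQ = self._tables(resolved, frailty)
        out = np.zeros(self.n_clusters)
        bad = False
        with np.errstate(divide="ignore"):
            if len(self._plain):
                vals = P[self._plain[:, 0], self._plain[:, 1], self._plain[:, 2]]
                logs = np.log(vals)
                bad = bad or not np.all(np.isfinite(logs))
                np.add.at(out, self._plain[:, 3], logs)
            for ki, s0, s1, ci in self._exact:
                v = PQ[int(ki)][int(s0), int(s1)]
                if v <= 0:
                    bad = True
                    out[ci] = -np.inf
                else:
                    out[ci] += math.log(v)
        cache: dict = {}
        for subj, ci in self._loop_subjects:
            out[ci] += subject_loglik(
                self.spec, subj, resolved=resolved, frailty=frailty, cache=cache
            )
        if bad:
            warnings.warn("zero transition probability in panel design", RuntimeWarning)
        return out

    def loglik(self, resolved, frailty: float = 1.0) -> float:
        return float(self.cluster_logliks(resolved, frailty).sum())

    # -- batched evaluation over frailty values -----------------------------

    def _tables_multi(self, resolved, frailties: np.ndarray):
        """P tables of shape (n_frailty, n_keys, n, n).

        Uses one eigendecomposition per constancy segment (Q(u) = u*Q so all
        frailty values share eigenvectors); falls back to expm per node if
        the eigen reconstruction is inaccurate.
        """
        n = self.spec.graph.n_states
        F = len(frailties)
        P = np.empty((F, len(self._keys), n, n))
        for ki, (kv, t0, t1) in enumerate(self._keys):
            covariates = dict(zip(self._covs, kv))
            pts = _segment_points(resolved, t0, t1)
            time_varying = not all(_is_step_hazard(rt.baseline) for rt in resolved.values())
            Pk = np.broadcast_to(np.eye(n), (F, n, n)).copy()
            for a, b in zip(pts, pts[1:]):
                nsub = max(1, int(math.ceil((b - a) / _WEIBULL_STEP))) if time_varying else 1
                h = (b - a) / nsub
                for i in range(nsub):
                    mid = a + (i + 0.5) * h
                    Q = intensity_matrix(self.spec, resolved, covariates, mid, 1.0)
                    Pseg = _expm_scaled(Q, h * frailties)
                    Pk = Pk @ Pseg
            np.clip(Pk, 0.0, 1.0, out=Pk)
            P[:, ki] = Pk
        PQ = {}
        for ki in self._exact_keyset:
            kv, t0, t1 = self._keys[ki]
            covariates = dict(zip(self._covs, kv))
            Q = intensity_matrix(self.spec, resolved, covariates, t1, 1.0)
            np.fill_diagonal(Q, 0.0)
            PQ[ki] = np.einsum("fij,jk->fik", P[:, ki], Q) * frailties[:, None, None]
        return P, PQ

    def cluster_logliks_multi(self, resolved, frailties) -> np.ndarray:
        """(n_frailty, n_cluster) conditional log-likelihoods, sharing the
        transition-probability work across frailty values."""
        frailties = np.asarray(frailties, dtype=float)
        P, PQ = self._tables_multi(resolved, frailties)
        F = len(frailties)
        out = np.zeros((F, self.n_clusters))
        with np.errstate(divide="ignore"):
            if len(self._plain):
                vals = np.log(P[:, self._plain[:, 0], self._plain[:, 1], self._plain[:, 2]])
                order = np.argsort(self._plain[:, 3], kind="stable")
                cl = self._plain[order, 3]
                starts = np.flatnonzero(np.r_[True, np.diff(cl) > 0])
                sums = np.add.reduceat(vals[:, order], starts, axis=1)
                out[:, cl[starts]] = sums
            for ki, s0, s1, ci in self._exact:
                v = PQ[int(ki)][:, int(s0), int(s1)]
                with np.errstate(divide="ignore"):
                    out[:, ci] += np.log(np.clip(v, 0.0, None))
        if self._loop_subjects:
            cache: dict = {}
            for f, u in enumerate(frailties):
                for subj, ci in self._loop_subjects:
                    out[f, ci] += subject_loglik(
                        self.spec, subj, resolved=resolved, frailty=float(u), cache=cache
                    )
        return out


def _expm_scaled(Q: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """expm(Q * s) for every s in ``scales`` via one eigendecomposition,
    with an expm fallback when the reconstruction is poor."""
    scales = np.asarray(scales, dtype=float)
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(scales, lam))
        out = np.einsum("ij,fj,jk->fik", V, E, Vinv).real
        # verify on the scale closest to 1
        i0 = int(np.argmin(np.abs(scales - 1.0)))
        ref = expm(Q * scales[i0])
        if np.max(np.abs(out[i0] - ref)) < 1e-10:
            return out
    except np.linalg.LinAlgError:
        pass
    return np.stack([expm(Q * s) for s in scales])
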