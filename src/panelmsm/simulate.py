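"""Seeded synthetic-data generators for every model class.

Paths are simulated exactly: on each interval where the generator is constant
in the covariates, the sojourn time is drawn by inverting the (closed-form)
total cumulative hazard out of the current state; the destination is drawn
with probabilities proportional to the transition intensities at the jump
time.  Panel observation reads the state at visit times, optionally passes it
through an emission model, and applies scenario-specific exact-time rules.

A single root seed fans out to per-subject generators through
``numpy.random.default_rng([seed, subject_index])`` so subject-level output
is reproducible independently of generation order.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .model_core import ModelSpec, intensity_matrix, resolve_parameters
from .panel_likelihood import ObservationRecord, PanelData, Subject

__all__ = [
    "simulate_path",
    "observe_panel",
    "state_at",
    "subject_rng",
    "scenario_library",
]


def subject_rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


# ---------------------------------------------------------------------------
# Exact path simulation
# ---------------------------------------------------------------------------


def _cov_at(segments: Sequence[tuple[float, Mapping[str, float]]], t: float) -> Mapping[str, float]:
    starts = [s for s, _ in segments]
    i = bisect_right(starts, t) - 1
    return segments[max(i, 0)][1]


def simulate_path(
    spec: ModelSpec,
    resolved: Mapping,
    covariate_segments: Sequence[tuple[float, Mapping[str, float]]],
    initial_state: str,
    t_max: float,
    rng: np.random.Generator,
    frailty: float = 1.0,
    t0: float = 0.0,
) -> list[tuple[float, str]]:
    """Exact event history [(time, state entered), ...] starting at (t0, initial_state)."""
    if t_max <= t0:
        raise ValueError("t_max must exceed t0")
    path = [(t0, initial_state)]
    t = t0
    state = initial_state
    seg_starts = sorted({t0, t_max} | {s for s, _ in covariate_segments if t0 < s < t_max})
    while True:
        exits = [(b, resolved[(state, b)]) for a, b in spec.graph.transitions if a == state]
        if not exits:
            break
        target = rng.exponential()
        # walk forward through covariate-constancy segments, accumulating hazard
        jump_t = None
        acc = 0.0
        cur = t
        while jump_t is None and cur < t_max:
            nxt_candidates = [s for s in seg_starts if s > cur]
            nxt = min(nxt_candidates) if nxt_candidates else t_max
            cov = _cov_at(covariate_segments, cur)
            mults = [frailty * math.exp(rt.linear_predictor(cov)) for _, rt in exits]

            def seg_cum(s: float) -> float:
                return sum(
                    m * float(rt.baseline.cumhaz(cur, s)) for m, (_, rt) in zip(mults, exits)
                )

            seg_total = seg_cum(nxt)
            if acc + seg_total >= target:
                need = target - acc
                lo, hi = cur, nxt
                if seg_cum(hi) <= need:
                    jump_t = hi
                else:
                    jump_t = brentq(lambda s: seg_cum(s) - need, lo, hi, xtol=1e-12)
                jump_cov = cov
            else:
                acc += seg_total
                cur = nxt
        if jump_t is None or jump_t >= t_max:
            break
        rates = np.array(
            [max(float(rt.rate(jump_t, jump_cov, frailty)), 0.0) for _, rt in exits]
        )
        if rates.sum() <= 0:
            rates = np.ones(len(exits))
        dest = exits[rng.choice(len(exits), p=rates / rates.sum())][0]
        path.append((float(jump_t), dest))
        t, state = float(jump_t), dest
    return path


def state_at(path: Sequence[tuple[float, str]], t: float) -> str:
    """State occupied at time t (right-continuous step function)."""
    i = bisect_right([tt for tt, _ in path], t) - 1
    return path[max(i, 0)][1]


def observe_panel(
    path: Sequence[tuple[float, str]],
    visit_times: Sequence[float],
    rng: np.random.Generator | None = None,
    emission=None,
    emission_covariates: Callable[[int, float], Mapping[str, float]] | None = None,
    exact_states: Sequence[str] = (),
    covariates: Mapping[str, float] | None = None,
) -> list[ObservationRecord]:
    """Panel records from an exact path.

    States listed in ``exact_states`` (e.g. death) are reported at their true
    event times with the exact flag; other states are read at visit times.
    If an emission model is given, the observed code at each visit is sampled
    from the emission row of the underlying state.
    """
    visit_times = sorted(visit_times)
    if any(t1 <= t0 for t0, t1 in zip(visit_times, visit_times[1:])):
        raise ValueError("visit times must be strictly increasing")
    cov = dict(covariates or {})
    recs: list[ObservationRecord] = []
    exact_events = [(t, s) for t, s in path[1:] if s in exact_states]
    stop = exact_events[0][0] if exact_events else math.inf
    for i, vt in enumerate(visit_times):
        if vt >= stop:
            break
        true_state = state_at(path, vt)
        if emission is None:
            recs.append(ObservationRecord(vt, (true_state,), covariates=dict(cov)))
        else:
            ecov = emission_covariates(i, vt) if emission_covariates else {}
            probs = emission.row(true_state, ecov)
            code = emission.codes[rng.choice(len(probs), p=probs)]
            recs.append(ObservationRecord(vt, (code,), covariates={**cov, **ecov}))
    for t, s in exact_events[:1]:
        recs.append(ObservationRecord(t, (s,), exact=True, covariates=dict(cov)))
    return recs


def _annual_visits(n_visits: int, rng: np.random.Generator, jitter: float = 0.0) -> np.ndarray:
    base = np.arange(1, n_visits + 1, dtype=float)
    if jitter:
        base = base + rng.uniform(-jitter, jitter, size=n_visits)
        base = np.sort(base)
    return base


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------


def scenario_library() -> dict[str, Callable[..., tuple[ModelSpec, dict, PanelData]]]:
    """Named generators mirroring the observation structure of each model class."""
    from . import clustered_frailty, expanded_joint, hidden_states, semicompeting

    return {
        "remission": hidden_states.simulate_remission_scenario,
        "semicompeting": semicompeting.simulate_semicompeting_scenario,
        "expanded": expanded_joint.simulate_expanded_scenario,
        "damage": clustered_frailty.simulate_damage_scenario,
    }
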