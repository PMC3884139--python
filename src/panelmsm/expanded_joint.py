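"""Expanded state space jointly modelling an ordinal outcome Y and a
fluctuating ordinal covariate W.

The joint process lives on the m*n lattice of (Y state, W level) pairs.
Allowed moves change exactly one sub-process by one level: (j,r)->(j+-1,r)
and (j,r)->(j,r+-1); the two sub-processes never jump simultaneously and Y
moves do not wrap across W levels.  Constraints make the expanded model
correspond to a proportional-intensity model for Y given W:

* regression coefficients of a Y move are shared across W levels,
* W-move rates (baseline and coefficients) are shared across Y states,
* Y-move baselines are free per W level, so their log ratios against level 1
  are the W effects on Y transitions.

The "misspecified" comparator is the plain m-state model for Y with W-level
dummy covariates carried forward between visits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np

from .model_core import (
    BaselineDef,
    ModelSpec,
    SpecificationError,
    StateGraph,
    Term,
    TransitionModel,
    resolve_parameters,
)
from .panel_likelihood import ObservationRecord, PanelData, Subject

__all__ = [
    "ExpandedSpace",
    "expand_state_space",
    "build_expanded_model",
    "build_misspecified_model",
    "activity_effects_from_baselines",
    "simulate_expanded_scenario",
    "misspecified_view",
]


@dataclass(frozen=True)
class ExpandedSpace:
    m: int  # number of Y states
    n: int  # number of W levels
    states: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]

    def label(self, j: int, r: int) -> str:
        return f"Y{j}W{r}"

    def pair(self, label: str) -> tuple[int, int]:
        j, r = label[1:].split("W")
        return int(j), int(r)

    def flat_index(self, j: int, r: int) -> int:
        # (j, r) -> j + m*(r-1), 1-based
        return j + self.m * (r - 1)


def expand_state_space(m: int, n: int) -> ExpandedSpace:
    """Lattice of (Y, W) states with single-sub-process adjacent moves only."""
    if m < 2 or n < 2:
        raise SpecificationError("expanded space requires m >= 2 and n >= 2")
    states = tuple(f"Y{j}W{r}" for r in range(1, n + 1) for j in range(1, m + 1))
    transitions = []
    for r in range(1, n + 1):
        for j in range(1, m + 1):
            for dj in (-1, 1):
                if 1 <= j + dj <= m:
                    transitions.append((f"Y{j}W{r}", f"Y{j + dj}W{r}"))
            for dr in (-1, 1):
                if 1 <= r + dr <= n:
                    transitions.append((f"Y{j}W{r}", f"Y{j}W{r + dr}"))
    return ExpandedSpace(m, n, states, tuple(transitions))


def build_expanded_model(
    space: ExpandedSpace,
    y_terms: Sequence[str] = (),
    w_terms: Sequence[str] = (),
) -> ModelSpec:
    """Expanded model with the correspondence constraints applied.

    ``y_terms`` are covariate names whose coefficients on a Y move are shared
    across W levels (one label per ordered Y pair); ``w_terms`` optionally
    let covariates modify the shared W-move rates.
    """
    transitions: dict[tuple[str, str], TransitionModel] = {}
    baselines: dict[str, Any] = {}
    for a, b in space.transitions:
        j0, r0 = space.pair(a)
        j1, r1 = space.pair(b)
        if r0 == r1:  # Y move at W level r0
            bl = f"lamY{j0}{j1}_w{r0}"
            terms = tuple(Term(c, f"bY{j0}{j1}_{c}") for c in y_terms)
        else:  # W move, shared across Y states
            bl = f"lamW{r0}{r1}"
            terms = tuple(Term(c, f"bW{r0}{r1}_{c}") for c in w_terms)
        baselines.setdefault(bl, BaselineDef(bl, "constant"))
        transitions[(a, b)] = TransitionModel((a, b), bl, terms)
    graph = StateGraph(space.states, space.transitions)
    return ModelSpec(
        graph=graph,
        transitions=transitions,
        baselines=baselines,
        metadata={"m": space.m, "n": space.n},
    )


def build_misspecified_model(
    m: int, n: int, extra_terms: Sequence[str] = ()
) -> ModelSpec:
    """Adjacent-reversible m-state model for Y with W-level dummies
    (levels 2..n vs 1, carried forward between visits) as covariates."""
    states = tuple(str(j) for j in range(1, m + 1))
    transitions_list = []
    for j in range(1, m + 1):
        for dj in (-1, 1):
            if 1 <= j + dj <= m:
                transitions_list.append((str(j), str(j + dj)))
    transitions = {}
    baselines = {}
    for a, b in transitions_list:
        bl = f"lam{a}{b}"
        baselines[bl] = BaselineDef(bl, "constant")
        terms = tuple(Term(f"w{lvl}", f"aW{lvl}_{a}{b}") for lvl in range(2, n + 1))
        terms += tuple(Term(c, f"b_{a}{b}_{c}") for c in extra_terms)
        transitions[(a, b)] = TransitionModel((a, b), bl, terms)
    graph = StateGraph(states, tuple(transitions_list))
    return ModelSpec(
        graph=graph, transitions=transitions, baselines=baselines, metadata={"m": m, "n": n}
    )


def activity_effects_from_baselines(fitted, space: ExpandedSpace):
    """Per-Y-pair, per-W-level log rate ratios against level 1, with
    delta-method CIs from the fitted covariance.

    On the working (log-rate) scale the effect is a difference of two
    parameters, so its variance is read directly from the covariance matrix.
    """
    import pandas as pd

    pv = fitted.pv
    cov = fitted.covariance
    rows = []
    pairs = sorted(
        {
            (space.pair(a)[0], space.pair(b)[0])
            for a, b in space.transitions
            if space.pair(a)[1] == space.pair(b)[1]
        }
    )
    for j0, j1 in pairs:
        ref = pv.index(f"lamY{j0}{j1}_w1")
        for r in range(1, space.n + 1):
            if r == 1:
                rows.append(
                    {"y_from": j0, "y_to": j1, "w_level": r, "effect": 0.0, "se": 0.0,
                     "ci_lower": 0.0, "ci_upper": 0.0}
                )
                continue
            i = pv.index(f"lamY{j0}{j1}_w{r}")
            eff = fitted.working[i] - fitted.working[ref]
            if cov is not None:
                var = cov[i, i] + cov[ref, ref] - 2.0 * cov[i, ref]
                se = math.sqrt(max(var, 0.0))
            else:
                se = math.nan
            rows.append(
                {
                    "y_from": j0,
                    "y_to": j1,
                    "w_level": r,
                    "effect": eff,
                    "se": se,
                    "ci_lower": eff - 1.96 * se,
                    "ci_upper": eff + 1.96 * se,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation and the misspecified data view
# ---------------------------------------------------------------------------


def simulate_expanded_scenario(
    n: int = 300,
    m: int = 3,
    n_w: int = 3,
    n_visits: int = 10,
    seed: int = 0,
    truth: Mapping[str, float] | None = None,
    w_effect: float = 1.2,
    w_switch_rate: float = 1.5,
):
    """Joint (Y, W) panel scenario with fast W switching.

    The true Y-move rates depend multiplicatively on the current W level
    (log-linear in level - 1 with slope ``w_effect`` for upward moves); W
    switches at rate ``w_switch_rate`` regardless of Y.  Both coordinates are
    recorded jointly at annual visits.  Returns (spec, truth, PanelData).
    """
    from .simulate import simulate_path, state_at, subject_rng

    space = expand_state_space(m, n_w)
    spec = build_expanded_model(space)
    if truth is None:
        truth = {}
        for bl in spec.baselines:
            if bl.startswith("lamY"):
                j0, j1 = int(bl[4]), int(bl[5])
                r = int(bl.split("_w")[1])
                base = 0.25 if j1 > j0 else 0.35
                eff = w_effect * (r - 1) if j1 > j0 else -0.5 * w_effect * (r - 1)
                truth[bl] = base * math.exp(eff)
            else:
                truth[bl] = w_switch_rate
    resolved = resolve_parameters(spec, truth)
    subjects = []
    visit_times = np.arange(1.0, n_visits + 1.0)
    for i in range(n):
        rng = subject_rng(seed, i)
        w0 = int(rng.integers(1, n_w + 1))
        init = f"Y1W{w0}"
        path = simulate_path(spec, resolved, [(0.0, {})], init, visit_times[-1] + 1.0, rng)
        recs = [ObservationRecord(0.0, (init,))]
        for vt in visit_times:
            recs.append(ObservationRecord(float(vt), (state_at(path, vt),)))
        subjects.append(Subject(i, recs))
    return spec, dict(truth), PanelData(subjects)


def misspecified_view(data: PanelData, space: ExpandedSpace) -> PanelData:
    """Project joint (Y, W) panel records to Y-state records with W-level
    dummy covariates (w2..wn) carried forward between visits."""
    subjects = []
    for subj in data.subjects:
        recs = []
        for r in subj.records:
            j, w = space.pair(r.states[0])
            cov = {f"w{lvl}": 1.0 if w == lvl else 0.0 for lvl in range(2, space.n + 1)}
            cov.update({k: v for k, v in r.covariates.items()})
            recs.append(ObservationRecord(r.time, (str(j),), covariates=cov))
        subjects.append(Subject(subj.id, recs, cluster=subj.cluster, entry_time=subj.entry_time))
    return PanelData(subjects)
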