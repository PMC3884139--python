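"""Declarative specification of continuous-time multi-state intensity models.

A :class:`ModelSpec` describes a finite state graph together with one
transition-intensity model per allowed transition.  Each intensity has a
baseline hazard (constant, piecewise-constant or Weibull) multiplied by a
log-linear term in covariates.  Parameter sharing, equality constraints and
derived-baseline rules (ratio-product and exponential-offset re-parameterizations)
are resolved here into fully numeric per-transition hazards.

The working parameterization is unconstrained: log for positive quantities
(rates, Weibull scale/shape, frailty variance), identity for regression
coefficients and offsets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "StateGraph",
    "ConstantHazard",
    "PiecewiseHazard",
    "WeibullHazard",
    "BaselineDef",
    "DerivedBaselineDef",
    "Term",
    "TransitionModel",
    "FrailtySpec",
    "ParameterVector",
    "ModelSpec",
    "SpecificationError",
    "baseline_hazard",
    "resolve_parameters",
    "intensity_matrix",
]


class SpecificationError(ValueError):
    """Raised for an inconsistent or incomplete model specification."""


# ---------------------------------------------------------------------------
# State graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateGraph:
    """Finite directed state graph with optional unobservable states."""

    states: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]
    unobservable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise SpecificationError("duplicate state labels")
        seen = set()
        for a, b in self.transitions:
            if a == b:
                raise SpecificationError(f"self transition {a}->{b}")
            if a not in self.states or b not in self.states:
                raise SpecificationError(f"transition {a}->{b} uses unknown state")
            if (a, b) in seen:
                raise SpecificationError(f"duplicate transition {a}->{b}")
            seen.add((a, b))
        for s in self.unobservable:
            if s not in self.states:
                raise SpecificationError(f"unobservable state {s} not in state list")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def absorbing(self) -> frozenset[str]:
        out = {a for a, _ in self.transitions}
        return frozenset(s for s in self.states if s not in out)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def successors(self, state: str) -> tuple[str, ...]:
        return tuple(b for a, b in self.transitions if a == state)


# ---------------------------------------------------------------------------
# Resolved (numeric) hazards
# ---------------------------------------------------------------------------


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time in hazard evaluation")
    return t


@dataclass(frozen=True)
class ConstantHazard:
    rate: float
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self):
        if self.rate < 0:
            raise SpecificationError("negative rate")

    def hazard(self, t):
        t = _check_time(t)
        return np.broadcast_to(float(self.rate), t.shape).copy() if t.shape else float(self.rate)

    def cumhaz(self, t0, t1):
        t0 = _check_time(t0)
        t1 = np.asarray(t1, dtype=float)
        return self.rate * (t1 - t0)

    def scaled(self, factor: float) -> "ConstantHazard":
        return ConstantHazard(self.rate * factor)


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard; intervals are left-closed, right-open."""

    cutpoints: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        if len(self.rates) != len(self.cutpoints) + 1:
            raise SpecificationError("piecewise hazard needs one more level than cutpoints")
        if any(r < 0 for r in self.rates):
            raise SpecificationError("negative rate level")
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise SpecificationError("cutpoints must be strictly increasing")

    def hazard(self, t):
        t = _check_time(t)
        idx = np.searchsorted(np.asarray(self.cutpoints), t, side="right")
        out = np.asarray(self.rates, dtype=float)[idx]
        return out if t.shape else float(out)

    def _cum0(self, t):
        # integral of the step function on [0, t]
        t = np.asarray(t, dtype=float)
        edges = np.concatenate([[0.0], np.asarray(self.cutpoints), [np.inf]])
        rates = np.asarray(self.rates, dtype=float)
        tt = t[..., None]
        seg = np.clip(tt - edges[:-1], 0.0, edges[1:] - edges[:-1])
        return np.sum(seg * rates, axis=-1)

    def cumhaz(self, t0, t1):
        _check_time(t0)
        return self._cum0(t1) - self._cum0(t0)

    def scaled(self, factor: float) -> "PiecewiseHazard":
        return PiecewiseHazard(self.cutpoints, tuple(r * factor for r in self.rates))


@dataclass(frozen=True)
class WeibullHazard:
    """Weibull hazard a*b*t^(b-1); cumulative hazard a*t^b."""

    a: float
    b: float
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise SpecificationError("Weibull parameters must be positive")

    def hazard(self, t):
        t = _check_time(t)
        with np.errstate(divide="ignore"):
            out = self.a * self.b * np.power(t, self.b - 1.0)
        return out if t.shape else float(out)

    def cumhaz(self, t0, t1):
        t0 = _check_time(t0)
        t1 = np.asarray(t1, dtype=float)
        return self.a * (np.power(t1, self.b) - np.power(t0, self.b))

    def scaled(self, factor: float) -> "WeibullHazard":
        return WeibullHazard(self.a * factor, self.b)


@dataclass(frozen=True)
class RatioProductHazard:
    """Pointwise prod(numerators) / (k * prod(denominators)); generic fallback."""

    numerators: tuple
    denominators: tuple
    k: float

    @property
    def cutpoints(self) -> tuple[float, ...]:
        pts: set[float] = set()
        for h in self.numerators + self.denominators:
            pts.update(h.cutpoints)
        return tuple(sorted(pts))

    def hazard(self, t):
        t = _check_time(t)
        num = np.ones_like(t, dtype=float) if t.shape else 1.0
        for h in self.numerators:
            num = num * h.hazard(t)
        den = self.k
        for h in self.denominators:
            den = den * h.hazard(t)
        return num / den

    def cumhaz(self, t0, t1):
        t0a = np.atleast_1d(np.asarray(t0, dtype=float))
        t1a = np.atleast_1d(np.asarray(t1, dtype=float))
        t0a, t1a = np.broadcast_arrays(t0a, t1a)
        out = np.empty(t0a.shape)
        for i, (lo, hi) in enumerate(zip(t0a.ravel(), t1a.ravel())):
            val, _ = quad(lambda s: float(self.hazard(s)), lo, hi, limit=200)
            out.ravel()[i] = val
        if np.ndim(t0) == 0 and np.ndim(t1) == 0:
            return float(out.ravel()[0])
        return out

    def scaled(self, factor: float) -> "RatioProductHazard":
        return RatioProductHazard(self.numerators, self.denominators, self.k / factor)


def baseline_hazard(family, t):
    """Evaluate a resolved baseline hazard at time ``t`` (vectorized)."""
    return family.hazard(t)


# ---------------------------------------------------------------------------
# Baseline / transition definitions (parameter names, not values)
# ---------------------------------------------------------------------------

_KINDS = ("constant", "piecewise", "weibull")


@dataclass(frozen=True)
class BaselineDef:
    name: str
    kind: str = "constant"
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SpecificationError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "piecewise" and not self.cutpoints:
            raise SpecificationError("piecewise baseline requires cutpoints")

    def param_names(self) -> tuple[str, ...]:
        if self.kind == "constant":
            return (self.name,)
        if self.kind == "weibull":
            return (f"{self.name}.a", f"{self.name}.b")
        return tuple(f"{self.name}.{i + 1}" for i in range(len(self.cutpoints) + 1))

    def param_scales(self) -> dict[str, str]:
        return {p: "log" for p in self.param_names()}

    def resolve(self, values: Mapping[str, float]):
        if self.kind == "constant":
            return ConstantHazard(values[self.name])
        if self.kind == "weibull":
            return WeibullHazard(values[f"{self.name}.a"], values[f"{self.name}.b"])
        rates = tuple(values[p] for p in self.param_names())
        return PiecewiseHazard(self.cutpoints, rates)


@dataclass(frozen=True)
class DerivedBaselineDef:
    """A baseline defined from other baselines.

    rule ``"exp_offset"``: hazard = sources[0] * exp(offset_param).
    rule ``"ratio_product"``: hazard = prod(numerators) / (k * prod(denominators)),
    with ``sources = numerators + denominators`` and ``n_num`` numerators.
    """

    name: str
    rule: str
    sources: tuple[str, ...]
    n_num: int = 1
    k: float = 1.0
    offset_param: str | None = None

    def __post_init__(self):
        if self.rule not in ("exp_offset", "ratio_product"):
            raise SpecificationError(f"unknown derived rule {self.rule!r}")
        if self.rule == "ratio_product" and self.k <= 0:
            raise SpecificationError("ratio-product constant k must be positive")

    def param_names(self) -> tuple[str, ...]:
        return (self.offset_param,) if self.offset_param else ()

    def param_scales(self) -> dict[str, str]:
        return {p: "identity" for p in self.param_names()}

    def resolve(self, resolved_sources: Sequence, values: Mapping[str, float]):
        if self.rule == "exp_offset":
            return resolved_sources[0].scaled(math.exp(values[self.offset_param]))
        nums = tuple(resolved_sources[: self.n_num])
        dens = tuple(resolved_sources[self.n_num :])
        return _reduce_ratio_product(nums, dens, self.k)


def _as_weibull(h):
    if isinstance(h, WeibullHazard):
        return h.a, h.b
    if isinstance(h, ConstantHazard):
        return h.rate, 1.0
    return None


def _reduce_ratio_product(nums, dens, k):
    parts = [_as_weibull(h) for h in nums + dens]
    if all(p is not None for p in parts):
        # power-law closure: c*t^(b-1) factors combine into another Weibull
        log_c = -math.log(k)
        exponent = 0.0
        for a, b in parts[: len(nums)]:
            log_c += math.log(a * b)
            exponent += b - 1.0
        for a, b in parts[len(nums) :]:
            log_c -= math.log(a * b)
            exponent -= b - 1.0
        shape = exponent + 1.0
        if shape <= 0:
            raise SpecificationError("ratio-product hazard has non-positive shape")
        c = math.exp(log_c)
        if abs(shape - 1.0) < 1e-12:
            return ConstantHazard(c)
        return WeibullHazard(c / shape, shape)
    pw = [h for h in nums + dens if isinstance(h, (PiecewiseHazard, ConstantHazard))]
    if len(pw) == len(nums) + len(dens):
        cuts: set[float] = set()
        for h in pw:
            cuts.update(h.cutpoints)
        cuts_t = tuple(sorted(cuts))
        probes = list(cuts_t) + [(cuts_t[-1] + 1.0) if cuts_t else 0.0]
        if not cuts_t:
            probes = [0.0]
        rates = []
        for lo in [0.0] + list(cuts_t):
            num = 1.0
            for h in nums:
                num *= float(h.hazard(lo))
            den = k
            for h in dens:
                den *= float(h.hazard(lo))
            rates.append(num / den)
        if cuts_t:
            return PiecewiseHazard(cuts_t, tuple(rates))
        return ConstantHazard(rates[0])
    return RatioProductHazard(tuple(nums), tuple(dens), k)


@dataclass(frozen=True)
class Term:
    """One log-linear covariate term; identical labels share one coefficient."""

    covariate: str
    label: str


@dataclass(frozen=True)
class TransitionModel:
    transition: tuple[str, str]
    baseline: str
    terms: tuple[Term, ...] = ()


@dataclass(frozen=True)
class FrailtySpec:
    """Gamma frailty with unit mean and variance theta, shared within clusters."""

    theta_param: str = "theta"
    quadrature_order: int = 30


# ---------------------------------------------------------------------------
# Parameter vector: working <-> natural transforms
# ---------------------------------------------------------------------------


_TRANSFORMS = {
    "log": (np.log, np.exp),
    "identity": (lambda x: x, lambda x: x),
    "logit": (
        lambda p: np.log(p / (1.0 - p)),
        lambda x: 1.0 / (1.0 + np.exp(-x)),
    ),
}


@dataclass(frozen=True)
class ParameterVector:
    names: tuple[str, ...]
    scales: tuple[str, ...]

    def __post_init__(self):
        for s in self.scales:
            if s not in _TRANSFORMS:
                raise SpecificationError(f"unknown scale {s!r}")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def scale_of(self, name: str) -> str:
        return self.scales[self.index(name)]

    def to_working(self, natural: Mapping[str, float]) -> np.ndarray:
        out = np.empty(len(self.names))
        for i, (nm, sc) in enumerate(zip(self.names, self.scales)):
            out[i] = _TRANSFORMS[sc][0](float(natural[nm]))
        return out

    def to_natural(self, working: Sequence[float]) -> dict[str, float]:
        working = np.asarray(working, dtype=float)
        if working.shape != (len(self.names),):
            raise ValueError("working vector has wrong length")
        return {
            nm: float(_TRANSFORMS[sc][1](w))
            for nm, sc, w in zip(self.names, self.scales, working)
        }


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.get(x, x)
        if p == x:
            return x
        root = self.find(p)
        self.parent[x] = root
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep lexicographically smallest as canonical for determinism
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


@dataclass
class ModelSpec:
    """Full declarative multi-state model.

    Parameters are referenced by name: baseline parameters carry the baseline
    name (e.g. ``lam12`` or ``lam3.a``), regression coefficients carry their
    sharing label.  ``equal`` groups unify parameter names; ``fixed`` pins
    named parameters to constants; derived baselines are evaluated after the
    baselines they reference.
    """

    graph: StateGraph
    transitions: dict[tuple[str, str], TransitionModel]
    baselines: dict[str, Any]
    equal: tuple[tuple[str, ...], ...] = ()
    fixed: dict[str, float] = field(default_factory=dict)
    emission: Any = None
    frailty: FrailtySpec | None = None
    state_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    initial_state: str | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        for tr in self.graph.transitions:
            if tr not in self.transitions:
                raise SpecificationError(f"transition {tr} has no intensity model")
        for tr, tm in self.transitions.items():
            if tr not in self.graph.transitions:
                raise SpecificationError(f"intensity model for disallowed transition {tr}")
            if tm.baseline not in self.baselines:
                raise SpecificationError(f"unknown baseline {tm.baseline!r} for {tr}")
        self._uf = _UnionFind()
        for group in self.equal:
            for other in group[1:]:
                self._uf.union(group[0], other)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        colors: dict[str, int] = {}

        def visit(name: str) -> None:
            if colors.get(name) == 1:
                raise SpecificationError("cyclic derived-baseline constraints")
            if colors.get(name) == 2:
                return
            colors[name] = 1
            bd = self.baselines.get(name)
            if bd is None:
                raise SpecificationError(f"derived rule references unknown baseline {name!r}")
            if isinstance(bd, DerivedBaselineDef):
                for src in bd.sources:
                    visit(src)
            colors[name] = 2

        for name in self.baselines:
            visit(name)

    # -- parameter bookkeeping ------------------------------------------------

    def canonical(self, name: str) -> str:
        return self._uf.find(name)

    def parameters(self) -> ParameterVector:
        names: list[str] = []
        scales: dict[str, str] = {}

        def add(name: str, scale: str) -> None:
            cn = self.canonical(name)
            if cn in self.fixed or name in self.fixed:
                return
            if cn not in scales:
                names.append(cn)
                scales[cn] = scale
            elif scales[cn] != scale:
                raise SpecificationError(f"parameter {cn} shared across scales")

        for bd in self.baselines.values():
            for p in bd.param_names():
                add(p, bd.param_scales()[p])
        for tm in self.transitions.values():
            for term in tm.terms:
                add(term.label, "identity")
        if self.emission is not None:
            for p, sc in self.emission.param_scales().items():
                add(p, sc)
        if self.frailty is not None:
            add(self.frailty.theta_param, "log")
        return ParameterVector(tuple(names), tuple(scales[n] for n in names))

    @property
    def covariates(self) -> tuple[str, ...]:
        seen: list[str] = []
        for tr in self.graph.transitions:
            for term in self.transitions[tr].terms:
                if term.covariate not in seen:
                    seen.append(term.covariate)
        return tuple(seen)

    def lookup(self, natural: Mapping[str, float], name: str) -> float:
        cn = self.canonical(name)
        if cn in self.fixed:
            return float(self.fixed[cn])
        if name in self.fixed:
            return float(self.fixed[name])
        if cn in natural:
            return float(natural[cn])
        if name in natural:
            return float(natural[name])
        raise SpecificationError(f"missing value for parameter {name!r}")


@dataclass(frozen=True)
class ResolvedTransition:
    baseline: Any
    coefs: tuple[tuple[str, float], ...]

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        lp = 0.0
        for cov, val in self.coefs:
            try:
                lp += val * float(covariates[cov])
            except KeyError:
                raise SpecificationError(f"missing covariate {cov!r}") from None
        return lp

    def rate(self, t, covariates: Mapping[str, float], frailty: float = 1.0):
        return frailty * self.baseline.hazard(t) * math.exp(self.linear_predictor(covariates))

    def cumhaz(self, t0, t1, covariates: Mapping[str, float], frailty: float = 1.0):
        return frailty * self.baseline.cumhaz(t0, t1) * math.exp(self.linear_predictor(covariates))


def resolve_parameters(
    spec: ModelSpec, natural: Mapping[str, float]
) -> dict[tuple[str, str], ResolvedTransition]:
    """Resolve all constraints into numeric per-transition hazards/coefficients."""
    values = {}
    for bd in spec.baselines.values():
        for p in bd.param_names():
            values[p] = spec.lookup(natural, p)

    resolved_baselines: dict[str, Any] = {}

    def resolve_baseline(name: str):
        if name in resolved_baselines:
            return resolved_baselines[name]
        bd = spec.baselines[name]
        if isinstance(bd, DerivedBaselineDef):
            srcs = [resolve_baseline(s) for s in bd.sources]
            out = bd.resolve(srcs, values)
        else:
            out = bd.resolve(values)
        resolved_baselines[name] = out
        return out

    result: dict[tuple[str, str], ResolvedTransition] = {}
    for tr in spec.graph.transitions:
        tm = spec.transitions[tr]
        coefs = tuple((term.covariate, spec.lookup(natural, term.label)) for term in tm.terms)
        result[tr] = ResolvedTransition(resolve_baseline(tm.baseline), coefs)
    return result


def intensity_matrix(
    spec: ModelSpec,
    resolved: Mapping[tuple[str, str], ResolvedTransition],
    covariates: Mapping[str, float],
    t: float,
    frailty: float = 1.0,
) -> np.ndarray:
    """Generator matrix Q(t): off-diagonals are transition rates, rows sum to 0."""
    n = spec.graph.n_states
    Q = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(spec.graph.states)}
    for (a, b), rt in resolved.items():
        Q[idx[a], idx[b]] = rt.rate(t, covariates, frailty)
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q
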