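"""Maximum-likelihood fitting, uncertainty and model comparison.

The objective is the total log-likelihood appropriate to the model class
(plain panel, hidden-state forward, frailty-marginal, or a bespoke callable),
maximized over the unconstrained working parameterization by quasi-Newton
search with finite-difference gradients.  The covariance is the inverse of
the negative numerical Hessian at the optimum.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .model_core import ModelSpec, ParameterVector, resolve_parameters
from .panel_likelihood import PanelData, PanelDesign

__all__ = ["FittedModel", "fit", "lr_test", "wald_summary", "default_start", "numerical_hessian"]

_WORK_BOUND = 20.0


@dataclass
class FittedModel:
    spec: ModelSpec
    pv: ParameterVector
    working: np.ndarray
    covariance: np.ndarray | None
    loglik: float
    converged: bool
    n_params: int
    message: str = ""
    boundary: tuple[str, ...] = ()

    def natural(self) -> dict[str, float]:
        return self.pv.to_natural(self.working)

    def se(self) -> np.ndarray:
        if self.covariance is None:
            return np.full(self.pv.n, np.nan)
        d = np.diag(self.covariance)
        return np.sqrt(np.clip(d, 0.0, None))

    def estimate(self, name: str) -> float:
        return float(self.working[self.pv.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se()[self.pv.index(name)])

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        e, s = self.estimate(name), self.se_of(name)
        return (e - z * s, e + z * s)


def build_objective(spec: ModelSpec, data: PanelData) -> Callable[[Mapping[str, float]], float]:
    """Log-likelihood of natural parameters for the model class implied by spec."""
    if spec.emission is not None:
        from .hidden_states import HMMLikelihood

        like = HMMLikelihood(spec, data)
        return like.loglik
    if spec.frailty is not None:
        from .clustered_frailty import MarginalLikelihood

        like = MarginalLikelihood(spec, data)
        return like.loglik
    design = PanelDesign(spec, data)

    def ll(natural: Mapping[str, float]) -> float:
        return design.loglik(resolve_parameters(spec, natural))

    return ll


def default_start(spec: ModelSpec, data: PanelData | None = None) -> dict[str, float]:
    """Crude starting values: occurrence/exposure rates where observable,
    0.1 otherwise; coefficients 0; frailty variance 0.1; emission logits 0."""
    pv = spec.parameters()
    counts: dict[tuple[str, str], float] = {tr: 0.0 for tr in spec.graph.transitions}
    exposure: dict[str, float] = {s: 0.0 for s in spec.graph.states}
    observed = False
    if data is not None and spec.emission is None:
        for subj in data.subjects:
            recs = subj.records
            for r0, r1 in zip(recs, recs[1:]):
                if len(r0.states) != 1 or len(r1.states) != 1:
                    continue
                observed = True
                exposure[r0.states[0]] += r1.time - r0.time
                if r0.states != r1.states and (r0.states[0], r1.states[0]) in counts:
                    counts[(r0.states[0], r1.states[0])] += 1.0
    crude: dict[str, float] = {}
    if observed:
        for tr, c in counts.items():
            expo = exposure[tr[0]]
            if expo > 0:
                bl = spec.transitions[tr].baseline
                crude.setdefault(bl, max(c, 0.5) / expo)
    natural: dict[str, float] = {}
    for name, scale in zip(pv.names, pv.scales):
        if scale == "log":
            base = name.split(".")[0]
            rate = crude.get(base, crude.get(name, 0.1))
            if name.endswith(".b"):
                natural[name] = 1.0  # Weibull shape
            elif name == "theta" or name.endswith("theta"):
                natural[name] = 0.1
            else:
                natural[name] = rate
        elif scale == "logit":
            natural[name] = 0.5
        else:
            natural[name] = 0.0
    return natural


def numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of f at x."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit(
    spec: ModelSpec,
    data: PanelData | None = None,
    start: Mapping[str, float] | None = None,
    objective: Callable[[Mapping[str, float]], float] | None = None,
    method: str = "L-BFGS-B",
    gtol: float = 1e-6,
    maxiter: int = 500,
    compute_covariance: bool = True,
    n_restarts: int = 0,
    rng: np.random.Generator | None = None,
) -> FittedModel:
    """Maximize the log-likelihood; returns estimates, covariance and diagnostics.

    ``objective`` maps a natural-parameter dict to the log-likelihood; by
    default it is built from the spec/data (panel, hidden-state or frailty).
    """
    pv = spec.parameters()
    if objective is None:
        if data is None:
            raise ValueError("either data or an objective is required")
        objective = build_objective(spec, data)
    if start is None:
        start = default_start(spec, data)
    x0 = pv.to_working(start)
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite starting values on the working scale")

    def neg(x: np.ndarray) -> float:
        natural = pv.to_natural(x)
        ll = objective(natural)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    bounds = [(-_WORK_BOUND, _WORK_BOUND)] * pv.n
    best = None
    starts = [x0]
    if n_restarts:
        rng = rng or np.random.default_rng(0)
        for _ in range(n_restarts):
            starts.append(x0 + rng.normal(scale=0.5, size=pv.n))
    for s0 in starts:
        res = optimize.minimize(
            neg,
            s0,
            method=method,
            bounds=bounds if method in ("L-BFGS-B", "TNC") else None,
            options={"maxiter": maxiter, "gtol": gtol}
            if method == "BFGS"
            else {"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    xhat = np.asarray(best.x, dtype=float)
    # a log-scale working value this extreme means the natural parameter ran
    # to the 0 or +inf boundary of its domain
    boundary = tuple(
        pv.names[i]
        for i in range(pv.n)
        if abs(abs(xhat[i]) - _WORK_BOUND) < 1e-6
        or (pv.scales[i] == "log" and abs(xhat[i]) > 12.0)
    )
    if boundary:
        warnings.warn(f"estimates at working-scale boundary: {boundary}", RuntimeWarning)
    cov = None
    if compute_covariance and pv.n:
        H = numerical_hessian(lambda x: -neg(x), xhat)
        try:
            cov = np.linalg.pinv(-H)
            cov = 0.5 * (cov + cov.T)
        except np.linalg.LinAlgError:
            cov = None
    return FittedModel(
        spec=spec,
        pv=pv,
        working=xhat,
        covariance=cov,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_params=pv.n,
        message=str(best.message),
        boundary=boundary,
    )


def lr_test(fit_full: FittedModel, fit_reduced: FittedModel, df: int | None = None):
    """Likelihood-ratio statistic and upper-tail chi-square p-value."""
    implied = fit_full.n_params - fit_reduced.n_params
    if df is None:
        df = implied
    if df != implied:
        raise ValueError(f"df={df} does not match parameter-count difference {implied}")
    if df <= 0:
        raise ValueError("full model must have more free parameters than reduced")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -1e-6:
        warnings.warn(
            "reduced model has higher likelihood than full model; refit advised",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def wald_summary(fitted: FittedModel, transform: str = "none", level: float = 0.95):
    """Per-parameter estimates, SEs and Wald CIs on the working scale, with an
    optional mapped scale ('exp' gives rates / rate ratios)."""
    import pandas as pd

    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fitted.se()
    rows = []
    for i, name in enumerate(fitted.pv.names):
        est = fitted.working[i]
        lo, hi = est - z * se[i], est + z * se[i]
        row = {
            "parameter": name,
            "scale": fitted.pv.scales[i],
            "estimate": est,
            "se": se[i],
            "ci_lower": lo,
            "ci_upper": hi,
        }
        if transform == "exp":
            row.update(
                {"ratio": math.exp(est), "ratio_lower": math.exp(lo), "ratio_upper": math.exp(hi)}
            )
        rows.append(row)
    return pd.DataFrame(rows)
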