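"""Deterministic and probabilistic sensitivity analyses.

The one-way DSA re-runs the full model with each registry parameter set to
its lower and upper bound in turn, everything else at base.  The PSA draws
all parameters jointly and independently from distributions quantile-matched
to the published intervals (interpreted as central 95% intervals):
probabilities and utilities from a beta, costs from a gamma, ratios (odds
ratios, mortality risks, the suicide multiplier) from a lognormal with
median at the base value.  Each replication re-evaluates both arms under
both perspectives from one set of draws, so the dominance fractions per
perspective come from the same simulations.

Randomness contract: one master seed; every parameter draws its replication
stream from its own deterministic child of that seed, so results do not
depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import outcomes
from .params import (
    PERSPECTIVES,
    ModelParameters,
    ParameterError,
    clone_params,
    param_registry,
    parameter_bounds,
)

DEFAULT_CEAC_THRESHOLDS = tuple(range(0, 200_001, 10_000))


# ---------------------------------------------------------------------------
# Deterministic (one-way)
# ---------------------------------------------------------------------------


@dataclass
class DsaRecord:
    parameter_id: str
    bound: str  # "lower" | "upper"
    value: float
    results: dict  # perspective -> IcurResult


def run_dsa(params: ModelParameters, perspectives=PERSPECTIVES) -> list:
    """One record per parameter per bound, all other parameters at base."""
    registry = {d.id: d for d in param_registry()}
    records = []
    for pid, lo, hi in parameter_bounds(params):
        d = registry[pid]
        if not d.in_dsa:
            continue
        for bound_name, value in (("lower", lo), ("upper", hi)):
            if d.kind == "age":
                value = int(round(value))
            varied = clone_params(params)
            d.set(varied, value)
            res = outcomes.run_model(varied)
            records.append(
                DsaRecord(
                    parameter_id=pid,
                    bound=bound_name,
                    value=value,
                    results={p: res[p]["icur"] for p in perspectives},
                )
            )
    return records


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


class Distribution:
    """A sampling distribution for one parameter."""

    kind = "point"

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class PointMass(Distribution):
    value: float
    kind: str = "point"

    def rvs(self, rng, size):
        return np.full(size, self.value)


@dataclass
class BetaDist(Distribution):
    a: float
    b: float
    kind: str = "beta"

    def rvs(self, rng, size):
        return rng.beta(self.a, self.b, size)

    @property
    def mean(self):
        return self.a / (self.a + self.b)


@dataclass
class GammaDist(Distribution):
    shape: float
    scale: float
    kind: str = "gamma"

    def rvs(self, rng, size):
        return rng.gamma(self.shape, self.scale, size)

    @property
    def mean(self):
        return self.shape * self.scale


@dataclass
class LogNormalDist(Distribution):
    mu: float  # log-scale median
    sigma: float
    kind: str = "lognormal"

    def rvs(self, rng, size):
        return rng.lognormal(self.mu, self.sigma, size)

    @property
    def median(self):
        return float(np.exp(self.mu))


def _central_width(dist, lo_q=0.025, hi_q=0.975):
    return dist.ppf(hi_q) - dist.ppf(lo_q)


def _beta_from_interval(mean: float, lo: float, hi: float) -> Distribution:
    """Beta with the given mean whose central 95% width matches (lo, hi)."""
    width = hi - lo
    if width <= 1e-12 or not (0.0 < mean < 1.0):
        return PointMass(mean)

    def gap(log_k):
        k = np.exp(log_k)
        return _central_width(stats.beta(mean * k, (1 - mean) * k)) - width

    lo_lk, hi_lk = np.log(0.2), np.log(1e7)
    if gap(lo_lk) < 0:  # requested width wider than any unimodal-ish beta gives
        k = 0.2
    else:
        k = float(np.exp(optimize.brentq(gap, lo_lk, hi_lk, xtol=1e-10)))
    return BetaDist(mean * k, (1 - mean) * k)


def _gamma_from_interval(mean: float, lo: float, hi: float) -> Distribution:
    width = hi - lo
    if width <= 1e-12 or mean <= 0:
        return PointMass(mean)

    def gap(log_k):
        k = np.exp(log_k)
        return _central_width(stats.gamma(k, scale=mean / k)) - width

    # the central 95% width is not monotone in the shape (it collapses again
    # as the shape -> 0), so bracket the root from the width maximum down
    grid = np.log(np.logspace(-3, 8, 45))
    gaps = np.array([gap(lk) for lk in grid])
    i_max = int(np.argmax(gaps))
    if gaps[i_max] < 0:  # requested width wider than any gamma of this mean
        k = float(np.exp(grid[i_max]))
    else:
        k = float(np.exp(optimize.brentq(gap, grid[i_max], np.log(1e8), xtol=1e-10)))
    return GammaDist(k, mean / k)


def _lognormal_from_interval(base: float, lo: float, hi: float) -> Distribution:
    if hi - lo <= 1e-12 or base <= 0 or lo <= 0:
        return PointMass(base)
    sigma = (np.log(hi) - np.log(lo)) / (2 * stats.norm.ppf(0.975))
    return LogNormalDist(float(np.log(base)), float(sigma))


def assign_distributions(params: ModelParameters) -> dict:
    """Registry id -> Distribution, per the family rules above.

    Parameters outside the PSA scope (the fixed intervention drug price, the
    additional-disutility scenario weight, entry age, the discount rate) get
    point masses at base.
    """
    bounds = {pid: (lo, hi) for pid, lo, hi in parameter_bounds(params)}
    out = {}
    for d in param_registry():
        base = d.get(params)
        lo, hi = bounds[d.id]
        if lo > hi:
            raise ParameterError(f"{d.id}: infeasible bounds ({lo}, {hi})")
        if not d.in_psa or hi - lo <= 1e-12:
            out[d.id] = PointMass(base)
        elif d.kind in ("probability", "utility"):
            out[d.id] = _beta_from_interval(base, lo, hi)
        elif d.kind == "cost":
            out[d.id] = _gamma_from_interval(base, lo, hi)
        elif d.kind == "ratio":
            out[d.id] = _lognormal_from_interval(base, lo, hi)
        elif d.kind == "disutility":
            # non-negative magnitudes: gamma; a zero base stays degenerate
            out[d.id] = _gamma_from_interval(base, max(lo, 0.0), hi) if base > 0 else PointMass(base)
        else:
            out[d.id] = PointMass(base)
    return out


def point_mass_distributions(params: ModelParameters) -> dict:
    """Degenerate distribution set (every parameter at base)."""
    return {d.id: PointMass(d.get(params)) for d in param_registry()}


# ---------------------------------------------------------------------------
# Probabilistic (Monte Carlo)
# ---------------------------------------------------------------------------


@dataclass
class PsaResult:
    n_reps: int
    seed: int
    delta_cost: dict  # perspective -> array of n_reps incremental costs
    delta_qaly: np.ndarray  # incremental QALYs (perspective-free)
    fraction_dominant: dict  # perspective -> fraction with (dC<0, dQ>0)
    ceac: dict  # perspective -> list of (threshold $/QALY, P(cost-effective))
    thresholds: tuple = DEFAULT_CEAC_THRESHOLDS

    def draws(self, perspective: str):
        return list(zip(self.delta_cost[perspective], self.delta_qaly))


def ceac_curve(delta_cost: np.ndarray, delta_qaly: np.ndarray, thresholds) -> list:
    """P(threshold * dQ - dC > 0) per willingness-to-pay threshold."""
    return [
        (float(lam), float(np.mean(lam * delta_qaly - delta_cost > 0.0)))
        for lam in thresholds
    ]


def run_psa(
    params: ModelParameters,
    n_reps: int = 10_000,
    seed: int = 0,
    distributions: dict | None = None,
    thresholds=DEFAULT_CEAC_THRESHOLDS,
) -> PsaResult:
    """Joint Monte Carlo over all parameter distributions."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    if distributions is None:
        distributions = assign_distributions(params)

    registry = param_registry()
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(registry))
    draws = {}
    for d, stream in zip(registry, streams):
        rng = np.random.default_rng(stream)
        draws[d.id] = distributions[d.id].rvs(rng, n_reps)
        if d.kind == "probability":
            draws[d.id] = np.clip(draws[d.id], 0.0, 1.0)

    delta_cost = {p: np.empty(n_reps) for p in PERSPECTIVES}
    delta_qaly = np.empty(n_reps)
    for rep in range(n_reps):
        varied = clone_params(params)
        for d in registry:
            value = float(draws[d.id][rep])
            if d.kind == "age":
                value = int(round(value))
            d.set(varied, value)
        res = outcomes.run_model(varied)
        for p in PERSPECTIVES:
            delta_cost[p][rep] = res[p]["icur"].delta_cost
        delta_qaly[rep] = res[PERSPECTIVES[0]]["icur"].delta_qaly

    fraction = {
        p: float(np.mean((delta_cost[p] < 0.0) & (delta_qaly > 0.0))) for p in PERSPECTIVES
    }
    ceac = {p: ceac_curve(delta_cost[p], delta_qaly, thresholds) for p in PERSPECTIVES}
    return PsaResult(
        n_reps=n_reps,
        seed=seed,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        fraction_dominant=fraction,
        ceac=ceac,
        thresholds=tuple(thresholds),
    )
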