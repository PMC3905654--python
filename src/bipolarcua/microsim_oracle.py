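"""Individual-level Monte Carlo oracle for the cohort engine.

Simulates patients one by one (vectorised across the sample) through the
same event logic as the cohort model — year-1 tree, then annual cycles with
death first, sequential competing complications in the configured order,
and fatal splits for incident CHD/stroke — but realises every event by
sampling rather than by matrix algebra.  Sample means of discounted cost
and QALY therefore estimate the cohort engine's exact expectations, and the
two must agree within Monte Carlo error.  This is a validation tool, not a
user-facing analysis mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import decision_tree
from .markov_engine import STATUS_EVENT, STATUS_NONE, STATUS_POST, adjusted_probability
from .params import (
    COMPLICATIONS,
    MOH,
    PERSPECTIVES,
    SEXES,
    SOCIETAL,
    ModelParameters,
    RunSpec,
)


@dataclass
class MicrosimArmResult:
    arm: str
    n: int
    mean_cost: dict  # perspective -> mean discounted cost per person
    se_cost: dict
    mean_qaly: float
    se_qaly: float


def _per_sex(values: dict, male: np.ndarray) -> np.ndarray:
    return np.where(male, values["male"], values["female"])


def simulate_arm(
    params: ModelParameters,
    arm: str = "intervention",
    n: int = 10_000,
    seed: int = 0,
    spec: RunSpec | None = None,
) -> MicrosimArmResult:
    """Simulate ``n`` patients on one arm; per-person discounted outcomes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or params.run
    arm_params = getattr(params, arm)
    utils, costs, epi, mort = (
        params.utilities,
        params.costs,
        params.epidemiology,
        params.mortality,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0 if arm == "intervention" else 1]))

    male = rng.random(n) < spec.sex_mix
    eps = rng.random(n) < arm_params.p_eps_y1
    switched = eps & (rng.random(n) < arm_params.p_switch_given_eps)
    wg = rng.random(n) < arm_params.p_weight_gain_y1

    cost = {p: np.zeros(n) for p in PERSPECTIVES}
    qaly = np.zeros(n)

    # year 1: the decision tree
    drug_y1 = np.where(
        switched,
        0.5 * arm_params.annual_drug_cost + 0.5 * arm_params.switch_drug_annual_cost,
        arm_params.annual_drug_cost,
    )
    y1_cost = drug_y1 + np.where(eps, costs.eps_management, 0.0)
    y1_qaly = np.maximum(
        utils.u_bpd
        - np.where(wg, utils.du_weight_gain * utils.wg_year1_exposure, 0.0)
        - np.where(eps, utils.du_eps * utils.eps_duration_years, 0.0),
        0.0,
    )
    rate = spec.discount_rate
    weights = {t: 1.0 for t in range(1, spec.horizon_years + 1)}
    if spec.half_cycle_correction:
        weights[1] = 0.5
        weights[spec.horizon_years] = 0.5

    def df(year):
        exp = year if spec.discount_first_year else year - 1
        return 1.0 / (1.0 + rate) ** exp

    for p in PERSPECTIVES:
        cost[p] += y1_cost * df(1) * weights[1]
    qaly += y1_qaly * df(1) * weights[1]

    # entry into the long-term phase: prevalent complications (independent)
    prev = {c: _per_sex({s: epi.prevalence[(c, s)] for s in SEXES}, male) for c in COMPLICATIONS}
    dm = rng.random(n) < prev["diabetes"]
    ht = rng.random(n) < prev["hypertension"]
    chd = np.where(rng.random(n) < prev["chd"], STATUS_POST, STATUS_NONE)
    st = np.where(rng.random(n) < prev["stroke"], STATUS_POST, STATUS_NONE)
    alive = np.ones(n, dtype=bool)

    drug_annual = np.where(switched, arm_params.switch_drug_annual_cost, arm_params.annual_drug_cost)
    du = {c: _per_sex({s: utils.du_complication[(c, s)] for s in SEXES}, male) for c in COMPLICATIONS}
    mort_rr = {c: _per_sex({s: params.risks.mortality_risk[(c, s)] for s in SEXES}, male) for c in COMPLICATIONS}

    for year in range(2, spec.horizon_years + 1):
        age = spec.entry_age + year - 1
        d = df(year) * weights[year]

        base_q = _per_sex(
            {
                s: mort.life_table[s][age]
                - mort.suicide.get(s, {}).get(age, 0.0) * (1.0 - mort.bpd_suicide_multiplier)
                for s in SEXES
            },
            male,
        )
        present = {
            "diabetes": dm,
            "hypertension": ht,
            "chd": chd != STATUS_NONE,
            "stroke": st != STATUS_NONE,
        }
        if spec.mortality_combination == "max":
            factor = np.ones(n)
            for c in COMPLICATIONS:
                factor = np.where(present[c], np.maximum(factor, mort_rr[c]), factor)
        else:
            factor = np.ones(n)
            for c in COMPLICATIONS:
                factor = np.where(present[c], factor * mort_rr[c], factor)
        q = np.clip(base_q * factor, 0.0, 1.0)
        died = alive & (rng.random(n) < q)
        alive = alive & ~died

        # event-year tiers from last cycle move to the post tier
        chd = np.where(chd == STATUS_EVENT, STATUS_POST, chd)
        st = np.where(st == STATUS_EVENT, STATUS_POST, st)

        acquired = np.zeros(n, dtype=bool)
        for c in spec.complication_order:
            p_base = {s: epi.incidence[(c, s)][age] for s in SEXES}
            p_wg = {
                s: float(
                    adjusted_probability(
                        p_base[s],
                        params.risks.odds_ratio_weight_gain[(c, s)],
                        as_rr=spec.or_as_rr,
                    )
                )
                for s in SEXES
            }
            p = np.where(wg, _per_sex(p_wg, male), _per_sex(p_base, male))
            if c == "diabetes":
                eligible = alive & ~dm & ~acquired
            elif c == "hypertension":
                eligible = alive & ~ht & ~acquired
            elif c == "chd":
                eligible = alive & (chd == STATUS_NONE) & ~acquired
            else:
                eligible = alive & (st == STATUS_NONE) & ~acquired
            hit = eligible & (rng.random(n) < p)
            acquired |= hit
            if c == "diabetes":
                dm |= hit
            elif c == "hypertension":
                ht |= hit
            elif c == "chd":
                fatal = hit & (rng.random(n) < epi.p_fatal_chd)
                alive = alive & ~fatal
                for persp in PERSPECTIVES:
                    cost[persp] += np.where(fatal, costs.direct["chd_fatal"] * d, 0.0)
                chd = np.where(hit & ~fatal, STATUS_EVENT, chd)
            else:
                fatal = hit & (rng.random(n) < epi.p_fatal_stroke)
                alive = alive & ~fatal
                for persp in PERSPECTIVES:
                    cost[persp] += np.where(fatal, costs.direct["stroke_fatal"] * d, 0.0)
                st = np.where(hit & ~fatal, STATUS_EVENT, st)

        # accrual over the year for survivors
        present = {
            "diabetes": dm,
            "hypertension": ht,
            "chd": chd != STATUS_NONE,
            "stroke": st != STATUS_NONE,
        }
        year_cost = drug_annual.copy()
        year_cost += np.where(dm, costs.direct["diabetes"], 0.0)
        year_cost += np.where(ht, costs.direct["hypertension"], 0.0)
        year_cost += np.where(chd == STATUS_EVENT, costs.direct["chd_y1"], 0.0)
        year_cost += np.where(chd == STATUS_POST, costs.direct["chd_y2plus"], 0.0)
        year_cost += np.where(st == STATUS_EVENT, costs.direct["stroke_y1"], 0.0)
        year_cost += np.where(st == STATUS_POST, costs.direct["stroke_y2plus"], 0.0)
        soc_extra = np.zeros(n)
        for c in COMPLICATIONS:
            soc_extra += np.where(present[c], costs.productivity[c], 0.0)
        soc_extra += np.where(st != STATUS_NONE, costs.informal_care_stroke, 0.0)
        cost[MOH] += np.where(alive, year_cost, 0.0) * d
        cost[SOCIETAL] += np.where(alive, year_cost + soc_extra, 0.0) * d

        du_stack = np.stack([np.where(present[c], du[c], -np.inf) for c in COMPLICATIONS])
        any_present = present["diabetes"] | present["hypertension"] | present["chd"] | present["stroke"]
        worst = np.where(any_present, du_stack.max(axis=0), 0.0)
        du_sum = np.stack([np.where(present[c], du[c], 0.0) for c in COMPLICATIONS]).sum(axis=0)
        comp = np.where(any_present, worst + utils.w_additional * (du_sum - worst), 0.0)
        u = np.maximum(utils.u_bpd - np.where(wg, utils.du_weight_gain, 0.0) - comp, 0.0)
        qaly += np.where(alive, u, 0.0) * d

    def mean_se(x):
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    mean_cost, se_cost = {}, {}
    for p in PERSPECTIVES:
        mean_cost[p], se_cost[p] = mean_se(cost[p])
    mean_qaly, se_qaly = mean_se(qaly)
    return MicrosimArmResult(
        arm=arm_params.name,
        n=n,
        mean_cost=mean_cost,
        se_cost=se_cost,
        mean_qaly=mean_qaly,
        se_qaly=se_qaly,
    )


def simulate_cohort(
    params: ModelParameters, n: int = 10_000, seed: int = 0, spec: RunSpec | None = None
) -> dict:
    """Both arms: {"intervention": MicrosimArmResult, "comparator": ...}."""
    return {
        arm: simulate_arm(params, arm=arm, n=n, seed=seed, spec=spec)
        for arm in ("intervention", "comparator")
    }
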