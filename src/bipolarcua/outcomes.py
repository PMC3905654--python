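"""Cost and QALY accrual, discounting, and the incremental cost-utility ratio.

Costs are accrued under two perspectives: the health-ministry (MoH)
perspective covers drugs, EPS management and the direct medical costs of
complications; the societal perspective adds productivity losses per
complication and informal care for stroke.  QALYs weight each alive year by
the baseline bipolar-disorder utility minus the permanent weight-gain
decrement and the complication decrement — by default only the most
debilitating complication counts, with an optional weight on the remaining
concurrent decrements.

Discounting is annual at ``run.discount_rate`` with the first year
undiscounted (factor 1 at year 1), the usual convention for annual-cycle
cost-utility models; a config flag moves the whole stream one year later.
Totals are reported per ``run.cohort_size_report`` persons (1,000 by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import decision_tree, markov_engine
from .decision_tree import Stratum
from .markov_engine import (
    DEAD_INDEX,
    N_STATES,
    STATES,
    STATUS_EVENT,
    STATUS_POST,
    HealthState,
)
from .params import (
    COMPLICATIONS,
    MOH,
    PERSPECTIVES,
    SEXES,
    SOCIETAL,
    CostParams,
    ModelParameters,
    ParameterError,
    RunSpec,
    TreatmentArmParams,
    UtilityParams,
)


@dataclass
class CycleAccrual:
    year: int
    cost: float  # discounted, per reported cohort
    qaly: float  # discounted, per reported cohort


@dataclass
class ArmOutcome:
    arm: str
    perspective: str
    horizon: int
    total_cost: float  # discounted, per reported cohort
    total_qaly: float
    per_cycle: list
    cohort_size: int

    def check(self) -> None:
        assert abs(self.total_cost - sum(c.cost for c in self.per_cycle)) <= 1e-6 * max(
            1.0, abs(self.total_cost)
        )
        assert abs(self.total_qaly - sum(c.qaly for c in self.per_cycle)) <= 1e-9 * max(
            1.0, abs(self.total_qaly)
        )


@dataclass
class IcurResult:
    delta_cost: float
    delta_qaly: float
    icur: float | None  # $/QALY when label == "ratio", else None
    label: str  # dominant | dominated | ratio | equivalent


def discount(amount: float, year_index: int, rate: float, first_year_discounted: bool = False) -> float:
    """Discount an amount accrued in model year ``year_index`` (1-based).

    Year 1 is undiscounted unless ``first_year_discounted``.
    """
    if year_index < 1:
        raise ValueError("year_index is 1-based")
    exponent = year_index if first_year_discounted else year_index - 1
    return amount / (1.0 + rate) ** exponent


def cycle_utility(state: HealthState, stratum, utils: UtilityParams, sex: str) -> float:
    """Annual utility of one alive state; a dead state contributes zero.

    ``stratum`` may be a :class:`Stratum` or a bare weight-gained flag.
    """
    if state.dead:
        return 0.0
    weight_gained = stratum.weight_gained if isinstance(stratum, Stratum) else bool(stratum)
    dus = [utils.du_complication[(c, sex)] for c in COMPLICATIONS if state.has(c)]
    comp = 0.0
    if dus:
        worst = max(dus)
        comp = worst + utils.w_additional * (sum(dus) - worst)
    u = utils.u_bpd - (utils.du_weight_gain if weight_gained else 0.0) - comp
    return max(u, 0.0)


def cycle_cost(
    state: HealthState,
    stratum: Stratum,
    arm: TreatmentArmParams,
    costs: CostParams,
    perspective: str = MOH,
) -> float:
    """Annual cost of occupying one alive state (fatal charges are separate)."""
    if state.dead:
        return 0.0
    if perspective not in PERSPECTIVES:
        raise ParameterError(f"unknown perspective {perspective!r}")
    total = arm.switch_drug_annual_cost if stratum.switched else arm.annual_drug_cost
    if state.has_diabetes:
        total += costs.direct["diabetes"]
    if state.has_hypertension:
        total += costs.direct["hypertension"]
    if state.chd_status == STATUS_EVENT:
        total += costs.direct["chd_y1"]
    elif state.chd_status == STATUS_POST:
        total += costs.direct["chd_y2plus"]
    if state.stroke_status == STATUS_EVENT:
        total += costs.direct["stroke_y1"]
    elif state.stroke_status == STATUS_POST:
        total += costs.direct["stroke_y2plus"]
    if perspective == SOCIETAL:
        for c in COMPLICATIONS:
            if state.has(c):
                total += costs.productivity[c]
        if state.stroke_status != 0:
            total += costs.informal_care_stroke
    return total


def _fatal_cost(costs: CostParams) -> dict:
    return {"chd": costs.direct["chd_fatal"], "stroke": costs.direct["stroke_fatal"]}


def _cost_vectors(arm: TreatmentArmParams, strata, costs: CostParams) -> dict:
    """perspective -> array[state, stratum] of annual occupancy costs."""
    out = {}
    for persp in PERSPECTIVES:
        mat = np.zeros((N_STATES, len(strata)))
        for k, stratum in enumerate(strata):
            for i, st in enumerate(STATES):
                mat[i, k] = cycle_cost(st, stratum, arm, costs, persp)
        out[persp] = mat
    return out


def _utility_vectors(strata, utils: UtilityParams) -> np.ndarray:
    """array[state, stratum, sex] of annual utilities."""
    mat = np.zeros((N_STATES, len(strata), len(SEXES)))
    for k, stratum in enumerate(strata):
        for si, sex in enumerate(SEXES):
            for i, st in enumerate(STATES):
                mat[i, k, si] = cycle_utility(st, stratum, utils, sex)
    return mat


def run_arm(
    params: ModelParameters,
    arm: str = "intervention",
    perspective: str = MOH,
    spec: RunSpec | None = None,
) -> ArmOutcome:
    """Chain the year-1 tree and the Markov years for one arm, one perspective."""
    return _run_arm_all(params, arm, spec)[perspective]


def _run_arm_all(params: ModelParameters, arm: str, spec: RunSpec | None = None) -> dict:
    """Evaluate one arm once, accruing both perspectives from one propagation."""
    spec = spec or params.run
    arm_params = getattr(params, arm)
    utils, costs = params.utilities, params.costs
    horizon = spec.horizon_years
    rate = spec.discount_rate
    scale = spec.cohort_size_report
    fatal = _fatal_cost(costs)

    dist = decision_tree.run_year_one(arm_params, utils, costs)
    weights = {t: 1.0 for t in range(1, horizon + 1)}
    if spec.half_cycle_correction:
        # trapezoid-style: first and last cycle at half weight
        weights[1] = 0.5
        weights[horizon] = 0.5

    def df(year):
        return discount(1.0, year, rate, spec.discount_first_year)

    per_cycle = {p: [] for p in PERSPECTIVES}
    y1_cost = dist.year1_cost * df(1) * weights[1] * scale
    y1_qaly = dist.year1_qaly * df(1) * weights[1] * scale
    for p in PERSPECTIVES:
        per_cycle[p].append(CycleAccrual(1, y1_cost, y1_qaly))

    if horizon > 1:
        cohort = markov_engine.initialize_cohort(dist, params.epidemiology, spec)
        cost_vec = _cost_vectors(arm_params, cohort.strata, costs)
        util_vec = _utility_vectors(cohort.strata, utils)
        for year in range(2, horizon + 1):
            cohort, events = markov_engine.advance(cohort, params)
            d = df(year) * weights[year]
            qaly = float(np.einsum("iks,iks->", cohort.mass, util_vec)) * d * scale
            fatal_charge = (
                events.fatal_chd_mass * fatal["chd"]
                + events.fatal_stroke_mass * fatal["stroke"]
            )
            for p in PERSPECTIVES:
                occupancy = float(
                    np.einsum("iks,ik->", cohort.mass, cost_vec[p])
                )
                per_cycle[p].append(
                    CycleAccrual(year, (occupancy + fatal_charge) * d * scale, qaly)
                )

    out = {}
    for p in PERSPECTIVES:
        cycles = per_cycle[p]
        outcome = ArmOutcome(
            arm=arm_params.name,
            perspective=p,
            horizon=horizon,
            total_cost=sum(c.cost for c in cycles),
            total_qaly=sum(c.qaly for c in cycles),
            per_cycle=cycles,
            cohort_size=scale,
        )
        outcome.check()
        out[p] = outcome
    return out


def run_model(params: ModelParameters, spec: RunSpec | None = None) -> dict:
    """Both arms, both perspectives: {perspective: {"intervention": ArmOutcome,
    "comparator": ArmOutcome, "icur": IcurResult}}."""
    spec = spec or params.run
    a = _run_arm_all(params, "intervention", spec)
    b = _run_arm_all(params, "comparator", spec)
    return {
        p: {"intervention": a[p], "comparator": b[p], "icur": compute_icur(a[p], b[p])}
        for p in PERSPECTIVES
    }


def compute_icur(a: ArmOutcome, b: ArmOutcome) -> IcurResult:
    """Incremental result of ``a`` (intervention) versus ``b`` (comparator)."""
    if a.perspective != b.perspective:
        raise ParameterError("ICUR requires outcomes under the same perspective")
    if a.horizon != b.horizon:
        raise ParameterError("ICUR requires outcomes over the same horizon")
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    if dc == 0.0 and dq == 0.0:
        return IcurResult(dc, dq, None, "equivalent")
    if dc < 0 and dq > 0:
        return IcurResult(dc, dq, None, "dominant")
    if dc > 0 and dq < 0:
        return IcurResult(dc, dq, None, "dominated")
    icur = math.inf if dq == 0 else dc / dq
    return IcurResult(dc, dq, icur, "ratio")
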