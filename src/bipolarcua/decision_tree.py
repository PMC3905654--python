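"""Year-one decision tree: EPS, switch-on-EPS, and significant weight gain.

The first model year is a decision tree over three events: an EPS-related
event (probability ``p_eps_y1``), a treatment switch given EPS
(``p_switch_given_eps``), and significant (>=7%) weight gain
(``p_weight_gain_y1``).  EPS and weight gain are treated as independent;
switching requires a preceding EPS event, so the 2x2x2 outcome cube
collapses to six reachable strata.  The tree emits the year-1 cost and QALY
accruals and the stratified cohort that enters the Markov model.

Timing conventions: switchers pay six months of the original drug and six
months of the switch drug in year 1 (EPS events cluster early in
treatment); the weight-gain disutility applies for ``wg_year1_exposure`` of
year 1 (default the full year) and permanently thereafter; the EPS
disutility applies for ``eps_duration_years`` (default three months) of
year 1 only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CostParams, TreatmentArmParams, UtilityParams

#: (weight_gained, had_eps, switched) for the six reachable strata
STRATUM_FLAGS = (
    (False, False, False),
    (False, True, False),
    (False, True, True),
    (True, False, False),
    (True, True, False),
    (True, True, True),
)

MASS_TOL = 1e-12


@dataclass(frozen=True)
class Stratum:
    weight_gained: bool
    had_eps: bool
    switched: bool
    mass: float

    def __post_init__(self):
        if self.switched and not self.had_eps:
            raise ValueError("a switch requires a preceding EPS event")
        if self.mass < 0:
            raise ValueError("stratum mass must be >= 0")


@dataclass(frozen=True)
class StratumDistribution:
    """Year-1 result: six strata with masses, plus aggregate accruals."""

    arm: str
    strata: tuple
    year1_cost: float  # expected cost per person, undiscounted
    year1_qaly: float  # expected QALY per person, undiscounted
    stratum_costs: tuple  # per-stratum year-1 cost, aligned with ``strata``
    stratum_qalys: tuple


def year1_accrual(
    arm: TreatmentArmParams,
    utils: UtilityParams,
    costs: CostParams,
    weight_gained: bool,
    had_eps: bool,
    switched: bool,
) -> tuple:
    """(cost, qaly) accrued in year 1 by one stratum."""
    if switched:
        drug = 0.5 * arm.annual_drug_cost + 0.5 * arm.switch_drug_annual_cost
    else:
        drug = arm.annual_drug_cost
    cost = drug + (costs.eps_management if had_eps else 0.0)
    qaly = utils.u_bpd
    if weight_gained:
        qaly -= utils.du_weight_gain * utils.wg_year1_exposure
    if had_eps:
        qaly -= utils.du_eps * utils.eps_duration_years
    return cost, max(qaly, 0.0)


def run_year_one(
    arm: TreatmentArmParams, utils: UtilityParams, costs: CostParams
) -> StratumDistribution:
    """Evaluate the one-year tree for one treatment arm."""
    p_wg = arm.p_weight_gain_y1
    p_eps = arm.p_eps_y1
    p_sw = arm.p_switch_given_eps

    strata = []
    stratum_costs = []
    stratum_qalys = []
    for wg, eps, sw in STRATUM_FLAGS:
        mass = (p_wg if wg else 1.0 - p_wg)
        if not eps:
            mass *= 1.0 - p_eps
        elif sw:
            mass *= p_eps * p_sw
        else:
            mass *= p_eps * (1.0 - p_sw)
        strata.append(Stratum(wg, eps, sw, mass))
        c, q = year1_accrual(arm, utils, costs, wg, eps, sw)
        stratum_costs.append(c)
        stratum_qalys.append(q)

    total = sum(s.mass for s in strata)
    if abs(total - 1.0) > MASS_TOL:
        raise AssertionError(f"stratum masses sum to {total!r}, not 1")

    year1_cost = sum(s.mass * c for s, c in zip(strata, stratum_costs))
    year1_qaly = sum(s.mass * q for s, q in zip(strata, stratum_qalys))
    return StratumDistribution(
        arm=arm.name,
        strata=tuple(strata),
        year1_cost=year1_cost,
        year1_qaly=year1_qaly,
        stratum_costs=tuple(stratum_costs),
        stratum_qalys=tuple(stratum_qalys),
    )
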