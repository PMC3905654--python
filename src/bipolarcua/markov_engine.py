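"""Markov cohort engine for long-term metabolic complications.

Health states are combinations of diabetes (absent/present), hypertension
(absent/present), CHD (none / event year / post-event) and stroke (none /
event year / post-event), plus an absorbing death state: 2*2*3*3 = 36 alive
states + 1 = 37.  Diabetes and hypertension are chronic; CHD and stroke are
punctual events whose event year carries higher costs, after which patients
remain in a cheaper "post" tier until death.

Annual transitions apply, in this order within a cycle:

1. background death, with the life table adjusted for the elevated
   bipolar-disorder suicide rate and multiplied by the mortality risk of
   every complication present;
2. among survivors, at most one new complication per year, resolved as
   sequential competing events in a fixed configurable order — candidate
   ``c`` occurs with its (weight-gain-adjusted) incidence thinned by the
   no-prior-event product of the candidates ranked before it;
3. an incident CHD or stroke event is split into a fatal part (to death,
   carrying a one-time fatal-event cost) and a non-fatal part (to the event
   year state); existing event-year states advance to the post tier.

Weight-gain odds ratios act on the odds scale by default (they are reported
as odds ratios); a config switch treats them as relative risks instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .decision_tree import Stratum, StratumDistribution
from .params import (
    COMPLICATIONS,
    SEXES,
    ComplicationRiskParams,
    EpidemiologyParams,
    ModelParameters,
    MortalityParams,
    ParameterError,
    RunSpec,
)

STATUS_NONE, STATUS_EVENT, STATUS_POST = 0, 1, 2

ROW_TOL = 1e-12
MASS_TOL = 1e-10


@dataclass(frozen=True)
class HealthState:
    has_diabetes: bool = False
    has_hypertension: bool = False
    chd_status: int = STATUS_NONE
    stroke_status: int = STATUS_NONE
    dead: bool = False

    def has(self, complication: str) -> bool:
        if self.dead:
            return False
        return {
            "diabetes": self.has_diabetes,
            "hypertension": self.has_hypertension,
            "chd": self.chd_status != STATUS_NONE,
            "stroke": self.stroke_status != STATUS_NONE,
        }[complication]


DEAD = HealthState(dead=True)


def enumerate_states() -> list:
    """All 36 alive states in canonical order, then the absorbing death state."""
    alive = [
        HealthState(dm, ht, chd, st)
        for dm, ht, chd, st in itertools.product(
            (False, True), (False, True), (0, 1, 2), (0, 1, 2)
        )
    ]
    return alive + [DEAD]


STATES = enumerate_states()
N_STATES = len(STATES)
DEAD_INDEX = N_STATES - 1
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

# static structure arrays over the 36 alive states
_ALIVE = STATES[:-1]
_DM = np.array([s.has_diabetes for s in _ALIVE])
_HT = np.array([s.has_hypertension for s in _ALIVE])
_CHD = np.array([s.chd_status for s in _ALIVE])
_ST = np.array([s.stroke_status for s in _ALIVE])
_PRESENT = {
    "diabetes": _DM.copy(),
    "hypertension": _HT.copy(),
    "chd": _CHD > 0,
    "stroke": _ST > 0,
}


# event-year tiers last exactly one cycle, then move to "post"
_STAY_IDX = np.array(
    [
        STATE_INDEX[
            HealthState(
                bool(dm), bool(ht),
                STATUS_POST if chd else STATUS_NONE,
                STATUS_POST if st else STATUS_NONE,
            )
        ]
        for dm, ht, chd, st in zip(_DM, _HT, _CHD, _ST)
    ]
)
_DEST_IDX = {}
for _c in COMPLICATIONS:
    idx = []
    for dm, ht, chd, st in zip(_DM, _HT, _CHD, _ST):
        dm2, ht2 = bool(dm), bool(ht)
        chd2 = STATUS_POST if chd else STATUS_NONE
        st2 = STATUS_POST if st else STATUS_NONE
        if _c == "diabetes":
            dm2 = True
        elif _c == "hypertension":
            ht2 = True
        elif _c == "chd":
            chd2 = STATUS_EVENT
        else:
            st2 = STATUS_EVENT
        idx.append(STATE_INDEX[HealthState(dm2, ht2, chd2, st2)])
    _DEST_IDX[_c] = np.array(idx)
_ABSENT = {c: ~_PRESENT[c] for c in COMPLICATIONS}


# ---------------------------------------------------------------------------
# Elementary probability operations
# ---------------------------------------------------------------------------


def adjusted_probability(p_base: float, or_value: float, as_rr: bool = False):
    """Apply an odds ratio (default) or relative risk to a base probability.

    On the odds scale: p' = OR*p/(1-p) / (1 + OR*p/(1-p)).  Accepts scalars
    or numpy arrays; ``p_base`` must lie in [0, 1).
    """
    p = np.asarray(p_base, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ParameterError(f"base probability {p_base!r} must lie in [0, 1)")
    if or_value <= 0:
        raise ParameterError(f"ratio {or_value!r} must be > 0")
    if as_rr:
        out = np.minimum(p * or_value, 1.0)
    else:
        odds = or_value * p / (1.0 - p)
        out = odds / (1.0 + odds)
    return out if out.ndim else float(out)


def _suicide_adjusted_base(mort: MortalityParams, sex: str, age: int) -> float:
    try:
        q = mort.life_table[sex][age]
    except KeyError:
        raise ParameterError(f"life table has no entry for {sex} age {age}")
    sui = mort.suicide.get(sex, {}).get(age, 0.0)
    return q - sui + mort.bpd_suicide_multiplier * sui


def adjusted_mortality(
    mort: MortalityParams,
    state: HealthState,
    sex: str,
    age: int,
    risks: ComplicationRiskParams,
    combination: str = "multiplicative",
) -> float:
    """Annual death probability for one state: suicide-substituted life-table
    mortality times the mortality risk of every complication present."""
    base = _suicide_adjusted_base(mort, sex, age)
    rrs = [risks.mortality_risk[(c, sex)] for c in COMPLICATIONS if state.has(c)]
    if rrs:
        if combination == "max":
            base *= max(rrs)
        else:
            for rr in rrs:
                base *= rr
    return float(np.clip(base, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------


@dataclass
class TransitionRow:
    """One source state's destination masses plus fatal-event components."""

    masses: np.ndarray  # length N_STATES, sums to 1
    fatal_chd: float  # mass dying of an incident CHD event (subset of dead)
    fatal_stroke: float


def _candidate_probability(
    params: ModelParameters, c: str, sex: str, age: int, weight_gained: bool
) -> float:
    try:
        p = params.epidemiology.incidence[(c, sex)][age]
    except KeyError:
        raise ParameterError(f"incidence table has no entry for {c}/{sex} age {age}")
    if weight_gained:
        return float(
            adjusted_probability(
                p, params.risks.odds_ratio_weight_gain[(c, sex)], as_rr=params.run.or_as_rr
            )
        )
    return float(p)


def build_transitions(
    state: HealthState,
    stratum: Stratum,
    sex: str,
    age: int,
    params: ModelParameters,
) -> TransitionRow:
    """Scalar reference construction of one transition row.

    The vectorised engine (:func:`transition_matrix`) must agree with this
    row for row; the agreement is pinned by a test.
    """
    if state.dead:
        masses = np.zeros(N_STATES)
        masses[DEAD_INDEX] = 1.0
        return TransitionRow(masses, 0.0, 0.0)

    q = adjusted_mortality(
        params.mortality, state, sex, age, params.risks, params.run.mortality_combination
    )
    survive = 1.0 - q

    remainder = 1.0
    takes = {}
    for c in params.run.complication_order:
        if state.has(c):
            continue
        p = _candidate_probability(params, c, sex, age, stratum.weight_gained)
        takes[c] = p * remainder
        remainder *= 1.0 - p

    i = STATE_INDEX[state]
    masses = np.zeros(N_STATES)
    masses[_STAY_IDX[i]] += survive * remainder
    fatal_chd = fatal_stroke = 0.0
    for c, take in takes.items():
        flow = survive * take
        if c == "chd":
            fatal_chd = flow * params.epidemiology.p_fatal_chd
            masses[DEAD_INDEX] += fatal_chd
            masses[_DEST_IDX[c][i]] += flow - fatal_chd
        elif c == "stroke":
            fatal_stroke = flow * params.epidemiology.p_fatal_stroke
            masses[DEAD_INDEX] += fatal_stroke
            masses[_DEST_IDX[c][i]] += flow - fatal_stroke
        else:
            masses[_DEST_IDX[c][i]] += flow
    masses[DEAD_INDEX] += q

    assert abs(masses.sum() - 1.0) < ROW_TOL
    return TransitionRow(masses, fatal_chd, fatal_stroke)


def transition_matrix(
    params: ModelParameters, weight_gained: bool, sex: str, age: int
) -> tuple:
    """(T, fatal_chd, fatal_stroke): the 37x37 annual transition matrix for
    one (weight-gain stratum, sex, age), with per-source fatal-event masses.
    """
    mort, risks, run = params.mortality, params.risks, params.run
    base = _suicide_adjusted_base(mort, sex, age)
    rr = np.ones(36)
    for c in COMPLICATIONS:
        rr_c = risks.mortality_risk[(c, sex)]
        if run.mortality_combination == "max":
            rr = np.where(_PRESENT[c], np.maximum(rr, rr_c), rr)
        else:
            rr = np.where(_PRESENT[c], rr * rr_c, rr)
    # with no complication present the risk factor is 1 in either combination
    none_present = ~(_PRESENT["diabetes"] | _PRESENT["hypertension"] | _PRESENT["chd"] | _PRESENT["stroke"])
    rr = np.where(none_present, 1.0, rr)
    q = np.clip(base * rr, 0.0, 1.0)
    survive = 1.0 - q

    p_c = {
        c: _candidate_probability(params, c, sex, age, weight_gained)
        for c in COMPLICATIONS
    }
    remainder = np.ones(36)
    takes = {}
    for c in run.complication_order:
        takes[c] = np.where(_ABSENT[c], p_c[c] * remainder, 0.0)
        remainder = np.where(_ABSENT[c], remainder * (1.0 - p_c[c]), remainder)

    rows = np.arange(36)
    T = np.zeros((N_STATES, N_STATES))
    T[rows, _STAY_IDX] += survive * remainder
    dead_col = q.copy()
    fatal_chd = survive * takes["chd"] * params.epidemiology.p_fatal_chd
    fatal_stroke = survive * takes["stroke"] * params.epidemiology.p_fatal_stroke
    for c in COMPLICATIONS:
        flow = survive * takes[c]
        if c == "chd":
            flow = flow - fatal_chd
        elif c == "stroke":
            flow = flow - fatal_stroke
        T[rows, _DEST_IDX[c]] += flow
    dead_col += fatal_chd + fatal_stroke
    T[rows, DEAD_INDEX] += dead_col
    T[DEAD_INDEX, DEAD_INDEX] = 1.0

    f_chd = np.zeros(N_STATES)
    f_chd[:36] = fatal_chd
    f_stroke = np.zeros(N_STATES)
    f_stroke[:36] = fatal_stroke
    return T, f_chd, f_stroke


# ---------------------------------------------------------------------------
# Cohort representation and propagation
# ---------------------------------------------------------------------------


@dataclass
class CohortVector:
    """Probability mass over (state, stratum, sex).

    ``mass`` has shape (37, n_strata, 2) with the sex axis ordered as
    :data:`bipolarcua.params.SEXES`; ``age`` is the age attained during the
    coming cycle; ``cycle_index`` counts completed model years.
    """

    mass: np.ndarray
    strata: tuple
    age: int
    cycle_index: int

    def total_mass(self) -> float:
        return float(self.mass.sum())

    def alive_mass(self) -> float:
        return float(self.mass[:DEAD_INDEX].sum())


@dataclass
class CycleEvents:
    """Per-cycle transition by-products needed for costing."""

    fatal_chd_mass: float
    fatal_stroke_mass: float


def initialize_cohort(
    strata: StratumDistribution, epi: EpidemiologyParams, spec: RunSpec
) -> CohortVector:
    """Distribute each stratum over complication states by baseline prevalence.

    Complications are independent at entry; prevalent CHD/stroke enter the
    post-event tier (their event year was not observed in-model).
    """
    n_k = len(strata.strata)
    mass = np.zeros((N_STATES, n_k, 2))
    sex_w = {"male": spec.sex_mix, "female": 1.0 - spec.sex_mix}
    for si, sex in enumerate(SEXES):
        state_p = np.zeros(N_STATES)
        for i, st in enumerate(_ALIVE):
            if st.chd_status == STATUS_EVENT or st.stroke_status == STATUS_EVENT:
                continue
            p = 1.0
            for c in COMPLICATIONS:
                prev = epi.prevalence[(c, sex)]
                p *= prev if st.has(c) else 1.0 - prev
            state_p[i] = p
        for k, stratum in enumerate(strata.strata):
            mass[:, k, si] = state_p * stratum.mass * sex_w[sex]
    cohort = CohortVector(
        mass=mass, strata=tuple(strata.strata), age=spec.entry_age + 1, cycle_index=1
    )
    assert abs(cohort.total_mass() - 1.0) < MASS_TOL
    return cohort


def advance(cohort: CohortVector, params: ModelParameters) -> tuple:
    """One annual cycle: returns (new cohort, fatal-event masses)."""
    new_mass = np.empty_like(cohort.mass)
    fatal_chd = fatal_stroke = 0.0
    cache = {}
    for k, stratum in enumerate(cohort.strata):
        wg = stratum.weight_gained
        for si, sex in enumerate(SEXES):
            key = (wg, sex)
            if key not in cache:
                cache[key] = transition_matrix(params, wg, sex, cohort.age)
            T, f_chd, f_stroke = cache[key]
            vec = cohort.mass[:, k, si]
            new_mass[:, k, si] = vec @ T
            fatal_chd += float(vec @ f_chd)
            fatal_stroke += float(vec @ f_stroke)
    new = CohortVector(
        mass=new_mass, strata=cohort.strata, age=cohort.age + 1,
        cycle_index=cohort.cycle_index + 1,
    )
    if abs(new.total_mass() - cohort.total_mass()) > MASS_TOL:
        raise AssertionError("cohort mass not conserved across a cycle")
    return new, CycleEvents(fatal_chd, fatal_stroke)
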