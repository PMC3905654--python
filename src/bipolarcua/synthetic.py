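"""Synthetic external inputs: life tables, suicide mortality, epidemiology.

The model needs three inputs that normally come from national statistics —
an age-by-sex life table, suicide mortality, and baseline prevalence /
annual incidence of the four metabolic complications.  This module generates
stand-ins with the statistical structure the model assumes (monotone-in-age
mortality, small prevalences at midlife, small mildly age-increasing
incidences) so the full pipeline runs with no external download.  Magnitudes
are calibrated to general-population Canadian orders of magnitude, not to
any specific published table.
"""

from __future__ import annotations

import copy
import math
from dataclasses import replace
from typing import Iterable, Mapping

import numpy as np

from .params import (
    COMPLICATIONS,
    SEXES,
    EpidemiologyParams,
    ModelParameters,
    MortalityParams,
    ParameterError,
    load_base_case,
)

#: reference prevalence at cohort entry (age ~40) and annual incidence at 40,
#: per sex; chosen once as mid-life general-population magnitudes
_PREVALENCE_40 = {
    ("diabetes", "male"): 0.060,
    ("diabetes", "female"): 0.050,
    ("hypertension", "male"): 0.140,
    ("hypertension", "female"): 0.120,
    ("chd", "male"): 0.040,
    ("chd", "female"): 0.020,
    ("stroke", "male"): 0.015,
    ("stroke", "female"): 0.010,
}
_INCIDENCE_40 = {
    ("diabetes", "male"): 0.0070,
    ("diabetes", "female"): 0.0060,
    ("hypertension", "male"): 0.0200,
    ("hypertension", "female"): 0.0180,
    ("chd", "male"): 0.0050,
    ("chd", "female"): 0.0030,
    ("stroke", "male"): 0.0015,
    ("stroke", "female"): 0.0012,
}
_AGE_GROWTH = 0.03  # annual relative growth of incidence with age

_SCALES = {"low": 0.2, "realistic": 1.0, "high": 2.5}
_INCIDENCE_CAP = {"low": 0.005, "realistic": 0.03, "high": 0.03}
_INCIDENCE_FLOOR = 0.001


def gompertz_table(spec: Mapping, ages: Iterable[int]) -> dict:
    """Annual mortality q(a) = 1 - exp(-b * exp(c * a)) per sex.

    ``spec`` maps sex -> {"b": float, "c": float}.
    """
    out: dict = {}
    for s in SEXES:
        if s not in spec:
            raise ParameterError(f"gompertz life table: missing sex {s!r}")
        b = float(spec[s]["b"])
        c = float(spec[s]["c"])
        if b < 0 or c < 0:
            raise ParameterError(f"gompertz parameters must be non-negative for {s}")
        table = {}
        for a in ages:
            q = 1.0 - math.exp(-b * math.exp(c * a))
            if not (0.0 <= q <= 1.0):
                raise ParameterError(f"gompertz q({a})={q:.4g} out of [0, 1] for {s}")
            table[int(a)] = q
        out[s] = table
    return out


def generate_life_table(
    gompertz: Mapping | None = None,
    ages: Iterable[int] = range(18, 81),
    suicide: Mapping | None = None,
    bpd_suicide_multiplier: float = 15.5,
) -> MortalityParams:
    """Synthetic general-population mortality with a flat suicide component.

    Defaults give 5-year all-cause mortality at age 40 below 2%, with male
    mortality above female, consistent with a mid-life general-population
    table.
    """
    ages = list(ages)
    if gompertz is None:
        gompertz = {"male": {"b": 5e-5, "c": 0.09}, "female": {"b": 3e-5, "c": 0.09}}
    if suicide is None:
        suicide = {"male": 1.7e-4, "female": 5e-5}
    life = gompertz_table(gompertz, ages)
    sui = {s: {a: float(suicide[s]) for a in ages} for s in SEXES}
    for s in SEXES:
        for a in ages:
            if sui[s][a] > life[s][a]:
                raise ParameterError(
                    f"suicide mortality exceeds all-cause mortality for {s} age {a}"
                )
    return MortalityParams(life_table=life, suicide=sui, bpd_suicide_multiplier=bpd_suicide_multiplier)


def generate_epidemiology(
    seed: int = 0,
    scale: str = "realistic",
    age_min: int = 18,
    age_max: int = 80,
    p_fatal_chd: float = 0.10,
    p_fatal_stroke: float = 0.15,
) -> EpidemiologyParams:
    """Baseline prevalence at entry and annual incidence by age and sex.

    Pure function of (seed, scale): a seeded +/-10% lognormal jitter is
    applied per (complication, sex) around the reference magnitudes, then
    prevalences are clipped to [0.01, 0.15] and incidences to the scale's
    range ([0.001, 0.005] for "low", [0.001, 0.03] otherwise), growing
    ~3%/year with age.
    """
    if scale not in _SCALES:
        raise ParameterError(f"unknown epidemiology scale {scale!r}")
    rng = np.random.default_rng(seed)
    mult = _SCALES[scale]
    cap = _INCIDENCE_CAP[scale]

    prevalence = {}
    incidence = {}
    for c in COMPLICATIONS:
        for s in SEXES:
            jitter_prev = float(np.exp(rng.normal(0.0, 0.05)))
            jitter_inc = float(np.exp(rng.normal(0.0, 0.05)))
            prev = float(np.clip(_PREVALENCE_40[(c, s)] * mult * jitter_prev, 0.01, 0.15))
            prevalence[(c, s)] = prev
            base_inc = _INCIDENCE_40[(c, s)] * mult * jitter_inc
            incidence[(c, s)] = {
                a: float(np.clip(base_inc * (1.0 + _AGE_GROWTH) ** (a - 40), _INCIDENCE_FLOOR, cap))
                for a in range(age_min, age_max + 1)
            }
    return EpidemiologyParams(
        prevalence=prevalence,
        incidence=incidence,
        p_fatal_chd=p_fatal_chd,
        p_fatal_stroke=p_fatal_stroke,
    )


def _zero_epidemiology(age_min: int = 18, age_max: int = 80) -> EpidemiologyParams:
    return EpidemiologyParams(
        prevalence={(c, s): 0.0 for c in COMPLICATIONS for s in SEXES},
        incidence={
            (c, s): {a: 0.0 for a in range(age_min, age_max + 1)}
            for c in COMPLICATIONS
            for s in SEXES
        },
        p_fatal_chd=0.0,
        p_fatal_stroke=0.0,
    )


def _zero_mortality(age_min: int = 18, age_max: int = 80) -> MortalityParams:
    zero = {s: {a: 0.0 for a in range(age_min, age_max + 1)} for s in SEXES}
    return MortalityParams(life_table=zero, suicide=copy.deepcopy(zero), bpd_suicide_multiplier=1.0)


def make_fixture_suite() -> dict:
    """Named parameter sets used throughout the tests and validation runs.

    * ``tables12_base`` — the published clinical/cost tables with synthetic
      epidemiology and life tables (the packaged base case).
    * ``zero_risk`` — no adverse events, no complications, no mortality;
      outcomes reduce to closed-form discounted annuities.
    * ``symmetric`` — comparator identical to the intervention; all
      incremental results are exactly zero.
    * ``high_incidence`` / ``low_incidence`` — epidemiology stress cases.
    """
    base = load_base_case()

    zero = copy.deepcopy(base)
    for arm in (zero.intervention, zero.comparator):
        arm.p_weight_gain_y1 = 0.0
        arm.p_eps_y1 = 0.0
    zero.epidemiology = _zero_epidemiology()
    zero.mortality = _zero_mortality()
    zero.printed_bounds = {}

    symmetric = copy.deepcopy(base)
    symmetric.comparator = replace(symmetric.intervention, name="mirror")

    high = copy.deepcopy(base)
    high.epidemiology = generate_epidemiology(
        seed=11, scale="high", p_fatal_chd=base.epidemiology.p_fatal_chd,
        p_fatal_stroke=base.epidemiology.p_fatal_stroke,
    )

    low = copy.deepcopy(base)
    low.epidemiology = generate_epidemiology(
        seed=12, scale="low", p_fatal_chd=base.epidemiology.p_fatal_chd,
        p_fatal_stroke=base.epidemiology.p_fatal_stroke,
    )

    return {
        "tables12_base": base,
        "zero_risk": zero,
        "symmetric": symmetric,
        "high_incidence": high,
        "low_incidence": low,
    }
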