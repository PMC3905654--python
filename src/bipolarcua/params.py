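"""Parameter store for the antipsychotic cost-utility model.

Holds every model input with its base-case value and sensitivity bounds,
loads and validates structured-text (YAML) configuration, and exposes a flat
parameter registry used by the deterministic and probabilistic sensitivity
analyses.

Conventions
-----------
* All monetary amounts are Canadian dollars at 2011 price levels, per year
  unless the name says otherwise (fatal-event costs are one-time charges).
* All probabilities are annual.
* Disutilities are stored as non-negative magnitudes to be subtracted from
  the baseline utility (a sensitivity bound may dip slightly below zero where
  the published interval crosses zero).
* ``sex_mix`` is the male fraction of the cohort.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping

import yaml

COMPLICATIONS = ("diabetes", "hypertension", "chd", "stroke")
SEXES = ("male", "female")
DIRECT_COST_KEYS = (
    "diabetes",
    "hypertension",
    "chd_y1",
    "chd_y2plus",
    "chd_fatal",
    "stroke_y1",
    "stroke_y2plus",
    "stroke_fatal",
)
MOH = "moh"
SOCIETAL = "societal"
PERSPECTIVES = (MOH, SOCIETAL)


class ParameterError(ValueError):
    """A model input is missing, malformed, or out of range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TreatmentArmParams:
    """One antipsychotic strategy: drug cost and first-year adverse events."""

    name: str
    annual_drug_cost: float
    p_weight_gain_y1: float
    p_eps_y1: float
    switch_drug_annual_cost: float
    p_switch_given_eps: float


@dataclass
class ComplicationRiskParams:
    """Weight-gain odds ratios and complication mortality hazard ratios.

    Keys are ``(complication, sex)`` tuples.
    """

    odds_ratio_weight_gain: dict
    mortality_risk: dict


@dataclass
class UtilityParams:
    u_bpd: float
    du_weight_gain: float
    du_eps: float
    eps_duration_years: float
    du_complication: dict  # (complication, sex) -> magnitude
    w_additional: float
    wg_year1_exposure: float  # fraction of year 1 the weight-gain disutility applies


@dataclass
class CostParams:
    eps_management: float
    direct: dict  # DIRECT_COST_KEYS -> $/year ($/event for *_fatal)
    productivity: dict  # complication -> $/year (societal perspective only)
    informal_care_stroke: float  # $/year (societal perspective only)


@dataclass
class EpidemiologyParams:
    prevalence: dict  # (complication, sex) -> probability at cohort entry
    incidence: dict  # (complication, sex) -> {age: annual probability}
    p_fatal_chd: float  # P(death | incident CHD event)
    p_fatal_stroke: float  # P(death | incident stroke event)


@dataclass
class MortalityParams:
    life_table: dict  # sex -> {age: annual all-cause mortality probability}
    suicide: dict  # sex -> {age: annual general-population suicide mortality}
    bpd_suicide_multiplier: float


@dataclass
class RunSpec:
    horizon_years: int = 5
    discount_rate: float = 0.05
    entry_age: int = 40
    sex_mix: float = 0.5  # fraction male
    cohort_size_report: int = 1000
    seed: int = 0
    complication_order: tuple = COMPLICATIONS
    or_as_rr: bool = False  # treat weight-gain ORs as relative risks instead
    mortality_combination: str = "multiplicative"  # or "max"
    discount_first_year: bool = False
    half_cycle_correction: bool = False


@dataclass
class ModelParameters:
    """Complete parameterisation of the model (clinical, cost, epidemiology)."""

    intervention: TreatmentArmParams
    comparator: TreatmentArmParams
    risks: ComplicationRiskParams
    utilities: UtilityParams
    costs: CostParams
    epidemiology: EpidemiologyParams
    mortality: MortalityParams
    run: RunSpec
    # registry id -> (lower, upper); either side may be None (published "N/A")
    printed_bounds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name}={value!r} must lie in [0, 1]")


def _check_nonneg(value: float, name: str) -> None:
    if value < 0:
        raise ParameterError(f"{name}={value!r} must be >= 0")


def _check_pos(value: float, name: str) -> None:
    if value <= 0:
        raise ParameterError(f"{name}={value!r} must be > 0")


def validate(params: ModelParameters) -> None:
    """Raise :class:`ParameterError` on the first violated invariant."""
    for attr in ("intervention", "comparator"):
        arm = getattr(params, attr)
        _check_prob(arm.p_weight_gain_y1, f"{attr}.p_weight_gain_y1")
        _check_prob(arm.p_eps_y1, f"{attr}.p_eps_y1")
        _check_prob(arm.p_switch_given_eps, f"{attr}.p_switch_given_eps")
        _check_nonneg(arm.annual_drug_cost, f"{attr}.annual_drug_cost")
        _check_nonneg(arm.switch_drug_annual_cost, f"{attr}.switch_drug_annual_cost")

    for (c, s) in _cs_pairs():
        _check_pos(params.risks.odds_ratio_weight_gain[(c, s)], f"risk.or.{c}.{s}")
        _check_pos(params.risks.mortality_risk[(c, s)], f"risk.mortality.{c}.{s}")

    u = params.utilities
    if not (0.0 <= u.u_bpd <= 1.0):
        raise ParameterError(f"utility.u_bpd={u.u_bpd!r} must lie in [0, 1]")
    _check_nonneg(u.du_weight_gain, "utility.du_weight_gain")
    _check_nonneg(u.du_eps, "utility.du_eps")
    if not (0.0 <= u.eps_duration_years <= 1.0):
        raise ParameterError("utility.eps_duration_years must lie in [0, 1]")
    if not (0.0 <= u.wg_year1_exposure <= 1.0):
        raise ParameterError("utility.wg_year1_exposure must lie in [0, 1]")
    if not (0.0 <= u.w_additional <= 1.0):
        raise ParameterError("utility.w_additional must lie in [0, 1]")

    c = params.costs
    _check_nonneg(c.eps_management, "cost.eps_management")
    for k in DIRECT_COST_KEYS:
        if k not in c.direct:
            raise ParameterError(f"cost.direct.{k} is missing")
        _check_nonneg(c.direct[k], f"cost.direct.{k}")
    for comp in COMPLICATIONS:
        if comp not in c.productivity:
            raise ParameterError(f"cost.productivity.{comp} is missing")
        _check_nonneg(c.productivity[comp], f"cost.productivity.{comp}")
    _check_nonneg(c.informal_care_stroke, "cost.informal_care_stroke")

    e = params.epidemiology
    _check_prob(e.p_fatal_chd, "epidemiology.p_fatal_chd")
    _check_prob(e.p_fatal_stroke, "epidemiology.p_fatal_stroke")
    for (comp, s) in _cs_pairs():
        _check_prob(e.prevalence[(comp, s)], f"epidemiology.prevalence.{comp}.{s}")
        table = e.incidence.get((comp, s))
        if not table:
            raise ParameterError(f"epidemiology.incidence.{comp}.{s} is missing")
        for age, p in table.items():
            _check_prob(p, f"epidemiology.incidence.{comp}.{s}[{age}]")

    m = params.mortality
    _check_pos(m.bpd_suicide_multiplier, "mortality.bpd_suicide_multiplier")
    for s in SEXES:
        for age, q in m.life_table.get(s, {}).items():
            _check_prob(q, f"mortality.life_table.{s}[{age}]")
        for age, q in m.suicide.get(s, {}).items():
            _check_prob(q, f"mortality.suicide.{s}[{age}]")
        if not m.life_table.get(s):
            raise ParameterError(f"mortality.life_table.{s} is missing")

    r = params.run
    if r.horizon_years < 1:
        raise ParameterError("run.horizon_years must be >= 1")
    _check_nonneg(r.discount_rate, "run.discount_rate")
    _check_prob(r.sex_mix, "run.sex_mix")
    if tuple(sorted(r.complication_order)) != tuple(sorted(COMPLICATIONS)):
        raise ParameterError("run.complication_order must permute the four complications")
    if r.mortality_combination not in ("multiplicative", "max"):
        raise ParameterError("run.mortality_combination must be 'multiplicative' or 'max'")

    # adjusted all-cause mortality must stay a probability with the suicide
    # substitution applied
    for s in SEXES:
        for age, q in m.life_table[s].items():
            sui = m.suicide.get(s, {}).get(age, 0.0)
            adj = q - sui + m.bpd_suicide_multiplier * sui
            if not (0.0 <= adj <= 1.0):
                raise ParameterError(
                    f"suicide-adjusted mortality {adj:.4g} out of [0, 1] for {s} age {age}"
                )


def _cs_pairs():
    return [(c, s) for c in COMPLICATIONS for s in SEXES]


# ---------------------------------------------------------------------------
# Config loading / saving
# ---------------------------------------------------------------------------


def _node(cfg: Mapping, *path: str) -> Any:
    cur: Any = cfg
    for key in path:
        if not isinstance(cur, Mapping) or key not in cur:
            raise ParameterError(f"missing config field: {'.'.join(path)}")
        cur = cur[key]
    return cur


def _scalar(node: Any, pid: str, bounds: dict) -> float:
    """Read a value node: either a plain number or {base, lower, upper}."""
    if isinstance(node, Mapping):
        if "base" not in node:
            raise ParameterError(f"{pid}: mapping value requires a 'base' entry")
        lo = node.get("lower")
        hi = node.get("upper")
        if lo is not None or hi is not None:
            bounds[pid] = (None if lo is None else float(lo), None if hi is None else float(hi))
        return float(node["base"])
    if node is None:
        raise ParameterError(f"{pid}: missing value")
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        raise ParameterError(f"{pid}: expected a number, got {node!r}")
    return float(node)


def _sex_table(node: Mapping, pid: str, bounds: dict) -> dict:
    out = {}
    for s in SEXES:
        if s not in node:
            raise ParameterError(f"{pid}.{s}: missing value")
        out[s] = _scalar(node[s], f"{pid}.{s}", bounds)
    return out


def _age_table_from_rows(rows: Iterable[Mapping], pid: str) -> dict:
    """Rows of {sex, age, value} -> {sex: {age: value}}."""
    out: dict = {s: {} for s in SEXES}
    for row in rows:
        try:
            sex, age, value = row["sex"], int(row["age"]), float(row["value"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParameterError(f"{pid}: bad row {row!r}") from exc
        if sex not in SEXES:
            raise ParameterError(f"{pid}: unknown sex {sex!r}")
        out[sex][age] = value
    return out


def _age_table_from_csv(path: Path, pid: str) -> dict:
    import pandas as pd

    frame = pd.read_csv(path, comment="#")
    missing = {"sex", "age", "value"} - set(frame.columns)
    if missing:
        raise ParameterError(f"{pid}: CSV {path} lacks columns {sorted(missing)}")
    return _age_table_from_rows(frame.to_dict("records"), pid)


def _load_mortality(cfg: Mapping, base_dir: Path, bounds: dict) -> MortalityParams:
    node = _node(cfg, "mortality")
    mult = _scalar(_node(node, "bpd_suicide_multiplier"), "mortality.bpd_suicide_multiplier", bounds)

    def load_component(name: str) -> dict:
        comp = _node(node, name)
        if "gompertz" in comp or "flat" in comp:
            from . import synthetic

            ages = range(int(comp.get("age_min", 18)), int(comp.get("age_max", 80)) + 1)
            if "gompertz" in comp:
                return synthetic.gompertz_table(comp["gompertz"], ages)
            return {s: {a: float(comp["flat"][s]) for a in ages} for s in SEXES}
        if "csv" in comp:
            return _age_table_from_csv(base_dir / comp["csv"], f"mortality.{name}")
        if "table" in comp:
            return _age_table_from_rows(comp["table"], f"mortality.{name}")
        raise ParameterError(f"mortality.{name}: provide 'gompertz'/'flat', 'table' or 'csv'")

    return MortalityParams(
        life_table=load_component("life_table"),
        suicide=load_component("suicide"),
        bpd_suicide_multiplier=mult,
    )


def _load_epidemiology(cfg: Mapping, base_dir: Path) -> EpidemiologyParams:
    node = _node(cfg, "epidemiology")
    p_fatal_chd = float(_node(node, "p_fatal_chd"))
    p_fatal_stroke = float(_node(node, "p_fatal_stroke"))

    if "synthetic" in node:
        from . import synthetic

        spec = node["synthetic"]
        epi = synthetic.generate_epidemiology(
            seed=int(spec.get("seed", 0)),
            scale=spec.get("scale", "realistic"),
            age_min=int(spec.get("age_min", 18)),
            age_max=int(spec.get("age_max", 80)),
        )
        return replace(epi, p_fatal_chd=p_fatal_chd, p_fatal_stroke=p_fatal_stroke)

    prevalence: dict = {}
    prev_node = _node(node, "prevalence")
    if isinstance(prev_node, Mapping) and "csv" in prev_node:
        import pandas as pd

        rows = pd.read_csv(base_dir / prev_node["csv"], comment="#").to_dict("records")
    else:
        rows = prev_node
    for row in rows:
        prevalence[(row["complication"], row["sex"])] = float(row["value"])

    inc_node = _node(node, "incidence")
    if isinstance(inc_node, Mapping) and "csv" in inc_node:
        import pandas as pd

        inc_rows = pd.read_csv(base_dir / inc_node["csv"], comment="#").to_dict("records")
    else:
        inc_rows = inc_node
    incidence: dict = {(c, s): {} for c in COMPLICATIONS for s in SEXES}
    for row in inc_rows:
        key = (row["complication"], row["sex"])
        if key not in incidence:
            raise ParameterError(f"epidemiology.incidence: unknown key {key!r}")
        incidence[key][int(row["age"])] = float(row["value"])

    return EpidemiologyParams(
        prevalence=prevalence,
        incidence=incidence,
        p_fatal_chd=p_fatal_chd,
        p_fatal_stroke=p_fatal_stroke,
    )


def from_dict(cfg: Mapping, base_dir: Path | None = None) -> ModelParameters:
    """Build and validate :class:`ModelParameters` from a parsed config mapping."""
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    bounds: dict = {}

    switch_node = _node(cfg, "switch")
    p_switch = _scalar(_node(switch_node, "p_switch_given_eps"), "switch.p_switch_given_eps", bounds)
    switch_cost = _scalar(_node(switch_node, "annual_drug_cost"), "switch.annual_drug_cost", bounds)

    def load_arm(role: str) -> TreatmentArmParams:
        node = _node(cfg, "arms", role)
        return TreatmentArmParams(
            name=str(_node(node, "name")),
            annual_drug_cost=_scalar(_node(node, "annual_drug_cost"), f"{role}.annual_drug_cost", bounds),
            p_weight_gain_y1=_scalar(_node(node, "p_weight_gain_y1"), f"{role}.p_weight_gain_y1", bounds),
            p_eps_y1=_scalar(_node(node, "p_eps_y1"), f"{role}.p_eps_y1", bounds),
            switch_drug_annual_cost=switch_cost,
            p_switch_given_eps=p_switch,
        )

    risks_node = _node(cfg, "risks")
    risks = ComplicationRiskParams(
        odds_ratio_weight_gain={
            (c, s): _scalar(_node(risks_node, "odds_ratio_weight_gain", c, s), f"risk.or.{c}.{s}", bounds)
            for c in COMPLICATIONS
            for s in SEXES
        },
        mortality_risk={
            (c, s): _scalar(_node(risks_node, "mortality", c, s), f"risk.mortality.{c}.{s}", bounds)
            for c in COMPLICATIONS
            for s in SEXES
        },
    )

    util_node = _node(cfg, "utilities")
    utilities = UtilityParams(
        u_bpd=_scalar(_node(util_node, "u_bpd"), "utility.u_bpd", bounds),
        du_weight_gain=_scalar(_node(util_node, "du_weight_gain"), "utility.du_weight_gain", bounds),
        du_eps=_scalar(_node(util_node, "du_eps"), "utility.du_eps", bounds),
        eps_duration_years=float(util_node.get("eps_duration_years", 0.25)),
        du_complication={
            (c, s): _scalar(_node(util_node, "du_complication", c, s), f"utility.du.{c}.{s}", bounds)
            for c in COMPLICATIONS
            for s in SEXES
        },
        w_additional=_scalar(_node(util_node, "w_additional"), "utility.w_additional", bounds),
        wg_year1_exposure=float(util_node.get("wg_year1_exposure", 1.0)),
    )

    cost_node = _node(cfg, "costs")
    costs = CostParams(
        eps_management=_scalar(_node(cost_node, "eps_management"), "cost.eps_management", bounds),
        direct={
            k: _scalar(_node(cost_node, "direct", k), f"cost.direct.{k}", bounds)
            for k in DIRECT_COST_KEYS
        },
        productivity={
            c: _scalar(_node(cost_node, "productivity", c), f"cost.productivity.{c}", bounds)
            for c in COMPLICATIONS
        },
        informal_care_stroke=_scalar(
            _node(cost_node, "informal_care_stroke"), "cost.informal_care_stroke", bounds
        ),
    )

    epidemiology = _load_epidemiology(cfg, base_dir)
    mortality = _load_mortality(cfg, base_dir, bounds)

    run_node = _node(cfg, "run")
    run = RunSpec(
        horizon_years=int(_node(run_node, "horizon_years")),
        discount_rate=_scalar(_node(run_node, "discount_rate"), "run.discount_rate", bounds),
        entry_age=int(_scalar(_node(run_node, "entry_age"), "run.entry_age", bounds)),
        sex_mix=_scalar(_node(run_node, "sex_mix"), "run.sex_mix", bounds),
        cohort_size_report=int(run_node.get("cohort_size_report", 1000)),
        seed=int(run_node.get("seed", 0)),
        complication_order=tuple(run_node.get("complication_order", COMPLICATIONS)),
        or_as_rr=bool(run_node.get("or_as_rr", False)),
        mortality_combination=str(run_node.get("mortality_combination", "multiplicative")),
        discount_first_year=bool(run_node.get("discount_first_year", False)),
        half_cycle_correction=bool(run_node.get("half_cycle_correction", False)),
    )

    params = ModelParameters(
        intervention=load_arm("intervention"),
        comparator=load_arm("comparator"),
        risks=risks,
        utilities=utilities,
        costs=costs,
        epidemiology=epidemiology,
        mortality=mortality,
        run=run,
        printed_bounds=bounds,
    )
    validate(params)
    return params


def load_parameters(config_path: str | Path) -> ModelParameters:
    """Load, resolve and validate a YAML model configuration."""
    path = Path(config_path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ParameterError(f"config {path} did not parse to a mapping")
    return from_dict(cfg, base_dir=path.parent)


def base_case_path() -> Path:
    """Path of the packaged base-case configuration (published tables)."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def load_base_case() -> ModelParameters:
    return load_parameters(base_case_path())


# --- saving ----------------------------------------------------------------


def _emit(value: float, pid: str, bounds: Mapping) -> Any:
    if pid in bounds:
        lo, hi = bounds[pid]
        return {"base": value, "lower": lo, "upper": hi}
    return value


def to_dict(params: ModelParameters) -> dict:
    """Serialise fully-resolved parameters (explicit tables) to a config dict."""
    b = params.printed_bounds
    cfg: dict = {
        "arms": {},
        "switch": {
            "p_switch_given_eps": _emit(
                params.intervention.p_switch_given_eps, "switch.p_switch_given_eps", b
            ),
            "annual_drug_cost": _emit(
                params.intervention.switch_drug_annual_cost, "switch.annual_drug_cost", b
            ),
        },
        "risks": {
            "odds_ratio_weight_gain": {
                c: {s: _emit(params.risks.odds_ratio_weight_gain[(c, s)], f"risk.or.{c}.{s}", b) for s in SEXES}
                for c in COMPLICATIONS
            },
            "mortality": {
                c: {s: _emit(params.risks.mortality_risk[(c, s)], f"risk.mortality.{c}.{s}", b) for s in SEXES}
                for c in COMPLICATIONS
            },
        },
        "utilities": {
            "u_bpd": _emit(params.utilities.u_bpd, "utility.u_bpd", b),
            "du_weight_gain": _emit(params.utilities.du_weight_gain, "utility.du_weight_gain", b),
            "du_eps": _emit(params.utilities.du_eps, "utility.du_eps", b),
            "eps_duration_years": params.utilities.eps_duration_years,
            "wg_year1_exposure": params.utilities.wg_year1_exposure,
            "w_additional": _emit(params.utilities.w_additional, "utility.w_additional", b),
            "du_complication": {
                c: {s: _emit(params.utilities.du_complication[(c, s)], f"utility.du.{c}.{s}", b) for s in SEXES}
                for c in COMPLICATIONS
            },
        },
        "costs": {
            "eps_management": _emit(params.costs.eps_management, "cost.eps_management", b),
            "direct": {k: _emit(params.costs.direct[k], f"cost.direct.{k}", b) for k in DIRECT_COST_KEYS},
            "productivity": {
                c: _emit(params.costs.productivity[c], f"cost.productivity.{c}", b) for c in COMPLICATIONS
            },
            "informal_care_stroke": _emit(
                params.costs.informal_care_stroke, "cost.informal_care_stroke", b
            ),
        },
        "mortality": {
            "bpd_suicide_multiplier": _emit(
                params.mortality.bpd_suicide_multiplier, "mortality.bpd_suicide_multiplier", b
            ),
            "life_table": {
                "table": [
                    {"sex": s, "age": a, "value": q}
                    for s in SEXES
                    for a, q in sorted(params.mortality.life_table[s].items())
                ]
            },
            "suicide": {
                "table": [
                    {"sex": s, "age": a, "value": q}
                    for s in SEXES
                    for a, q in sorted(params.mortality.suicide.get(s, {}).items())
                ]
            },
        },
        "epidemiology": {
            "p_fatal_chd": params.epidemiology.p_fatal_chd,
            "p_fatal_stroke": params.epidemiology.p_fatal_stroke,
            "prevalence": [
                {"complication": c, "sex": s, "value": params.epidemiology.prevalence[(c, s)]}
                for c in COMPLICATIONS
                for s in SEXES
            ],
            "incidence": [
                {"complication": c, "sex": s, "age": a, "value": v}
                for c in COMPLICATIONS
                for s in SEXES
                for a, v in sorted(params.epidemiology.incidence[(c, s)].items())
            ],
        },
        "run": {
            "horizon_years": params.run.horizon_years,
            "discount_rate": _emit(params.run.discount_rate, "run.discount_rate", b),
            "entry_age": _emit(params.run.entry_age, "run.entry_age", b),
            "sex_mix": _emit(params.run.sex_mix, "run.sex_mix", b),
            "cohort_size_report": params.run.cohort_size_report,
            "seed": params.run.seed,
            "complication_order": list(params.run.complication_order),
            "or_as_rr": params.run.or_as_rr,
            "mortality_combination": params.run.mortality_combination,
            "discount_first_year": params.run.discount_first_year,
            "half_cycle_correction": params.run.half_cycle_correction,
        },
    }
    for role in ("intervention", "comparator"):
        arm = getattr(params, role)
        cfg["arms"][role] = {
            "name": arm.name,
            "annual_drug_cost": _emit(arm.annual_drug_cost, f"{role}.annual_drug_cost", b),
            "p_weight_gain_y1": _emit(arm.p_weight_gain_y1, f"{role}.p_weight_gain_y1", b),
            "p_eps_y1": _emit(arm.p_eps_y1, f"{role}.p_eps_y1", b),
        }
    return cfg


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a fully-resolved config; ``load_parameters`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False)


def config_hash(params: ModelParameters) -> str:
    """Stable hash of the resolved parameter set, for output provenance."""
    blob = json.dumps(to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Parameter registry (flat view used by DSA / PSA)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDef:
    """One scalar model input addressable by id, with get/set accessors."""

    id: str
    kind: str  # probability | cost | ratio | utility | disutility | weight | rate | age
    get: Callable[[ModelParameters], float]
    set: Callable[[ModelParameters, float], None]
    in_psa: bool = True
    in_dsa: bool = True


def _attr_def(pid, obj_attr, field_name, kind, **kw):
    return ParamDef(
        pid,
        kind,
        get=lambda p: getattr(getattr(p, obj_attr), field_name),
        set=lambda p, v: setattr(getattr(p, obj_attr), field_name, v),
        **kw,
    )


def _dict_def(pid, obj_path, key, kind, **kw):
    def getter(p, path=obj_path, k=key):
        obj = p
        for a in path[:-1]:
            obj = getattr(obj, a)
        return getattr(obj, path[-1])[k]

    def setter(p, v, path=obj_path, k=key):
        obj = p
        for a in path[:-1]:
            obj = getattr(obj, a)
        getattr(obj, path[-1])[k] = v

    return ParamDef(pid, kind, get=getter, set=setter, **kw)


def param_registry() -> list:
    """The flat list of sensitivity-addressable parameters, stable order."""
    defs: list = []
    for role in ("intervention", "comparator"):
        vary_cost = role == "comparator"  # the intervention price has no published interval
        defs.append(_attr_def(f"{role}.p_weight_gain_y1", role, "p_weight_gain_y1", "probability"))
        defs.append(_attr_def(f"{role}.p_eps_y1", role, "p_eps_y1", "probability"))
        defs.append(
            _attr_def(
                f"{role}.annual_drug_cost",
                role,
                "annual_drug_cost",
                "cost",
                in_psa=vary_cost,
                in_dsa=vary_cost,
            )
        )

    def both_arms(field_name):
        def setter(p, v, f=field_name):
            setattr(p.intervention, f, v)
            setattr(p.comparator, f, v)

        return setter

    defs.append(
        ParamDef(
            "switch.p_switch_given_eps",
            "probability",
            get=lambda p: p.intervention.p_switch_given_eps,
            set=both_arms("p_switch_given_eps"),
        )
    )
    defs.append(
        ParamDef(
            "switch.annual_drug_cost",
            "cost",
            get=lambda p: p.intervention.switch_drug_annual_cost,
            set=both_arms("switch_drug_annual_cost"),
        )
    )

    for c in COMPLICATIONS:
        for s in SEXES:
            defs.append(_dict_def(f"risk.or.{c}.{s}", ("risks", "odds_ratio_weight_gain"), (c, s), "ratio"))
    for c in COMPLICATIONS:
        for s in SEXES:
            defs.append(_dict_def(f"risk.mortality.{c}.{s}", ("risks", "mortality_risk"), (c, s), "ratio"))

    defs.append(_attr_def("utility.u_bpd", "utilities", "u_bpd", "utility"))
    defs.append(_attr_def("utility.du_weight_gain", "utilities", "du_weight_gain", "disutility"))
    defs.append(_attr_def("utility.du_eps", "utilities", "du_eps", "disutility"))
    # the published scenario values for this weight are not a confidence
    # interval, so it is a DSA scenario only
    defs.append(_attr_def("utility.w_additional", "utilities", "w_additional", "weight", in_psa=False))
    for c in COMPLICATIONS:
        for s in SEXES:
            defs.append(_dict_def(f"utility.du.{c}.{s}", ("utilities", "du_complication"), (c, s), "disutility"))

    defs.append(_attr_def("cost.eps_management", "costs", "eps_management", "cost"))
    for k in DIRECT_COST_KEYS:
        defs.append(_dict_def(f"cost.direct.{k}", ("costs", "direct"), k, "cost"))
    for c in COMPLICATIONS:
        defs.append(_dict_def(f"cost.productivity.{c}", ("costs", "productivity"), c, "cost"))
    defs.append(_attr_def("cost.informal_care_stroke", "costs", "informal_care_stroke", "cost"))

    defs.append(
        _attr_def("mortality.bpd_suicide_multiplier", "mortality", "bpd_suicide_multiplier", "ratio")
    )
    defs.append(_attr_def("epidemiology.p_fatal_chd", "epidemiology", "p_fatal_chd", "probability"))
    defs.append(_attr_def("epidemiology.p_fatal_stroke", "epidemiology", "p_fatal_stroke", "probability"))

    defs.append(_attr_def("run.sex_mix", "run", "sex_mix", "probability"))
    defs.append(_attr_def("run.entry_age", "run", "entry_age", "age", in_psa=False))
    defs.append(_attr_def("run.discount_rate", "run", "discount_rate", "rate", in_psa=False))
    return defs


_FIXED_IDS = {"intervention.annual_drug_cost"}  # published interval is "N/A": held fixed


def parameter_bounds(params: ModelParameters) -> list:
    """(id, lower, upper) per registry parameter.

    Published intervals are used verbatim; a missing side or a parameter with
    no published interval falls back to base +/- 25%.  Probabilities are
    clipped to [0, 1].
    """
    out = []
    for d in param_registry():
        base = d.get(params)
        if d.id in _FIXED_IDS:
            out.append((d.id, base, base))
            continue
        lo_hi = params.printed_bounds.get(d.id)
        lo = hi = None
        if lo_hi is not None:
            lo, hi = lo_hi
        if lo is None:
            lo = base * 0.75
        if hi is None:
            hi = base * 1.25
        if d.kind == "probability":
            lo, hi = max(0.0, lo), min(1.0, hi)
        out.append((d.id, float(lo), float(hi)))
    return out


def get_value(params: ModelParameters, pid: str) -> float:
    for d in param_registry():
        if d.id == pid:
            return d.get(params)
    raise KeyError(pid)


def clone_params(params: ModelParameters) -> ModelParameters:
    """Cheap copy safe for registry ``set``: scalar holders and small dicts are
    copied, the (read-only) age tables are shared."""
    return ModelParameters(
        intervention=replace(params.intervention),
        comparator=replace(params.comparator),
        risks=ComplicationRiskParams(
            odds_ratio_weight_gain=dict(params.risks.odds_ratio_weight_gain),
            mortality_risk=dict(params.risks.mortality_risk),
        ),
        utilities=replace(params.utilities, du_complication=dict(params.utilities.du_complication)),
        costs=CostParams(
            eps_management=params.costs.eps_management,
            direct=dict(params.costs.direct),
            productivity=dict(params.costs.productivity),
            informal_care_stroke=params.costs.informal_care_stroke,
        ),
        epidemiology=replace(params.epidemiology),
        mortality=replace(params.mortality),
        run=replace(params.run),
        printed_bounds=params.printed_bounds,
    )


def with_value(params: ModelParameters, pid: str, value: float) -> ModelParameters:
    """Functional single-parameter update (used by the DSA)."""
    new = clone_params(params)
    for d in param_registry():
        if d.id == pid:
            if d.kind == "age":
                value = int(round(value))
            d.set(new, value)
            return new
    raise KeyError(pid)
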