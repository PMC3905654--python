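"""State space, transition construction, and cohort propagation."""

import copy

import numpy as np
import pytest

from bipolarcua import markov_engine as mk
from bipolarcua.decision_tree import Stratum, run_year_one
from bipolarcua.markov_engine import (
    DEAD,
    DEAD_INDEX,
    STATE_INDEX,
    HealthState,
    adjusted_mortality,
    adjusted_probability,
    advance,
    build_transitions,
    enumerate_states,
    initialize_cohort,
    transition_matrix,
)
from bipolarcua.params import COMPLICATIONS, SEXES, ParameterError

WG = Stratum(weight_gained=True, had_eps=False, switched=False, mass=1.0)
NO_WG = Stratum(weight_gained=False, had_eps=False, switched=False, mass=1.0)


class TestStateSpace:
    def test_thirty_seven_states(self):
        states = enumerate_states()
        assert len(states) == 37
        assert len(set(states)) == 37

    def test_contains_anchor_states(self):
        states = enumerate_states()
        assert HealthState() in states  # all-none alive
        assert DEAD in states
        # closure of the product set: everything at once, post-event tiers
        assert HealthState(True, True, mk.STATUS_POST, mk.STATUS_POST) in states


class TestAdjustedProbability:
    def test_odds_ratio_identity(self):
        assert adjusted_probability(0.10, 1.0) == pytest.approx(0.10)

    def test_odds_scale_transform(self):
        # odds 0.1111... * 2.69 = 0.298889; back-transform 0.298889/1.298889
        assert adjusted_probability(0.10, 2.69) == pytest.approx(0.2301117, abs=1e-6)

    def test_zero_preserved(self):
        assert adjusted_probability(0.0, 5.0) == 0.0

    def test_certain_event_rejected(self):
        with pytest.raises(ParameterError):
            adjusted_probability(1.0, 2.0)

    def test_relative_risk_mode(self):
        assert adjusted_probability(0.10, 2.69, as_rr=True) == pytest.approx(0.269)
        assert adjusted_probability(0.6, 2.0, as_rr=True) == 1.0


class TestAdjustedMortality:
    def _mortality(self, life, suicide, multiplier):
        from bipolarcua.params import MortalityParams

        return MortalityParams(
            life_table={s: {45: life} for s in SEXES},
            suicide={s: {45: suicide} for s in SEXES},
            bpd_suicide_multiplier=multiplier,
        )

    def test_identity_without_complications_and_unit_multiplier(self, base_params):
        mort = self._mortality(0.0030, 0.0002, 1.0)
        q = adjusted_mortality(mort, HealthState(), "male", 45, base_params.risks)
        assert q == pytest.approx(0.0030)

    def test_suicide_substitution(self, base_params):
        # 0.0030 - 0.0002 + 15.5 * 0.0002 = 0.0059
        mort = self._mortality(0.0030, 0.0002, 15.5)
        q = adjusted_mortality(mort, HealthState(), "male", 45, base_params.risks)
        assert q == pytest.approx(0.0059)

    def test_complication_risk_multiplies(self, base_params):
        mort = self._mortality(0.0030, 0.0002, 15.5)
        state = HealthState(has_diabetes=True)
        q = adjusted_mortality(mort, state, "male", 45, base_params.risks)
        assert q == pytest.approx(0.0059 * 1.88)  # published diabetes risk, men

    def test_concomitant_risks_combine_multiplicatively_or_by_max(self, base_params):
        mort = self._mortality(0.0030, 0.0002, 15.5)
        state = HealthState(has_diabetes=True, stroke_status=mk.STATUS_POST)
        q_mult = adjusted_mortality(mort, state, "male", 45, base_params.risks)
        q_max = adjusted_mortality(mort, state, "male", 45, base_params.risks, combination="max")
        assert q_mult == pytest.approx(0.0059 * 1.88 * 2.37)
        assert q_max == pytest.approx(0.0059 * 2.37)

    def test_age_outside_table_raises(self, base_params):
        mort = self._mortality(0.003, 0.0002, 15.5)
        with pytest.raises(ParameterError):
            adjusted_mortality(mort, HealthState(), "male", 99, base_params.risks)


def _toy_params(base_params, incidences, mortality_q=0.0, p_fatal_chd=0.0, p_fatal_stroke=0.0):
    """Base params with flat incidence/mortality overrides for hand arithmetic."""
    p = copy.deepcopy(base_params)
    ages = range(18, 81)
    p.epidemiology.incidence = {
        (c, s): {a: incidences.get(c, 0.0) for a in ages} for c in COMPLICATIONS for s in SEXES
    }
    p.epidemiology.p_fatal_chd = p_fatal_chd
    p.epidemiology.p_fatal_stroke = p_fatal_stroke
    p.mortality.life_table = {s: {a: mortality_q for a in ages} for s in SEXES}
    p.mortality.suicide = {s: {a: 0.0 for a in ages} for s in SEXES}
    return p


class TestBuildTransitions:
    def test_identity_row_when_nothing_can_happen(self, base_params):
        p = _toy_params(base_params, {})
        row = build_transitions(HealthState(), NO_WG, "male", 45, p)
        assert row.masses[STATE_INDEX[HealthState()]] == pytest.approx(1.0)

    def test_death_resolved_first_then_single_incidence(self, base_params):
        p = _toy_params(base_params, {"diabetes": 0.05}, mortality_q=0.01)
        row = build_transitions(HealthState(), NO_WG, "male", 45, p)
        assert row.masses[STATE_INDEX[HealthState(has_diabetes=True)]] == pytest.approx(0.0495)
        assert row.masses[DEAD_INDEX] == pytest.approx(0.01)
        assert row.masses[STATE_INDEX[HealthState()]] == pytest.approx(0.9405)

    def test_sequential_competing_events_thin_in_order(self, base_params):
        p = _toy_params(base_params, {"diabetes": 0.03, "hypertension": 0.04})
        row = build_transitions(HealthState(), NO_WG, "male", 45, p)
        assert row.masses[STATE_INDEX[HealthState(has_diabetes=True)]] == pytest.approx(0.03)
        assert row.masses[STATE_INDEX[HealthState(has_hypertension=True)]] == pytest.approx(
            0.04 * 0.97
        )
        assert row.masses[STATE_INDEX[HealthState()]] == pytest.approx(0.97 * 0.96)

    def test_fatal_split_of_incident_stroke(self, base_params):
        p = _toy_params(base_params, {"stroke": 0.10}, p_fatal_stroke=0.15)
        row = build_transitions(HealthState(), NO_WG, "male", 45, p)
        assert row.fatal_stroke == pytest.approx(0.015)
        event = HealthState(stroke_status=mk.STATUS_EVENT)
        assert row.masses[STATE_INDEX[event]] == pytest.approx(0.085)

    def test_event_year_advances_to_post(self, base_params):
        p = _toy_params(base_params, {})
        src = HealthState(chd_status=mk.STATUS_EVENT)
        row = build_transitions(src, NO_WG, "male", 45, p)
        assert row.masses[STATE_INDEX[HealthState(chd_status=mk.STATUS_POST)]] == pytest.approx(1.0)

    def test_rows_sum_to_one_and_dead_is_absorbing(self, base_params):
        for state in mk.STATES:
            row = build_transitions(state, WG, "female", 45, base_params)
            assert row.masses.sum() == pytest.approx(1.0, abs=1e-12)
        dead_row = build_transitions(DEAD, WG, "female", 45, base_params)
        assert dead_row.masses[DEAD_INDEX] == 1.0

    def test_vectorised_matrix_matches_scalar_reference(self, base_params):
        """The fast engine agrees row for row with the reference builder."""
        for wg, stratum in ((True, WG), (False, NO_WG)):
            for sex in SEXES:
                T, f_chd, f_stroke = transition_matrix(base_params, wg, sex, 43)
                for i, state in enumerate(mk.STATES):
                    row = build_transitions(state, stratum, sex, 43, base_params)
                    np.testing.assert_allclose(T[i], row.masses, atol=1e-14)
                    assert f_chd[i] == pytest.approx(row.fatal_chd, abs=1e-14)
                    assert f_stroke[i] == pytest.approx(row.fatal_stroke, abs=1e-14)


class TestInitializeCohort:
    def test_zero_prevalence_starts_all_none(self, zero_risk):
        dist = run_year_one(zero_risk.intervention, zero_risk.utilities, zero_risk.costs)
        cohort = initialize_cohort(dist, zero_risk.epidemiology, zero_risk.run)
        alive_none = cohort.mass[STATE_INDEX[HealthState()]].sum()
        assert alive_none == pytest.approx(1.0)

    def test_prevalence_product_measure(self, base_params):
        p = copy.deepcopy(base_params)
        p.epidemiology.prevalence = {(c, s): 0.0 for c in COMPLICATIONS for s in SEXES}
        for s in SEXES:
            p.epidemiology.prevalence[("diabetes", s)] = 0.05
            p.epidemiology.prevalence[("hypertension", s)] = 0.10
        dist = run_year_one(p.intervention, p.utilities, p.costs)
        cohort = initialize_cohort(dist, p.epidemiology, p.run)
        dm_only = cohort.mass[STATE_INDEX[HealthState(has_diabetes=True)]].sum()
        both = cohort.mass[STATE_INDEX[HealthState(True, True)]].sum()
        assert dm_only == pytest.approx(0.05 * 0.90)
        assert both == pytest.approx(0.05 * 0.10)

    def test_prevalent_events_enter_post_tier(self, base_params):
        dist = run_year_one(base_params.intervention, base_params.utilities, base_params.costs)
        cohort = initialize_cohort(dist, base_params.epidemiology, base_params.run)
        for i, state in enumerate(mk.STATES[:-1]):
            if state.chd_status == mk.STATUS_EVENT or state.stroke_status == mk.STATUS_EVENT:
                assert cohort.mass[i].sum() == 0.0
        assert cohort.total_mass() == pytest.approx(1.0, abs=1e-10)


class TestAdvance:
    def test_zero_risk_cohort_unchanged(self, zero_risk):
        dist = run_year_one(zero_risk.intervention, zero_risk.utilities, zero_risk.costs)
        cohort = initialize_cohort(dist, zero_risk.epidemiology, zero_risk.run)
        after, events = advance(cohort, zero_risk)
        np.testing.assert_allclose(after.mass, cohort.mass, atol=1e-15)
        assert after.age == cohort.age + 1
        assert after.cycle_index == cohort.cycle_index + 1
        assert events.fatal_chd_mass == 0.0

    def test_mass_conserved_over_horizon(self, base_params):
        dist = run_year_one(base_params.intervention, base_params.utilities, base_params.costs)
        cohort = initialize_cohort(dist, base_params.epidemiology, base_params.run)
        for _ in range(6):
            cohort, _events = advance(cohort, base_params)
            assert cohort.total_mass() == pytest.approx(1.0, abs=1e-10)

    def test_dead_mass_never_decreases(self, base_params):
        dist = run_year_one(base_params.comparator, base_params.utilities, base_params.costs)
        cohort = initialize_cohort(dist, base_params.epidemiology, base_params.run)
        dead = 0.0
        for _ in range(6):
            cohort, _ = advance(cohort, base_params)
            new_dead = cohort.mass[DEAD_INDEX].sum()
            assert new_dead >= dead - 1e-15
            dead = new_dead

    def test_complication_occupancy_monotone_non_decreasing(self, base_params):
        """Complication flags never revert along the cohort path."""
        dist = run_year_one(base_params.comparator, base_params.utilities, base_params.costs)
        cohort = initialize_cohort(dist, base_params.epidemiology, base_params.run)
        prev = {c: 0.0 for c in COMPLICATIONS}
        for _ in range(6):
            cohort, _ = advance(cohort, base_params)
            for c in COMPLICATIONS:
                mask = np.array([s.has(c) for s in mk.STATES])
                occ = cohort.mass[mask].sum()
                # occupancy can only shrink through death, which is tracked
                assert occ >= prev[c] - cohort.mass[DEAD_INDEX].sum() - 1e-12
                prev[c] = occ

    def test_weight_gain_stratum_dominates_complication_occupancy(self, base_params):
        """Under ORs >= 1 the weight-gained stratum accumulates more total
        complication burden, and at least as much of each complication up to
        the sequential-competition displacement (the higher incidence of the
        earlier-resolved complications thins a late low-OR candidate such as
        stroke by a few 1e-5 of mass)."""
        dist = run_year_one(base_params.comparator, base_params.utilities, base_params.costs)
        cohort = initialize_cohort(dist, base_params.epidemiology, base_params.run)
        wg_idx = [k for k, s in enumerate(cohort.strata) if s.weight_gained]
        no_idx = [k for k, s in enumerate(cohort.strata) if not s.weight_gained]
        wg_total = cohort.mass[:, wg_idx].sum()
        no_total = cohort.mass[:, no_idx].sum()
        n_comp = np.array([sum(s.has(c) for c in COMPLICATIONS) for s in mk.STATES])
        for _ in range(5):
            cohort, _ = advance(cohort, base_params)
            burden_wg = (cohort.mass[:, wg_idx].sum(axis=(1, 2)) * n_comp).sum() / wg_total
            burden_no = (cohort.mass[:, no_idx].sum(axis=(1, 2)) * n_comp).sum() / no_total
            assert burden_wg > burden_no
            for c in COMPLICATIONS:
                mask = np.array([s.has(c) for s in mk.STATES])
                occ_wg = cohort.mass[mask][:, wg_idx].sum() / wg_total
                occ_no = cohort.mass[mask][:, no_idx].sum() / no_total
                assert occ_wg >= occ_no - 2e-4

    def test_unit_odds_ratios_make_strata_identical(self, base_params):
        p = copy.deepcopy(base_params)
        p.risks.odds_ratio_weight_gain = {
            (c, s): 1.0 for c in COMPLICATIONS for s in SEXES
        }
        dist = run_year_one(p.comparator, p.utilities, p.costs)
        cohort = initialize_cohort(dist, p.epidemiology, p.run)
        for _ in range(4):
            cohort, _ = advance(cohort, p)
        # normalised state distribution identical across wg / non-wg strata
        wg_idx = [k for k, s in enumerate(cohort.strata) if s.weight_gained]
        no_idx = [k for k, s in enumerate(cohort.strata) if not s.weight_gained]
        wg = cohort.mass[:, wg_idx].sum(axis=(1, 2))
        no = cohort.mass[:, no_idx].sum(axis=(1, 2))
        np.testing.assert_allclose(wg / wg.sum(), no / no.sum(), atol=1e-12)

    def test_complication_order_has_negligible_effect(self, base_params):
        """At realistic incidences, permuting the within-cycle resolution
        order moves totals by well under a percent."""
        from bipolarcua import outcomes

        p2 = copy.deepcopy(base_params)
        p2.run.complication_order = ("stroke", "chd", "hypertension", "diabetes")
        a = outcomes.run_model(base_params)["moh"]["icur"]
        b = outcomes.run_model(p2)["moh"]["icur"]
        assert a.delta_qaly == pytest.approx(b.delta_qaly, rel=1e-2)
        assert a.delta_cost == pytest.approx(b.delta_cost, rel=1e-2)
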