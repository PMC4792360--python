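"""State-transition model: hazard conversion, risk adjustment, intervention effects."""

import copy

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acosim.disease import (
    DiseaseError,
    HealthState,
    InterventionStatus,
    PatientState,
    SurvivalCurve,
    cycle_hazards_from_survival,
    default_transition_parameters,
    effective_risk_reduction,
    sample_outpatient_visits,
    step_patient,
    transition_probabilities,
)
from acosim.population import PatientProfile


def onsite_state(profile, cycles=10):
    return PatientState(profile, HealthState.CHF_ONSITE, cycles)


class TestCycleHazards:
    def test_constant_curve_gives_zero_mortality(self):
        curve = SurvivalCurve(np.array([0.0, 360.0]), np.array([1.0, 1.0]))
        mort = cycle_hazards_from_survival(curve)
        assert np.all(mort.per_cycle == 0.0) and mort.tail == 0.0

    def test_first_interval_closed_form(self, default_params):
        # S drops 1.00 -> 0.98 over 30 days => per-15-day p = 1 - 0.98**0.5
        mort = cycle_hazards_from_survival(default_params.survival_outpatient)
        assert mort.per_cycle[0] == pytest.approx(1.0 - 0.98 ** 0.5, abs=1e-9)
        assert mort.per_cycle[0] == pytest.approx(0.010050, abs=1e-6)

    @pytest.mark.parametrize("source,knots", [
        ("outpatient", {2: 0.98, 24: 0.87, 120: 0.49}),
        ("inpatient", {2: 0.84, 24: 0.66, 120: 0.33}),
    ])
    def test_telescoping_reproduces_knots(self, default_params, source, knots):
        curve = getattr(default_params, f"survival_{source}")
        mort = cycle_hazards_from_survival(curve)
        surv = np.cumprod(1.0 - mort.per_cycle)
        for n_cycles, expected in knots.items():
            assert surv[n_cycles - 1] == pytest.approx(expected, abs=1e-6)

    def test_increasing_segment_rejected(self):
        curve = SurvivalCurve(np.array([0.0, 30.0, 60.0]), np.array([1.0, 0.8, 0.9]))
        with pytest.raises(DiseaseError):
            cycle_hazards_from_survival(curve)


class TestEffectiveRiskReduction:
    def test_full_partial_and_none(self, default_params):
        assert effective_risk_reduction(
            InterventionStatus(True, True), default_params) == (0.20, 0.13)
        assert effective_risk_reduction(
            InterventionStatus(False, False), default_params) == (0.0, 0.0)
        rh, rm = effective_risk_reduction(InterventionStatus(True, False), default_params)
        assert (rh, rm) == (pytest.approx(0.10), pytest.approx(0.065))

    @given(h=st.booleans(), p=st.booleans(), phi=st.floats(0, 1))
    def test_reduction_bounded_by_full_effect(self, h, p, phi, default_params):
        params = copy.copy(default_params)
        params.partial_effect_fraction = phi
        rh, rm = effective_risk_reduction(InterventionStatus(h, p), params)
        assert 0.0 <= rh <= params.rr_hosp and 0.0 <= rm <= params.rr_mort


class TestTransitionProbabilities:
    @pytest.mark.parametrize("age,group,expected", [
        (70, 2, 0.01663), (80, 4, 0.02360), (90, 5, 0.03489)])
    def test_hospitalization_by_age_group(self, default_params, age, group, expected):
        prof = PatientProfile(id=0, age=age, age_group=group, race="white",
                              gender="male", income="low", has_diabetes=False,
                              has_hypertension=False, has_chf=True,
                              chf_dx_source="outpatient")
        probs = transition_probabilities(
            onsite_state(prof), InterventionStatus(), default_params)
        assert probs[HealthState.CHF_HOSPITALIZED] == pytest.approx(expected, abs=1e-12)

    def test_full_intervention_scales_hospitalization(self, default_params, chf_patient):
        prof = copy.copy(chf_patient)
        prof.age, prof.age_group = 70, 1
        probs = transition_probabilities(
            onsite_state(prof), InterventionStatus(True, True), default_params)
        assert probs[HealthState.CHF_HOSPITALIZED] == pytest.approx(0.01663 * 0.8, abs=1e-12)
        assert probs[HealthState.CHF_HOSPITALIZED] == pytest.approx(0.013304)

    def test_zero_hazards_stay_put(self, chf_patient):
        params = default_transition_parameters()
        params.hosp_prob_by_age = (0.0,) * 5
        params.survival_outpatient = SurvivalCurve(
            np.array([0.0, 1800.0]), np.array([1.0, 1.0]))
        probs = transition_probabilities(
            onsite_state(chf_patient), InterventionStatus(), params)
        assert probs[HealthState.CHF_ONSITE] == 1.0

    def test_intervention_strictly_reduces_risks(self, default_params, chf_patient):
        none = transition_probabilities(
            onsite_state(chf_patient), InterventionStatus(), default_params)
        full = transition_probabilities(
            onsite_state(chf_patient), InterventionStatus(True, True), default_params)
        assert full[HealthState.CHF_HOSPITALIZED] < none[HealthState.CHF_HOSPITALIZED]
        assert full[HealthState.DEAD] < none[HealthState.DEAD]

    @given(cycles=st.integers(0, 200), h=st.booleans(), p=st.booleans(),
           state=st.sampled_from([HealthState.CHF_FREE, HealthState.CHF_ONSITE,
                                  HealthState.CHF_HOSPITALIZED]))
    def test_vector_sums_to_one(self, cycles, h, p, state, default_params, chf_patient):
        prof = copy.copy(chf_patient)
        if state == HealthState.CHF_FREE:
            prof.has_chf, prof.chf_dx_source = False, "none"
        probs = transition_probabilities(
            PatientState(prof, state, cycles), InterventionStatus(h, p), default_params)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in probs.values())

    def test_dead_patient_rejected(self, default_params, chf_patient):
        with pytest.raises(DiseaseError):
            transition_probabilities(PatientState(chf_patient, HealthState.DEAD),
                                     InterventionStatus(), default_params)


class TestStepPatient:
    def test_monte_carlo_matches_exact_vector(self, default_params, chf_patient, rng):
        exact = transition_probabilities(
            onsite_state(chf_patient), InterventionStatus(), default_params)
        n = 100_000
        counts = {s: 0 for s in HealthState}
        for _ in range(n):
            new, _ = step_patient(onsite_state(copy.copy(chf_patient)),
                                  InterventionStatus(), default_params, rng)
            counts[new.health] += 1
        for s, p in exact.items():
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(counts[s] / n - p) <= 3 * se + 1e-9, s

    def test_dead_patient_rejected(self, default_params, chf_patient, rng):
        with pytest.raises(DiseaseError):
            step_patient(PatientState(chf_patient, HealthState.DEAD),
                         InterventionStatus(), default_params, rng)

    def test_inpatient_onset_selects_inpatient_curve(self, default_params, rng):
        # a new inpatient-diagnosed patient must face the 0.84 30-day survival curve
        prof = PatientProfile(id=0, age=70, age_group=2, race="white", gender="male",
                              income="low", has_diabetes=False, has_hypertension=False,
                              has_chf=False, chf_dx_source="none")
        params = copy.copy(default_params)
        params.chf_incidence_base = 1.0
        params.incidence_age_multipliers = (1.0,) * 5
        params.p_incidence_inpatient = 1.0
        new, events = step_patient(PatientState(prof, HealthState.CHF_FREE),
                                   InterventionStatus(), params, rng)
        assert "chf_onset_inpatient" in events and "hospitalization" in events
        assert prof.chf_dx_source == "inpatient"
        mort = params.cycle_mortality("inpatient")
        assert (1.0 - mort.per_cycle[0]) ** 2 == pytest.approx(0.84, abs=1e-9)

    def test_chronic_flags_are_monotone(self, default_params, rng):
        prof = PatientProfile(id=0, age=70, age_group=2, race="black", gender="male",
                              income="low", has_diabetes=True, has_hypertension=True,
                              has_chf=False, chf_dx_source="none")
        state = PatientState(prof, HealthState.CHF_FREE)
        for _ in range(100):
            if state.health == HealthState.DEAD:
                break
            state, _ = step_patient(state, InterventionStatus(), default_params, rng)
            assert prof.has_diabetes and prof.has_hypertension
            if prof.has_chf:
                assert prof.chf_dx_source in ("outpatient", "inpatient")

    def test_cohort_survival_reproduces_curve(self, default_params, rng):
        # no hospitalization exits, no intervention: the simulated survival of an
        # outpatient-diagnosed CHF cohort reproduces the tabulated 30-day proportion
        params = copy.copy(default_params)
        params.hosp_prob_by_age = (0.0,) * 5
        n = 4000
        alive = 0
        for _ in range(n):
            prof = PatientProfile(id=0, age=70, age_group=2, race="white",
                                  gender="male", income="low", has_diabetes=False,
                                  has_hypertension=False, has_chf=True,
                                  chf_dx_source="outpatient")
            state = PatientState(prof, HealthState.CHF_ONSITE, 0)
            for _ in range(2):  # 30 days
                if state.health == HealthState.DEAD:
                    break
                state, _ = step_patient(state, InterventionStatus(), params, rng)
            alive += state.health != HealthState.DEAD
        se = np.sqrt(0.98 * 0.02 / n)
        assert abs(alive / n - 0.98) < 3 * se


class TestOutpatientVisits:
    def test_cycle_mean_matches_annual_rate(self, default_params, chf_patient, rng):
        n = 100_000
        draws = sum(sample_outpatient_visits(onsite_state(chf_patient), default_params, rng)
                    for _ in range(n))
        expected = default_params.visit_rate_per_cycle
        se = np.sqrt(expected / n)  # Poisson
        assert abs(draws / n - expected) < 3 * se

    def test_annual_regular_visits_equal_nine(self, default_params):
        assert default_params.visit_rate_per_cycle * default_params.cycles_per_year \
            == pytest.approx(9.0)

    def test_zero_rate_no_discharge_gives_zero(self, chf_patient, rng):
        params = default_transition_parameters()
        params.visit_rate_per_year = 0.0
        assert sample_outpatient_visits(onsite_state(chf_patient), params, rng) == 0

    def test_followup_visit_after_discharge_with_intervening_pcp(self, chf_patient, rng):
        params = default_transition_parameters()
        params.visit_rate_per_year = 0.0
        v = sample_outpatient_visits(onsite_state(chf_patient), params, rng,
                                     pcp_intervenes=True, discharged_last_cycle=True)
        assert v == 1
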