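"""TPB decision components: attitude, norm, control, intention, softmax choice."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acosim.providers import (
    PROVIDER_TYPES,
    PriorYearObservation,
    ProviderAgent,
    ProviderError,
    choice_probability,
    choose_behavior,
    compute_attitude,
    compute_intention,
    compute_pbc,
    compute_subjective_norm,
    estimate_expectations,
    exchange_messages,
    make_provider_roster,
    record_interaction,
    utility_profit,
    utility_quality,
)

unit = st.floats(0.0, 1.0)


def agent(kind="hospital", network="ACO", beta=(0.5, 0.5), **kw):
    return ProviderAgent(id=0, kind=kind, network=network, beta=beta, **kw)


class TestAttitude:
    def test_saturated_utilities_give_full_attitude(self):
        for beta in PROVIDER_TYPES.values():
            assert compute_attitude(1.0, 1.0, beta) == pytest.approx(1.0)

    def test_weighted_combination(self):
        assert compute_attitude(0.5, 0.25, (0.8, 0.2)) == pytest.approx(0.45)

    def test_profit_oriented_weights_profit_four_to_one(self):
        b = PROVIDER_TYPES["profit"]
        assert b == (0.8, 0.2) and b[0] / b[1] == pytest.approx(4.0)

    def test_beta_off_simplex_rejected(self):
        with pytest.raises(ProviderError):
            compute_attitude(0.5, 0.5, (0.9, 0.2))

    @given(up=unit, uq=unit, b1=unit)
    def test_attitude_stays_in_unit_interval(self, up, uq, b1):
        a = compute_attitude(up, uq, (b1, 1.0 - b1))
        assert 0.0 <= a <= 1.0 + 1e-12


class TestExpectations:
    def test_pure_cost_without_saving_forecast(self):
        prior = PriorYearObservation(100.0, 0.5, 0.2)
        (ep0, ep1), _ = estimate_expectations(
            agent(), prior, expected_saving_share_per_chf_patient=0.0,
            intervention_cost_per_patient_year=648.0, rr_hosp=0.2, rr_mort=0.13)
        assert ep1 < ep0

    def test_quality_expectation_applies_known_reductions(self):
        prior = PriorYearObservation(0.0, 0.5, 0.2)
        _, (eq0, eq1) = estimate_expectations(
            agent(), prior, 0.0, 648.0, rr_hosp=0.2, rr_mort=0.13)
        assert eq0 == (0.5, 0.2)
        assert eq1[0] == pytest.approx(0.5 * 0.8)
        assert eq1[1] == pytest.approx(0.2 * 0.87)

    def test_behaviors_differ_only_by_decision_terms(self):
        prior = PriorYearObservation(250.0, 0.4, 0.15)
        (ep0, ep1), _ = estimate_expectations(
            agent(), prior, expected_saving_share_per_chf_patient=900.0,
            intervention_cost_per_patient_year=648.0, rr_hosp=0.2, rr_mort=0.13,
            margin_per_admission=-1186.0)
        margin_gain = 1186.0 * 0.2 * 0.4
        assert ep1 - ep0 == pytest.approx(-648.0 + 900.0 + margin_gain)

    def test_profit_utility_maps_sign_around_half(self):
        assert utility_profit(0.0) == pytest.approx(0.5)
        assert utility_profit(500.0) > 0.5 > utility_profit(-500.0)

    def test_quality_utility_decreases_in_rates(self):
        assert utility_quality(0.0, 0.0) == 1.0
        assert utility_quality(0.4, 0.2) > utility_quality(0.6, 0.3)


class TestSubjectiveNorm:
    def test_no_messages_is_uninformative(self):
        assert compute_subjective_norm((0, 0)) == (0.5, 0.5)

    def test_proportion_transform(self):
        sn0, sn1 = compute_subjective_norm((1, 3))
        assert sn1 == pytest.approx(0.75) and sn0 == pytest.approx(0.25)

    @given(nm0=st.integers(0, 1000), nm1=st.integers(0, 1000))
    def test_norms_in_unit_interval_and_complementary(self, nm0, nm1):
        sn0, sn1 = compute_subjective_norm((nm0, nm1))
        assert 0.0 <= sn0 <= 1.0 and 0.0 <= sn1 <= 1.0
        assert sn0 + sn1 == pytest.approx(1.0)


class TestMessaging:
    def test_conservation_and_support_direction(self, rng):
        agents = make_provider_roster(["profit", "quality", "neutral"],
                                      ["neutral"] * 5, "ACO")
        for a in agents:
            a.attitude_favored = 1
        for _ in range(10):
            exchange_messages(agents, rng)
        received = np.array([a.messages_received for a in agents])
        assert received.sum() == 10 * len(agents)   # one message per agent per tick
        assert received[:, 0].sum() == 0            # all supported k=1

    def test_singleton_network_warns_and_noop(self, rng):
        solo = [agent()]
        with pytest.warns(UserWarning):
            exchange_messages(solo, rng)
        assert solo[0].messages_received == [0, 0]

    def test_expected_messages_per_agent_equals_ticks(self, rng):
        agents = make_provider_roster(["neutral"] * 3, ["neutral"] * 15, "ACO")
        ticks = 200
        for _ in range(ticks):
            exchange_messages(agents, rng)
        per_agent = np.array([sum(a.messages_received) for a in agents])
        assert per_agent.sum() == ticks * len(agents)
        se = np.sqrt(ticks)  # approx Poisson noise per agent
        assert np.all(np.abs(per_agent - ticks) < 5 * se)


class TestInteractionsAndPBC:
    def test_counterpart_behavior_drives_ni(self):
        h = agent("hospital")
        p_on = agent("pcp", behavior_k=1)
        p_off = agent("pcp")
        for counterpart in (p_on, p_on, p_on, p_off):
            record_interaction(h, counterpart)
        assert (h.ni, h.ti) == (3, 4)
        assert compute_pbc(h.ni, h.ti)[1] == pytest.approx(0.75)

    def test_pbc_zero_branch_and_priors(self):
        assert compute_pbc(0, 0) == (1.0, 0.5)          # year-1 default
        assert compute_pbc(0, 0, prev=0.9) == (1.0, 0.9)
        assert compute_pbc(0, 7)[1] == 0.0

    def test_pbc_for_usual_care_is_always_one(self):
        for ni, ti in ((0, 0), (2, 5), (5, 5)):
            assert compute_pbc(ni, ti)[0] == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ProviderError):
            compute_pbc(5, 4)


class TestIntentionAndChoice:
    def test_extremes(self):
        assert compute_intention(1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert compute_intention(0.0, 0.0, 0.0) == 0.0

    def test_equal_weights_mean(self):
        assert compute_intention(0.6, 0.9, 0.75) == pytest.approx(0.75)

    def test_weights_off_simplex_rejected(self):
        with pytest.raises(ProviderError):
            compute_intention(0.5, 0.5, 0.5, weights=(0.5, 0.5, 0.5))

    def test_softmax_symmetry(self):
        assert choice_probability(0.42, 0.42, tau=1.0) == pytest.approx(0.5)

    def test_softmax_closed_form_unit_gap(self):
        assert choice_probability(0.0, 1.0, tau=1.0) \
            == pytest.approx(math.e / (1.0 + math.e), abs=1e-9)

    def test_argmax_limit(self, rng):
        assert choose_behavior(0.3, 0.7, tau=0.0, rng=rng) == 1
        assert choose_behavior(0.7, 0.3, tau=0.0, rng=rng) == 0
        assert choose_behavior(0.5, 0.5, tau=0.0, rng=rng) == 0  # tie-break: usual care

    @given(i0=unit, i1=unit, tau=st.floats(0.01, 10.0))
    def test_softmax_normalized_and_monotone(self, i0, i1, tau):
        p1 = choice_probability(i0, i1, tau)
        p0 = choice_probability(i1, i0, tau)
        assert p0 + p1 == pytest.approx(1.0, abs=1e-9)
        if i1 > i0:
            assert p1 >= 0.5


class TestRoster:
    def test_controlled_agents_fixed_to_usual_care(self):
        with pytest.raises(ProviderError):
            ProviderAgent(id=0, kind="pcp", network="controlled",
                          beta=(0.5, 0.5), behavior_k=1)

    def test_roster_composition(self):
        roster = make_provider_roster(["profit", "quality", "neutral"],
                                      ["profit"] * 15, "ACO")
        kinds = [a.kind for a in roster]
        assert kinds[:3] == ["hospital"] * 3 and kinds[3:] == ["pcp"] * 15
        assert roster[0].beta == (0.8, 0.2)
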