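"""Simulation engine: two provider networks, a shared patient cohort, annual settlement.

One simulation run advances a cohort of Medicare patient agents through 15-day
cycles for a number of years.  Patients are randomly split between an ACO network
(shared-saving payment) and a controlled network (fee-for-service usual care), each
with its own hospital and PCP agents.  Within a year the engine executes patient
state transitions, outpatient visits, reimbursements, discharge interactions and
provider message passing; at each year end the payer settles the shared saving and
ACO providers run their Theory-of-Planned-Behavior decision for the next year.

The patient loop is vectorized over the cohort with numpy; the per-patient scalar
operations in :mod:`acosim.disease` define the same transition law and are used as
the oracle in tests.  Determinism: a run is a pure function of (config, seed), with
independent named RNG streams for population, disease and behavior.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import providers as prov
from .disease import (
    HealthState,
    TransitionParameters,
    default_transition_parameters,
)
from .payment import (
    CostSchedule,
    PaymentConfig,
    SavingsReport,
    annual_intervention_cost,
    default_cost_schedule,
    settle_shared_saving,
)
from .population import (
    PopulationSpec,
    assign_networks,
    make_default_population_fixture,
    sample_characteristic_arrays,
)

NETWORKS = ("ACO", "controlled")
_AGE_BAND_HIGHS = np.array([69, 74, 79, 84])


class EngineError(ValueError):
    """Raised for invalid simulation configurations."""


def default_pcp_types(n_pcps: int = 15) -> tuple[str, ...]:
    """Equal split of PCP types (exact 5/5/5 at the default roster size)."""
    kinds = ("profit", "quality", "neutral")
    return tuple(kinds[i % 3] for i in range(n_pcps))


@dataclass
class SimulationConfig:
    """Full configuration of one simulation study."""

    years: int = 5
    cycles_per_year: int = 24
    n_patients: int = 10_000
    n_hospitals: int = 3
    n_pcps: int = 15
    n_replications: int = 500
    hospital_types: tuple = ("profit", "quality", "neutral")
    pcp_types: tuple = field(default_factory=default_pcp_types)
    assignment: str = "bernoulli"           # network assignment: "bernoulli" | "stratified"
    payment: PaymentConfig = field(default_factory=PaymentConfig)
    costs: CostSchedule = field(default_factory=default_cost_schedule)
    clinical: TransitionParameters = field(default_factory=default_transition_parameters)
    population: PopulationSpec = field(default_factory=make_default_population_fixture)
    tau: float = 0.0                        # softmax irrationality; 0 = rational arg-max
    intention_weights: tuple = prov.DEFAULT_INTENTION_WEIGHTS
    profit_utility_scale: float = prov.DEFAULT_PROFIT_UTILITY_SCALE
    quality_bounds: tuple = prov.DEFAULT_QUALITY_BOUNDS
    force_intervention: bool = False        # all ACO agents intervene every year (for tests)
    scenario: str = "baseline"

    def validate(self) -> None:
        for name in ("years", "cycles_per_year", "n_patients", "n_hospitals", "n_pcps"):
            if getattr(self, name) < 1:
                raise EngineError(f"{name} must be at least 1")
        if len(self.hospital_types) != self.n_hospitals:
            raise EngineError("hospital_types must list one type per hospital")
        if len(self.pcp_types) != self.n_pcps:
            raise EngineError("pcp_types must list one type per PCP")
        for t in (*self.hospital_types, *self.pcp_types):
            if t not in prov.PROVIDER_TYPES:
                raise EngineError(f"unknown provider type {t!r}")
        self.payment.validate()
        self.costs.validate()
        self.clinical.validate()
        self.population.validate()


@dataclass
class SimulationResult:
    """Outputs of one simulation run."""

    per_year: pd.DataFrame
    provider_trace: pd.DataFrame
    summary: dict


class Simulation:
    """Mutable state of one simulation run (advance with :meth:`run_year`)."""

    def __init__(self, cfg: SimulationConfig, seed: int):
        cfg.validate()
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        pop_ss, dis_ss, beh_ss = ss.spawn(3)
        self.rng_pop = np.random.default_rng(pop_ss)
        self.rng_dis = np.random.default_rng(dis_ss)
        self.rng_beh = np.random.default_rng(beh_ss)

        self._init_cohort()
        self._init_providers()
        self._init_mortality_tables()

        self.cycle = 0          # global cycle counter
        self.year = 0
        self.reports: list[dict] = []
        self.trace_rows: list[dict] = []
        self.last_settlement: SavingsReport | None = None

    # -- initialization ----------------------------------------------------

    def _init_cohort(self) -> None:
        cfg = self.cfg
        a = sample_characteristic_arrays(cfg.population, cfg.n_patients, self.rng_pop)
        n = cfg.n_patients
        self.age = a["age"].astype(np.int32)
        self.age_group0 = self.age_group0_from_age(self.age)
        self.race = a["race"].astype(np.intp)
        self.gender = a["gender"].astype(np.intp)
        self.income = a["income"]
        self.diab = a["diabetes"].astype(bool)
        self.hyp = a["hypertension"].astype(bool)
        self.dx_source = a["dx_source"].astype(np.int8)    # 0 none, 1 outpatient, 2 inpatient
        self.state = np.where(a["chf"] == 1, HealthState.CHF_ONSITE,
                              HealthState.CHF_FREE).astype(np.int8)
        self.onset_cycle = np.where(a["chf"] == 1, -1, 0).astype(np.int32)
        self.network = assign_networks(n, self.rng_pop, cfg.assignment)  # 0 ACO, 1 controlled
        self.hosp_idx = self.rng_pop.integers(0, cfg.n_hospitals, size=n).astype(np.intp)
        self.pcp_idx = self.rng_pop.integers(0, cfg.n_pcps, size=n).astype(np.intp)

        self.followup_due = np.zeros(n, dtype=bool)

    @staticmethod
    def age_group0_from_age(age: np.ndarray) -> np.ndarray:
        return np.searchsorted(_AGE_BAND_HIGHS, age).astype(np.intp)

    def _init_providers(self) -> None:
        cfg = self.cfg
        self.roster: dict[str, list[prov.ProviderAgent]] = {}
        for offset, net in enumerate(NETWORKS):
            self.roster[net] = prov.make_provider_roster(
                list(cfg.hospital_types), list(cfg.pcp_types), net,
                id_offset=offset * (cfg.n_hospitals + cfg.n_pcps))
        self._refresh_behavior_arrays()

    def _refresh_behavior_arrays(self) -> None:
        cfg = self.cfg
        aco = self.roster["ACO"]
        if cfg.force_intervention:
            for a in aco:
                a.behavior_k = 1
        self.hosp_beh = np.array([a.behavior_k for a in aco[:cfg.n_hospitals]], dtype=np.int8)
        self.pcp_beh = np.array([a.behavior_k for a in aco[cfg.n_hospitals:]], dtype=np.int8)

    def _init_mortality_tables(self) -> None:
        c = self.cfg.clinical
        horizon = self.cfg.years * self.cfg.cycles_per_year + 2
        t = np.arange(horizon)
        self.mort_out = c.cycle_mortality("outpatient").prob(t)
        self.mort_in = c.cycle_mortality("inpatient").prob(t)
        self.bg_mort = c.background_mortality  # (age group, gender), per cycle

    # -- yearly bookkeeping -------------------------------------------------

    def _reset_year_counters(self) -> None:
        n = self.cfg.n_patients
        self.admissions_year = np.zeros(n, dtype=np.int16)
        self.chf_year = np.zeros(n, dtype=bool)
        self.died_year = np.zeros(n, dtype=bool)
        self.visits_year = np.zeros(n, dtype=np.int32)
        for net in NETWORKS:
            for a in self.roster[net]:
                a.reset_year_counters()

    # -- one 15-day cycle ---------------------------------------------------

    def _patient_behaviors(self) -> tuple[np.ndarray, np.ndarray]:
        """Current behavior of each patient's home hospital and PCP (0 off-network)."""
        aco = self.network == 0
        h = np.where(aco, self.hosp_beh[self.hosp_idx], 0).astype(np.int8)
        p = np.where(aco, self.pcp_beh[self.pcp_idx], 0).astype(np.int8)
        return h, p

    def step_cycle(self) -> None:
        cfg = self.cfg
        c = cfg.clinical
        n = cfg.n_patients
        rng = self.rng_dis
        alive = self.state < HealthState.DEAD

        # patients with CHF at any point this year count toward the settlement
        self.chf_year |= alive & (self.dx_source > 0)

        # intervention status: current behaviors of the patient's hospital and PCP;
        # full effect needs both, a single intervening party achieves the partial fraction
        beh_h, beh_p = self._patient_behaviors()
        level = beh_h + beh_p
        scale = np.choose(level, [0.0, c.partial_effect_fraction, 1.0])
        rrh = scale * c.rr_hosp
        rrm = scale * c.rr_mort

        u = rng.random(n)
        new_state = self.state.copy()
        died = np.zeros(n, dtype=bool)
        admitted = np.zeros(n, dtype=bool)
        onset_out = np.zeros(n, dtype=bool)
        onset_in = np.zeros(n, dtype=bool)
        discharged = np.zeros(n, dtype=bool)

        # CHF-free patients: background mortality, risk-adjusted CHF onset
        free = alive & (self.state == HealthState.CHF_FREE)
        if free.any():
            p_d = self.bg_mort[self.age_group0, self.gender]
            p_chf = (c.chf_incidence_base
                     * np.asarray(c.incidence_age_multipliers)[self.age_group0])
            p_chf = np.where(self.diab, p_chf * c.incidence_diabetes_multiplier, p_chf)
            p_chf = np.where(self.hyp, p_chf * c.incidence_hypertension_multiplier, p_chf)
            died |= free & (u < p_d)
            onset_in = free & ~died & (u < p_d + p_chf * c.p_incidence_inpatient)
            onset_out = free & ~died & ~onset_in & (u < p_d + p_chf)

        # CHF patients: survival-curve mortality by diagnosis source and time since onset
        chf_alive = alive & (self.state >= HealthState.CHF_ONSITE)
        t_onset = np.clip(self.cycle - self.onset_cycle - 1, 0, len(self.mort_out) - 1)
        p_mort = np.where(self.dx_source == 2, self.mort_in[t_onset], self.mort_out[t_onset])
        p_mort = p_mort * (1.0 - rrm)
        if c.chf_mortality_mode == "add":
            p_mort = np.minimum(1.0, p_mort + self.bg_mort[self.age_group0, self.gender])

        onsite = alive & (self.state == HealthState.CHF_ONSITE)
        if onsite.any():
            p_h = np.asarray(c.hosp_prob_by_age)[self.age_group0] * (1.0 - rrh)
            died |= onsite & (u < p_mort)
            admitted |= onsite & ~died & (u < p_mort + p_h)

        inhosp = alive & (self.state == HealthState.CHF_HOSPITALIZED)
        if inhosp.any():
            died |= inhosp & (u < p_mort)
            discharged = inhosp & ~died

        admitted |= onset_in

        # apply state changes
        new_state[died] = HealthState.DEAD
        new_state[admitted] = HealthState.CHF_HOSPITALIZED
        new_state[onset_out] = HealthState.CHF_ONSITE
        new_state[discharged] = HealthState.CHF_ONSITE
        onset = onset_in | onset_out
        self.dx_source[onset_in] = 2
        self.dx_source[onset_out] = 1
        self.onset_cycle[onset] = self.cycle
        self.chf_year |= onset
        self.died_year |= died
        self.state = new_state

        # comorbidity incidence (chronic flags are monotone)
        survivors = self.state < HealthState.DEAD
        new_diab = survivors & ~self.diab & (rng.random(n) < c.diabetes_incidence)
        p_hyp_inc = np.asarray(c.hypertension_incidence_by_race)[self.race]
        new_hyp = survivors & ~self.hyp & (rng.random(n) < p_hyp_inc)
        self.diab |= new_diab
        self.hyp |= new_hyp

        # admissions bookkeeping (admitting hospital = home hospital)
        self.admissions_year[admitted] += 1
        for net_code in (0, 1):
            mask = admitted & (self.network == net_code)
            np.add.at(self.adm_by_hosp[net_code], self.hosp_idx[mask], 1)

        # discharge interactions (ACO only): hospital and PCP communicate and observe
        # whether the counterpart conducts the intervention
        d_aco = discharged & (self.network == 0)
        if d_aco.any():
            h_ids = self.hosp_idx[d_aco]
            p_ids = self.pcp_idx[d_aco]
            np.add.at(self.ti_h, h_ids, 1)
            np.add.at(self.ti_p, p_ids, 1)
            np.add.at(self.ni_h, h_ids, beh_p[d_aco])
            np.add.at(self.ni_p, p_ids, beh_h[d_aco])

        # outpatient visits: regular Poisson process plus intervention follow-up
        visits = np.zeros(n, dtype=np.int64)
        ambulatory = (self.state == HealthState.CHF_FREE) | (self.state == HealthState.CHF_ONSITE)
        visits[ambulatory] = rng.poisson(c.visit_rate_per_cycle, ambulatory.sum())
        followup = self.followup_due & (self.state != HealthState.DEAD)
        visits[followup] += 1
        self.followup_due = discharged & (beh_p == 1)
        self.visits_year += visits

        chf_patient = self.dx_source > 0
        for net_code in (0, 1):
            mask = self.network == net_code
            self.chf_visits[net_code] += int(visits[mask & chf_patient].sum())
            np.add.at(self.visits_by_pcp[net_code], self.pcp_idx[mask], visits[mask])

        # provider message passing (ACO network only; controlled agents never decide)
        if not cfg.force_intervention and cfg.payment.model == "shared_saving":
            prov.exchange_messages(self.roster["ACO"], self.rng_beh)

        self.cycle += 1

    # -- one simulation year ------------------------------------------------

    def run_year(self) -> dict:
        """Run 24 cycles, settle the shared saving, and run provider decisions."""
        cfg = self.cfg
        self._reset_year_counters()
        self.adm_by_hosp = np.zeros((2, cfg.n_hospitals), dtype=np.int64)
        self.visits_by_pcp = np.zeros((2, cfg.n_pcps), dtype=np.int64)
        self.chf_visits = np.zeros(2, dtype=np.int64)
        self.ti_h = np.zeros(cfg.n_hospitals, dtype=np.int64)
        self.ni_h = np.zeros(cfg.n_hospitals, dtype=np.int64)
        self.ti_p = np.zeros(cfg.n_pcps, dtype=np.int64)
        self.ni_p = np.zeros(cfg.n_pcps, dtype=np.int64)

        for _ in range(cfg.cycles_per_year):
            self.step_cycle()

        report = self._settle_and_report()
        self._provider_decisions(report)
        self._age_cohort()
        self.year += 1
        self.reports.append(report)
        return report

    def _network_metrics(self, net_code: int) -> dict:
        cfg = self.cfg
        mask = self.network == net_code
        chf = self.chf_year & mask
        n_chf = int(chf.sum())
        adm = int(self.adm_by_hosp[net_code].sum())
        deaths = int((self.died_year & chf).sum())
        cost = adm * cfg.costs.payer_cost_per_admission \
            + self.chf_visits[net_code] * cfg.costs.outpatient_reimbursement
        return {
            "n_chf": n_chf,
            "admissions": adm,
            "chf_visits": int(self.chf_visits[net_code]),
            "chf_deaths": deaths,
            "admissions_per_chf_py": adm / n_chf if n_chf else np.nan,
            "admission_share": float((self.admissions_year[chf] > 0).mean()) if n_chf else np.nan,
            "mortality": deaths / n_chf if n_chf else np.nan,
            "payer_chf_cost": float(cost),
            "cost_per_chf": cost / n_chf if n_chf else np.nan,
        }

    def _settle_and_report(self) -> dict:
        cfg = self.cfg
        aco = self._network_metrics(0)
        ctrl = self._network_metrics(1)

        settlement = None
        if (cfg.payment.model == "shared_saving"
                and aco["n_chf"] > 0 and ctrl["n_chf"] > 0):
            settlement = settle_shared_saving(
                ctrl["cost_per_chf"], aco["cost_per_chf"], aco["n_chf"], cfg.payment,
                cfg.n_hospitals, cfg.n_pcps)
        self.last_settlement = settlement

        report = {"year": self.year}
        for name, m in (("aco", aco), ("ctrl", ctrl)):
            report.update({f"{name}_{k}": v for k, v in m.items()})
        if settlement is not None:
            report.update({
                "saving_per_chf": settlement.saving_per_chf_patient,
                "shared_total": settlement.shared_saving_total,
                "hospital_pool": settlement.hospital_pool,
                "pcp_pool": settlement.pcp_pool,
                "ssp_per_chf": settlement.ssp_per_chf_patient,
                "percent_saving": settlement.percent_saving,
            })
        else:
            report.update({"saving_per_chf": 0.0, "shared_total": 0.0,
                           "hospital_pool": 0.0, "pcp_pool": 0.0,
                           "ssp_per_chf": 0.0, "percent_saving": 0.0})
        # ACO payment per CHF patient includes the shared saving distributed
        if aco["n_chf"]:
            report["aco_payment_per_chf"] = (
                aco["payer_chf_cost"] + report["shared_total"]) / aco["n_chf"]
        else:
            report["aco_payment_per_chf"] = np.nan
        report["ctrl_payment_per_chf"] = ctrl["cost_per_chf"]
        report["n_intervening_hospitals"] = int(self.hosp_beh.sum())
        report["n_intervening_pcps"] = int(self.pcp_beh.sum())
        report["alive"] = int((self.state < HealthState.DEAD).sum())
        report["dead"] = int((self.state == HealthState.DEAD).sum())
        return report

    def _provider_ledgers_and_quality(self, settlement: SavingsReport | None) -> None:
        cfg = self.cfg
        for net_code, net in enumerate(NETWORKS):
            roster = self.roster[net]
            mask_net = self.network == net_code
            chf_net = self.chf_year & mask_net
            for j, agent in enumerate(roster):
                if agent.kind == "hospital":
                    own = chf_net & (self.hosp_idx == j)
                    adm = int(self.adm_by_hosp[net_code][j])
                    service = adm * cfg.costs.hospital_net_per_admission
                    share = settlement.hospital_share_each \
                        if (settlement and net_code == 0) else 0.0
                else:
                    p = j - cfg.n_hospitals
                    own = chf_net & (self.pcp_idx == p)
                    service = int(self.visits_by_pcp[net_code][p]) * cfg.costs.pcp_net_per_visit
                    share = settlement.pcp_share_each \
                        if (settlement and net_code == 0) else 0.0
                n_own = int(own.sum())
                # an intervening provider enrolls every CHF patient on its own panel
                enrolled = n_own if agent.behavior_k else 0
                cost_int = annual_intervention_cost(agent.kind, enrolled, cfg.costs)
                adm_own = int(self.admissions_year[own].sum())
                deaths_own = int((self.died_year & own).sum())
                agent.ledger[self.year] = {
                    "service_profit": float(service),
                    "intervention_cost": float(cost_int),
                    "shared_saving": float(share),
                    "profit": float(service - cost_int + share),
                    "n_own_chf": n_own,
                    "n_enrolled": enrolled,
                }
                agent.quality_stats[self.year] = {
                    "admissions_per_chf_py": adm_own / n_own if n_own else 0.0,
                    "mortality": deaths_own / n_own if n_own else 0.0,
                }

    def _expected_saving_share(self, agent_kind: str, n_own_chf: int,
                               adm_rate: float, n_chf_aco: int) -> float:
        """Naive prospective shared-saving share per own CHF patient under k = 1.

        The agent assumes the network-wide intervention succeeds: the saving is the
        avoided hospitalization spending (full risk reduction applied to the observed
        admission rate), of which it receives its equal within-type share.
        """
        cfg = self.cfg
        if cfg.payment.model != "shared_saving" or n_own_chf == 0:
            return 0.0
        c = cfg.clinical
        saving_total = (c.rr_hosp * adm_rate * cfg.costs.payer_cost_per_admission
                        * n_chf_aco)
        pool = cfg.payment.ssr * saving_total
        if agent_kind == "hospital":
            share = pool * cfg.payment.srh / cfg.n_hospitals
        else:
            share = pool * (1.0 - cfg.payment.srh) / cfg.n_pcps
        return share / n_own_chf

    def _provider_decisions(self, report: dict) -> None:
        cfg = self.cfg
        self._provider_ledgers_and_quality(self.last_settlement)
        if cfg.force_intervention or cfg.payment.model != "shared_saving":
            self._refresh_behavior_arrays()
            return

        # write vectorized interaction counts back onto the ACO agents
        aco = self.roster["ACO"]
        for j in range(cfg.n_hospitals):
            aco[j].ni, aco[j].ti = int(self.ni_h[j]), int(self.ti_h[j])
        for p in range(cfg.n_pcps):
            a = aco[cfg.n_hospitals + p]
            a.ni, a.ti = int(self.ni_p[p]), int(self.ti_p[p])

        n_chf_aco = report["aco_n_chf"]
        adm_rate = report["aco_admissions_per_chf_py"]
        if not np.isfinite(adm_rate):
            adm_rate = 0.0

        for agent in aco:
            led = agent.ledger[self.year]
            q = agent.quality_stats[self.year]
            n_own = led["n_own_chf"]
            prior = prov.PriorYearObservation(
                profit_per_chf_patient=led["service_profit"] / n_own if n_own else 0.0,
                admission_rate=q["admissions_per_chf_py"],
                mortality_rate=q["mortality"],
            )
            forecast = self._expected_saving_share(agent.kind, n_own, adm_rate, n_chf_aco)
            if agent.kind == "hospital":
                cost_int = cfg.costs.hospital_intervention_cost_per_patient_year
                margin = cfg.costs.hospital_net_per_admission
            else:
                cost_int = cfg.costs.pcp_intervention_cost_per_patient_year
                margin = 0.0
            (ep0, ep1), (eq0, eq1) = prov.estimate_expectations(
                agent, prior, forecast, cost_int,
                cfg.clinical.rr_hosp, cfg.clinical.rr_mort, margin_per_admission=margin)

            a0 = prov.compute_attitude(
                prov.utility_profit(ep0, cfg.profit_utility_scale),
                prov.utility_quality(*eq0, cfg.quality_bounds), agent.beta)
            a1 = prov.compute_attitude(
                prov.utility_profit(ep1, cfg.profit_utility_scale),
                prov.utility_quality(*eq1, cfg.quality_bounds), agent.beta)
            sn0, sn1 = prov.compute_subjective_norm(tuple(agent.messages_received))
            pbc0, pbc1 = prov.compute_pbc(agent.ni, agent.ti, prev=agent.pbc_prev)
            i0 = prov.compute_intention(a0, sn0, pbc0, cfg.intention_weights)
            i1 = prov.compute_intention(a1, sn1, pbc1, cfg.intention_weights)
            k = prov.choose_behavior(i0, i1, cfg.tau, self.rng_beh)

            agent.tpb = prov.TPBState(
                attitude=(a0, a1), subjective_norm=(sn0, sn1), pbc=(pbc0, pbc1),
                intention=(i0, i1), choice_probability=prov.choice_probability(i0, i1, cfg.tau),
                tau=cfg.tau)
            self.trace_rows.append({
                "year": self.year, "agent": agent.id, "kind": agent.kind,
                "beta1": agent.beta[0], "A0": a0, "A1": a1, "SN1": sn1,
                "PBC1": pbc1, "I0": i0, "I1": i1, "k_next": k,
            })
            agent.attitude_favored = int(a1 > a0)
            agent.pbc_prev = pbc1
            agent.behavior_k = k
        self._refresh_behavior_arrays()

    def _age_cohort(self) -> None:
        alive = self.state < HealthState.DEAD
        self.age[alive] += 1
        self.age_group0 = self.age_group0_from_age(self.age)

    # -- full run -----------------------------------------------------------

    def run(self) -> SimulationResult:
        for _ in range(self.cfg.years):
            self.run_year()
        per_year = pd.DataFrame(self.reports)
        trace = pd.DataFrame(self.trace_rows)
        return SimulationResult(per_year=per_year, provider_trace=trace,
                                summary=summarize_run(per_year))


#: Outcome columns averaged over simulation years in the run summary.
SUMMARY_COLUMNS = (
    "aco_admissions_per_chf_py", "ctrl_admissions_per_chf_py",
    "aco_admission_share", "ctrl_admission_share",
    "aco_mortality", "ctrl_mortality",
    "aco_payment_per_chf", "ctrl_payment_per_chf",
    "saving_per_chf", "ssp_per_chf", "percent_saving",
    "n_intervening_hospitals", "n_intervening_pcps",
)


def summarize_run(per_year: pd.DataFrame) -> dict:
    """Mean over simulation years of the headline outcomes of one run."""
    return {col: float(per_year[col].mean()) for col in SUMMARY_COLUMNS}


def run_simulation(cfg: SimulationConfig, seed: int) -> SimulationResult:
    """One deterministic simulation run of ``cfg.years`` years for a given seed."""
    return Simulation(cfg, seed).run()


@dataclass
class ReplicationSummary:
    """Mean and 95% confidence interval of each outcome over replications."""

    table: pd.DataFrame        # index: outcome; columns: mean, sd, ci_lo, ci_hi
    replicates: pd.DataFrame   # one row per replication
    n_replications: int

    def mean(self, outcome: str) -> float:
        return float(self.table.loc[outcome, "mean"])

    def ci(self, outcome: str) -> tuple[float, float]:
        row = self.table.loc[outcome]
        return float(row["ci_lo"]), float(row["ci_hi"])


def _rep_seed(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def run_replications(
    cfg: SimulationConfig,
    n_reps: int,
    seed: int,
    ci_method: str = "normal",
    show_progress: bool = False,
) -> ReplicationSummary:
    """Monte-Carlo replications: mean and 95% CI of each outcome.

    The normal-approximation interval is ``mean ± 1.96 sd / sqrt(n)``; a percentile
    bootstrap (2000 resamples) is available via ``ci_method='bootstrap'``.
    """
    if n_reps < 2:
        raise EngineError("at least 2 replications are required for a CI")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    iterator = range(n_reps)
    if show_progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="replications")
        except ImportError:
            pass
    rows = []
    for i in iterator:
        res = run_simulation(cfg, _rep_seed(children[i]))
        rows.append(res.summary)
    reps = pd.DataFrame(rows)
    table = summarize_replicates(reps, ci_method=ci_method)
    return ReplicationSummary(table=table, replicates=reps, n_replications=n_reps)


def summarize_replicates(reps: pd.DataFrame, ci_method: str = "normal",
                         n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-outcome mean, sd, and 95% CI over a table of replication summaries."""
    n = len(reps)
    mean = reps.mean()
    sd = reps.std(ddof=1)
    if ci_method == "normal":
        half = 1.96 * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.stack([reps.to_numpy()[i].mean(axis=0) for i in idx])
        lo = pd.Series(np.percentile(boots, 2.5, axis=0), index=reps.columns)
        hi = pd.Series(np.percentile(boots, 97.5, axis=0), index=reps.columns)
    else:
        raise EngineError(f"unknown ci_method {ci_method!r}")
    return pd.DataFrame({"mean": mean, "sd": sd, "ci_lo": lo, "ci_hi": hi})
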