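"""Payer-side accounting: fee-for-service cash flows and the shared-saving settlement.

The payer reimburses CHF-related services under fee-for-service in both provider
networks.  At the end of each simulation year the per-CHF-patient cost of the ACO
network is compared with that of the controlled network; the difference (floored at
zero) is the saving per CHF patient.  A fraction SSR of the total saving is returned
to ACO providers, split between hospitals and PCP clinics by SRH and distributed
equally within each provider type.  The remainder is the shared saving to payer (SSP).

All dollar amounts are USD (2011).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class PaymentError(ValueError):
    """Raised for malformed cost schedules, payment configs, or settlement inputs."""


@dataclass
class CostSchedule:
    """Per-event and per-patient-year cash flows.

    ``hosp_reimbursement`` is the payer's payment to the hospital for one CHF-related
    admission; the hospital's net margin on that admission is ``hospital_net_per_admission``
    (negative: Medicare CHF admissions run at a loss).  The inpatient physician fee is a
    fixed fraction of the hospital reimbursement and is paid by the payer to (unmodeled)
    inpatient physicians.  A PCP clinic keeps ``1 - pcp_operating_cost_fraction`` of the
    outpatient visit reimbursement.

    The intervention (comprehensive discharge planning with post-discharge follow-up)
    has a pooled cost of ``intervention_pooled_monthly`` per patient-month over a
    ``intervention_months``-long program; its effects last ``effect_months``, so the
    amortized cost is ``intervention_pooled_monthly * intervention_months / effect_months``
    per patient-month.  The PCP-side cost is the opportunity cost of care-manager
    communication, one standard visit slot per patient-year.
    """

    hosp_reimbursement: float = 14_822.0
    hospital_net_per_admission: float = -1_186.0
    physician_fee_fraction_of_hosp: float = 0.18
    outpatient_reimbursement: float = 85.0
    pcp_operating_cost_fraction: float = 0.60
    intervention_pooled_monthly: float = 108.0
    intervention_months: float = 6.0
    effect_months: float = 12.0
    pcp_intervention_cost_per_patient_year: float = 69.0

    @property
    def inpatient_physician_fee(self) -> float:
        """Payer's inpatient physician payment per admission (rounded to whole USD)."""
        return round(self.physician_fee_fraction_of_hosp * self.hosp_reimbursement)

    @property
    def pcp_net_per_visit(self) -> float:
        """PCP net income per outpatient visit after operating costs (whole USD)."""
        return round((1.0 - self.pcp_operating_cost_fraction) * self.outpatient_reimbursement)

    @property
    def intervention_monthly_amortized(self) -> float:
        """Intervention cost per patient per month, amortized over the effect window."""
        return self.intervention_pooled_monthly * self.intervention_months / self.effect_months

    @property
    def hospital_intervention_cost_per_patient_year(self) -> float:
        """Hospital-side intervention cost per enrolled patient per year."""
        return self.intervention_monthly_amortized * 12.0

    @property
    def payer_cost_per_admission(self) -> float:
        """Payer outflow per CHF-related admission (hospital service + physician fee)."""
        return self.hosp_reimbursement + self.inpatient_physician_fee

    def validate(self) -> None:
        if not 0.0 <= self.pcp_operating_cost_fraction <= 1.0:
            raise PaymentError("pcp_operating_cost_fraction must be in [0, 1]")
        if not 0.0 <= self.physician_fee_fraction_of_hosp <= 1.0:
            raise PaymentError("physician_fee_fraction_of_hosp must be in [0, 1]")
        for name in ("hosp_reimbursement", "outpatient_reimbursement",
                     "intervention_pooled_monthly", "intervention_months", "effect_months",
                     "pcp_intervention_cost_per_patient_year"):
            if getattr(self, name) < 0:
                raise PaymentError(f"{name} must be non-negative")


def default_cost_schedule() -> CostSchedule:
    return CostSchedule()


@dataclass
class PaymentConfig:
    """Payment model for the ACO network.

    ``ssr`` (shared saving rate): fraction of the total saving awarded to providers.
    ``srh`` (sharing rate to hospital): fraction of the shared saving that goes to
    hospital agents; PCP clinics receive the remainder.
    """

    model: str = "shared_saving"  # "shared_saving" | "ffs"
    ssr: float = 0.5
    srh: float = 0.7

    def validate(self) -> None:
        if self.model not in ("shared_saving", "ffs"):
            raise PaymentError(f"unknown payment model {self.model!r}")
        if not 0.0 <= self.ssr <= 1.0:
            raise PaymentError("ssr must be in [0, 1]")
        if not 0.0 <= self.srh <= 1.0:
            raise PaymentError("srh must be in [0, 1]")


@dataclass
class SavingsReport:
    """Outcome of one annual shared-saving settlement."""

    controlled_cost_per_chf_patient: float
    aco_cost_per_chf_patient: float
    n_chf_aco: int
    saving_per_chf_patient: float
    shared_saving_total: float
    hospital_pool: float
    pcp_pool: float
    hospital_share_each: float
    pcp_share_each: float
    ssp_per_chf_patient: float
    percent_saving: float


def reimburse_event(event: str, schedule: CostSchedule) -> dict[str, float]:
    """Cash flows triggered by one clinical event, keyed by agent.

    ``payer`` is the payer's net flow (negative = outflow); ``hospital`` and ``pcp``
    are the provider nets after their operating costs.
    """
    if event == "hospitalization":
        return {
            "payer": -schedule.payer_cost_per_admission,
            "hospital": schedule.hospital_net_per_admission,
            "pcp": 0.0,
        }
    if event == "visit":
        return {
            "payer": -schedule.outpatient_reimbursement,
            "hospital": 0.0,
            "pcp": schedule.pcp_net_per_visit,
        }
    raise PaymentError(f"unknown event type {event!r}")


def annual_intervention_cost(kind: str, n_enrolled: int, schedule: CostSchedule) -> float:
    """Annual intervention cost borne by one provider for ``n_enrolled`` patients."""
    if n_enrolled < 0:
        raise PaymentError("n_enrolled must be non-negative")
    if kind == "hospital":
        return schedule.hospital_intervention_cost_per_patient_year * n_enrolled
    if kind == "pcp":
        return schedule.pcp_intervention_cost_per_patient_year * n_enrolled
    raise PaymentError(f"unknown provider kind {kind!r}")


def compute_network_cost_per_chf_patient(payer_chf_outflow: float, n_chf: int) -> float:
    """Payer's CHF-related cost per CHF patient served during the year.

    ``payer_chf_outflow`` is the total payer spending attributable to CHF patients
    (admissions, their outpatient visits, and any shared saving already distributed),
    as a positive number.
    """
    if n_chf <= 0:
        raise PaymentError("cost per CHF patient is undefined for n_chf = 0")
    if payer_chf_outflow < 0:
        raise PaymentError("payer outflow must be non-negative")
    return payer_chf_outflow / n_chf


def settle_shared_saving(
    controlled_cost: float,
    aco_cost: float,
    n_chf_aco: int,
    cfg: PaymentConfig,
    n_hospitals: int = 3,
    n_pcps: int = 15,
) -> SavingsReport:
    """Annual shared-saving settlement between the payer and the ACO network.

    The saving per CHF patient is the controlled-vs-ACO cost difference, floored at
    zero (no saving if the ACO network is more expensive).  A fraction SSR of the
    total saving is shared; SRH of the shared pool goes to hospitals, split equally,
    and the rest to PCP clinics, split equally.  ``ssp_per_chf_patient`` is the saving
    the payer retains per CHF patient, and ``percent_saving`` expresses it relative to
    the controlled network's per-patient payment.
    """
    if controlled_cost < 0 or aco_cost < 0:
        raise PaymentError("network costs must be non-negative")
    if n_chf_aco < 0:
        raise PaymentError("n_chf_aco must be non-negative")
    cfg.validate()

    saving_pp = max(0.0, controlled_cost - aco_cost)
    if cfg.model == "ffs":
        saving_pp = 0.0
    shared_total = cfg.ssr * saving_pp * n_chf_aco
    hospital_pool = shared_total * cfg.srh
    pcp_pool = shared_total - hospital_pool
    ssp_pp = saving_pp * (1.0 - cfg.ssr)
    percent = 100.0 * ssp_pp / controlled_cost if controlled_cost > 0 else 0.0
    return SavingsReport(
        controlled_cost_per_chf_patient=controlled_cost,
        aco_cost_per_chf_patient=aco_cost,
        n_chf_aco=n_chf_aco,
        saving_per_chf_patient=saving_pp,
        shared_saving_total=shared_total,
        hospital_pool=hospital_pool,
        pcp_pool=pcp_pool,
        hospital_share_each=hospital_pool / n_hospitals if n_hospitals else 0.0,
        pcp_share_each=pcp_pool / n_pcps if n_pcps else 0.0,
        ssp_per_chf_patient=ssp_pp,
        percent_saving=percent,
    )
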