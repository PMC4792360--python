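"""Patient disease-progression model on a half-month (15-day) cycle.

A Medicare patient agent occupies one of four states: CHF-free, CHF on-site
(diagnosed, in the community), CHF-related hospitalization, or dead (absorbing;
the agent is removed from the simulation).  Per-cycle transition probabilities are
risk-adjusted by the patient's characteristics and reduced when the patient is under
the CHF intervention (comprehensive discharge planning with post-discharge follow-up).

Mortality of CHF patients follows one of two all-cause survival curves keyed to the
diagnosis setting (outpatient vs inpatient first diagnosis), converted to per-cycle
probabilities by piecewise-exponential interpolation.  Non-CHF patients face
life-table background mortality.  Regular outpatient visits are a Poisson process;
an intervening PCP additionally schedules one follow-up visit in the cycle after a
hospital discharge.

Conventions: a simulation year is 24 cycles of 15 days (360 days); survival-curve
knot times and the visit rate are annualized on that basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .population import GENDERS, N_AGE_GROUPS, RACES, PatientProfile


class DiseaseError(ValueError):
    """Raised for invalid clinical parameters or illegal patient operations."""


class HealthState(IntEnum):
    CHF_FREE = 0
    CHF_ONSITE = 1
    CHF_HOSPITALIZED = 2
    DEAD = 3


@dataclass
class SurvivalCurve:
    """All-cause survival proportions for CHF patients at knot times since onset."""

    times_days: np.ndarray  # increasing, starting at 0
    survival: np.ndarray    # non-increasing, starting at 1.0

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)

    def validate(self, cycle_days: float | None = None) -> None:
        t, s = self.times_days, self.survival
        if t.shape != s.shape or t.ndim != 1 or len(t) < 2:
            raise DiseaseError("survival curve needs matching 1-d time/survival arrays")
        if t[0] != 0 or s[0] != 1.0:
            raise DiseaseError("survival curve must start at (0 days, 1.0)")
        if np.any(np.diff(t) <= 0):
            raise DiseaseError("survival curve times must be strictly increasing")
        if np.any(np.diff(s) > 0):
            raise DiseaseError("survival curve has an increasing segment")
        if np.any(s <= 0):
            raise DiseaseError("survival proportions must be positive")
        if cycle_days is not None and np.any(np.mod(t, cycle_days) != 0):
            raise DiseaseError("survival knots must align with cycle boundaries")


@dataclass
class CycleMortality:
    """Per-cycle death probabilities by whole cycles since CHF onset."""

    per_cycle: np.ndarray  # index = cycles since onset, up to the last knot
    tail: float            # constant hazard continuation beyond the last knot

    def prob(self, cycles_since_onset):
        """Vectorized lookup; times beyond the last knot use the tail probability."""
        t = np.asarray(cycles_since_onset)
        idx = np.clip(t, 0, len(self.per_cycle) - 1)
        out = np.where(t < len(self.per_cycle), self.per_cycle[idx], self.tail)
        return out if out.ndim else float(out)


def cycle_hazards_from_survival(curve: SurvivalCurve, cycle_days: float = 15.0) -> CycleMortality:
    """Convert a knotted survival curve to per-cycle death probabilities.

    Within each knot interval the hazard is constant:
    ``lambda_i = -ln(S_{i+1}/S_i) / (t_{i+1} - t_i)``; the per-cycle probability is
    ``1 - exp(-lambda_i * cycle_days)``.  Composing per-cycle survival over the cycles
    spanning an interval reproduces the tabulated knot values exactly.  Beyond the last
    knot the final interval's hazard continues.
    """
    curve.validate(cycle_days)
    t, s = curve.times_days, curve.survival
    hazards = -np.log(s[1:] / s[:-1]) / np.diff(t)  # per day, one per interval
    n_cycles = int(t[-1] / cycle_days)
    per_cycle = np.empty(n_cycles)
    interval = np.searchsorted(t[1:], np.arange(n_cycles) * cycle_days, side="right")
    per_cycle[:] = 1.0 - np.exp(-hazards[interval] * cycle_days)
    tail = 1.0 - np.exp(-hazards[-1] * cycle_days)
    return CycleMortality(per_cycle=per_cycle, tail=tail)


@dataclass
class InterventionStatus:
    """Which side(s) of a patient's care team conduct the CHF intervention."""

    hospital_intervenes: bool = False
    pcp_intervenes: bool = False


@dataclass
class TransitionParameters:
    """Clinical inputs of the state-transition model, on the per-cycle scale.

    Hospitalization probabilities from the CHF-diagnosed state are per-cycle by age
    group (65-74 = groups 1-2, 75-84 = groups 3-4, >=85 = group 5).  ``rr_hosp`` and
    ``rr_mort`` are the full-effect relative risk reductions of the intervention on
    CHF hospitalization and mortality; when only one of the hospital/PCP pair
    intervenes, both reductions are scaled by ``partial_effect_fraction``.
    """

    cycle_days: float = 15.0
    cycles_per_year: int = 24

    # CHF onset (from the CHF-free state)
    chf_incidence_base: float = 4.1880e-4           # per cycle, age group 1, no comorbidity
    incidence_age_multipliers: tuple = (1.0, 1.4, 1.9, 2.6, 3.5)
    incidence_diabetes_multiplier: float = 1.5
    incidence_hypertension_multiplier: float = 1.8
    p_incidence_inpatient: float = 0.5              # share of onsets diagnosed in hospital

    # CHF-diagnosed state -> hospitalization, per cycle by age group 1..5
    hosp_prob_by_age: tuple = (0.01663, 0.01663, 0.02360, 0.02360, 0.03489)

    # CHF mortality: survival proportions since onset by diagnosis source
    survival_outpatient: SurvivalCurve = field(default_factory=lambda: SurvivalCurve(
        np.array([0.0, 30.0, 360.0, 1800.0]), np.array([1.00, 0.98, 0.87, 0.49])))
    survival_inpatient: SurvivalCurve = field(default_factory=lambda: SurvivalCurve(
        np.array([0.0, 30.0, 360.0, 1800.0]), np.array([1.00, 0.84, 0.66, 0.33])))
    chf_mortality_mode: str = "replace"             # "replace" | "add" background mortality

    # per-cycle background mortality, shape (age group 1..5, gender) — see defaults below
    background_mortality: np.ndarray | None = None

    # comorbidity incidence, per cycle
    diabetes_incidence: float = 6.2946e-4
    hypertension_incidence_by_race: tuple = (1.4837e-3, 1.9164e-3, 1.7004e-3)

    # intervention effects
    rr_hosp: float = 0.20
    rr_mort: float = 0.13
    partial_effect_fraction: float = 0.5

    # outpatient utilization
    visit_rate_per_year: float = 9.0

    _mortality_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.background_mortality is None:
            self.background_mortality = default_background_mortality(self.cycles_per_year)
        self.background_mortality = np.asarray(self.background_mortality, dtype=float)

    def validate(self) -> None:
        probs = [self.chf_incidence_base, self.p_incidence_inpatient,
                 self.diabetes_incidence, self.rr_hosp, self.rr_mort,
                 self.partial_effect_fraction,
                 *self.hosp_prob_by_age, *self.hypertension_incidence_by_race]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise DiseaseError("all probabilities must lie in [0, 1]")
        if len(self.hosp_prob_by_age) != N_AGE_GROUPS:
            raise DiseaseError("hosp_prob_by_age needs one entry per age group")
        if self.background_mortality.shape != (N_AGE_GROUPS, len(GENDERS)):
            raise DiseaseError("background_mortality must have shape (age groups, genders)")
        if np.any(self.background_mortality < 0) or np.any(self.background_mortality > 1):
            raise DiseaseError("background mortality probabilities must lie in [0, 1]")
        if len(self.hypertension_incidence_by_race) != len(RACES):
            raise DiseaseError("hypertension incidence needs one entry per race")
        if self.chf_mortality_mode not in ("replace", "add"):
            raise DiseaseError(f"unknown chf_mortality_mode {self.chf_mortality_mode!r}")
        if self.visit_rate_per_year < 0:
            raise DiseaseError("visit_rate_per_year must be non-negative")
        self.survival_outpatient.validate(self.cycle_days)
        self.survival_inpatient.validate(self.cycle_days)

    def cycle_mortality(self, dx_source: str) -> CycleMortality:
        """Per-cycle CHF mortality table for a diagnosis source ('outpatient'|'inpatient')."""
        if dx_source not in self._mortality_cache:
            curve = {"outpatient": self.survival_outpatient,
                     "inpatient": self.survival_inpatient}.get(dx_source)
            if curve is None:
                raise DiseaseError(f"unknown diagnosis source {dx_source!r}")
            self._mortality_cache[dx_source] = cycle_hazards_from_survival(curve, self.cycle_days)
        return self._mortality_cache[dx_source]

    @property
    def visit_rate_per_cycle(self) -> float:
        return self.visit_rate_per_year / self.cycles_per_year


def per_cycle_from_annual(annual: float, cycles_per_year: int = 24) -> float:
    """Per-cycle probability equivalent to an annual probability under a constant hazard."""
    return 1.0 - (1.0 - annual) ** (1.0 / cycles_per_year)


def default_background_mortality(cycles_per_year: int = 24) -> np.ndarray:
    """Per-cycle all-cause mortality for non-CHF patients by age group and gender.

    Annual probabilities are stylized US life-table values for ages 65+ (male, female
    columns); see the fixture notes in the population module.
    """
    annual = np.array([
        [0.020, 0.014],   # 65-69
        [0.030, 0.021],   # 70-74
        [0.046, 0.033],   # 75-79
        [0.072, 0.053],   # 80-84
        [0.150, 0.130],   # 85+
    ])
    return per_cycle_from_annual(annual, cycles_per_year)


def default_transition_parameters() -> TransitionParameters:
    return TransitionParameters()


@dataclass
class PatientState:
    """A patient's current position in the transition model."""

    profile: PatientProfile
    health: HealthState
    cycles_since_onset: int = 0  # meaningful only once CHF is diagnosed

    @classmethod
    def initial(cls, profile: PatientProfile) -> "PatientState":
        health = HealthState.CHF_ONSITE if profile.has_chf else HealthState.CHF_FREE
        return cls(profile=profile, health=health, cycles_since_onset=0)


def effective_risk_reduction(
    status: InterventionStatus, params: TransitionParameters
) -> tuple[float, float]:
    """Relative risk reductions (hospitalization, mortality) for a patient's status.

    Full effect requires both the admitting hospital and the patient's PCP to conduct
    the intervention; a single intervening party achieves only the partial fraction.
    """
    n = int(status.hospital_intervenes) + int(status.pcp_intervenes)
    if n == 2:
        scale = 1.0
    elif n == 1:
        scale = params.partial_effect_fraction
    else:
        scale = 0.0
    return scale * params.rr_hosp, scale * params.rr_mort


def chf_incidence_probability(profile: PatientProfile, params: TransitionParameters) -> float:
    """Per-cycle risk-adjusted probability of developing CHF for a CHF-free patient."""
    if not 1 <= profile.age_group <= N_AGE_GROUPS:
        raise DiseaseError(f"unknown age group {profile.age_group}")
    p = params.chf_incidence_base * params.incidence_age_multipliers[profile.age_group - 1]
    if profile.has_diabetes:
        p *= params.incidence_diabetes_multiplier
    if profile.has_hypertension:
        p *= params.incidence_hypertension_multiplier
    return min(p, 1.0)


def comorbidity_incidence(profile: PatientProfile, params: TransitionParameters) -> tuple[float, float]:
    """Per-cycle probabilities of developing (diabetes, hypertension); zero once present."""
    p_diab = 0.0 if profile.has_diabetes else params.diabetes_incidence
    if profile.has_hypertension:
        p_hyp = 0.0
    else:
        p_hyp = params.hypertension_incidence_by_race[RACES.index(profile.race)]
    return p_diab, p_hyp


def transition_probabilities(
    state: PatientState, status: InterventionStatus, params: TransitionParameters
) -> dict[HealthState, float]:
    """Per-cycle probability vector over next health states (including staying put)."""
    profile = state.profile
    if state.health == HealthState.DEAD:
        raise DiseaseError("transition probabilities are undefined for a dead patient")
    if not 1 <= profile.age_group <= N_AGE_GROUPS:
        raise DiseaseError(f"unknown age group {profile.age_group}")
    red_h, red_m = effective_risk_reduction(status, params)
    gender_idx = GENDERS.index(profile.gender)
    probs = {s: 0.0 for s in HealthState}

    if state.health == HealthState.CHF_FREE:
        p_death = params.background_mortality[profile.age_group - 1, gender_idx]
        p_chf = chf_incidence_probability(profile, params)
        probs[HealthState.DEAD] = p_death
        probs[HealthState.CHF_HOSPITALIZED] = p_chf * params.p_incidence_inpatient
        probs[HealthState.CHF_ONSITE] = p_chf * (1.0 - params.p_incidence_inpatient)
        probs[HealthState.CHF_FREE] = 1.0 - p_death - p_chf
    else:
        mort = params.cycle_mortality(profile.chf_dx_source)
        p_death = mort.prob(state.cycles_since_onset) * (1.0 - red_m)
        if params.chf_mortality_mode == "add":
            p_death = min(1.0, p_death
                          + params.background_mortality[profile.age_group - 1, gender_idx])
        if state.health == HealthState.CHF_ONSITE:
            p_hosp = params.hosp_prob_by_age[profile.age_group - 1] * (1.0 - red_h)
            probs[HealthState.DEAD] = p_death
            probs[HealthState.CHF_HOSPITALIZED] = p_hosp
            probs[HealthState.CHF_ONSITE] = 1.0 - p_death - p_hosp
        else:  # in hospital: discharge next cycle unless the patient dies
            probs[HealthState.DEAD] = p_death
            probs[HealthState.CHF_ONSITE] = 1.0 - p_death
    return probs


def step_patient(
    state: PatientState,
    status: InterventionStatus,
    params: TransitionParameters,
    rng: np.random.Generator,
) -> tuple[PatientState, list[str]]:
    """Advance one patient by one cycle: one categorical state draw plus comorbidity draws.

    Returns the updated state and the events that occurred ("hospitalization",
    "discharge", "death", "chf_onset_outpatient", "chf_onset_inpatient",
    "new_diabetes", "new_hypertension").  Chronic conditions are incurable: the
    comorbidity and CHF flags never revert.
    """
    if state.health == HealthState.DEAD:
        raise DiseaseError("cannot step a dead patient")
    profile = state.profile
    events: list[str] = []

    probs = transition_probabilities(state, status, params)
    order = [HealthState.DEAD, HealthState.CHF_HOSPITALIZED,
             HealthState.CHF_ONSITE, HealthState.CHF_FREE]
    u = rng.random()
    cum = 0.0
    new_health = state.health
    for s in order:
        cum += probs[s]
        if u < cum:
            new_health = s
            break

    cycles_since_onset = state.cycles_since_onset
    if profile.has_chf:
        cycles_since_onset += 1

    if new_health == HealthState.DEAD:
        events.append("death")
    elif state.health == HealthState.CHF_FREE and new_health != HealthState.CHF_FREE:
        profile.has_chf = True
        profile.chf_dx_source = (
            "inpatient" if new_health == HealthState.CHF_HOSPITALIZED else "outpatient")
        events.append(f"chf_onset_{profile.chf_dx_source}")
        if new_health == HealthState.CHF_HOSPITALIZED:
            events.append("hospitalization")
        cycles_since_onset = 0
    elif state.health == HealthState.CHF_ONSITE and new_health == HealthState.CHF_HOSPITALIZED:
        events.append("hospitalization")
    elif state.health == HealthState.CHF_HOSPITALIZED and new_health == HealthState.CHF_ONSITE:
        events.append("discharge")

    if new_health != HealthState.DEAD:
        p_diab, p_hyp = comorbidity_incidence(profile, params)
        if p_diab > 0 and rng.random() < p_diab:
            profile.has_diabetes = True
            events.append("new_diabetes")
        if p_hyp > 0 and rng.random() < p_hyp:
            profile.has_hypertension = True
            events.append("new_hypertension")

    return PatientState(profile=profile, health=new_health,
                        cycles_since_onset=cycles_since_onset), events


def sample_outpatient_visits(
    state: PatientState,
    params: TransitionParameters,
    rng: np.random.Generator,
    pcp_intervenes: bool = False,
    discharged_last_cycle: bool = False,
) -> int:
    """Outpatient visits this cycle: Poisson regular visits plus intervention follow-up.

    Regular visits follow a Poisson process with annual rate ``visit_rate_per_year``
    (mean ``visit_rate_per_year / cycles_per_year`` per cycle); patients spending the
    cycle in hospital generate none.  If the patient's PCP conducts the intervention,
    one deterministic follow-up visit occurs in the cycle after a discharge.
    """
    if state.health == HealthState.DEAD:
        raise DiseaseError("cannot sample visits for a dead patient")
    visits = 0
    if state.health != HealthState.CHF_HOSPITALIZED:
        visits += int(rng.poisson(params.visit_rate_per_cycle))
    if discharged_last_cycle and pcp_intervenes:
        visits += 1
    return visits
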