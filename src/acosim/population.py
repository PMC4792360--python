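"""Synthetic Medicare patient cohorts from a conditional-probability chain.

Patient characteristics are four demographic variables (age, race, gender, income)
and three chronic health conditions (diabetes, hypertension, CHF).  Because the
variables are correlated, the joint distribution is factorized as a chain and
sampled in order:

    demographics  ->  diabetes | demographics
                  ->  hypertension | diabetes, demographics
                  ->  CHF | hypertension, diabetes, demographics

The default fixture (``make_default_population_fixture``) is an explicitly synthetic,
versioned parameterization with marginals plausible for the US Medicare 65+
population; it is not calibrated to any survey microdata and every scalar behind it
is documented below so users can substitute their own tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

N_AGE_GROUPS = 5
#: Age bands for groups 1..5: 65-74 split into groups 1-2, 75-84 into 3-4, >=85 group 5.
AGE_GROUP_BANDS = ((65, 69), (70, 74), (75, 79), (80, 84), (85, 95))
RACES = ("white", "black", "other")
GENDERS = ("male", "female")
INCOMES = ("low", "middle", "high")
DX_SOURCES = ("none", "outpatient", "inpatient")

DEMO_SHAPE = (N_AGE_GROUPS, len(RACES), len(GENDERS), len(INCOMES))


class PopulationError(ValueError):
    """Raised when a population specification is malformed or non-normalized."""


def age_group_of(age: int) -> int:
    """Age group 1..5 for an age in years (>= 65); ages beyond 85 stay in group 5."""
    if age < 65:
        raise PopulationError(f"patients must be 65 or older, got age {age}")
    for g, (lo, hi) in enumerate(AGE_GROUP_BANDS, start=1):
        if age <= hi:
            return g
    return N_AGE_GROUPS


@dataclass
class PopulationSpec:
    """Conditional-probability tables defining the joint patient distribution.

    ``demographics_table`` has shape (age group, race, gender, income) and sums to 1.
    The conditional tables share the demographic axes; hypertension adds a trailing
    diabetes axis (0/1) and CHF adds trailing diabetes and hypertension axes.
    ``p_initial_inpatient_dx`` is the probability that a prevalent (initially CHF)
    patient was first diagnosed in the inpatient setting, which selects the survival
    curve used for that patient.
    """

    demographics_table: np.ndarray                       # DEMO_SHAPE
    p_diabetes: np.ndarray                               # DEMO_SHAPE
    p_hypertension: np.ndarray                           # DEMO_SHAPE + (2,)
    p_chf: np.ndarray                                    # DEMO_SHAPE + (2, 2)
    p_initial_inpatient_dx: float = 0.5
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.demographics_table = np.asarray(self.demographics_table, dtype=float)
        self.p_diabetes = np.asarray(self.p_diabetes, dtype=float)
        self.p_hypertension = np.asarray(self.p_hypertension, dtype=float)
        self.p_chf = np.asarray(self.p_chf, dtype=float)

    def validate(self) -> None:
        if self.demographics_table.shape != DEMO_SHAPE:
            raise PopulationError(
                f"demographics_table must have shape {DEMO_SHAPE}, "
                f"got {self.demographics_table.shape}")
        if np.any(self.demographics_table < 0):
            raise PopulationError("demographics_table has negative probabilities")
        if abs(self.demographics_table.sum() - 1.0) > 1e-9:
            raise PopulationError(
                f"demographics_table must sum to 1 (got {self.demographics_table.sum()!r})")
        for name, table, shape in (
            ("p_diabetes", self.p_diabetes, DEMO_SHAPE),
            ("p_hypertension", self.p_hypertension, DEMO_SHAPE + (2,)),
            ("p_chf", self.p_chf, DEMO_SHAPE + (2, 2)),
        ):
            if table.shape != shape:
                raise PopulationError(f"{name} must have shape {shape}, got {table.shape}")
            if np.any(table < 0) or np.any(table > 1):
                raise PopulationError(f"{name} has probabilities outside [0, 1]")
        if not 0.0 <= self.p_initial_inpatient_dx <= 1.0:
            raise PopulationError("p_initial_inpatient_dx must be in [0, 1]")

    def joint_distribution(self) -> pd.DataFrame:
        """Exact joint probability of every (demographic cell, diab, hyp, chf) cell.

        Brute-force enumeration of the chain; used as the oracle for sampling checks.
        """
        rows = []
        for cell in itertools.product(*(range(n) for n in DEMO_SHAPE)):
            p_demo = self.demographics_table[cell]
            for diab, hyp, chf in itertools.product((0, 1), repeat=3):
                pd_ = self.p_diabetes[cell]
                ph = self.p_hypertension[cell + (diab,)]
                pc = self.p_chf[cell + (diab, hyp)]
                p = (p_demo
                     * (pd_ if diab else 1 - pd_)
                     * (ph if hyp else 1 - ph)
                     * (pc if chf else 1 - pc))
                rows.append({
                    "age_group": cell[0] + 1, "race": RACES[cell[1]],
                    "gender": GENDERS[cell[2]], "income": INCOMES[cell[3]],
                    "diabetes": bool(diab), "hypertension": bool(hyp), "chf": bool(chf),
                    "probability": p,
                })
        return pd.DataFrame(rows)


@dataclass
class PatientProfile:
    """Characteristics and care-network assignment of one patient agent."""

    id: int
    age: int
    age_group: int
    race: str
    gender: str
    income: str
    has_diabetes: bool
    has_hypertension: bool
    has_chf: bool
    chf_dx_source: str = "none"          # "none" | "outpatient" | "inpatient"
    network: Optional[str] = None        # "ACO" | "controlled"
    pcp_id: Optional[int] = None
    hospital_id: Optional[int] = None

    def validate(self) -> None:
        if self.age < 65:
            raise PopulationError("patient age must be >= 65")
        if self.age_group != age_group_of(self.age):
            raise PopulationError("age_group inconsistent with age")
        if (self.chf_dx_source == "none") != (not self.has_chf):
            raise PopulationError("chf_dx_source must be 'none' iff the patient has no CHF")


def sample_characteristic_arrays(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized chain sampling of ``n`` patients' characteristics (no assignment).

    Returns integer-coded arrays: age, age_group (1..5), race, gender, income,
    diabetes, hypertension, chf, dx_source (0 none / 1 outpatient / 2 inpatient).
    """
    spec.validate()
    flat = spec.demographics_table.ravel()
    cells = rng.choice(flat.size, size=n, p=flat)
    ag0, race, gender, income = np.unravel_index(cells, DEMO_SHAPE)

    diab = (rng.random(n) < spec.p_diabetes[ag0, race, gender, income]).astype(np.int8)
    hyp = (rng.random(n) < spec.p_hypertension[ag0, race, gender, income, diab]).astype(np.int8)
    chf = (rng.random(n) < spec.p_chf[ag0, race, gender, income, diab, hyp]).astype(np.int8)
    dx = np.where(chf == 1,
                  np.where(rng.random(n) < spec.p_initial_inpatient_dx, 2, 1),
                  0).astype(np.int8)

    lows = np.array([b[0] for b in AGE_GROUP_BANDS])
    highs = np.array([b[1] for b in AGE_GROUP_BANDS])
    age = lows[ag0] + rng.integers(0, highs[ag0] - lows[ag0] + 1)

    return {
        "age": age.astype(np.int16), "age_group": (ag0 + 1).astype(np.int8),
        "race": race.astype(np.int8), "gender": gender.astype(np.int8),
        "income": income.astype(np.int8), "diabetes": diab, "hypertension": hyp,
        "chf": chf, "dx_source": dx,
    }


def _profile_from_arrays(arrays: dict[str, np.ndarray], i: int, pid: int) -> PatientProfile:
    return PatientProfile(
        id=pid,
        age=int(arrays["age"][i]),
        age_group=int(arrays["age_group"][i]),
        race=RACES[arrays["race"][i]],
        gender=GENDERS[arrays["gender"][i]],
        income=INCOMES[arrays["income"][i]],
        has_diabetes=bool(arrays["diabetes"][i]),
        has_hypertension=bool(arrays["hypertension"][i]),
        has_chf=bool(arrays["chf"][i]),
        chf_dx_source=DX_SOURCES[arrays["dx_source"][i]],
    )


def sample_patient(spec: PopulationSpec, rng: np.random.Generator) -> PatientProfile:
    """Sample one patient by the conditional chain (demographics, then diabetes,
    then hypertension, then CHF)."""
    arrays = sample_characteristic_arrays(spec, 1, rng)
    return _profile_from_arrays(arrays, 0, pid=0)


def assign_networks(n: int, rng: np.random.Generator, method: str = "bernoulli") -> np.ndarray:
    """Assign patients to networks: 0 = ACO, 1 = controlled.

    "bernoulli" flips an independent fair coin per patient; "stratified" produces an
    exact (within one) 50/50 split in random order, for variance reduction.
    """
    if method == "bernoulli":
        return rng.integers(0, 2, size=n).astype(np.int8)
    if method == "stratified":
        half = n // 2
        out = np.concatenate([np.zeros(n - half, dtype=np.int8), np.ones(half, dtype=np.int8)])
        return rng.permutation(out)
    raise PopulationError(f"unknown assignment method {method!r}")


def generate_cohort(
    spec: PopulationSpec,
    n: int,
    rng: np.random.Generator,
    n_hospitals: int = 3,
    n_pcps: int = 15,
    assignment: str = "bernoulli",
) -> list[PatientProfile]:
    """Generate ``n`` patients, assign each to a network, a PCP, and a home hospital.

    Within a network every patient draws a PCP uniformly among the network's
    ``n_pcps`` PCP agents and a home hospital uniformly among its ``n_hospitals``
    hospital agents; both networks therefore serve populations with identical
    characteristics up to sampling error.
    """
    if n < 1:
        raise PopulationError("cohort size must be at least 1")
    arrays = sample_characteristic_arrays(spec, n, rng)
    network = assign_networks(n, rng, assignment)
    hosp = rng.integers(0, n_hospitals, size=n)
    pcp = rng.integers(0, n_pcps, size=n)
    cohort = []
    for i in range(n):
        p = _profile_from_arrays(arrays, i, pid=i)
        p.network = "ACO" if network[i] == 0 else "controlled"
        p.hospital_id = int(hosp[i])
        p.pcp_id = int(pcp[i])
        cohort.append(p)
    return cohort


def cohort_frame(cohort: list[PatientProfile]) -> pd.DataFrame:
    """Cohort as a tidy table, one row per patient (for CSV export)."""
    return pd.DataFrame([vars(p) for p in cohort])


# ---------------------------------------------------------------------------
# Default synthetic fixture
# ---------------------------------------------------------------------------

#: Version tag of the default synthetic population fixture.
FIXTURE_VERSION = "synthetic-v1"

#: Marginal shares of the five age groups (65-69, 70-74, 75-79, 80-84, 85+).
DEFAULT_AGE_SHARES = (0.30, 0.25, 0.20, 0.15, 0.10)
#: Race marginals (white, black, other).
DEFAULT_RACE_SHARES = (0.80, 0.10, 0.10)
#: Gender marginals (male, female).
DEFAULT_GENDER_SHARES = (0.45, 0.55)
#: Income-band marginals (low, middle, high).
DEFAULT_INCOME_SHARES = (0.30, 0.50, 0.20)

#: Diabetes prevalence by age group, plus additive race effects.
DEFAULT_DIABETES_BY_AGE = (0.20, 0.22, 0.24, 0.24, 0.22)
DEFAULT_DIABETES_RACE_SHIFT = (0.0, 0.08, 0.04)
#: Hypertension prevalence by age group, plus diabetes and race effects.
DEFAULT_HYPERTENSION_BY_AGE = (0.52, 0.56, 0.60, 0.63, 0.65)
DEFAULT_HYPERTENSION_DIABETES_SHIFT = 0.10
DEFAULT_HYPERTENSION_RACE_SHIFT = (0.0, 0.12, 0.04)
#: CHF prevalence by age group, plus diabetes and hypertension effects.
DEFAULT_CHF_BY_AGE = (0.06, 0.08, 0.10, 0.13, 0.16)
DEFAULT_CHF_DIABETES_SHIFT = 0.05
DEFAULT_CHF_HYPERTENSION_SHIFT = 0.04


def make_default_population_fixture() -> PopulationSpec:
    """Documented synthetic population fixture (version ``synthetic-v1``).

    Demographics are the product of the four marginals above (independence across
    demographic variables is a deliberate simplification).  Comorbidity conditionals
    are additive in the documented age/race/comorbidity shifts, clipped to [0, 1].
    Overall prevalences implied: diabetes ~0.24, hypertension ~0.60, CHF ~0.13 —
    plausible for Medicare beneficiaries 65+, chosen by the package authors and not
    fitted to any survey microdata.
    """
    demo = (np.array(DEFAULT_AGE_SHARES)[:, None, None, None]
            * np.array(DEFAULT_RACE_SHARES)[None, :, None, None]
            * np.array(DEFAULT_GENDER_SHARES)[None, None, :, None]
            * np.array(DEFAULT_INCOME_SHARES)[None, None, None, :])

    ag = np.arange(N_AGE_GROUPS)
    race = np.arange(len(RACES))
    p_diab = (np.array(DEFAULT_DIABETES_BY_AGE)[:, None, None, None]
              + np.array(DEFAULT_DIABETES_RACE_SHIFT)[None, :, None, None])
    p_diab = np.broadcast_to(p_diab, DEMO_SHAPE).copy().clip(0, 1)

    base_hyp = (np.array(DEFAULT_HYPERTENSION_BY_AGE)[:, None, None, None]
                + np.array(DEFAULT_HYPERTENSION_RACE_SHIFT)[None, :, None, None])
    p_hyp = np.stack(
        [base_hyp + d * DEFAULT_HYPERTENSION_DIABETES_SHIFT for d in (0, 1)], axis=-1)
    p_hyp = np.broadcast_to(p_hyp, DEMO_SHAPE + (2,)).copy().clip(0, 1)

    base_chf = np.array(DEFAULT_CHF_BY_AGE)[:, None, None, None]
    p_chf = np.stack(
        [np.stack([base_chf + d * DEFAULT_CHF_DIABETES_SHIFT
                   + h * DEFAULT_CHF_HYPERTENSION_SHIFT
                   for h in (0, 1)], axis=-1)
         for d in (0, 1)], axis=-2)
    p_chf = np.broadcast_to(p_chf, DEMO_SHAPE + (2, 2)).copy().clip(0, 1)

    spec = PopulationSpec(
        demographics_table=demo, p_diabetes=p_diab, p_hypertension=p_hyp,
        p_chf=p_chf, p_initial_inpatient_dx=0.5, version=FIXTURE_VERSION)
    spec.validate()
    return spec
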