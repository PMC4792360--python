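"""YAML configuration loading for simulation runs.

A run configuration file is a flat-ish YAML document overriding the package
defaults, for example::

    n_patients: 10000
    years: 5
    scenario: baseline          # baseline | profit | quality
    payment:
      model: shared_saving
      ssr: 0.5
      srh: 0.7
    clinical:
      rr_hosp: 0.20
      rr_mort: 0.13
      partial_effect_fraction: 0.5
    population:
      p_initial_inpatient_dx: 0.5

Only scalar fields of the clinical, cost and population blocks can be overridden
from YAML; the full conditional-probability tables of a custom population are
supplied programmatically through :class:`acosim.population.PopulationSpec`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import SimulationConfig
from .experiments import apply_scenario, make_scenario
from .payment import PaymentConfig


class ConfigError(ValueError):
    pass


_TOP_LEVEL_SCALARS = (
    "years", "cycles_per_year", "n_patients", "n_hospitals", "n_pcps",
    "n_replications", "assignment", "tau", "profit_utility_scale",
    "force_intervention",
)
_CLINICAL_SCALARS = (
    "chf_incidence_base", "incidence_diabetes_multiplier",
    "incidence_hypertension_multiplier", "p_incidence_inpatient",
    "diabetes_incidence", "rr_hosp", "rr_mort", "partial_effect_fraction",
    "visit_rate_per_year", "chf_mortality_mode",
)
_COST_SCALARS = (
    "hosp_reimbursement", "hospital_net_per_admission",
    "physician_fee_fraction_of_hosp", "outpatient_reimbursement",
    "pcp_operating_cost_fraction", "intervention_pooled_monthly",
    "intervention_months", "effect_months", "pcp_intervention_cost_per_patient_year",
)
_POPULATION_SCALARS = ("p_initial_inpatient_dx",)


def config_from_dict(data: dict) -> SimulationConfig:
    cfg = SimulationConfig()
    data = dict(data or {})

    scenario = data.pop("scenario", None)
    if scenario is not None:
        cfg = apply_scenario(cfg, make_scenario(scenario, cfg.n_hospitals, cfg.n_pcps))

    for block_name, target, allowed in (
        ("payment", None, None),
        ("clinical", cfg.clinical, _CLINICAL_SCALARS),
        ("costs", cfg.costs, _COST_SCALARS),
        ("population", cfg.population, _POPULATION_SCALARS),
    ):
        block = data.pop(block_name, None)
        if not block:
            continue
        if block_name == "payment":
            cfg.payment = PaymentConfig(**block)
            continue
        for key, value in block.items():
            if key not in allowed:
                raise ConfigError(f"unknown {block_name} option {key!r}")
            setattr(target, key, value)

    for key, value in data.items():
        if key not in _TOP_LEVEL_SCALARS:
            raise ConfigError(f"unknown configuration option {key!r}")
        setattr(cfg, key, value)

    cfg.validate()
    return cfg


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
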