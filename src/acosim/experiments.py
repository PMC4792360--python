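"""Experiment drivers: baseline study, SSR x SRH payment sweeps, sensitivity analysis.

The baseline study uses the mixed provider roster (one profit-oriented, one
quality-oriented and one neutral hospital; PCP types split equally) with SSR = 0.5
and SRH = 0.7.  Scenario two makes every provider profit-oriented and scenario
three quality-oriented.  The payment sweep re-runs the replicated simulation over a
grid of (SSR, SRH) values; the sensitivity analysis perturbs each listed parameter
by +/-20% one at a time and ranks parameters by the induced range of the shared
saving to payer (SSP).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .engine import (
    ReplicationSummary,
    SimulationConfig,
    default_pcp_types,
    run_replications,
)
from .payment import PaymentConfig


class ExperimentError(ValueError):
    """Raised for invalid scenario or sensitivity specifications."""


@dataclass
class Scenario:
    """A provider-mix scenario, optionally with payment-parameter grids."""

    name: str
    hospital_types: tuple
    pcp_types: tuple
    ssr_grid: tuple = tuple(round(0.1 * i, 1) for i in range(1, 10))
    srh_grid: tuple = tuple(round(0.1 * i, 1) for i in range(0, 11))

    def validate(self) -> None:
        for v in (*self.ssr_grid, *self.srh_grid):
            if not 0.0 <= v <= 1.0:
                raise ExperimentError("grid values must lie in [0, 1]")


def make_scenario(name: str, n_hospitals: int = 3, n_pcps: int = 15) -> Scenario:
    """The three study scenarios: 'baseline' (mixed), 'profit', 'quality'."""
    if name == "baseline":
        h = tuple(("profit", "quality", "neutral")[i % 3] for i in range(n_hospitals))
        p = default_pcp_types(n_pcps)
    elif name in ("profit", "quality"):
        h = (name,) * n_hospitals
        p = (name,) * n_pcps
    else:
        raise ExperimentError(f"unknown scenario {name!r}")
    return Scenario(name=name, hospital_types=h, pcp_types=p)


def apply_scenario(cfg: SimulationConfig, scenario: Scenario) -> SimulationConfig:
    cfg = copy.deepcopy(cfg)
    cfg.hospital_types = tuple(scenario.hospital_types)
    cfg.pcp_types = tuple(scenario.pcp_types)
    cfg.scenario = scenario.name
    return cfg


def run_baseline(
    cfg: SimulationConfig | None = None,
    n_reps: int = 50,
    seed: int = 0,
    show_progress: bool = False,
) -> ReplicationSummary:
    """The baseline study: mixed provider roster, SSR = 0.5, SRH = 0.7."""
    cfg = copy.deepcopy(cfg) if cfg is not None else SimulationConfig()
    cfg = apply_scenario(cfg, make_scenario("baseline", cfg.n_hospitals, cfg.n_pcps))
    cfg.payment = PaymentConfig(model="shared_saving", ssr=0.5, srh=0.7)
    return run_replications(cfg, n_reps, seed, show_progress=show_progress)


def sweep_payment(
    scenario: Scenario,
    cfg: SimulationConfig | None = None,
    ssr_grid: tuple | None = None,
    srh_grid: tuple | None = None,
    n_reps: int = 50,
    seed: int = 0,
    show_progress: bool = False,
) -> pd.DataFrame:
    """Replicated outcomes over an (SSR, SRH) grid; one tidy row per grid point.

    Columns carry the replication means (and 95% CI bounds for the three headline
    outcomes), suitable for plotting SSP / hospitalization / mortality against the
    payment parameters.
    """
    scenario.validate()
    base = copy.deepcopy(cfg) if cfg is not None else SimulationConfig()
    base = apply_scenario(base, scenario)
    ssr_grid = tuple(ssr_grid) if ssr_grid is not None else scenario.ssr_grid
    srh_grid = tuple(srh_grid) if srh_grid is not None else scenario.srh_grid
    rows = []
    for ssr in ssr_grid:
        for srh in srh_grid:
            run_cfg = copy.deepcopy(base)
            run_cfg.payment = PaymentConfig(model="shared_saving", ssr=ssr, srh=srh)
            summ = run_replications(run_cfg, n_reps, seed, show_progress=show_progress)
            row = {"scenario": scenario.name, "ssr": ssr, "srh": srh}
            row.update({k: summ.mean(k) for k in summ.table.index})
            for k in ("ssp_per_chf", "aco_admissions_per_chf_py", "aco_mortality"):
                lo, hi = summ.ci(k)
                row[f"{k}_ci_lo"], row[f"{k}_ci_hi"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


#: Parameters of the one-at-a-time sensitivity analysis and how each is applied.
SENSITIVITY_PARAMETERS = (
    "rr_hosp",                      # intervention effect on hospitalization
    "rr_mort",                      # intervention effect on mortality
    "hospital_intervention_cost",   # pooled monthly intervention cost (hospital side)
    "hospital_operating_cost",      # hospital operating cost per admission
    "pcp_intervention_cost",        # PCP opportunity cost per patient-year
    "pcp_operating_cost_fraction",  # PCP operating cost share of visit revenue
)


@dataclass
class SensitivitySpec:
    """One-at-a-time +/-20% perturbation study of SSP."""

    parameters: tuple = SENSITIVITY_PARAMETERS
    factors: tuple = (0.8, 1.2)

    def validate(self) -> None:
        for p in self.parameters:
            if p not in SENSITIVITY_PARAMETERS:
                raise ExperimentError(f"unknown sensitivity parameter {p!r}")
        if tuple(sorted(self.factors)) != (0.8, 1.2):
            raise ExperimentError("perturbation factors must be {0.8, 1.2}")


def _perturb(cfg: SimulationConfig, parameter: str, factor: float) -> SimulationConfig:
    cfg = copy.deepcopy(cfg)
    if parameter == "rr_hosp":
        cfg.clinical.rr_hosp *= factor
    elif parameter == "rr_mort":
        cfg.clinical.rr_mort *= factor
    elif parameter == "hospital_intervention_cost":
        cfg.costs.intervention_pooled_monthly *= factor
    elif parameter == "hospital_operating_cost":
        operating = cfg.costs.hosp_reimbursement - cfg.costs.hospital_net_per_admission
        cfg.costs.hospital_net_per_admission = cfg.costs.hosp_reimbursement \
            - operating * factor
    elif parameter == "pcp_intervention_cost":
        cfg.costs.pcp_intervention_cost_per_patient_year *= factor
    elif parameter == "pcp_operating_cost_fraction":
        cfg.costs.pcp_operating_cost_fraction = min(
            1.0, cfg.costs.pcp_operating_cost_fraction * factor)
    else:
        raise ExperimentError(f"unknown sensitivity parameter {parameter!r}")
    return cfg


def run_sensitivity(
    spec: SensitivitySpec,
    cfg: SimulationConfig | None = None,
    n_reps: int = 50,
    seed: int = 0,
    show_progress: bool = False,
) -> pd.DataFrame:
    """Tornado table: SSP under each +/-20% perturbation, ranked by absolute range."""
    spec.validate()
    base_cfg = copy.deepcopy(cfg) if cfg is not None else SimulationConfig()
    base = run_replications(base_cfg, n_reps, seed, show_progress=show_progress)
    base_ssp = base.mean("ssp_per_chf")
    rows = []
    for p in spec.parameters:
        ssp = {}
        for f in sorted(spec.factors):
            summ = run_replications(_perturb(base_cfg, p, f), n_reps, seed,
                                    show_progress=show_progress)
            ssp[f] = summ.mean("ssp_per_chf")
        lo, hi = ssp[min(spec.factors)], ssp[max(spec.factors)]
        rows.append({
            "parameter": p, "ssp_low": lo, "ssp_high": hi, "ssp_base": base_ssp,
            "ssp_range": abs(hi - lo),
        })
    out = pd.DataFrame(rows).sort_values("ssp_range", ascending=False, ignore_index=True)
    return out
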