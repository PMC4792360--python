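"""Hospital and PCP agents with a Theory-of-Planned-Behavior decision model.

Each year an ACO provider agent decides whether to conduct the CHF intervention
(behavior k = 1) or provide usual care (k = 0).  Intention toward each behavior is a
convex combination of three predictors, each a utility in [0, 1]:

* attitude      ``A^k = b1 * U_p(EP^k) + b2 * U_q(EQ^k)`` — beliefs about the
  financial (expected profit EP) and quality (expected adverse-event rates EQ)
  consequences of the behavior, weighted by the agent's priorities ``beta``;
* subjective norm  ``SN^k = U_sn(nm^k)`` — peer pressure, estimated from supportive
  messages received from other providers in the network during the year;
* perceived behavioral control  ``PBC^1 = ni / ti`` — the fraction of discharge
  interactions in which the counterpart provider was observed intervening
  (collaboration is needed for the intervention; not intervening needs none, so
  ``PBC^0 = 1`` always).

The behavior is then drawn from a softmax over the two intentions with
irrationality parameter tau; tau -> 0 is the rational arg-max limit (the default).
Controlled-network agents always provide usual care.

The functional forms of ``U_p``, ``U_q``, ``U_sn`` and the intention combination are
deliberately pluggable model choices; the defaults are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PROVIDER_TYPES: dict[str, tuple[float, float]] = {
    "profit": (0.8, 0.2),
    "quality": (0.2, 0.8),
    "neutral": (0.5, 0.5),
}

#: Dollar scale of the logistic profit-utility transform (per own CHF patient).
DEFAULT_PROFIT_UTILITY_SCALE = 500.0
#: Reference bounds mapping the combined adverse-event index to quality utility.
DEFAULT_QUALITY_BOUNDS = (0.0, 1.0)
DEFAULT_INTENTION_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


class ProviderError(ValueError):
    """Raised for invalid provider parameters or bookkeeping."""


def _check_simplex(weights, name: str) -> None:
    if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ProviderError(f"{name} must be non-negative and sum to 1, got {weights}")


@dataclass
class TPBState:
    """One year's decision trace of a provider agent."""

    attitude: tuple[float, float] = (0.5, 0.5)          # A^0, A^1
    subjective_norm: tuple[float, float] = (0.5, 0.5)   # SN^0, SN^1
    pbc: tuple[float, float] = (1.0, 0.5)               # PBC^0, PBC^1
    intention: tuple[float, float] = (0.0, 0.0)         # I^0, I^1
    choice_probability: float = 0.0                     # P^1
    tau: float = 0.0


@dataclass
class ProviderAgent:
    """A hospital or PCP clinic agent.

    ``beta = (b1, b2)`` weights profit vs quality in the attitude; the three
    stylized provider types are profit-oriented (0.8, 0.2), quality-oriented
    (0.2, 0.8) and neutral (0.5, 0.5).  ``messages_received`` counts supportive
    messages per behavior during the current year; ``ni``/``ti`` count discharge
    interactions (with an intervening counterpart / total).  Ledger amounts are
    USD (2011).
    """

    id: int
    kind: str                       # "hospital" | "pcp"
    network: str                    # "ACO" | "controlled"
    beta: tuple[float, float]
    behavior_k: int = 0
    messages_received: list[int] = field(default_factory=lambda: [0, 0])
    ni: int = 0
    ti: int = 0
    pbc_prev: float = 0.5
    attitude_favored: int = 0       # behavior currently favored by attitude
    tpb: TPBState = field(default_factory=TPBState)
    ledger: dict = field(default_factory=dict)
    quality_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("hospital", "pcp"):
            raise ProviderError(f"unknown provider kind {self.kind!r}")
        if self.network not in ("ACO", "controlled"):
            raise ProviderError(f"unknown network {self.network!r}")
        _check_simplex(self.beta, "beta")
        if self.network == "controlled" and self.behavior_k != 0:
            raise ProviderError("controlled-network agents always provide usual care")

    def reset_year_counters(self) -> None:
        self.messages_received = [0, 0]
        self.ni = 0
        self.ti = 0


# ---------------------------------------------------------------------------
# TPB components
# ---------------------------------------------------------------------------

def utility_profit(profit: float, scale: float = DEFAULT_PROFIT_UTILITY_SCALE) -> float:
    """Bounded logistic transform of per-patient profit: losses < 0.5 < gains."""
    return 1.0 / (1.0 + math.exp(-profit / scale))


def utility_quality(
    admission_rate: float,
    mortality_rate: float,
    bounds: tuple[float, float] = DEFAULT_QUALITY_BOUNDS,
) -> float:
    """Linear transform of adverse-event rates; lower rates give higher utility.

    The two rates are averaged into a single adverse-event index and mapped linearly
    from ``bounds`` (worst, i.e. upper bound, -> 0; best -> 1), clipped to [0, 1].
    """
    lo, hi = bounds
    if hi <= lo:
        raise ProviderError("quality bounds must satisfy upper > lower")
    index = 0.5 * admission_rate + 0.5 * mortality_rate
    return float(np.clip((hi - index) / (hi - lo), 0.0, 1.0))


def compute_attitude(ep_utility: float, eq_utility: float, beta: tuple[float, float]) -> float:
    """Attitude toward a behavior: profit/quality utilities weighted by beta."""
    _check_simplex(beta, "beta")
    if not (0.0 <= ep_utility <= 1.0 and 0.0 <= eq_utility <= 1.0):
        raise ProviderError("utilities must lie in [0, 1]")
    return beta[0] * ep_utility + beta[1] * eq_utility


@dataclass
class PriorYearObservation:
    """What an agent observed about its own panel in the prior year.

    ``profit_per_chf_patient`` is the realized service profit per own CHF patient,
    excluding intervention costs and shared-saving receipts (those are what the
    decision is about).  Rates are among the agent's own CHF patients.
    """

    profit_per_chf_patient: float
    admission_rate: float
    mortality_rate: float


def estimate_expectations(
    agent: ProviderAgent,
    prior: PriorYearObservation,
    expected_saving_share_per_chf_patient: float,
    intervention_cost_per_patient_year: float,
    rr_hosp: float,
    rr_mort: float,
    margin_per_admission: float = 0.0,
) -> tuple[tuple[float, float], tuple[tuple[float, float], tuple[float, float]]]:
    """Expected profit and quality under each behavior for next year.

    Returns ``((EP^0, EP^1), ((adm^0, mort^0), (adm^1, mort^1)))``, all per own CHF
    patient.  EP^0 is the prior-year service profit.  For k = 1 the agent subtracts
    the intervention cost, adds the shared-saving share it expects to receive if the
    intervention succeeds network-wide, and (for hospitals) accounts for the change
    in admission margins from avoided admissions.  Expected quality under k = 1
    applies the known intervention risk reductions to the prior-year rates.
    """
    ep0 = prior.profit_per_chf_patient
    margin_effect = -margin_per_admission * rr_hosp * prior.admission_rate
    ep1 = (ep0
           - intervention_cost_per_patient_year
           + expected_saving_share_per_chf_patient
           + margin_effect)
    eq0 = (prior.admission_rate, prior.mortality_rate)
    eq1 = (prior.admission_rate * (1.0 - rr_hosp), prior.mortality_rate * (1.0 - rr_mort))
    return (ep0, ep1), (eq0, eq1)


def compute_subjective_norm(nm: tuple[int, int]) -> tuple[float, float]:
    """Subjective norm utilities (SN^0, SN^1) from message counts by behavior.

    The default transform is the received-message proportion; with no messages the
    norm is uninformative (0.5 for both behaviors).
    """
    nm0, nm1 = nm
    if nm0 < 0 or nm1 < 0:
        raise ProviderError("message counts must be non-negative")
    total = nm0 + nm1
    if total == 0:
        return 0.5, 0.5
    return nm0 / total, nm1 / total


def exchange_messages(agents: list[ProviderAgent], rng: np.random.Generator) -> None:
    """One messaging tick: every agent sends one supportive message to a random peer.

    The message supports the sender's currently attitude-favored behavior; recipients
    are drawn uniformly among the other agents of the network.  A singleton network is
    a no-op.  Message conservation holds: totals received equal totals sent.
    """
    n = len(agents)
    if n < 2:
        import warnings
        warnings.warn("messaging requires at least two agents in the network")
        return
    targets = rng.integers(0, n - 1, size=n)
    for i, agent in enumerate(agents):
        t = targets[i] + (targets[i] >= i)  # skip self
        agents[t].messages_received[agent.attitude_favored] += 1


def record_interaction(hospital: ProviderAgent, pcp: ProviderAgent) -> None:
    """Record a discharge interaction: each party observes the other's behavior."""
    hospital.ti += 1
    pcp.ti += 1
    if pcp.behavior_k == 1:
        hospital.ni += 1
    if hospital.behavior_k == 1:
        pcp.ni += 1


def compute_pbc(ni: int, ti: int, prev: float = 0.5) -> tuple[float, float]:
    """Perceived behavioral control (PBC^0, PBC^1).

    PBC^1 is the observed fraction of interactions with an intervening counterpart;
    with no interactions it carries the previous year's value forward (initially
    0.5).  Not intervening requires no collaboration, so PBC^0 is always 1.
    """
    if ni < 0 or ti < 0 or ni > ti:
        raise ProviderError("interaction counts must satisfy 0 <= ni <= ti")
    pbc1 = ni / ti if ti > 0 else prev
    return 1.0, pbc1


def compute_intention(
    attitude: float,
    subjective_norm: float,
    pbc: float,
    weights: tuple[float, float, float] = DEFAULT_INTENTION_WEIGHTS,
) -> float:
    """Intention toward a behavior: convex combination of the three predictors."""
    _check_simplex(weights, "intention weights")
    for name, v in (("attitude", attitude), ("subjective_norm", subjective_norm),
                    ("pbc", pbc)):
        if not 0.0 <= v <= 1.0:
            raise ProviderError(f"{name} must lie in [0, 1], got {v}")
    return weights[0] * attitude + weights[1] * subjective_norm + weights[2] * pbc


def choice_probability(i0: float, i1: float, tau: float) -> float:
    """Softmax probability of choosing the intervention (k = 1).

    ``tau`` adjusts decision irrationality; ``tau <= 0`` is the rational arg-max
    limit, with the deterministic tie-break toward usual care (k = 0).
    """
    if tau <= 0.0:
        return 1.0 if i1 > i0 else 0.0
    # subtract the max for numerical stability
    m = max(i0, i1)
    e0 = math.exp((i0 - m) / tau)
    e1 = math.exp((i1 - m) / tau)
    return e1 / (e0 + e1)


def choose_behavior(i0: float, i1: float, tau: float, rng: np.random.Generator) -> int:
    """Draw the next-year behavior from the softmax over intentions."""
    p1 = choice_probability(i0, i1, tau)
    if p1 in (0.0, 1.0):
        return int(p1)
    return int(rng.random() < p1)


def make_provider_roster(
    hospital_types: list[str],
    pcp_types: list[str],
    network: str,
    id_offset: int = 0,
) -> list[ProviderAgent]:
    """Build a network's provider agents from type labels ('profit'|'quality'|'neutral')."""
    agents = []
    for i, t in enumerate(hospital_types):
        agents.append(ProviderAgent(id=id_offset + i, kind="hospital", network=network,
                                    beta=PROVIDER_TYPES[t]))
    for i, t in enumerate(pcp_types):
        agents.append(ProviderAgent(id=id_offset + len(hospital_types) + i, kind="pcp",
                                    network=network, beta=PROVIDER_TYPES[t]))
    return agents
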