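"""Markov cohort engine for the anticoagulation decision model.

Seven states: healthy-with-AF, a one-cycle gastrointestinal-bleed tunnel,
four absorbing-except-death post-event states (heart failure, myocardial
infarction, ischemic stroke, intracranial hemorrhage), and death. Cycles are
one year; the cohort starts 100% healthy, transition probabilities come from
annual event incidence split by acute case fatality, and each cycle's costs
and utilities are attributed to end-of-cycle occupancy and discounted by
(1 + r)^-t with no half-cycle correction.

Cost components per cycle: annual medication cost in every alive state,
event-related cost charged once on entry into a post-event state (and for
the single tunnel cycle of a GI bleed), and an annual post-event cost while
residing in a post-event state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .codes import EVENTS

STATES: Tuple[str, ...] = (
    "healthy",
    "gi_bleed",
    "post_hf",
    "post_mi",
    "post_is",
    "post_ich",
    "death",
)
HEALTHY, GI_TUNNEL, DEATH = 0, 1, len(STATES) - 1
POST_STATE_INDEX: Dict[str, int] = {"HF": 2, "MI": 3, "IS": 4, "ICH": 5}
_CHRONIC_EVENTS: Tuple[str, ...] = ("HF", "MI", "IS", "ICH")


class ParameterError(ValueError):
    """Raised when strategy parameters violate model invariants."""


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings: horizon, discounting, decision threshold.

    ``fatality_mode`` controls post-event mortality: ``annual_post_state``
    reuses the acute case fatality as an annual post-state death probability
    (the only mortality figure the parameter tables carry), ``acute_only``
    confines fatality to the event year. ``utility_mode`` decides whether a
    post-event utility replaces the drug (healthy-state) utility or
    multiplies it.
    """

    n_cycles: int = 20
    discount_rate: float = 0.045
    wtp: float = 32_000.0
    krw_per_usd: float = 1_000.0
    fatality_mode: str = "annual_post_state"
    incidence_stratum: str = "pooled"
    utility_mode: str = "replace"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ParameterError("discount_rate must be in [0, 1)")
        if self.wtp <= 0:
            raise ParameterError("wtp must be positive")
        if self.fatality_mode not in ("annual_post_state", "acute_only"):
            raise ParameterError(f"unknown fatality_mode {self.fatality_mode!r}")
        if self.utility_mode not in ("replace", "multiply"):
            raise ParameterError(f"unknown utility_mode {self.utility_mode!r}")


@dataclass(frozen=True)
class StrategyParameters:
    """All inputs for one treatment strategy (drug)."""

    drug: str
    annual_event_prob: Mapping[str, float]
    fatality: Mapping[str, float]
    drug_utility: float
    event_utilities: Mapping[str, float]
    medication_annual: float
    event_costs: Mapping[str, float]
    post_event_annual: Mapping[str, float] = field(
        default_factory=lambda: {e: 0.0 for e in EVENTS}
    )

    def validate(self) -> None:
        total = 0.0
        for e in EVENTS:
            p = self.annual_event_prob.get(e, 0.0)
            f = self.fatality.get(e, 0.0)
            if not 0.0 <= p <= 1.0 or not 0.0 <= f <= 1.0:
                raise ParameterError(f"{self.drug}: probability for {e} out of [0, 1]")
            total += p
        if total > 1.0 + 1e-12:
            raise ParameterError(
                f"{self.drug}: annual event probabilities sum to {total:.4f} > 1"
            )
        if not 0.0 <= self.drug_utility <= 1.05:
            raise ParameterError(f"{self.drug}: drug utility out of [0, 1.05]")
        for e in EVENTS:
            if not 0.0 <= self.event_utilities.get(e, 0.0) <= 1.05:
                raise ParameterError(f"{self.drug}: utility for {e} out of range")
        if self.medication_annual < 0 or any(
            self.event_costs.get(e, 0.0) < 0 or self.post_event_annual.get(e, 0.0) < 0
            for e in EVENTS
        ):
            raise ParameterError(f"{self.drug}: costs must be non-negative")

    def replace(self, **kwargs) -> "StrategyParameters":
        return replace(self, **kwargs)


def discount_factor(cycle: int, rate: float) -> float:
    """(1 + rate)^(-cycle); rewards of cycle 1 are discounted one period."""
    if cycle < 1 or int(cycle) != cycle:
        raise ValueError("cycle must be an integer >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return float((1.0 + rate) ** (-cycle))


def annuity_factor(n_cycles: int, rate: float) -> float:
    """Sum of discount factors for cycles 1..n (closed form)."""
    if rate == 0:
        return float(n_cycles)
    return float((1.0 - (1.0 + rate) ** (-n_cycles)) / rate)


def build_transition_matrix(
    params: StrategyParameters, settings: Optional[ModelSettings] = None
) -> np.ndarray:
    """Row-stochastic 7x7 transition matrix for one strategy."""
    settings = settings or ModelSettings()
    params.validate()
    p = {e: float(params.annual_event_prob.get(e, 0.0)) for e in EVENTS}
    f = {e: float(params.fatality.get(e, 0.0)) for e in EVENTS}

    m = np.zeros((len(STATES), len(STATES)))
    acute_death = sum(p[e] * f[e] for e in _CHRONIC_EVENTS)
    for e in _CHRONIC_EVENTS:
        m[HEALTHY, POST_STATE_INDEX[e]] = p[e] * (1.0 - f[e])
    m[HEALTHY, GI_TUNNEL] = p["GI"]
    m[HEALTHY, DEATH] = acute_death
    m[HEALTHY, HEALTHY] = 1.0 - sum(p.values())

    m[GI_TUNNEL, DEATH] = f["GI"]
    m[GI_TUNNEL, HEALTHY] = 1.0 - f["GI"]

    for e in _CHRONIC_EVENTS:
        s = POST_STATE_INDEX[e]
        annual = f[e] if settings.fatality_mode == "annual_post_state" else 0.0
        m[s, DEATH] = annual
        m[s, s] = 1.0 - annual

    m[DEATH, DEATH] = 1.0
    row_err = np.abs(m.sum(axis=1) - 1.0).max()
    if row_err > 1e-12:
        raise ParameterError(f"{params.drug}: transition rows deviate from 1 by {row_err:.2e}")
    return m


@dataclass
class CohortTrace:
    """State occupancancy per cycle with discounted reward accumulators."""

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    cycle_cost: np.ndarray  # discounted, per cycle 1..n
    cycle_qaly: np.ndarray
    cost_components: Dict[str, float]  # medication / event / post_event

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.occupancy.shape[0] - 1
        frame = pd.DataFrame(self.occupancy, columns=list(STATES))
        frame.insert(0, "cycle", np.arange(n + 1))
        frame["discounted_cost"] = np.concatenate([[0.0], np.cumsum(self.cycle_cost)])
        frame["discounted_qaly"] = np.concatenate([[0.0], np.cumsum(self.cycle_qaly)])
        return frame


def run_cohort_trace(
    matrix: np.ndarray,
    params: StrategyParameters,
    settings: Optional[ModelSettings] = None,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted costs and QALYs."""
    settings = settings or ModelSettings()
    n = settings.n_cycles
    occ = np.zeros((n + 1, len(STATES)))
    occ[0, HEALTHY] = 1.0

    u_drug = params.drug_utility
    if settings.utility_mode == "multiply":
        u_event = {e: params.event_utilities[e] * u_drug for e in EVENTS}
    else:
        u_event = {e: params.event_utilities[e] for e in EVENTS}

    cycle_cost = np.zeros(n)
    cycle_qaly = np.zeros(n)
    components = {"medication": 0.0, "event": 0.0, "post_event": 0.0}

    for t in range(1, n + 1):
        occ[t] = occ[t - 1] @ matrix
        d = discount_factor(t, settings.discount_rate)

        alive = occ[t, HEALTHY] + occ[t, GI_TUNNEL] + sum(
            occ[t, POST_STATE_INDEX[e]] for e in _CHRONIC_EVENTS
        )
        med = params.medication_annual * alive
        # Event cost is per incident event: charged on the whole fraction that
        # has the event this cycle, whether they survive into the post state
        # (or GI tunnel) or die acutely.
        entry_cost = occ[t - 1, HEALTHY] * params.annual_event_prob.get("GI", 0.0) * params.event_costs.get("GI", 0.0)
        post_cost = 0.0
        for e in _CHRONIC_EVENTS:
            s = POST_STATE_INDEX[e]
            incident = occ[t - 1, HEALTHY] * params.annual_event_prob.get(e, 0.0)
            entry_cost += incident * params.event_costs.get(e, 0.0)
            post_cost += occ[t, s] * params.post_event_annual.get(e, 0.0)

        utility = u_drug * occ[t, HEALTHY] + u_event["GI"] * occ[t, GI_TUNNEL]
        for e in _CHRONIC_EVENTS:
            utility += u_event[e] * occ[t, POST_STATE_INDEX[e]]

        cycle_cost[t - 1] = d * (med + entry_cost + post_cost)
        cycle_qaly[t - 1] = d * utility
        components["medication"] += d * med
        components["event"] += d * entry_cost
        components["post_event"] += d * post_cost

    return CohortTrace(
        strategy=params.drug,
        occupancy=occ,
        cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly,
        cost_components=components,
    )


def run_strategy(
    params: StrategyParameters, settings: Optional[ModelSettings] = None
) -> CohortTrace:
    settings = settings or ModelSettings()
    return run_cohort_trace(build_transition_matrix(params, settings), params, settings)


def microsimulate(
    matrix: np.ndarray,
    n_walkers: int,
    n_cycles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual-level Monte Carlo counterpart of the cohort trace.

    Returns occupancy fractions of shape (n_cycles + 1, n_states); used as
    an independent oracle for the deterministic trace.
    """
    counts = np.zeros(len(STATES), dtype=np.int64)
    counts[HEALTHY] = n_walkers
    occupancy = np.zeros((n_cycles + 1, len(STATES)))
    occupancy[0] = counts / n_walkers
    for t in range(1, n_cycles + 1):
        nxt = np.zeros(len(STATES), dtype=np.int64)
        for s in range(len(STATES)):
            if counts[s]:
                nxt += rng.multinomial(counts[s], matrix[s])
        counts = nxt
        occupancy[t] = counts / n_walkers
    return occupancy


def run_base_case(
    strategies: Iterable[StrategyParameters],
    settings: Optional[ModelSettings] = None,
    reference: str = "warfarin",
) -> Tuple[pd.DataFrame, Dict[str, CohortTrace]]:
    """Run every strategy and report incremental results vs the reference.

    Returns a base-case table (strategy, cost, incremental cost, QALY, ICER,
    dominance, NMB at WTP) and the per-strategy traces.
    """
    from .cea import icer

    settings = settings or ModelSettings()
    strategies = list(strategies)
    if len(strategies) < 2:
        raise ParameterError("need at least two strategies")
    names = [s.drug for s in strategies]
    if reference not in names:
        raise ParameterError(f"reference strategy {reference!r} not among {names}")

    traces = {s.drug: run_strategy(s, settings) for s in strategies}
    ref = traces[reference]
    rows: List[dict] = []
    for name in names:
        tr = traces[name]
        if name == reference:
            rows.append(
                {
                    "strategy": name,
                    "cost": tr.total_cost,
                    "qaly": tr.total_qaly,
                    "incremental_cost": np.nan,
                    "incremental_qaly": np.nan,
                    "icer": np.nan,
                    "dominance": "reference",
                    "nmb_at_wtp": np.nan,
                    "cost_effective": np.nan,
                }
            )
            continue
        res = icer(
            {"cost": ref.total_cost, "qaly": ref.total_qaly},
            {"cost": tr.total_cost, "qaly": tr.total_qaly},
            settings.wtp,
        )
        rows.append(
            {
                "strategy": name,
                "cost": tr.total_cost,
                "qaly": tr.total_qaly,
                "incremental_cost": res.delta_cost,
                "incremental_qaly": res.delta_qaly,
                "icer": res.ratio,
                "dominance": res.label,
                "nmb_at_wtp": res.nmb_at_wtp,
                "cost_effective": res.cost_effective_at_wtp,
            }
        )
    return pd.DataFrame(rows), traces
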