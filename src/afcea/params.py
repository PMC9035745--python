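"""Model-parameter container linking estimation outputs to the Markov engine.

Base-case values for utilities, medication costs, event-related costs and
case-fatality counts are the published figures for the Korean
intermediate-stroke-risk anticoagulation comparison; annual event incidence
comes either from the claims-based estimator or from configuration. All
currency is USD (a fixed 1,000 KRW/USD conversion is applied on ingest when
inputs are in KRW).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from .codes import DRUGS, EVENTS
from .markov import ModelSettings, StrategyParameters

logger = logging.getLogger(__name__)

#: Treatment-state (drug) utilities.
DRUG_UTILITY: Mapping[str, float] = {
    "warfarin": 0.987,
    "rivaroxaban": 0.994,
    "apixaban": 0.998,
    "dabigatran": 0.970,
    "edoxaban": 0.998,
}

#: Post-event health-state utilities.
EVENT_UTILITY: Mapping[str, float] = {"HF": 0.69, "MI": 0.84, "IS": 0.41, "ICH": 0.56, "GI": 0.70}

#: Annual medication cost, USD (365 x daily price).
MEDICATION_COST: Mapping[str, float] = {
    "warfarin": 19.490,
    "rivaroxaban": 795.426,
    "apixaban": 470.968,
    "dabigatran": 870.890,
    "edoxaban": 670.010,
}

#: Mean admission cost per event, USD.
EVENT_COST: Mapping[str, float] = {
    "HF": 2964.92,
    "MI": 7482.15,
    "IS": 4557.36,
    "ICH": 7108.77,
    "GI": 1583.03,
}

#: In-hospital case-fatality counts (deaths, events) per event type.
FATALITY_COUNTS: Mapping[str, Tuple[int, int]] = {
    "HF": (4, 1223),
    "MI": (0, 61),
    "IS": (2, 92),
    "ICH": (1, 8),
    "GI": (1, 54),
}

#: Published annual ischemic-stroke incidence (fraction/year) by score stratum.
IS_RATE_BY_SCORE: Mapping[int, Mapping[str, float]] = {
    1: {"warfarin": 0.0075, "rivaroxaban": 0.0107, "apixaban": 0.0150, "dabigatran": 0.0455, "edoxaban": 0.0133},
    2: {"warfarin": 0.0152, "rivaroxaban": 0.0064, "apixaban": 0.0062, "dabigatran": 0.0053, "edoxaban": 0.0064},
}


@dataclass(frozen=True)
class ModelParameters:
    """One strategy set: incidence, fatality, utilities, costs, settings.

    ``incidence`` maps (drug, event) -> annual probability for the stratum
    already chosen by the caller. Optional count pairs back the Beta
    distributions of the probabilistic sensitivity analysis.
    """

    settings: ModelSettings
    incidence: Mapping[Tuple[str, str], float]
    fatality: Mapping[str, float]
    drug_utilities: Mapping[str, float] = field(default_factory=lambda: dict(DRUG_UTILITY))
    event_utilities: Mapping[str, float] = field(default_factory=lambda: dict(EVENT_UTILITY))
    medication_costs: Mapping[str, float] = field(default_factory=lambda: dict(MEDICATION_COST))
    event_costs: Mapping[str, float] = field(default_factory=lambda: dict(EVENT_COST))
    post_event_costs: Mapping[str, float] = field(default_factory=lambda: {e: 0.0 for e in EVENTS})
    fatality_counts: Optional[Mapping[str, Tuple[int, int]]] = None
    incidence_counts: Optional[Mapping[Tuple[str, str], Tuple[float, float]]] = None
    reference: str = "warfarin"

    @property
    def drugs(self) -> Tuple[str, ...]:
        return tuple(sorted({d for d, _ in self.incidence}, key=DRUGS.index))

    def strategy(self, drug: str) -> StrategyParameters:
        return StrategyParameters(
            drug=drug,
            annual_event_prob={e: self.incidence[(drug, e)] for e in EVENTS},
            fatality=dict(self.fatality),
            drug_utility=self.drug_utilities[drug],
            event_utilities=dict(self.event_utilities),
            medication_annual=self.medication_costs[drug],
            event_costs=dict(self.event_costs),
            post_event_annual=dict(self.post_event_costs),
        )

    def strategies(self) -> Tuple[StrategyParameters, ...]:
        return tuple(self.strategy(d) for d in self.drugs)

    def with_values(self, overrides: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with named scalar parameters replaced.

        Names follow the sensitivity-analysis convention:
        ``incidence:<drug>:<event>``, ``fatality:<event>``,
        ``drug_utility:<drug>``, ``event_utility:<event>``,
        ``med_cost:<drug>``, ``event_cost:<event>``, ``post_cost:<event>``.
        """
        incidence = dict(self.incidence)
        fatality = dict(self.fatality)
        drug_utilities = dict(self.drug_utilities)
        event_utilities = dict(self.event_utilities)
        med = dict(self.medication_costs)
        event_costs = dict(self.event_costs)
        post = dict(self.post_event_costs)
        for name, value in overrides.items():
            kind, _, rest = name.partition(":")
            if kind == "incidence":
                drug, _, event = rest.partition(":")
                incidence[(drug, event)] = value
            elif kind == "fatality":
                fatality[rest] = value
            elif kind == "drug_utility":
                drug_utilities[rest] = value
            elif kind == "event_utility":
                event_utilities[rest] = value
            elif kind == "med_cost":
                med[rest] = value
            elif kind == "event_cost":
                event_costs[rest] = value
            elif kind == "post_cost":
                post[rest] = value
            else:
                raise KeyError(f"unknown parameter name {name!r}")
        return replace(
            self,
            incidence=incidence,
            fatality=fatality,
            drug_utilities=drug_utilities,
            event_utilities=event_utilities,
            medication_costs=med,
            event_costs=event_costs,
            post_event_costs=post,
        )

    def value(self, name: str) -> float:
        kind, _, rest = name.partition(":")
        if kind == "incidence":
            drug, _, event = rest.partition(":")
            return self.incidence[(drug, event)]
        table = {
            "fatality": self.fatality,
            "drug_utility": self.drug_utilities,
            "event_utility": self.event_utilities,
            "med_cost": self.medication_costs,
            "event_cost": self.event_costs,
            "post_cost": self.post_event_costs,
        }[kind]
        return table[rest]


def base_fatality() -> Dict[str, float]:
    return {e: d / n for e, (d, n) in FATALITY_COUNTS.items()}


def demo_parameters(
    settings: Optional[ModelSettings] = None,
    post_event_costs: Optional[Mapping[str, float]] = None,
    person_years_per_drug: float = 4000.0,
) -> ModelParameters:
    """A fully populated, realistic parameter set for demos and checks.

    Ischemic-stroke incidence uses the published score-2 stratum (the
    direction of effect that matches the published base case: warfarin
    1.52%/yr vs 0.53-0.64%/yr under DOACs); other events carry the package's
    documented default rates. Post-event annual costs are nonzero
    placeholders — the source derives them by subtraction from unpublished
    totals — and can be overridden.
    """
    from .synthetic import DEFAULT_EVENT_PROBS

    settings = settings or ModelSettings()
    incidence: Dict[Tuple[str, str], float] = {}
    counts: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for d in DRUGS:
        for e in EVENTS:
            p = IS_RATE_BY_SCORE[2][d] if e == "IS" else DEFAULT_EVENT_PROBS[d][e]
            incidence[(d, e)] = p
            counts[(d, e)] = (p * person_years_per_drug, person_years_per_drug)
    post = dict(post_event_costs) if post_event_costs is not None else {
        "HF": 1500.0, "MI": 1200.0, "IS": 2400.0, "ICH": 3000.0, "GI": 0.0,
    }
    return ModelParameters(
        settings=settings,
        incidence=incidence,
        fatality=base_fatality(),
        post_event_costs=post,
        fatality_counts=dict(FATALITY_COUNTS),
        incidence_counts=counts,
    )


def parameters_from_estimates(
    incidence_table: pd.DataFrame,
    fatality_table: pd.DataFrame,
    settings: Optional[ModelSettings] = None,
    post_event_costs: Optional[Mapping[str, float]] = None,
    fallback_fatality: Optional[Mapping[str, float]] = None,
) -> ModelParameters:
    """Assemble model parameters from estimator outputs.

    Picks the incidence stratum named in ``settings.incidence_stratum``.
    Undefined estimated fatality cells (zero observed events) fall back to
    ``fallback_fatality`` (default: the published base-case values), logged.
    """
    settings = settings or ModelSettings()
    stratum = {"score1": "1", "score2": "2", "pooled": "pooled"}[settings.incidence_stratum]
    sub = incidence_table[incidence_table["score"].astype(str) == stratum]
    if not len(sub):
        raise ValueError(f"incidence table has no rows for stratum {stratum!r}")
    incidence = {}
    counts = {}
    for _, r in sub.iterrows():
        key = (r["drug"], r["event"])
        incidence[key] = float(r["rate"]) if pd.notna(r["rate"]) else 0.0
        counts[key] = (float(r["events"]), float(r["person_years"]))

    fallback = dict(fallback_fatality) if fallback_fatality is not None else base_fatality()
    fatality = {}
    fat_counts = {}
    for _, r in fatality_table.iterrows():
        e = r["event"]
        if pd.isna(r["probability"]):
            logger.warning("no observed %s events; using fallback fatality %.4f", e, fallback[e])
            fatality[e] = fallback[e]
        else:
            fatality[e] = float(r["probability"])
            fat_counts[e] = (int(r["deaths"]), int(r["events"]))

    if post_event_costs is None:
        warnings.warn(
            "post-event annual costs not supplied; defaulting to 0 "
            "(the source derives them by subtraction from unpublished totals)",
            stacklevel=2,
        )
    return ModelParameters(
        settings=settings,
        incidence=incidence,
        fatality=fatality,
        post_event_costs=dict(post_event_costs) if post_event_costs else {e: 0.0 for e in EVENTS},
        fatality_counts=fat_counts or None,
        incidence_counts=counts,
    )
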