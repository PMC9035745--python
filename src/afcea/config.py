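"""Run configuration: schema validation, defaults, and hashing.

A run config is a YAML/JSON mapping with blocks ``generator``, ``windows``,
``codemap``, ``model`` (required) and ``psa``/``dsa``. Unknown keys are
errors — nothing is silently ignored — and every default that gets applied
is logged so a run can be reconstructed from its log alone. Currency is USD
throughout; KRW inputs are converted once on ingest at the fixed rate in
``model.settings.krw_per_usd``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping, Optional

import yaml

from .codes import CodeMap, DRUGS, EVENTS, StudyWindow
from .markov import ModelSettings
from .params import (
    DRUG_UTILITY,
    EVENT_COST,
    EVENT_UTILITY,
    FATALITY_COUNTS,
    MEDICATION_COST,
    ModelParameters,
    base_fatality,
)
from .synthetic import GeneratorConfig

logger = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    """Schema violation, reported with the offending key path."""


_SETTINGS_KEYS = {
    "n_cycles", "discount_rate", "wtp", "krw_per_usd",
    "fatality_mode", "incidence_stratum", "utility_mode",
}
_GENERATOR_KEYS = {
    "n_patients", "sex_ratio", "age_min", "age_max", "age_mean",
    "comorbidity_prevalences", "drug_assignment_probs", "true_annual_event_probs",
    "true_fatality_probs", "switcher_fraction", "intermediate_risk_fraction",
    "washout_violator_fraction", "followup_years", "seed",
}
_WINDOW_KEYS = {"washout_start", "washout_end", "enroll_start", "enroll_end"}
_MODEL_KEYS = {"settings", "utilities", "costs", "incidence", "fatality", "currency"}
_UTILITY_KEYS = {"drug", "event"}
_COST_KEYS = {"medication", "event", "post_event"}
_PSA_KEYS = {"n_iter", "seed", "cost_cv", "event_utility_cv", "drug_utility_cv"}
_DSA_KEYS = {"bounds"}
_TOP_KEYS = {"generator", "windows", "codemap", "model", "psa", "dsa"}


def _check_keys(block: Mapping[str, Any], allowed: set, path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigValidationError(f"unknown key(s) at {path}: {sorted(unknown)}")


def _require_mapping(value: Any, path: str) -> Mapping[str, Any]:
    if not isinstance(value, Mapping):
        raise ConfigValidationError(f"{path} must be a mapping")
    return value


@dataclass
class RunConfig:
    """Fully validated configuration for the end-to-end pipeline."""

    generator: GeneratorConfig
    window: StudyWindow
    codemap: CodeMap
    settings: ModelSettings
    drug_utilities: Dict[str, float]
    event_utilities: Dict[str, float]
    medication_costs: Dict[str, float]
    event_costs: Dict[str, float]
    post_event_costs: Dict[str, float]
    incidence_override: Optional[Dict[str, Dict[str, float]]]
    fatality_override: Optional[Dict[str, float]]
    psa_n_iter: int = 10_000
    psa_cost_cv: float = 0.2
    psa_event_utility_cv: float = 0.2
    psa_drug_utility_cv: float = 0.005
    raw: Dict[str, Any] = field(default_factory=dict)

    def semantic_dict(self) -> Dict[str, Any]:
        """Canonical content used for the manifest hash."""
        return {
            "generator": self.generator.to_dict(),
            "window": {
                "washout_start": str(self.window.washout_start.date()),
                "washout_end": str(self.window.washout_end.date()),
                "enroll_start": str(self.window.enroll_start.date()),
                "enroll_end": str(self.window.enroll_end.date()),
            },
            "codemap": {
                "af_codes": list(self.codemap.af_codes),
                "components": {k: list(v) for k, v in sorted(self.codemap.component_codes.items())},
            },
            "settings": {
                "n_cycles": self.settings.n_cycles,
                "discount_rate": self.settings.discount_rate,
                "wtp": self.settings.wtp,
                "krw_per_usd": self.settings.krw_per_usd,
                "fatality_mode": self.settings.fatality_mode,
                "incidence_stratum": self.settings.incidence_stratum,
                "utility_mode": self.settings.utility_mode,
            },
            "drug_utilities": dict(sorted(self.drug_utilities.items())),
            "event_utilities": dict(sorted(self.event_utilities.items())),
            "medication_costs": dict(sorted(self.medication_costs.items())),
            "event_costs": dict(sorted(self.event_costs.items())),
            "post_event_costs": dict(sorted(self.post_event_costs.items())),
            "incidence_override": self.incidence_override,
            "fatality_override": self.fatality_override,
            "psa": {
                "n_iter": self.psa_n_iter,
                "cost_cv": self.psa_cost_cv,
                "event_utility_cv": self.psa_event_utility_cv,
                "drug_utility_cv": self.psa_drug_utility_cv,
            },
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _default(name: str, value):
    logger.info("config default applied: %s = %r", name, value)
    return value


def _named_map(block: Mapping[str, Any], names, path: str, non_negative: bool = False) -> Dict[str, float]:
    out = {}
    _check_keys(block, set(names), path)
    for key in names:
        if key not in block:
            raise ConfigValidationError(f"missing key {path}.{key}")
        value = float(block[key])
        if non_negative and value < 0:
            raise ConfigValidationError(f"{path}.{key} must be non-negative, got {value}")
        out[key] = value
    return out


def validate_config(raw: str | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a config document, applying logged defaults."""
    if isinstance(raw, str):
        parsed = yaml.safe_load(raw)
    else:
        parsed = raw
    if parsed is None or not isinstance(parsed, Mapping):
        raise ConfigValidationError(
            "config is empty or not a mapping; required blocks: model (plus "
            "optional generator, windows, codemap, psa, dsa)"
        )
    _check_keys(parsed, _TOP_KEYS, "<root>")
    if "model" not in parsed:
        raise ConfigValidationError("missing required block: model")

    # Windows
    win_block = _require_mapping(parsed.get("windows", {}), "windows")
    _check_keys(win_block, _WINDOW_KEYS, "windows")
    window = StudyWindow().replace(**win_block) if win_block else StudyWindow()

    # Code map
    cm_block = _require_mapping(parsed.get("codemap", {}), "codemap")
    codemap = CodeMap().with_overrides(cm_block) if cm_block else CodeMap()

    # Generator
    gen_block = dict(_require_mapping(parsed.get("generator", {}), "generator"))
    _check_keys(gen_block, _GENERATOR_KEYS, "generator")
    generator = GeneratorConfig(window=window, **gen_block)
    generator.validate()

    # Model block
    model = _require_mapping(parsed["model"], "model")
    _check_keys(model, _MODEL_KEYS, "model")
    settings_block = dict(_require_mapping(model.get("settings", {}), "model.settings"))
    _check_keys(settings_block, _SETTINGS_KEYS, "model.settings")
    defaults = ModelSettings()
    for key in _SETTINGS_KEYS:
        if key not in settings_block:
            settings_block[key] = _default(f"model.settings.{key}", getattr(defaults, key))
    settings = ModelSettings(**settings_block)

    krw = str(model.get("currency", "USD")).upper()
    if krw not in ("USD", "KRW"):
        raise ConfigValidationError("model.currency must be 'USD' or 'KRW'")
    scale = 1.0 / settings.krw_per_usd if krw == "KRW" else 1.0

    util_block = _require_mapping(model.get("utilities", {}), "model.utilities")
    _check_keys(util_block, _UTILITY_KEYS, "model.utilities")
    if "drug" in util_block:
        drug_u = _named_map(_require_mapping(util_block["drug"], "model.utilities.drug"), DRUGS, "model.utilities.drug")
    else:
        drug_u = _default("model.utilities.drug", dict(DRUG_UTILITY))
    if "event" in util_block:
        event_u = _named_map(_require_mapping(util_block["event"], "model.utilities.event"), EVENTS, "model.utilities.event")
    else:
        event_u = _default("model.utilities.event", dict(EVENT_UTILITY))

    cost_block = _require_mapping(model.get("costs", {}), "model.costs")
    _check_keys(cost_block, _COST_KEYS, "model.costs")
    if "medication" in cost_block:
        med_c = _named_map(
            _require_mapping(cost_block["medication"], "model.costs.medication"),
            DRUGS, "model.costs.medication", non_negative=True,
        )
    else:
        med_c = _default("model.costs.medication", dict(MEDICATION_COST))
    if "event" in cost_block:
        event_c = _named_map(
            _require_mapping(cost_block["event"], "model.costs.event"),
            EVENTS, "model.costs.event", non_negative=True,
        )
    else:
        event_c = _default("model.costs.event", dict(EVENT_COST))
    if "post_event" in cost_block:
        post_c = _named_map(
            _require_mapping(cost_block["post_event"], "model.costs.post_event"),
            EVENTS, "model.costs.post_event", non_negative=True,
        )
    else:
        post_c = _default("model.costs.post_event", {e: 0.0 for e in EVENTS})
    med_c = {k: v * scale for k, v in med_c.items()}
    event_c = {k: v * scale for k, v in event_c.items()}
    post_c = {k: v * scale for k, v in post_c.items()}

    incidence_override = None
    if "incidence" in model:
        block = _require_mapping(model["incidence"], "model.incidence")
        _check_keys(block, set(DRUGS), "model.incidence")
        incidence_override = {
            d: _named_map(_require_mapping(block[d], f"model.incidence.{d}"), EVENTS, f"model.incidence.{d}")
            for d in block
        }
        for d, probs in incidence_override.items():
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigValidationError(f"model.incidence.{d} probabilities out of [0, 1]")

    fatality_override = None
    if "fatality" in model:
        block = _require_mapping(model["fatality"], "model.fatality")
        fatality_override = _named_map(block, EVENTS, "model.fatality")
        if any(not 0 <= f <= 1 for f in fatality_override.values()):
            raise ConfigValidationError("model.fatality probabilities out of [0, 1]")

    psa_block = dict(_require_mapping(parsed.get("psa", {}), "psa"))
    _check_keys(psa_block, _PSA_KEYS, "psa")
    dsa_block = _require_mapping(parsed.get("dsa", {}), "dsa")
    _check_keys(dsa_block, _DSA_KEYS, "dsa")

    return RunConfig(
        generator=generator,
        window=window,
        codemap=codemap,
        settings=settings,
        drug_utilities=drug_u,
        event_utilities=event_u,
        medication_costs=med_c,
        event_costs=event_c,
        post_event_costs=post_c,
        incidence_override=incidence_override,
        fatality_override=fatality_override,
        psa_n_iter=int(psa_block.get("n_iter", _default("psa.n_iter", 10_000))),
        psa_cost_cv=float(psa_block.get("cost_cv", _default("psa.cost_cv", 0.2))),
        psa_event_utility_cv=float(psa_block.get("event_utility_cv", _default("psa.event_utility_cv", 0.2))),
        psa_drug_utility_cv=float(psa_block.get("drug_utility_cv", _default("psa.drug_utility_cv", 0.005))),
        raw=dict(parsed),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(fh.read())


def parameters_from_config(cfg: RunConfig) -> Optional[ModelParameters]:
    """Model parameters straight from config, when incidence is overridden.

    Returns None when incidence must come from the claims estimator.
    """
    if cfg.incidence_override is None:
        return None
    incidence = {
        (d, e): cfg.incidence_override[d][e] for d in cfg.incidence_override for e in EVENTS
    }
    fatality = cfg.fatality_override or base_fatality()
    return ModelParameters(
        settings=cfg.settings,
        incidence=incidence,
        fatality=fatality,
        drug_utilities=cfg.drug_utilities,
        event_utilities=cfg.event_utilities,
        medication_costs=cfg.medication_costs,
        event_costs=cfg.event_costs,
        post_event_costs=cfg.post_event_costs,
        fatality_counts=dict(FATALITY_COUNTS) if cfg.fatality_override is None else None,
    )
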