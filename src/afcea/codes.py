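"""ICD-10 code maps, composite-event definitions, and study calendar windows.

Code lists follow the claims-phenotyping conventions for non-valvular atrial
fibrillation (AF) cohorts: AF itself is identified by I48 and its subcodes,
CHA2DS2-VASc components by diagnosis-code prefixes in the year before the
index date, and outcome events by admission/outpatient utilization rules.
Prefix matching is "code starts with prefix" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

import pandas as pd

DRUGS: Tuple[str, ...] = ("warfarin", "rivaroxaban", "apixaban", "dabigatran", "edoxaban")
DOACS: Tuple[str, ...] = DRUGS[1:]
EVENTS: Tuple[str, ...] = ("HF", "MI", "IS", "ICH", "GI")

#: CHA2DS2-VASc component -> ICD-10 prefixes. Diabetes has no standard claims
#: definition in many published code tables; E10-E14 is the conventional
#: default and is overridable through :class:`CodeMap`.
DEFAULT_COMPONENT_CODES: Mapping[str, Tuple[str, ...]] = {
    "hypertension": ("I10", "I11", "I12", "I13", "I15"),
    "heart_failure": ("I50",),
    "stroke": ("I60", "I61", "I62", "I63", "I64"),
    "myocardial_infarction": ("I21", "I22"),
    "peripheral_artery_disease": ("I70", "I71"),
    "diabetes": ("E10", "E11", "E12", "E13", "E14"),
}

AF_CODES: Tuple[str, ...] = ("I48",)  # I48 prefix covers I48.0 and I48.1

#: Outcome-event ICD-10 prefixes. Note ischemic stroke uses I63 only, while
#: the CHA2DS2-VASc stroke-history component uses the wider I60-I64 set.
EVENT_CODES: Mapping[str, Tuple[str, ...]] = {
    "HF": ("I50",),
    "MI": ("I21", "I22"),
    "IS": ("I63",),
    "ICH": ("I60", "I61", "I62"),
    "GI": ("K22.6", "K25", "K26", "K27", "K28", "K92.2"),
}

#: Events whose claims definition additionally requires brain imaging (CT/MRI)
#: on a qualifying visit.
IMAGING_EVENTS: Tuple[str, ...] = ("IS", "ICH")


@dataclass(frozen=True)
class EventDefinition:
    """One composite-outcome event: code prefixes plus the utilization rule.

    The utilization rule is fixed across events: at least one admission or at
    least two outpatient visits within a follow-up year; ``imaging_required``
    additionally demands a matching visit with the brain-imaging flag set.
    """

    event: str
    icd10_prefixes: Tuple[str, ...]
    imaging_required: bool = False

    def matches(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.icd10_prefixes)


def default_event_definitions() -> Tuple[EventDefinition, ...]:
    return tuple(
        EventDefinition(e, tuple(EVENT_CODES[e]), imaging_required=e in IMAGING_EVENTS)
        for e in EVENTS
    )


@dataclass(frozen=True)
class CodeMap:
    """Configurable ICD-10 prefix sets for AF and CHA2DS2-VASc components."""

    af_codes: Tuple[str, ...] = AF_CODES
    component_codes: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_CODES)
    )

    def __post_init__(self) -> None:
        for name, prefixes in self.component_codes.items():
            if not prefixes or any(not p for p in prefixes):
                raise ValueError(f"component {name!r} has an empty code prefix")
        if not self.af_codes:
            raise ValueError("af_codes must be non-empty")

    def with_overrides(self, overrides: Mapping[str, Sequence[str]]) -> "CodeMap":
        merged = dict(self.component_codes)
        af = self.af_codes
        for key, prefixes in overrides.items():
            if key == "af_codes":
                af = tuple(prefixes)
            elif key in merged:
                merged[key] = tuple(prefixes)
            else:
                raise KeyError(f"unknown codemap component {key!r}")
        return CodeMap(af_codes=af, component_codes=merged)

    def is_af(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.af_codes)

    def component_prefixes(self, component: str) -> Tuple[str, ...]:
        return tuple(self.component_codes[component])


@dataclass(frozen=True)
class StudyWindow:
    """Half-open calendar windows: washout [start, end) precedes enrollment.

    Defaults mirror a three-year national-claims extract (enrollment
    2016-08-01 to 2019-07-31 inclusive) with the preceding year as washout.
    """

    washout_start: pd.Timestamp = pd.Timestamp("2015-08-01")
    washout_end: pd.Timestamp = pd.Timestamp("2016-08-01")
    enroll_start: pd.Timestamp = pd.Timestamp("2016-08-01")
    enroll_end: pd.Timestamp = pd.Timestamp("2019-08-01")

    def __post_init__(self) -> None:
        if not (self.washout_start < self.washout_end <= self.enroll_start < self.enroll_end):
            raise ValueError("windows must be ordered: washout before enrollment")

    @property
    def study_end(self) -> pd.Timestamp:
        """End of observable follow-up (exclusive)."""
        return self.enroll_end

    def replace(self, **kwargs) -> "StudyWindow":
        return replace(self, **{k: pd.Timestamp(v) for k, v in kwargs.items()})


def code_prefix_mask(codes: pd.Series, prefixes: Sequence[str]) -> pd.Series:
    """Boolean mask over a Series of ICD-10 codes matching any prefix."""
    mask = pd.Series(False, index=codes.index)
    for p in prefixes:
        mask |= codes.str.startswith(p)
    return mask
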