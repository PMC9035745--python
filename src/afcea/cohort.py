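"""New-user anticoagulant cohort construction from claims tables.

Applies, in order: (1) a one-year washout free of AF and AF-related event
diagnoses; (2) the utilization/index-date rule (first AF admission or second
AF outpatient visit inside the enrollment window, whichever is earlier);
(3) adult age, exposure to exactly one anticoagulant class (patients
prescribed both warfarin and a DOAC are excluded as switchers); and (4) the
intermediate-stroke-risk filter, CHA2DS2-VASc 1 in men or 2 in women.
Exclusions are attributed to the first failing criterion so the attrition
table is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .codes import CodeMap, DOACS, EVENT_CODES, StudyWindow, code_prefix_mask
from .synthetic import ClaimsDataset

_LOOKBACK = pd.Timedelta(days=365)

#: CHA2DS2-VASc points per component (age handled separately).
_COMPONENT_POINTS = {
    "congestive_heart_failure": 1,
    "hypertension": 1,
    "diabetes": 1,
    "stroke_history": 2,
    "vascular_disease": 1,
}


class DataError(ValueError):
    """Raised for malformed claims content (bad sex codes, dates, ...)."""


@dataclass(frozen=True)
class RiskProfile:
    """CHA2DS2-VASc components and total for one patient at index."""

    patient_id: str
    age_at_index: int
    sex: str  # 'male' | 'female'
    congestive_heart_failure: bool
    hypertension: bool
    diabetes: bool
    stroke_history: bool
    vascular_disease: bool

    @property
    def component_points(self) -> Dict[str, int]:
        pts = {
            "age": 2 if self.age_at_index >= 75 else (1 if self.age_at_index >= 65 else 0),
            "sex": 1 if self.sex == "female" else 0,
        }
        for comp, weight in _COMPONENT_POINTS.items():
            pts[comp] = weight if getattr(self, comp) else 0
        return pts

    @property
    def total(self) -> int:
        return sum(self.component_points.values())

    @property
    def intermediate_risk(self) -> bool:
        return (self.sex == "male" and self.total == 1) or (
            self.sex == "female" and self.total == 2
        )


def completed_years(birth: pd.Timestamp, ref: pd.Timestamp) -> int:
    """Age in completed calendar years at the reference date."""
    years = ref.year - birth.year
    if (ref.month, ref.day) < (birth.month, birth.day):
        years -= 1
    return years


def determine_index_date(af_visits: pd.DataFrame) -> Optional[pd.Timestamp]:
    """Index date: min(first AF admission, second AF outpatient visit).

    ``af_visits`` must already be restricted to AF codes within the
    enrollment window. Returns ``None`` when neither rule is satisfied.
    """
    if not len(af_visits):
        return None
    candidates = []
    adm = af_visits.loc[af_visits["setting"] == "admission", "date"]
    if len(adm):
        candidates.append(adm.min())
    out = af_visits.loc[af_visits["setting"] == "outpatient", "date"].sort_values()
    if len(out) >= 2:
        candidates.append(out.iloc[1])
    return min(candidates) if candidates else None


def _normalize_sex(value: str) -> str:
    mapping = {"M": "male", "F": "female", "male": "male", "female": "female"}
    try:
        return mapping[value]
    except KeyError:
        raise DataError(f"unknown sex value {value!r}") from None


def score_chads_vasc(
    patient: pd.Series,
    history: pd.DataFrame,
    index_date: pd.Timestamp,
    codemap: CodeMap,
) -> RiskProfile:
    """CHA2DS2-VASc profile from demographics and one year of history.

    ``history`` is the patient's visits; only rows dated in
    [index − 365 d, index) contribute comorbidity flags.
    """
    sex = _normalize_sex(patient["sex"])
    age = completed_years(pd.Timestamp(patient["birth_date"]), index_date)
    window = history[(history["date"] >= index_date - _LOOKBACK) & (history["date"] < index_date)]
    codes = window["icd10_code"].astype(str)

    def has(*components: str) -> bool:
        return any(
            code_prefix_mask(codes, codemap.component_prefixes(c)).any() for c in components
        )

    return RiskProfile(
        patient_id=str(patient["patient_id"]),
        age_at_index=age,
        sex=sex,
        congestive_heart_failure=has("heart_failure"),
        hypertension=has("hypertension"),
        diabetes=has("diabetes"),
        stroke_history=has("stroke"),
        vascular_disease=has("myocardial_infarction", "peripheral_artery_disease"),
    )


def _index_dates(dataset: ClaimsDataset, codemap: CodeMap, window: StudyWindow) -> pd.Series:
    """Vectorized index-date computation for every patient with AF visits."""
    v = dataset.visits
    af = v[
        code_prefix_mask(v["icd10_code"].astype(str), codemap.af_codes)
        & (v["date"] >= window.enroll_start)
        & (v["date"] < window.enroll_end)
    ]
    first_adm = af[af["setting"] == "admission"].groupby("patient_id")["date"].min()
    out_sorted = af[af["setting"] == "outpatient"].sort_values("date", kind="mergesort").copy()
    out_sorted["visit_rank"] = out_sorted.groupby("patient_id").cumcount()
    second_out = out_sorted[out_sorted["visit_rank"] == 1].set_index("patient_id")["date"]
    combined = pd.concat([first_adm, second_out], axis=1, keys=["adm", "out2"])
    return combined.min(axis=1)


def apply_inclusion(
    dataset: ClaimsDataset,
    codemap: CodeMap,
    window: StudyWindow,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply criteria 1-3, returning candidates plus an exclusion tally.

    Candidates carry ``patient_id, sex, birth_date, death_date, index_date,
    drug, age_at_index`` in stable patient-id order. The tally attributes
    each excluded patient to the first failing criterion.
    """
    patients = dataset.patients.sort_values("patient_id").reset_index(drop=True)
    attrition: Dict[str, int] = {"input": len(patients)}
    if not len(patients):
        empty = pd.DataFrame(
            columns=["patient_id", "sex", "birth_date", "death_date", "index_date", "drug", "age_at_index"]
        )
        attrition.update(
            {k: 0 for k in ("washout", "no_index_event", "under_18", "no_anticoagulant", "switcher")}
        )
        return empty, attrition

    v = dataset.visits
    codes = v["icd10_code"].astype(str)

    # Criterion 1: no AF or AF-related event diagnosis during washout.
    washout_codes = code_prefix_mask(codes, codemap.af_codes)
    for prefixes in EVENT_CODES.values():
        washout_codes |= code_prefix_mask(codes, prefixes)
    in_washout = (v["date"] >= window.washout_start) & (v["date"] < window.washout_end)
    washout_ids = set(v.loc[washout_codes & in_washout, "patient_id"])
    keep = ~patients["patient_id"].isin(washout_ids)
    attrition["washout"] = int((~keep).sum())
    patients = patients[keep]

    # Criterion 2: an index date exists within the enrollment window.
    index_dates = _index_dates(dataset, codemap, window)
    patients = patients.merge(
        index_dates.rename("index_date"), left_on="patient_id", right_index=True, how="left"
    )
    has_index = patients["index_date"].notna()
    attrition["no_index_event"] = int((~has_index).sum())
    patients = patients[has_index]

    # Criterion 3: adults on exactly one anticoagulant class.
    patients["age_at_index"] = [
        completed_years(b, i) for b, i in zip(patients["birth_date"], patients["index_date"])
    ]
    adult = patients["age_at_index"] >= 18
    attrition["under_18"] = int((~adult).sum())
    patients = patients[adult]

    rx = dataset.prescriptions
    rx_drugs = rx.groupby("patient_id")["drug_name"].agg(set)
    first_rx = rx.sort_values(["date", "drug_name"], kind="mergesort").groupby("patient_id")[
        "drug_name"
    ].first()
    patients = patients.merge(
        rx_drugs.rename("drug_set"), left_on="patient_id", right_index=True, how="left"
    ).merge(first_rx.rename("drug"), left_on="patient_id", right_index=True, how="left")

    has_drug = patients["drug_set"].notna()
    attrition["no_anticoagulant"] = int((~has_drug).sum())
    patients = patients[has_drug]

    doac_set = set(DOACS)
    is_switcher = patients["drug_set"].map(
        lambda s: "warfarin" in s and bool(s & doac_set)
    ).astype(bool)
    attrition["switcher"] = int(is_switcher.sum())
    patients = patients[~is_switcher]

    candidates = patients.drop(columns=["drug_set"]).reset_index(drop=True)
    return candidates, attrition


def score_candidates(
    candidates: pd.DataFrame, visits: pd.DataFrame, codemap: CodeMap
) -> pd.DataFrame:
    """Vectorized CHA2DS2-VASc scoring for the candidate table."""
    out = candidates.copy()
    if not len(out):
        for col in ("congestive_heart_failure", "hypertension", "diabetes", "stroke_history", "vascular_disease"):
            out[col] = pd.Series(dtype=bool)
        out["score"] = pd.Series(dtype=int)
        return out

    merged = visits.merge(out[["patient_id", "index_date"]], on="patient_id", how="inner")
    lookback = merged[
        (merged["date"] >= merged["index_date"] - _LOOKBACK) & (merged["date"] < merged["index_date"])
    ]
    codes = lookback["icd10_code"].astype(str)

    component_prefixes = {
        "congestive_heart_failure": codemap.component_prefixes("heart_failure"),
        "hypertension": codemap.component_prefixes("hypertension"),
        "diabetes": codemap.component_prefixes("diabetes"),
        "stroke_history": codemap.component_prefixes("stroke"),
        "vascular_disease": codemap.component_prefixes("myocardial_infarction")
        + codemap.component_prefixes("peripheral_artery_disease"),
    }
    for comp, prefixes in component_prefixes.items():
        hit_ids = set(lookback.loc[code_prefix_mask(codes, prefixes), "patient_id"])
        out[comp] = out["patient_id"].isin(hit_ids)

    sex = out["sex"].map({"M": "male", "F": "female", "male": "male", "female": "female"})
    if sex.isna().any():
        bad = out.loc[sex.isna(), "sex"].iloc[0]
        raise DataError(f"unknown sex value {bad!r}")
    out["sex"] = sex

    age_points = np.where(out["age_at_index"] >= 75, 2, np.where(out["age_at_index"] >= 65, 1, 0))
    out["score"] = (
        age_points
        + (out["sex"] == "female").astype(int)
        + out["congestive_heart_failure"].astype(int)
        + out["hypertension"].astype(int)
        + out["diabetes"].astype(int)
        + 2 * out["stroke_history"].astype(int)
        + out["vascular_disease"].astype(int)
    )
    return out


def select_intermediate_risk(scored: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Keep exactly (male, score 1) and (female, score 2)."""
    keep = ((scored["sex"] == "male") & (scored["score"] == 1)) | (
        (scored["sex"] == "female") & (scored["score"] == 2)
    )
    cohort = scored[keep].reset_index(drop=True)
    counts = cohort["drug"].value_counts().to_dict()
    return cohort, counts


def build_cohort(
    dataset: ClaimsDataset,
    codemap: Optional[CodeMap] = None,
    window: Optional[StudyWindow] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Full cohort pipeline: inclusion criteria, scoring, risk selection.

    Returns the cohort table (one row per member, with index date, drug,
    risk components, score, and follow-up end = min(death, study end)) and
    the ordered attrition tally.
    """
    codemap = codemap or CodeMap()
    window = window or StudyWindow()
    candidates, attrition = apply_inclusion(dataset, codemap, window)
    scored = score_candidates(candidates, dataset.visits, codemap)
    cohort, _ = select_intermediate_risk(scored)
    attrition["not_intermediate_risk"] = len(scored) - len(cohort)
    attrition["included"] = len(cohort)

    if len(cohort):
        death = pd.to_datetime(cohort["death_date"])
        cohort["followup_end"] = death.fillna(window.study_end).clip(upper=window.study_end)
    else:
        cohort["followup_end"] = pd.Series(dtype="datetime64[ns]")
    return cohort, attrition


def write_cohort(cohort: pd.DataFrame, attrition: Dict[str, int], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False, date_format="%Y-%m-%d")
    pd.DataFrame(
        [{"criterion": k, "count": c} for k, c in attrition.items()]
    ).to_csv(out / "attrition.csv", index=False)
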