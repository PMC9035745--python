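"""Synthetic administrative-claims generator with known ground truth.

Emulates the structure of a national health-insurance extract — patient
demographics, dated ICD-10 visit records (admission/outpatient, with a
brain-imaging flag), and drug prescriptions — for a new-user anticoagulant
cohort in atrial fibrillation. Every downstream stage (cohort construction,
event detection, incidence estimation) can therefore be tested against the
configured truth without any real data.

Event histories are simulated per patient-year as competing Bernoulli draws
(a categorical draw over the five event types, at most one event per year),
matching the one-event-per-year counting rule used by the incidence
estimator. The final partial follow-up year uses a length-scaled event
probability so that fractional person-year estimation is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import json
import numpy as np
import pandas as pd

from .codes import (
    DEFAULT_COMPONENT_CODES,
    DOACS,
    DRUGS,
    EVENTS,
    EVENT_CODES,
    IMAGING_EVENTS,
    StudyWindow,
)

_DAY = pd.Timedelta(days=1)

#: Printed score-1 annual ischemic-stroke rates per drug, used as realistic
#: generator defaults; other events share plausible constants across drugs.
DEFAULT_EVENT_PROBS: Mapping[str, Mapping[str, float]] = {
    drug: {"HF": 0.040, "MI": 0.004, "IS": p_is, "ICH": 0.0015, "GI": 0.006}
    for drug, p_is in zip(DRUGS, (0.0075, 0.0107, 0.0150, 0.0455, 0.0133))
}

DEFAULT_FATALITY_PROBS: Mapping[str, float] = {
    "HF": 4 / 1223,
    "MI": 0.0,
    "IS": 2 / 92,
    "ICH": 1 / 8,
    "GI": 1 / 54,
}

_SINGLE_POINT_COMORBIDITIES = ("hypertension", "diabetes", "heart_failure", "vascular_disease")

_COMORBIDITY_CODE_POOL: Mapping[str, tuple] = {
    "hypertension": DEFAULT_COMPONENT_CODES["hypertension"],
    "diabetes": DEFAULT_COMPONENT_CODES["diabetes"],
    "heart_failure": DEFAULT_COMPONENT_CODES["heart_failure"],
    "vascular_disease": DEFAULT_COMPONENT_CODES["myocardial_infarction"]
    + DEFAULT_COMPONENT_CODES["peripheral_artery_disease"],
    "prior_stroke": DEFAULT_COMPONENT_CODES["stroke"],
}


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic claims population.

    ``true_annual_event_probs`` maps drug -> event -> annual probability;
    ``true_fatality_probs`` maps event -> in-hospital case-fatality
    probability. ``intermediate_risk_fraction`` controls how many patients are
    constructed to sit exactly at the intermediate-risk threshold
    (CHA2DS2-VASc 1 in men, 2 in women); the remainder draw age and
    comorbidities freely so the downstream risk filter has work to do.
    """

    n_patients: int = 10_000
    sex_ratio: float = 0.5  # fraction female
    age_min: int = 18
    age_max: int = 90
    age_mean: Optional[float] = None  # triangular mode when given, else uniform
    comorbidity_prevalences: Dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.35,
            "diabetes": 0.15,
            "heart_failure": 0.08,
            "vascular_disease": 0.06,
            "prior_stroke": 0.05,
        }
    )
    drug_assignment_probs: Dict[str, float] = field(
        default_factory=lambda: {d: 0.2 for d in DRUGS}
    )
    true_annual_event_probs: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {d: dict(DEFAULT_EVENT_PROBS[d]) for d in DRUGS}
    )
    true_fatality_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FATALITY_PROBS)
    )
    switcher_fraction: float = 0.05
    intermediate_risk_fraction: float = 0.8
    washout_violator_fraction: float = 0.03
    followup_years: int = 2
    window: StudyWindow = field(default_factory=StudyWindow)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        for name, value in [
            ("sex_ratio", self.sex_ratio),
            ("switcher_fraction", self.switcher_fraction),
            ("intermediate_risk_fraction", self.intermediate_risk_fraction),
            ("washout_violator_fraction", self.washout_violator_fraction),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not 18 <= self.age_min <= self.age_max:
            raise ConfigError("require 18 <= age_min <= age_max")
        for name, p in self.comorbidity_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"comorbidity prevalence {name}={p} out of [0, 1]")
        if set(self.drug_assignment_probs) != set(DRUGS):
            raise ConfigError(f"drug_assignment_probs must cover exactly {DRUGS}")
        total = sum(self.drug_assignment_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"drug_assignment_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.drug_assignment_probs.values()):
            raise ConfigError("drug assignment probabilities must be non-negative")
        for drug in DRUGS:
            probs = self.true_annual_event_probs.get(drug)
            if probs is None or set(probs) != set(EVENTS):
                raise ConfigError(f"true_annual_event_probs[{drug!r}] must cover {EVENTS}")
            if any(not 0.0 <= probs[e] <= 1.0 for e in EVENTS):
                raise ConfigError(f"event probabilities for {drug} out of [0, 1]")
            if sum(probs.values()) > 1.0 + 1e-12:
                raise ConfigError(f"event probabilities for {drug} sum above 1")
        for e in EVENTS:
            f = self.true_fatality_probs.get(e)
            if f is None or not 0.0 <= f <= 1.0:
                raise ConfigError(f"fatality probability for {e} missing or out of [0, 1]")
        if self.followup_years < 1:
            raise ConfigError("followup_years must be >= 1")
        horizon = (self.window.study_end - self.window.enroll_start).days
        if self.followup_years * 365 + 31 > horizon:
            raise ConfigError("followup_years does not fit inside the enrollment window")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "sex_ratio": self.sex_ratio,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "age_mean": self.age_mean,
            "comorbidity_prevalences": dict(self.comorbidity_prevalences),
            "drug_assignment_probs": dict(self.drug_assignment_probs),
            "true_annual_event_probs": {d: dict(v) for d, v in self.true_annual_event_probs.items()},
            "true_fatality_probs": dict(self.true_fatality_probs),
            "switcher_fraction": self.switcher_fraction,
            "intermediate_risk_fraction": self.intermediate_risk_fraction,
            "washout_violator_fraction": self.washout_violator_fraction,
            "followup_years": self.followup_years,
            "window": {
                "washout_start": str(self.window.washout_start.date()),
                "washout_end": str(self.window.washout_end.date()),
                "enroll_start": str(self.window.enroll_start.date()),
                "enroll_end": str(self.window.enroll_end.date()),
            },
            "seed": self.seed,
        }


_PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "death_date"]
_VISIT_COLUMNS = ["patient_id", "date", "icd10_code", "setting", "brain_imaging_flag"]
_RX_COLUMNS = ["patient_id", "date", "drug_name"]


@dataclass
class ClaimsDataset:
    """Three linked claims tables: patients, visits, prescriptions."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    prescriptions: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.patients["patient_id"])
        for name, table in [("visits", self.visits), ("prescriptions", self.prescriptions)]:
            orphans = set(table["patient_id"]) - ids
            if orphans:
                raise ValueError(f"{name} reference unknown patients: {sorted(orphans)[:5]}")
        if len(self.patients):
            merged = self.visits.merge(
                self.patients[["patient_id", "death_date"]], on="patient_id"
            )
            bad = merged["death_date"].notna() & (merged["date"] > merged["death_date"])
            if bad.any():
                raise ValueError("visits dated after the patient's death")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False, date_format="%Y-%m-%d")
        self.visits.to_csv(out / "visits.csv", index=False, date_format="%Y-%m-%d")
        self.prescriptions.to_csv(out / "prescriptions.csv", index=False, date_format="%Y-%m-%d")

    @classmethod
    def read(cls, in_dir: str | Path) -> "ClaimsDataset":
        src = Path(in_dir)
        patients = pd.read_csv(src / "patients.csv", dtype={"patient_id": str})
        visits = pd.read_csv(src / "visits.csv", dtype={"patient_id": str})
        rx = pd.read_csv(src / "prescriptions.csv", dtype={"patient_id": str})
        for frame, col in [(patients, "birth_date"), (patients, "death_date"), (visits, "date"), (rx, "date")]:
            try:
                frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d")
            except (ValueError, TypeError) as exc:
                raise ValueError(f"malformed date in column {col!r}: {exc}") from exc
        if len(visits):
            visits["brain_imaging_flag"] = visits["brain_imaging_flag"].astype(bool)
        return cls(patients=patients, visits=visits, prescriptions=rx)


def _empty_dataset() -> ClaimsDataset:
    return ClaimsDataset(
        patients=pd.DataFrame(columns=_PATIENT_COLUMNS),
        visits=pd.DataFrame(columns=_VISIT_COLUMNS),
        prescriptions=pd.DataFrame(columns=_RX_COLUMNS),
    )


def _timestamp_array(base: pd.Timestamp, day_offsets: np.ndarray) -> pd.Series:
    return pd.Series(base + pd.to_timedelta(day_offsets.astype("int64"), unit="D"))


def generate_population(config: GeneratorConfig) -> ClaimsDataset:
    """Generate a synthetic claims dataset; deterministic given the seed."""
    config.validate()
    n = config.n_patients
    if n == 0:
        return _empty_dataset()

    rng = np.random.default_rng(config.seed)
    win = config.window
    drug_idx_all = {d: i for i, d in enumerate(DRUGS)}

    pid = np.array([f"P{i:07d}" for i in range(n)])
    female = rng.random(n) < config.sex_ratio
    intermediate = rng.random(n) < config.intermediate_risk_fraction
    washout_violator = rng.random(n) < config.washout_violator_fraction

    # Index dates: at least 30 days after enrollment start, with at least
    # `followup_years` of potential follow-up before the study end.
    lo = 30
    hi = (win.study_end - win.enroll_start).days - config.followup_years * 365
    index_offset = rng.integers(lo, hi + 1, size=n)
    index = _timestamp_array(win.enroll_start, index_offset)

    # Ages and comorbidity flags. Intermediate-risk patients are built to sit
    # exactly at the score threshold via an age point (65-74) or exactly one
    # single-point comorbidity at age < 65; everyone else draws freely.
    comorbidity = {c: np.zeros(n, dtype=bool) for c in _COMORBIDITY_CODE_POOL}
    age = np.zeros(n, dtype=np.int64)

    free = ~intermediate
    n_free = int(free.sum())
    if n_free:
        if config.age_mean is not None:
            draws = rng.triangular(config.age_min, config.age_mean, config.age_max + 1, n_free)
            age[free] = np.clip(draws.astype(np.int64), config.age_min, config.age_max)
        else:
            age[free] = rng.integers(config.age_min, config.age_max + 1, size=n_free)
        for c, prev in config.comorbidity_prevalences.items():
            comorbidity[c][free] = rng.random(n_free) < prev

    n_mid = int(intermediate.sum())
    if n_mid:
        age_route = rng.random(n_mid) < 0.5
        mid_idx = np.flatnonzero(intermediate)
        age[mid_idx[age_route]] = rng.integers(65, 75, size=int(age_route.sum()))
        n_com = int((~age_route).sum())
        age[mid_idx[~age_route]] = rng.integers(config.age_min, 65, size=n_com)
        weights = np.array(
            [config.comorbidity_prevalences.get(c, 0.0) for c in _SINGLE_POINT_COMORBIDITIES],
            dtype=float,
        )
        weights = weights / weights.sum() if weights.sum() > 0 else np.full(4, 0.25)
        which = rng.choice(len(_SINGLE_POINT_COMORBIDITIES), size=n_com, p=weights)
        for k, c in enumerate(_SINGLE_POINT_COMORBIDITIES):
            comorbidity[c][mid_idx[~age_route][which == k]] = True

    # Birth dates consistent with completed-years age at index.
    jitter = rng.integers(5, 361, size=n)
    birth = index - pd.to_timedelta(np.round(age * 365.25).astype("int64") + jitter, unit="D")

    visit_frames = []

    def add_visits(mask_or_idx, dates, codes, setting, imaging=False):
        frame = pd.DataFrame(
            {
                "patient_id": pid[mask_or_idx],
                "date": pd.Series(dates).reset_index(drop=True),
                "icd10_code": codes,
                "setting": setting,
                "brain_imaging_flag": imaging,
            }
        )
        visit_frames.append(frame)

    # AF qualifying visits defining the index date.
    af_code_choices = np.array(["I48", "I48.0", "I48.1"])
    admission_route = rng.random(n) < 0.3
    adm_idx = np.flatnonzero(admission_route)
    out_idx = np.flatnonzero(~admission_route)
    if adm_idx.size:
        add_visits(adm_idx, index.iloc[adm_idx], rng.choice(af_code_choices, adm_idx.size), "admission")
        extra = adm_idx[rng.random(adm_idx.size) < 0.5]
        if extra.size:
            avail = np.maximum(index_offset[extra] - 1, 1)
            gap = np.minimum(rng.integers(10, 171, size=extra.size), avail)
            add_visits(
                extra,
                index.iloc[extra] - pd.to_timedelta(gap, unit="D"),
                rng.choice(af_code_choices, extra.size),
                "outpatient",
            )
    if out_idx.size:
        add_visits(out_idx, index.iloc[out_idx], rng.choice(af_code_choices, out_idx.size), "outpatient")
        avail = np.maximum(index_offset[out_idx] - 1, 1)
        gap = np.minimum(rng.integers(7, 181, size=out_idx.size), avail)
        add_visits(
            out_idx,
            index.iloc[out_idx] - pd.to_timedelta(gap, unit="D"),
            rng.choice(af_code_choices, out_idx.size),
            "outpatient",
        )

    # Washout violators: an AF visit inside the washout year.
    wv_idx = np.flatnonzero(washout_violator)
    if wv_idx.size:
        span = (win.washout_end - win.washout_start).days
        offs = rng.integers(0, span, size=wv_idx.size)
        add_visits(
            wv_idx,
            _timestamp_array(win.washout_start, offs),
            rng.choice(af_code_choices, wv_idx.size),
            "outpatient",
        )

    # Comorbidity history in the lookback year, clipped to the enrollment
    # window so lookback codes never land in the washout year.
    for c, flags in comorbidity.items():
        c_idx = np.flatnonzero(flags)
        if not c_idx.size:
            continue
        span = np.minimum(index_offset[c_idx], 365)
        offs = rng.integers(1, np.maximum(span, 2))
        codes = rng.choice(np.array(_COMORBIDITY_CODE_POOL[c]), size=c_idx.size)
        add_visits(c_idx, index.iloc[c_idx] - pd.to_timedelta(offs, unit="D"), codes, "outpatient")

    # Drug assignment and prescriptions.
    drug_probs = np.array([config.drug_assignment_probs[d] for d in DRUGS])
    drug_idx = rng.choice(len(DRUGS), size=n, p=drug_probs)
    drug = np.array(DRUGS)[drug_idx]
    rx_frames = [pd.DataFrame({"patient_id": pid, "date": index, "drug_name": drug})]

    switcher = rng.random(n) < config.switcher_fraction
    sw_idx = np.flatnonzero(switcher)
    if sw_idx.size:
        other = np.where(
            drug[sw_idx] == "warfarin", rng.choice(np.array(DOACS), size=sw_idx.size), "warfarin"
        )
        sw_dates = index.iloc[sw_idx] + pd.to_timedelta(rng.integers(30, 301, size=sw_idx.size), unit="D")

    # Event simulation per follow-up year through the study end; final partial
    # year scales the event probability by its length fraction.
    event_prob = np.zeros((len(DRUGS), len(EVENTS)))
    for d in DRUGS:
        for j, e in enumerate(EVENTS):
            event_prob[drug_idx_all[d], j] = config.true_annual_event_probs[d][e]
    fatality = np.array([config.true_fatality_probs[e] for e in EVENTS])
    p_patient = event_prob[drug_idx]  # (n, 5)

    alive = np.ones(n, dtype=bool)
    death_offset = np.full(n, -1, dtype=np.int64)  # days from enroll_start
    study_days = (win.study_end - win.enroll_start).days
    max_years = int(np.ceil((study_days - lo) / 365)) + 1

    for y in range(max_years):
        ws = index_offset + 365 * y
        we = np.minimum(ws + 365, study_days)
        active = alive & (ws < study_days)
        if not active.any():
            break
        frac = np.where(active, (we - ws) / 365.0, 0.0)
        cum = np.cumsum(p_patient * frac[:, None], axis=1)
        u = rng.random(n)
        hit = active & (u < cum[:, -1])
        which_event = np.argmax(u[:, None] < cum, axis=1)
        hit_idx = np.flatnonzero(hit)
        if hit_idx.size == 0:
            continue
        ev = which_event[hit_idx]
        window_len = we[hit_idx] - ws[hit_idx]
        ev_off = ws[hit_idx] + rng.integers(0, np.maximum(window_len, 1))
        ev_dates = _timestamp_array(win.enroll_start, ev_off)
        codes = np.array([rng.choice(EVENT_CODES[EVENTS[e]]) for e in ev])
        imaging = np.isin(np.array(EVENTS)[ev], IMAGING_EVENTS)
        frame = pd.DataFrame(
            {
                "patient_id": pid[hit_idx],
                "date": ev_dates.values,
                "icd10_code": codes,
                "setting": "admission",
                "brain_imaging_flag": imaging,
            }
        )
        visit_frames.append(frame)
        fatal = rng.random(hit_idx.size) < fatality[ev]
        dead = hit_idx[fatal]
        if dead.size:
            death_offset[dead] = ev_off[fatal] + rng.integers(0, 31, size=dead.size)
            alive[dead] = False

    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    has_death = death_offset >= 0
    if has_death.any():
        death_date[has_death] = _timestamp_array(
            win.enroll_start, death_offset[has_death]
        ).values

    if sw_idx.size:
        # Switch prescriptions must not post-date death.
        capped = pd.Series(sw_dates).reset_index(drop=True)
        dd = death_date.iloc[sw_idx].reset_index(drop=True)
        capped = capped.where(dd.isna() | (capped <= dd), dd)
        rx_frames.append(
            pd.DataFrame({"patient_id": pid[sw_idx], "date": capped.values, "drug_name": other})
        )

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": np.where(female, "F", "M"),
            "birth_date": birth,
            "death_date": death_date.values,
        }
    )
    visits = (
        pd.concat(visit_frames, ignore_index=True)
        .sort_values(["patient_id", "date", "icd10_code"], kind="mergesort")
        .reset_index(drop=True)
    )
    prescriptions = (
        pd.concat(rx_frames, ignore_index=True)
        .sort_values(["patient_id", "date", "drug_name"], kind="mergesort")
        .reset_index(drop=True)
    )
    dataset = ClaimsDataset(patients=patients, visits=visits, prescriptions=prescriptions)
    dataset.validate()
    return dataset


def ground_truth_parameters(config: GeneratorConfig):
    """True incidence and fatality tables implied by the config.

    Returns ``(incidence, fatality)`` data frames shaped like the estimator's
    output so recovery tests can compare cell by cell.
    """
    config.validate()
    incidence = pd.DataFrame(
        [
            {"drug": d, "event": e, "rate": config.true_annual_event_probs[d][e]}
            for d in DRUGS
            for e in EVENTS
        ]
    )
    fatality = pd.DataFrame(
        [{"event": e, "probability": config.true_fatality_probs[e]} for e in EVENTS]
    )
    return incidence, fatality


def write_ground_truth(config: GeneratorConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
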