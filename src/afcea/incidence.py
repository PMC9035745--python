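"""Composite-outcome detection and annual incidence / case-fatality rates.

Events (heart failure, myocardial infarction, ischemic stroke, intracranial
hemorrhage, gastrointestinal bleeding) are detected per follow-up year —
index-anniversary windows, not calendar years — under the claims rule
"admission >= 1 or outpatient >= 2", with brain imaging additionally
required for IS and ICH. However often the codes recur inside one follow-up
year, at most one event of each type is counted for that year.

Annual incidence per (drug, score, event) is first-event count divided by
person-years at risk, where a member stops contributing to an event type at
their first event of that type, at death, or at follow-up end (whole years;
the final partial year contributes its fraction). Case fatality per event
type is deaths within 30 days of the event date over all detected events.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .codes import EVENTS, EventDefinition, default_event_definitions, code_prefix_mask

_YEAR_DAYS = 365.0
_FATALITY_WINDOW = pd.Timedelta(days=30)

_EVENT_COLUMNS = ["patient_id", "event", "year", "event_date"]


class EstimationError(ValueError):
    """Raised when a rate cannot be defined (e.g. zero person-years)."""


def detect_events(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    definitions: Optional[Iterable[EventDefinition]] = None,
) -> pd.DataFrame:
    """Detect at most one event per member, follow-up year, and event type.

    ``cohort`` needs ``patient_id, index_date, followup_end``; ``visits`` is
    the raw visit table. Returns a long frame with columns
    ``patient_id, event, year, event_date`` where ``year`` indexes
    index-anniversary windows from 0 and ``event_date`` is the date the
    utilization rule was met (first admission or second outpatient visit,
    whichever is earlier).
    """
    definitions = tuple(definitions) if definitions is not None else default_event_definitions()
    if not len(cohort) or not len(visits):
        return pd.DataFrame(columns=_EVENT_COLUMNS)

    merged = visits.merge(
        cohort[["patient_id", "index_date", "followup_end"]], on="patient_id", how="inner"
    )
    merged = merged[(merged["date"] >= merged["index_date"])]
    if not len(merged):
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    merged["year"] = (
        (merged["date"] - merged["index_date"]).dt.days // int(_YEAR_DAYS)
    ).astype(int)
    codes = merged["icd10_code"].astype(str)

    records: List[pd.DataFrame] = []
    for d in definitions:
        sub = merged[code_prefix_mask(codes, d.icd10_prefixes)]
        if not len(sub):
            continue
        keys = ["patient_id", "year"]
        adm = sub[sub["setting"] == "admission"]
        adm_first = adm.groupby(keys)["date"].min().rename("adm_date")
        out = sub[sub["setting"] == "outpatient"].sort_values("date", kind="mergesort").copy()
        out["visit_rank"] = out.groupby(keys).cumcount()
        out_second = out[out["visit_rank"] == 1].set_index(keys)["date"].rename("out2_date")
        table = pd.concat([adm_first, out_second], axis=1)
        if d.imaging_required:
            imaging_ok = sub.groupby(keys)["brain_imaging_flag"].any()
            table = table[imaging_ok.reindex(table.index, fill_value=False)]
        if not len(table):
            continue
        event_date = table.min(axis=1)
        event_date = event_date[event_date.notna()]
        if not len(event_date):
            continue
        frame = event_date.rename("event_date").reset_index()
        frame["event"] = d.event
        records.append(frame[_EVENT_COLUMNS])

    if not records:
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    return (
        pd.concat(records, ignore_index=True)
        .sort_values(["patient_id", "event", "year"], kind="mergesort")
        .reset_index(drop=True)
    )


def _person_years(cohort: pd.DataFrame, first_event_year: pd.Series) -> pd.Series:
    """Per-member person-years at risk for one event type."""
    total = (cohort["followup_end"] - cohort["index_date"]).dt.days / _YEAR_DAYS
    y = first_event_year.reindex(cohort["patient_id"]).to_numpy(dtype=float)
    t = total.to_numpy(dtype=float)
    has_event = ~np.isnan(y)
    y0 = np.nan_to_num(y)
    # Event year contributes fully, except a partial final year contributes
    # its observed fraction; event-free members contribute elapsed time.
    py = np.where(has_event, y0 + np.clip(t - y0, 0.0, 1.0), t)
    return pd.Series(py, index=cohort.index)


def estimate_incidence(
    cohort: pd.DataFrame, events: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Annual incidence per (drug, score, event), plus pooled-score rows.

    ``rate = first events / person-years``. Cells with zero person-years are
    undefined: with ``strict=True`` an :class:`EstimationError` is raised,
    otherwise the rate is NaN.
    """
    if not len(cohort):
        return pd.DataFrame(columns=["drug", "score", "event", "events", "person_years", "rate"])

    rows = []
    strata = [(s, cohort["score"] == s) for s in sorted(cohort["score"].unique())]
    strata.append(("pooled", pd.Series(True, index=cohort.index)))
    for event in EVENTS:
        ev = events[events["event"] == event] if len(events) else events
        first_year = (
            ev.groupby("patient_id")["year"].min().astype(float)
            if len(ev)
            else pd.Series(dtype=float)
        )
        py_all = _person_years(cohort, first_year)
        has_event = cohort["patient_id"].isin(set(ev["patient_id"]) if len(ev) else set())
        for score, stratum_mask in strata:
            for drug in sorted(cohort["drug"].unique()):
                mask = stratum_mask & (cohort["drug"] == drug)
                n_events = int(has_event[mask].sum())
                py = float(py_all[mask].sum())
                if py <= 0:
                    if strict:
                        raise EstimationError(
                            f"zero person-years for (drug={drug}, score={score}, event={event})"
                        )
                    rate = float("nan")
                else:
                    rate = n_events / py
                rows.append(
                    {
                        "drug": drug,
                        "score": score,
                        "event": event,
                        "events": n_events,
                        "person_years": py,
                        "rate": rate,
                    }
                )
    return pd.DataFrame(rows)


def truncate_percent(probability: float, decimals: int = 2) -> float:
    """Truncate (toward zero) a probability, expressed in percent.

    Reported case-fatality percentages follow the truncation convention of
    the source registry tables (e.g. 4/1223 -> 0.32%).
    """
    scale = 10.0 ** decimals
    return float(np.trunc(probability * 100.0 * scale) / scale)


def estimate_fatality(events: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Case fatality per event type: deaths within 30 days of the event date.

    Returns columns ``event, deaths, events, probability, percent`` where
    ``percent`` is the 2-decimal truncated display value and ``probability``
    keeps full precision. Event types with zero detected events are flagged
    with NaN probability.
    """
    rows = []
    if len(events):
        merged = events.merge(
            patients[["patient_id", "death_date"]], on="patient_id", how="left"
        )
        merged["death_date"] = pd.to_datetime(merged["death_date"])
        fatal = (
            merged["death_date"].notna()
            & (merged["death_date"] >= merged["event_date"])
            & (merged["death_date"] <= merged["event_date"] + _FATALITY_WINDOW)
        )
    for event in EVENTS:
        if len(events):
            mask = merged["event"] == event
            n_events = int(mask.sum())
            n_deaths = int((fatal & mask).sum())
        else:
            n_events = n_deaths = 0
        if n_events == 0:
            prob = pct = float("nan")
        else:
            prob = n_deaths / n_events
            pct = truncate_percent(prob)
        rows.append(
            {"event": event, "deaths": n_deaths, "events": n_events, "probability": prob, "percent": pct}
        )
    return pd.DataFrame(rows)


def incidence_counts(
    incidence: pd.DataFrame, stratum: str = "pooled"
) -> Dict[Tuple[str, str], Tuple[int, float]]:
    """(drug, event) -> (events, person_years) for a chosen score stratum."""
    sub = incidence[incidence["score"].astype(str) == str(stratum)]
    return {
        (r["drug"], r["event"]): (int(r["events"]), float(r["person_years"]))
        for _, r in sub.iterrows()
    }


def write_estimates(incidence: pd.DataFrame, fatality: pd.DataFrame, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incidence.to_csv(out / "incidence.csv", index=False)
    fatality.to_csv(out / "fatality.csv", index=False)
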