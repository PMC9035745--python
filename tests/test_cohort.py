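"""Cohort construction: index dates, inclusion criteria, risk scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from afcea.codes import CodeMap, StudyWindow
from afcea.cohort import (
    DataError,
    RiskProfile,
    apply_inclusion,
    build_cohort,
    determine_index_date,
    score_candidates,
    score_chads_vasc,
    select_intermediate_risk,
)
from afcea.synthetic import ClaimsDataset

from conftest import make_patients, make_visits

CODEMAP = CodeMap()
WINDOW = StudyWindow()


class TestIndexDate:
    def test_second_outpatient_visit_defines_index(self):
        visits = make_visits(
            [("p", "2017-01-10", "I48", "outpatient"), ("p", "2017-03-02", "I48", "outpatient")]
        )
        assert determine_index_date(visits) == pd.Timestamp("2017-03-02")

    def test_admission_precedes_second_outpatient(self):
        visits = make_visits(
            [("p", "2017-02-01", "I48", "admission"), ("p", "2017-01-10", "I48", "outpatient")]
        )
        assert determine_index_date(visits) == pd.Timestamp("2017-02-01")

    def test_single_outpatient_visit_is_insufficient(self):
        visits = make_visits([("p", "2017-01-10", "I48", "outpatient")])
        assert determine_index_date(visits) is None


class TestScoring:
    def _profile(self, sex, birth, history_rows, index="2018-01-01"):
        patient = pd.Series({"patient_id": "p", "sex": sex, "birth_date": pd.Timestamp(birth)})
        history = make_visits(history_rows) if history_rows else make_visits(
            [("p", "2016-01-01", "Z00", "outpatient")]
        )
        return score_chads_vasc(patient, history, pd.Timestamp(index), CODEMAP)

    def test_male_70_scores_one_from_age_alone(self):
        prof = self._profile("M", "1947-06-01", [])
        assert prof.total == 1 and prof.component_points["age"] == 1

    def test_female_66_with_hypertension_scores_three(self):
        prof = self._profile("F", "1951-06-01", [("p", "2017-07-01", "I10", "outpatient")])
        assert prof.total == 3

    def test_male_80_with_prior_stroke_scores_four(self):
        prof = self._profile("M", "1937-06-01", [("p", "2017-07-01", "I63", "outpatient")])
        assert prof.total == 4 and prof.component_points["age"] == 2

    def test_age_boundary_75_scores_two_points_never_three(self):
        prof = self._profile("M", "1943-01-01", [])  # exactly 75 at index
        assert prof.component_points["age"] == 2 and prof.total == 2

    def test_lookback_excludes_index_day_and_older_history(self):
        too_old = self._profile("M", "1988-01-01", [("p", "2016-12-31", "I10", "outpatient")])
        on_index = self._profile("M", "1988-01-01", [("p", "2018-01-01", "I10", "outpatient")])
        inside = self._profile("M", "1988-01-01", [("p", "2017-06-01", "I10", "outpatient")])
        assert too_old.total == 0 and on_index.total == 0 and inside.total == 1

    def test_unknown_sex_raises(self):
        with pytest.raises(DataError):
            self._profile("X", "1950-01-01", [])

    def test_scoring_matches_brute_force_on_random_profiles(self):
        """Independent component-sum oracle over 1,000 random profiles."""
        rng = np.random.default_rng(11)
        components = {
            "heart_failure": "I50", "hypertension": "I10", "diabetes": "E11",
            "stroke": "I63", "myocardial_infarction": "I21",
            "peripheral_artery_disease": "I70",
        }
        names = list(components)
        index = pd.Timestamp("2018-06-01")
        for _ in range(1000):
            age = int(rng.integers(18, 95))
            sex = "F" if rng.random() < 0.5 else "M"
            flags = {c: bool(rng.random() < 0.3) for c in names}
            rows = [
                ("p", "2018-01-15", components[c], "outpatient") for c in names if flags[c]
            ]
            birth = index - pd.DateOffset(years=age) - pd.Timedelta(days=30)
            patient = pd.Series({"patient_id": "p", "sex": sex, "birth_date": birth})
            history = make_visits(rows) if rows else make_visits(
                [("p", "2018-01-15", "Z00", "outpatient")]
            )
            prof = score_chads_vasc(patient, history, index, CODEMAP)
            expected = (
                (2 if age >= 75 else 1 if age >= 65 else 0)
                + (1 if sex == "F" else 0)
                + flags["heart_failure"] + flags["hypertension"] + flags["diabetes"]
                + 2 * flags["stroke"]
                + (1 if flags["myocardial_infarction"] or flags["peripheral_artery_disease"] else 0)
            )
            assert prof.total == expected

    @given(
        base=st.lists(
            st.sampled_from(["I10", "I50", "E11", "I63", "I21", "I70"]), max_size=4
        ),
        extra=st.sampled_from(["I10", "I50", "E11", "I63", "I21", "I70"]),
    )
    def test_adding_a_comorbidity_never_decreases_the_score(self, base, extra):
        index = pd.Timestamp("2018-06-01")
        patient = pd.Series(
            {"patient_id": "p", "sex": "M", "birth_date": pd.Timestamp("1950-01-01")}
        )
        rows = [("p", "2018-01-15", c, "outpatient") for c in base] or [
            ("p", "2018-01-15", "Z00", "outpatient")
        ]
        before = score_chads_vasc(patient, make_visits(rows), index, CODEMAP).total
        rows.append(("p", "2018-01-15", extra, "outpatient"))
        after = score_chads_vasc(patient, make_visits(rows), index, CODEMAP).total
        assert after >= before


class TestInclusion:
    def _dataset(self, patients, visits, rx_rows):
        rx = pd.DataFrame(rx_rows, columns=["patient_id", "date", "drug_name"])
        rx["date"] = pd.to_datetime(rx["date"])
        return ClaimsDataset(patients=patients, visits=visits, prescriptions=rx)

    def test_af_visit_in_washout_year_excludes_under_criterion_one(self):
        patients = make_patients([("p", "M", "1950-01-01")])
        visits = make_visits(
            [
                ("p", "2016-03-01", "I48", "outpatient"),  # washout violation
                ("p", "2017-01-10", "I48", "outpatient"),
                ("p", "2017-02-10", "I48", "outpatient"),
            ]
        )
        ds = self._dataset(patients, visits, [("p", "2017-02-10", "warfarin")])
        candidates, tally = apply_inclusion(ds, CODEMAP, WINDOW)
        assert len(candidates) == 0 and tally["washout"] == 1

    def test_seventeen_year_old_excluded_by_age(self):
        patients = make_patients([("p", "M", "2000-06-01")])
        visits = make_visits(
            [("p", "2017-01-10", "I48", "outpatient"), ("p", "2017-02-10", "I48", "outpatient")]
        )
        ds = self._dataset(patients, visits, [("p", "2017-02-10", "warfarin")])
        candidates, tally = apply_inclusion(ds, CODEMAP, WINDOW)
        assert len(candidates) == 0 and tally["under_18"] == 1

    def test_dual_class_user_excluded_as_switcher(self):
        patients = make_patients([("p", "M", "1950-01-01")])
        visits = make_visits(
            [("p", "2017-01-10", "I48", "outpatient"), ("p", "2017-02-10", "I48", "outpatient")]
        )
        ds = self._dataset(
            patients, visits,
            [("p", "2017-02-10", "warfarin"), ("p", "2017-06-01", "rivaroxaban")],
        )
        candidates, tally = apply_inclusion(ds, CODEMAP, WINDOW)
        assert len(candidates) == 0 and tally["switcher"] == 1

    def test_exclusions_account_for_every_patient(self, small_population):
        ds, _ = small_population
        cohort, tally = build_cohort(ds)
        excluded = sum(
            tally[k]
            for k in (
                "washout", "no_index_event", "under_18", "no_anticoagulant",
                "switcher", "not_intermediate_risk",
            )
        )
        assert tally["input"] == tally["included"] + excluded
        assert tally["included"] == len(cohort)


class TestIntermediateRisk:
    @pytest.mark.parametrize(
        "sex,score,kept",
        [("male", 1, True), ("male", 0, False), ("male", 2, False),
         ("female", 2, True), ("female", 1, False), ("female", 3, False)],
    )
    def test_threshold_is_exact(self, sex, score, kept):
        scored = pd.DataFrame(
            [{"patient_id": "p", "sex": sex, "score": score, "drug": "warfarin"}]
        )
        cohort, _ = select_intermediate_risk(scored)
        assert (len(cohort) == 1) is kept

    def test_vectorized_scoring_agrees_with_per_patient_path(self, small_population):
        ds, _ = small_population
        candidates, _ = apply_inclusion(ds, CODEMAP, WINDOW)
        scored = score_candidates(candidates, ds.visits, CODEMAP)
        sample = scored.sample(n=60, random_state=0)
        for _, row in sample.iterrows():
            patient = ds.patients.set_index("patient_id").loc[row["patient_id"]]
            patient = pd.Series(
                {"patient_id": row["patient_id"], "sex": patient["sex"],
                 "birth_date": patient["birth_date"]}
            )
            history = ds.visits[ds.visits["patient_id"] == row["patient_id"]]
            prof = score_chads_vasc(patient, history, row["index_date"], CODEMAP)
            assert prof.total == row["score"]

    def test_cohort_members_match_generator_intent(self, small_population):
        ds, config = small_population
        cohort, _ = build_cohort(ds)
        assert len(cohort) > 0.5 * config.n_patients
        male = cohort["sex"] == "male"
        assert (cohort.loc[male, "score"] == 1).all()
        assert (cohort.loc[~male, "score"] == 2).all()


def test_diabetes_codes_are_configurable():
    codemap = CodeMap().with_overrides({"diabetes": ["E08"]})
    assert codemap.component_prefixes("diabetes") == ("E08",)
    with pytest.raises(KeyError):
        CodeMap().with_overrides({"nonexistent": ["X"]})
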