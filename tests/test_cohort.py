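"""At-risk rules, person-time arithmetic, age bands and mid-year populations."""

import numpy as np
import pandas as pd
import pytest

from dupmine.cohort import (
    RunInError,
    age_band,
    age_bands_for_scheme,
    build_subcohort,
    midyear_population,
    risk_interval,
    risk_intervals,
)


_PATIENT_COLS = ["patient_id", "birth_date", "sex", "registration_start", "registration_end"]


def _patients(rows):
    df = pd.DataFrame(rows, columns=_PATIENT_COLS)
    for c in ("birth_date", "registration_start", "registration_end"):
        df[c] = pd.to_datetime(df[c])
    return df


def _pat(pid="P1", birth="1950-06-15", start="2012-01-01", end="2021-12-31", sex="male"):
    return dict(patient_id=pid, birth_date=birth, sex=sex,
                registration_start=start, registration_end=end)


def _summ(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "has_dd", "first_dd_date", "n_dd_contacts"])
    df["first_dd_date"] = pd.to_datetime(df["first_dd_date"])
    return df


NO_DD = _summ([])


class TestAgeBands:
    @pytest.mark.parametrize(
        "age, band",
        [(39.99, "<40"), (40.0, "40-50"), (49.999, "40-50"), (50.0, "50-60"),
         (89.9, "80-90"), (90.0, "90+"), (93, "90+"), (0, "<40")],
    )
    def test_decade_boundaries_half_open(self, age, band):
        assert age_band(age, "decade") == band

    def test_figure_scheme(self):
        assert age_band(40.5, "figure") == "<=40"
        assert age_band(41.0, "figure") == "41-50"
        assert age_band(80.2, "figure") == "71-80"

    def test_negative_age_domain_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            age_band(-1)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown age band scheme"):
            age_band(50, "quintiles")

    def test_partition_every_age_in_exactly_one_band(self):
        ages = np.arange(0, 110, 0.25)
        labels = [age_band(a) for a in ages]
        assert set(labels) <= set(age_bands_for_scheme("decade"))


class TestRiskInterval:
    def test_full_year_coverage(self):
        iv = risk_interval(_pat(), None, 2019)
        assert iv["person_time"] == 1.0

    def test_rule3_prior_diagnosis_excludes(self):
        iv = risk_interval(_pat(), dict(first_dd_date="2018-06-01"), 2019)
        assert iv is None

    def test_rule1_entered_later_excludes(self):
        iv = risk_interval(_pat(start="2020-03-01"), None, 2019)
        assert iv is None

    def test_rule2_left_prior_excludes(self):
        iv = risk_interval(_pat(end="2018-11-30"), None, 2019)
        assert iv is None

    def test_late_registration_day_count(self):
        iv = risk_interval(_pat(start="2019-07-02"), None, 2019)
        assert iv["person_time"] == pytest.approx(183 / 365)

    def test_diagnosis_truncation_within_year(self):
        iv = risk_interval(_pat(), dict(first_dd_date="2019-07-02"), 2019)
        assert iv["person_time"] == pytest.approx(183 / 365)
        iv_full = risk_interval(_pat(), dict(first_dd_date="2019-07-02"), 2019,
                                truncate_at_diagnosis=False)
        assert iv_full["person_time"] == 1.0

    def test_leap_year_full_coverage_is_one(self):
        iv = risk_interval(_pat(start="2012-01-01", end="2021-12-31"), None, 2020)
        assert iv["person_time"] == 1.0

    def test_mid_year_entry_in_leap_year(self):
        iv = risk_interval(_pat(start="2020-07-02"), None, 2020)
        assert iv["person_time"] == pytest.approx(183 / 366)


class TestSubCohort:
    def test_empty(self):
        sc = build_subcohort(_patients([]), NO_DD, 2019)
        assert sc.total_person_years == 0 and not sc.members

    def test_incident_case_with_truncated_person_time(self):
        pats = _patients([_pat()])
        summ = _summ([("P1", True, "2019-07-02", 1)])
        sc = build_subcohort(pats, summ, 2019)
        assert sc.incident_cases == {"P1"}
        assert sc.total_person_years == pytest.approx(183 / 365)

    def test_future_diagnosis_member_not_incident(self):
        pats = _patients([_pat()])
        summ = _summ([("P1", True, "2020-02-01", 1)])
        sc = build_subcohort(pats, summ, 2019)
        assert "P1" in sc.members and not sc.incident_cases

    def test_rule3_consistency_excluded_after_incident_year(self):
        pats = _patients([_pat()])
        summ = _summ([("P1", True, "2018-05-01", 1)])
        for year in (2019, 2020, 2021):
            assert "P1" not in build_subcohort(pats, summ, year).members

    def test_additivity_split_interval_preserves_total(self):
        whole = _patients([_pat(pid="A", start="2019-01-01", end="2019-12-31")])
        split = _patients([
            _pat(pid="B1", start="2019-01-01", end="2019-05-20"),
            _pat(pid="B2", start="2019-05-21", end="2019-12-31"),
        ])
        t_whole = build_subcohort(whole, NO_DD, 2019).total_person_years
        t_split = build_subcohort(split, NO_DD, 2019).total_person_years
        assert t_whole == pytest.approx(t_split)
        assert t_whole == pytest.approx(1.0)

    def test_denominator_monotone_in_registration_interval(self):
        wide = _patients([_pat(start="2019-01-01", end="2019-12-31")])
        narrow = _patients([_pat(start="2019-03-01", end="2019-10-31")])
        t_wide = build_subcohort(wide, NO_DD, 2019).total_person_years
        t_narrow = build_subcohort(narrow, NO_DD, 2019).total_person_years
        assert t_narrow < t_wide


class TestMidYear:
    def test_deregistered_before_july_not_counted(self):
        pats = _patients([_pat(end="2021-06-30")])
        my = midyear_population(pats, NO_DD, 2021)
        assert my.registered_total == 0

    def test_registered_on_july_first_counted(self):
        pats = _patients([_pat(end="2021-07-01")])
        my = midyear_population(pats, NO_DD, 2021)
        assert my.registered_total == 1

    def test_ever_diagnosed_counts_old_case(self):
        pats = _patients([_pat()])
        summ = _summ([("P1", True, "2015-02-01", 3)])
        my = midyear_population(pats, summ, 2021)
        assert my.cases_total == 1

    def test_contact_in_year_definition(self):
        pats = _patients([_pat()])
        summ = _summ([("P1", True, "2015-02-01", 3)])
        dd_contacts = pd.DataFrame(
            dict(patient_id=["P1"], contact_date=pd.to_datetime(["2015-02-01"]))
        )
        my = midyear_population(pats, summ, 2021, case_definition="contact_in_year",
                                dd_contacts=dd_contacts)
        assert my.cases_total == 0  # no DD contact during 2021

    def test_empty_table_all_strata_zero(self):
        my = midyear_population(_patients([]), NO_DD, 2021)
        assert my.registered_total == 0
        assert len(my.strata) == 2 * len(age_bands_for_scheme("decade"))

    def test_run_in_guard(self):
        pats = _patients([_pat()])
        with pytest.raises(RunInError):
            midyear_population(pats, NO_DD, 2021, data_start_year=2015)
        with pytest.warns(UserWarning):
            midyear_population(pats, NO_DD, 2021, data_start_year=2015,
                               allow_short_run_in=True)

    def test_stratum_sums_match_overall(self, small_dataset):
        from dupmine.textmine import label_contacts, summarize_patients
        labels = label_contacts(small_dataset.contacts)
        summaries = summarize_patients(labels)
        my = midyear_population(small_dataset.patients, summaries, 2021)
        assert (my.strata["dd_cases"] <= my.strata["registered"]).all()
        assert my.cases_total == my.strata["dd_cases"].sum()
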