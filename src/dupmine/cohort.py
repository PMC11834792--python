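"""Per-year at-risk sub-cohorts, person-years and mid-year populations.

Incidence denominators follow the dynamic-cohort convention: for each
analysis year a sub-cohort excludes patients who (1) entered the registry
after that year, (2) left before it, or (3) already had a DD diagnosis
before it.  Person-time is the registered fraction of the calendar year
(actual day counts, leap-aware), right-truncated at the first DD contact
date by default.  Prevalence denominators are the patients registered on
1 July (mid-year population), stratified by sex and age band, guarded by
a minimum run-in period of data history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BAND_SCHEMES",
    "age_band",
    "age_bands_for_scheme",
    "risk_interval",
    "risk_intervals",
    "SubCohort",
    "build_subcohort",
    "MidYearPopulation",
    "midyear_population",
    "RunInError",
]

#: Half-open age bands [lower, upper): "40-50" means 40 <= age < 50.
AGE_BAND_SCHEMES = {
    "decade": ([40, 50, 60, 70, 80, 90],
               ["<40", "40-50", "50-60", "60-70", "70-80", "80-90", "90+"]),
    "figure": ([41, 51, 61, 71, 81, 91],
               ["<=40", "41-50", "51-60", "61-70", "71-80", "81-90", "90+"]),
}


class RunInError(RuntimeError):
    """Prevalence requested for a year with insufficient data history."""


def age_bands_for_scheme(scheme: str = "decade") -> list[str]:
    try:
        return list(AGE_BAND_SCHEMES[scheme][1])
    except KeyError:
        raise ValueError(f"unknown age band scheme {scheme!r}") from None


def age_band(age_years: float, scheme: str = "decade") -> str:
    """Band label for one age; negative ages are a domain error."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    edges, labels = _scheme(scheme)
    return labels[int(np.digitize(age_years, edges))]


def _scheme(scheme: str):
    try:
        return AGE_BAND_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown age band scheme {scheme!r}") from None


def _age_bands(ages: np.ndarray, scheme: str) -> np.ndarray:
    edges, labels = _scheme(scheme)
    return np.array(labels, dtype=object)[np.digitize(ages, edges)]


def _effective_end(patients: pd.DataFrame, study_end: pd.Timestamp) -> pd.Series:
    return patients["registration_end"].fillna(study_end)


# ---------------------------------------------------------------------------
# risk intervals
# ---------------------------------------------------------------------------

def risk_intervals(
    patients: pd.DataFrame,
    summaries: pd.DataFrame,
    year: int,
    *,
    truncate_at_diagnosis: bool = True,
    study_end: pd.Timestamp | str | None = None,
) -> pd.DataFrame:
    """At-risk intervals for every patient in ``year`` (vectorised).

    Returns one row per at-risk patient: ``patient_id, year, start, end,
    person_time`` with ``person_time`` = inclusive days / days in year.
    Patients excluded by rules (1)-(3) are absent.
    """
    y0 = pd.Timestamp(year=year, month=1, day=1)
    y1 = pd.Timestamp(year=year, month=12, day=31)
    days_in_year = (y1 - y0).days + 1
    study_end = pd.Timestamp(study_end) if study_end is not None else y1

    df = patients.merge(
        summaries[["patient_id", "first_dd_date"]], on="patient_id", how="left"
    )
    reg_start = df["registration_start"]
    reg_end = _effective_end(df, max(study_end, y1))
    first_dd = df["first_dd_date"]

    rule1 = reg_start.dt.year > year
    rule2 = reg_end.dt.year < year
    rule3 = first_dd.notna() & (first_dd < y0)
    at_risk = ~(rule1 | rule2 | rule3) & reg_start.notna()

    start = reg_start.clip(lower=y0)
    end = reg_end.clip(upper=y1)
    if truncate_at_diagnosis:
        dd_in_year = first_dd.notna() & (first_dd >= y0) & (first_dd <= y1)
        end = end.where(~dd_in_year, np.minimum(end, first_dd))
    days = (end - start).dt.days + 1
    at_risk &= days > 0

    out = pd.DataFrame(
        {
            "patient_id": df.loc[at_risk, "patient_id"].to_numpy(),
            "year": year,
            "start": start[at_risk].to_numpy(),
            "end": end[at_risk].to_numpy(),
            "person_time": (days[at_risk] / days_in_year).to_numpy(),
        }
    )
    return out


def risk_interval(
    patient: pd.Series | dict,
    summary: pd.Series | dict | None,
    year: int,
    *,
    truncate_at_diagnosis: bool = True,
) -> dict | None:
    """Single-patient risk interval, or None if any exclusion rule fires."""
    pat = pd.DataFrame([dict(patient)])
    if summary is not None and dict(summary).get("first_dd_date") is not None:
        summ = pd.DataFrame([{"patient_id": pat["patient_id"].iloc[0],
                              "first_dd_date": pd.Timestamp(dict(summary)["first_dd_date"])}])
    else:
        summ = pd.DataFrame({"patient_id": pat["patient_id"], "first_dd_date": pd.NaT})
    for c in ("birth_date", "registration_start", "registration_end"):
        if c in pat.columns:
            pat[c] = pd.to_datetime(pat[c])
    res = risk_intervals(pat, summ, year, truncate_at_diagnosis=truncate_at_diagnosis)
    if len(res) == 0:
        return None
    return res.iloc[0].to_dict()


# ---------------------------------------------------------------------------
# sub-cohorts
# ---------------------------------------------------------------------------

@dataclass
class SubCohort:
    """One analysis year's at-risk population."""

    year: int
    members: set
    incident_cases: set
    total_person_years: float
    intervals: pd.DataFrame


def build_subcohort(
    patients: pd.DataFrame,
    summaries: pd.DataFrame,
    year: int,
    *,
    truncate_at_diagnosis: bool = True,
    study_end=None,
) -> SubCohort:
    """At-risk sub-cohort for ``year`` with incident cases and person-years."""
    ivs = risk_intervals(
        patients, summaries, year,
        truncate_at_diagnosis=truncate_at_diagnosis, study_end=study_end,
    )
    members = set(ivs["patient_id"])
    s = summaries.loc[summaries["first_dd_date"].notna()]
    incident = set(
        s.loc[s["first_dd_date"].dt.year == year, "patient_id"]
    ) & members
    return SubCohort(
        year=year,
        members=members,
        incident_cases=incident,
        total_person_years=float(ivs["person_time"].sum()),
        intervals=ivs,
    )


# ---------------------------------------------------------------------------
# mid-year population
# ---------------------------------------------------------------------------

@dataclass
class MidYearPopulation:
    """Registered patients and DD cases on 1 July of a year, by stratum."""

    year: int
    strata: pd.DataFrame  # sex, age_band, registered, dd_cases
    case_definition: str

    @property
    def registered_total(self) -> int:
        return int(self.strata["registered"].sum())

    @property
    def cases_total(self) -> int:
        return int(self.strata["dd_cases"].sum())


def midyear_population(
    patients: pd.DataFrame,
    summaries: pd.DataFrame,
    year: int,
    *,
    run_in_years: int = 10,
    data_start_year: int | None = None,
    scheme: str = "decade",
    case_definition: str = "ever_diagnosed",
    dd_contacts: pd.DataFrame | None = None,
    allow_short_run_in: bool = False,
) -> MidYearPopulation:
    """Mid-year (1 July) population and DD cases, by sex and age band.

    ``case_definition``:

    * ``ever_diagnosed`` — a registered patient whose first DD contact is
      on or before 1 July of ``year`` (point-in-time diagnosed status);
    * ``contact_in_year`` — a registered patient with a DD contact during
      the calendar year (requires ``dd_contacts`` with columns
      ``patient_id, contact_date``).

    When ``data_start_year`` is given and ``year - data_start_year`` is
    below ``run_in_years``, raises :class:`RunInError` unless
    ``allow_short_run_in`` (then warns).
    """
    if case_definition not in ("ever_diagnosed", "contact_in_year"):
        raise ValueError(f"unknown case_definition {case_definition!r}")
    _scheme(scheme)  # validate early
    if data_start_year is not None and year - data_start_year < run_in_years:
        msg = (
            f"prevalence year {year} has only {year - data_start_year} years of history; "
            f"run-in of {run_in_years} required"
        )
        if not allow_short_run_in:
            raise RunInError(msg)
        warnings.warn(msg, stacklevel=2)

    mid = pd.Timestamp(year=year, month=7, day=1)
    reg_end = patients["registration_end"]
    registered = (
        patients["registration_start"].notna()
        & (patients["registration_start"] <= mid)
        & (reg_end.isna() | (reg_end >= mid))
    )
    pop = patients.loc[registered, ["patient_id", "sex", "birth_date"]].copy()
    ages = (mid - pop["birth_date"]).dt.days / 365.25
    pop["age_band"] = _age_bands(ages.to_numpy(), scheme)

    if case_definition == "ever_diagnosed":
        s = summaries.loc[summaries["first_dd_date"].notna()]
        case_ids = set(s.loc[s["first_dd_date"] <= mid, "patient_id"])
    else:
        if dd_contacts is None:
            raise ValueError("contact_in_year requires dd_contacts")
        dates = pd.to_datetime(dd_contacts["contact_date"])
        in_year = dates.dt.year == year
        case_ids = set(dd_contacts.loc[in_year, "patient_id"])
    pop["is_case"] = pop["patient_id"].isin(case_ids)

    _, labels = _scheme(scheme)
    strata = (
        pop.groupby(["sex", "age_band"], observed=False)
        .agg(registered=("patient_id", "size"), dd_cases=("is_case", "sum"))
        .reset_index()
    )
    # complete missing strata with zeros, fixed band order
    full = pd.MultiIndex.from_product(
        [["male", "female"], labels], names=["sex", "age_band"]
    ).to_frame(index=False)
    strata = full.merge(strata, on=["sex", "age_band"], how="left").fillna(
        {"registered": 0, "dd_cases": 0}
    )
    strata["registered"] = strata["registered"].astype(int)
    strata["dd_cases"] = strata["dd_cases"].astype(int)
    return MidYearPopulation(year=year, strata=strata, case_definition=case_definition)
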