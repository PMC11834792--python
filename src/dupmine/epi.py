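"""Incidence rates, prevalences, exact intervals and the full pipeline.

Point estimates are events / person-years (per 1000) and cases /
mid-year population (percent).  Interval conventions:

* binomial proportions get exact Clopper-Pearson limits (beta-quantile
  form of the tail inversion, the ``binom.exact`` convention);
* Poisson counts get exact Garwood limits (chi-square tail inversion);
* directly standardized prevalences get the Fay-Feuer gamma limits, the
  convention of the classical ``ageadjust.direct`` routine.

``run_pipeline`` composes the whole analysis: ingest -> eligibility
filters -> deduplication -> candidate extraction and rule-based
classification -> per-year sub-cohorts -> rates and mid-year prevalence,
plus a Table-1-style descriptive summary of the prevalent cases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import ingest, textmine
from .cohort import (
    MidYearPopulation,
    age_bands_for_scheme,
    build_subcohort,
    midyear_population,
)
from .textmine import RuleSet, default_ruleset

__all__ = [
    "RateEstimate",
    "PrevalenceEstimate",
    "StandardPopulation",
    "clopper_pearson",
    "garwood",
    "incidence_rate",
    "point_prevalence",
    "direct_standardize",
    "esp2013_standard",
    "PipelineReport",
    "run_pipeline",
]

DEFAULT_COMORBIDITIES = {
    "Diabetes mellitus": "T90",
    "Excessive smoking": "P17",
    "Alcohol abuse": "P15",
    "Hypercholesterolemia": "T93",
    "Overweight/Obesity": "T82",
    "Epilepsy": "N88",
}


# ---------------------------------------------------------------------------
# exact intervals
# ---------------------------------------------------------------------------

def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) interval for x successes in n trials.

    Lower limit is 0 when x = 0 and upper limit 1 when x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    alpha = 1.0 - conf_level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def garwood(events: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact Poisson (Garwood) limits for an event count (unscaled)."""
    if events < 0:
        raise ValueError("events must be >= 0")
    alpha = 1.0 - conf_level
    low = 0.0 if events == 0 else float(stats.chi2.ppf(alpha / 2, 2 * events) / 2)
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2)
    return low, high


@dataclass(frozen=True)
class RateEstimate:
    """Incidence rate per 1000 person-years with an exact Poisson CI."""

    events: int
    person_years: float
    rate_per_1000: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


def incidence_rate(events: int, person_years: float, conf_level: float = 0.95) -> RateEstimate:
    """Events per 1000 person-years with Garwood limits."""
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    if events < 0 or int(events) != events:
        raise ValueError("events must be a non-negative integer")
    events = int(events)
    scale = 1000.0 / person_years
    lo, hi = garwood(events, conf_level)
    return RateEstimate(
        events=events,
        person_years=float(person_years),
        rate_per_1000=events * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
        conf_level=conf_level,
    )


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point prevalence in percent with an exact binomial CI."""

    cases: int
    population: int
    percent: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    undefined: bool = False  # empty stratum


def point_prevalence(
    midyear: MidYearPopulation | tuple[int, int],
    strata_filter=None,
    conf_level: float = 0.95,
) -> PrevalenceEstimate:
    """Prevalence from a mid-year population (optionally a stratum subset).

    ``strata_filter`` is a callable over the strata frame returning a
    boolean mask (e.g. ``lambda s: s["sex"] == "male"``).  An empty
    population yields a flagged estimate with undefined CI rather than an
    exception.  Accepts a plain ``(cases, population)`` pair too.
    """
    if isinstance(midyear, MidYearPopulation):
        strata = midyear.strata
        if strata_filter is not None:
            strata = strata.loc[strata_filter(strata)]
        cases = int(strata["dd_cases"].sum())
        population = int(strata["registered"].sum())
    else:
        cases, population = (int(v) for v in midyear)
    if population == 0:
        return PrevalenceEstimate(0, 0, float("nan"), float("nan"), float("nan"),
                                  conf_level, undefined=True)
    lo, hi = clopper_pearson(cases, population, conf_level)
    return PrevalenceEstimate(
        cases=cases,
        population=population,
        percent=100.0 * cases / population,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# direct standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardPopulation:
    """Weights per age band; normalized before use."""

    name: str
    weights: dict

    def normalized(self) -> dict:
        total = float(sum(self.weights.values()))
        if total <= 0:
            raise ValueError("standard population weights must sum to > 0")
        return {b: w / total for b, w in self.weights.items()}


def esp2013_standard(scheme: str = "decade") -> StandardPopulation:
    """European Standard Population 2013 collapsed onto the decade bands."""
    if scheme != "decade":
        raise ValueError("ESP2013 standard is provided for the decade scheme")
    return StandardPopulation(
        name="ESP2013-decade",
        weights={
            "<40": 47000, "40-50": 14000, "50-60": 13500, "60-70": 11500,
            "70-80": 9000, "80-90": 4000, "90+": 1000,
        },
    )


def direct_standardize(
    stratum_prevalences: dict[str, PrevalenceEstimate],
    standard: StandardPopulation,
    conf_level: float = 0.95,
) -> PrevalenceEstimate:
    """Directly standardized prevalence with Fay-Feuer gamma limits.

    The point estimate is the weighted sum of stratum proportions with
    normalized standard weights.  Raises a configuration error naming any
    standard band missing from the stratum map.
    """
    weights = standard.normalized()
    missing = [b for b in weights if b not in stratum_prevalences]
    if missing:
        raise KeyError(f"stratum prevalences missing band(s) {missing}")
    alpha = 1.0 - conf_level
    rate = var = 0.0
    wm = 0.0
    cases = pop = 0
    for band, w in weights.items():
        est = stratum_prevalences[band]
        if est.population == 0:
            continue
        p = est.cases / est.population
        rate += w * p
        var += (w / est.population) ** 2 * est.cases
        wm = max(wm, w / est.population)
        cases += est.cases
        pop += est.population
    if rate == 0:
        lo = 0.0
    else:
        lo = float(stats.gamma.ppf(alpha / 2, a=rate**2 / var, scale=var / rate))
    num, den = rate + wm, var + wm**2
    hi = float(stats.gamma.ppf(1 - alpha / 2, a=num**2 / den, scale=den / num))
    return PrevalenceEstimate(
        cases=cases, population=pop, percent=100.0 * rate,
        ci_low=100.0 * lo, ci_high=100.0 * hi, conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    """All tables produced by one end-to-end run."""

    incidence: pd.DataFrame          # year x sex ('all'/'male'/'female') rates
    incidence_by_band: pd.DataFrame  # year x band rates
    prevalence: pd.DataFrame         # overall + per sex (+ sex x band)
    standardized: PrevalenceEstimate | None
    descriptives: pd.DataFrame
    midyear: MidYearPopulation
    summaries: pd.DataFrame
    case_ids: set
    n_patients: int
    exclusions: pd.DataFrame
    merges: pd.DataFrame
    patients: pd.DataFrame | None = None  # post-filter, post-dedup


def _prevalence_rows(midyear: MidYearPopulation, scheme_bands: list[str]) -> pd.DataFrame:
    rows = []

    def add(label_sex, label_band, flt):
        est = point_prevalence(midyear, flt)
        rows.append(
            dict(sex=label_sex, age_band=label_band, cases=est.cases,
                 population=est.population, percent=est.percent,
                 ci_low=est.ci_low, ci_high=est.ci_high)
        )

    add("all", "all", None)
    for sex in ("male", "female"):
        add(sex, "all", lambda s, sex=sex: s["sex"] == sex)
        for band in scheme_bands:
            add(sex, band, lambda s, sex=sex, band=band: (s["sex"] == sex) & (s["age_band"] == band))
    return pd.DataFrame(rows)


def run_pipeline(
    dataset,
    rules: RuleSet | None = None,
    years: range | list[int] = range(2017, 2022),
    *,
    mode: str = "code_and_text",
    case_definition: str = "ever_diagnosed",
    prevalence_year: int = 2021,
    run_in_years: int = 10,
    truncate_at_diagnosis: bool = True,
    scheme: str = "decade",
    standard: StandardPopulation | None = None,
    study_end: str | pd.Timestamp = "2021-12-31",
    comorbidities: dict[str, str] = DEFAULT_COMORBIDITIES,
    allow_short_run_in: bool = False,
) -> PipelineReport:
    """Run ingest -> classification -> cohorts -> estimates.

    ``dataset`` is either a directory containing ``patients.csv`` and
    ``contacts.csv`` or an object with ``patients``/``contacts`` frames
    (e.g. a generated :class:`~dupmine.synthetic_ehr.SyntheticDataset`).
    """
    rules = rules or default_ruleset()
    if isinstance(dataset, (str, os.PathLike)):
        patients = ingest.read_patients(os.path.join(dataset, "patients.csv"))
        contacts = ingest.read_contacts(os.path.join(dataset, "contacts.csv"), patients)
    else:
        patients, contacts = dataset.patients.copy(), dataset.contacts.copy()

    patients, exclusions = ingest.filter_valid_patients(patients, study_end)
    patients, contacts, merges = ingest.deduplicate_patients(patients, contacts)
    known = set(patients["patient_id"])
    contacts = contacts.loc[contacts["patient_id"].isin(known)]

    labels = textmine.label_contacts(contacts, rules, mode=mode)
    summaries = textmine.summarize_patients(labels)

    data_start_year = int(patients["registration_start"].dt.year.min()) if len(patients) else None

    inc_rows, band_rows = [], []
    for year in years:
        sc = build_subcohort(
            patients, summaries, year,
            truncate_at_diagnosis=truncate_at_diagnosis, study_end=study_end,
        )
        est = (
            incidence_rate(len(sc.incident_cases), sc.total_person_years)
            if sc.total_person_years > 0
            else None
        )
        inc_rows.append(
            dict(year=year, sex="all",
                 events=len(sc.incident_cases), person_years=sc.total_person_years,
                 rate_per_1000=est.rate_per_1000 if est else float("nan"),
                 ci_low=est.ci_low if est else float("nan"),
                 ci_high=est.ci_high if est else float("nan"))
        )
        # sex strata
        sex_map = patients.set_index("patient_id")["sex"]
        ivs = sc.intervals
        ivs_sex = ivs["patient_id"].map(sex_map)
        for sex in ("male", "female"):
            py = float(ivs.loc[(ivs_sex == sex).to_numpy(), "person_time"].sum())
            ev = sum(1 for p in sc.incident_cases if sex_map.get(p) == sex)
            est_s = incidence_rate(ev, py) if py > 0 else None
            inc_rows.append(
                dict(year=year, sex=sex, events=ev, person_years=py,
                     rate_per_1000=est_s.rate_per_1000 if est_s else float("nan"),
                     ci_low=est_s.ci_low if est_s else float("nan"),
                     ci_high=est_s.ci_high if est_s else float("nan"))
            )
        # age-band strata (age on 1 July of the analysis year)
        mid = pd.Timestamp(year=year, month=7, day=1)
        binfo = patients.set_index("patient_id")["birth_date"]
        ages = (mid - ivs["patient_id"].map(binfo)).dt.days / 365.25
        from .cohort import _age_bands  # local import to avoid cycle at top
        bands = _age_bands(ages.to_numpy(), scheme)
        for band in age_bands_for_scheme(scheme):
            bmask = bands == band
            py = float(ivs.loc[bmask, "person_time"].sum())
            in_band = set(ivs.loc[bmask, "patient_id"])
            ev = len(sc.incident_cases & in_band)
            est_b = incidence_rate(ev, py) if py > 0 else None
            band_rows.append(
                dict(year=year, age_band=band, events=ev, person_years=py,
                     rate_per_1000=est_b.rate_per_1000 if est_b else float("nan"),
                     ci_low=est_b.ci_low if est_b else float("nan"),
                     ci_high=est_b.ci_high if est_b else float("nan"))
            )

    dd_contacts = labels.loc[labels["is_dd"], ["patient_id", "contact_date"]]
    midyear = midyear_population(
        patients, summaries, prevalence_year,
        run_in_years=run_in_years, data_start_year=data_start_year,
        scheme=scheme, case_definition=case_definition,
        dd_contacts=dd_contacts, allow_short_run_in=allow_short_run_in,
    )
    prevalence = _prevalence_rows(midyear, age_bands_for_scheme(scheme))

    standardized = None
    if standard is None and scheme == "decade":
        standard = esp2013_standard()
    if standard is not None:
        per_band = {}
        for band in age_bands_for_scheme(scheme):
            sub = midyear.strata.loc[midyear.strata["age_band"] == band]
            per_band[band] = point_prevalence(
                (int(sub["dd_cases"].sum()), int(sub["registered"].sum()))
            )
        standardized = direct_standardize(per_band, standard)

    descriptives = _descriptives(
        patients, contacts, summaries, midyear, prevalence_year, comorbidities
    )
    case_ids = set(summaries.loc[summaries["has_dd"], "patient_id"])

    return PipelineReport(
        incidence=pd.DataFrame(inc_rows),
        incidence_by_band=pd.DataFrame(band_rows),
        prevalence=prevalence,
        standardized=standardized,
        descriptives=descriptives,
        midyear=midyear,
        summaries=summaries,
        case_ids=case_ids,
        n_patients=len(patients),
        exclusions=exclusions,
        merges=merges,
        patients=patients,
    )


def scenario_metrics(dataset, rules: RuleSet | None = None) -> dict:
    """Headline pipeline estimates for one dataset (both retrieval modes).

    Runs the full pipeline in ``code_and_text`` mode (2019/2020 incidence,
    2021 mid-year prevalence overall and by sex) and re-runs case
    ascertainment in ``code_only`` mode for the coded-retrieval prevalence.
    Each entry carries the counts behind it so Monte-Carlo standard errors
    can be formed.  Also reports whether the code-only case set is a
    subset of the combined one (it always should be).
    """
    rep = run_pipeline(dataset, rules, years=[2019, 2020])
    rep_co = run_pipeline(dataset, rules, years=[], mode="code_only")

    def _prev(report, sex):
        p = report.prevalence
        r = p[(p["sex"] == sex) & (p["age_band"] == "all")].iloc[0]
        return dict(value=float(r["percent"]), cases=int(r["cases"]),
                    population=int(r["population"]))

    def _inc(year):
        i = rep.incidence
        r = i[(i["year"] == year) & (i["sex"] == "all")].iloc[0]
        return dict(value=float(r["rate_per_1000"]), events=int(r["events"]),
                    person_years=float(r["person_years"]))

    return {
        "prevalence_2021_percent": _prev(rep, "all"),
        "prevalence_2021_male_percent": _prev(rep, "male"),
        "prevalence_2021_female_percent": _prev(rep, "female"),
        "incidence_2019_per_1000py": _inc(2019),
        "incidence_2020_per_1000py": _inc(2020),
        "prevalence_2021_code_only_percent": _prev(rep_co, "all"),
        "code_only_subset_of_combined": rep_co.case_ids <= rep.case_ids,
    }


def _descriptives(
    patients: pd.DataFrame,
    contacts: pd.DataFrame,
    summaries: pd.DataFrame,
    midyear: MidYearPopulation,
    year: int,
    comorbidities: dict[str, str],
) -> pd.DataFrame:
    """Table-1-style description of the mid-year prevalent DD patients.

    Median/IQR use linear interpolation between order statistics (the
    default quantile convention of numpy and of R's ``quantile`` type 7).
    """
    mid = pd.Timestamp(year=year, month=7, day=1)
    reg_end = patients["registration_end"]
    registered = (
        (patients["registration_start"] <= mid)
        & (reg_end.isna() | (reg_end >= mid))
    )
    s = summaries.loc[summaries["first_dd_date"].notna()]
    case_ids = set(s.loc[s["first_dd_date"] <= mid, "patient_id"]) & set(
        patients.loc[registered, "patient_id"]
    )
    cases = patients.loc[patients["patient_id"].isin(case_ids)]
    n = len(cases)
    rows = [dict(variable="n", value=float(n), percent=float("nan"))]
    if n:
        first_dd = summaries.set_index("patient_id")["first_dd_date"]
        age_at_dx = (
            (cases["patient_id"].map(first_dd) - cases["birth_date"]).dt.days / 365.25
        )
        mid_age = (mid - cases["birth_date"]).dt.days / 365.25
        q25, q50, q75 = np.quantile(mid_age.to_numpy(), [0.25, 0.5, 0.75])
        rows.append(dict(variable="age_midyear_median", value=q50, percent=float("nan")))
        rows.append(dict(variable="age_midyear_q25", value=q25, percent=float("nan")))
        rows.append(dict(variable="age_midyear_q75", value=q75, percent=float("nan")))
        d25, d50, d75 = np.quantile(age_at_dx.dropna().to_numpy(), [0.25, 0.5, 0.75])
        rows.append(dict(variable="age_at_first_dd_median", value=d50, percent=float("nan")))
        rows.append(dict(variable="age_at_first_dd_q25", value=d25, percent=float("nan")))
        rows.append(dict(variable="age_at_first_dd_q75", value=d75, percent=float("nan")))
        n_male = int((cases["sex"] == "male").sum())
        rows.append(dict(variable="male", value=float(n_male), percent=100.0 * n_male / n))
        code_by_patient = contacts.loc[contacts["patient_id"].isin(case_ids)]
        for label, code in comorbidities.items():
            with_code = code_by_patient.loc[
                code_by_patient["icpc_code"] == code, "patient_id"
            ].nunique()
            rows.append(dict(variable=label, value=float(with_code), percent=100.0 * with_code / n))
    return pd.DataFrame(rows)
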