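"""Scenario configuration for the synthetic primary-care registry generator.

A :class:`ScenarioConfig` fixes every stochastic ingredient of a synthetic
registry: population structure, practice onboarding (with historical-data
lookback), age- and sex-specific first-presentation hazards for Dupuytren's
disease (DD), care-seeking multipliers per calendar year, the probability
that a DD contact carries the ICPC code L99.03, the free-text note mix, and
the duplicate-record rate.  The generator is deterministic given
``(config, seed)``.

The bundled ``paper2021`` scenario is calibrated so that the full pipeline
(ingest -> text mining -> cohorts -> rates) recovers headline registry
figures: overall 2021 mid-year prevalence ~1.99% (2.50% male / 1.50%
female), overall first-presentation incidence ~1.72/1000 person-years in
2019 dipping to ~1.41 in 2020, and a code-only prevalence of ~1.38%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = ["ScenarioConfig", "ConfigurationError", "paper2021", "get_scenario"]

SEXES = ("male", "female")

#: Age bands used for DD hazards (same labels as the cohort decade scheme).
HAZARD_BANDS = ("<40", "40-50", "50-60", "60-70", "70-80", "80-90", "90+")


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates an invariant."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Truth parameters for one synthetic registry scenario.

    Parameters
    ----------
    n_patients:
        Number of patient records before duplicate injection.
    year_range:
        Inclusive ``(first_year, last_year)`` calendar window of the
        simulated registry extract.
    sex_ratio_male:
        Probability that a patient is male.
    age_distribution:
        ``(age_band, weight)`` pairs; ``age_band`` is ``"lo-hi"`` in whole
        years of age on 1 July of ``last_year``; weights must sum to 1.
    practice_onboarding:
        ``(practice_id, onboarding_year)`` pairs.  Each practice delivers
        data from ``onboarding_year - lookback_years`` onwards.
    lookback_years:
        Years of historical data a practice supplies at onboarding.
    late_registration_fraction:
        Fraction of patients who register after their practice's data start
        (new inhabitants); the rest are registered from the data start.
    deregistration_hazard:
        Annual hazard of leaving the registry (move/death), constant.
    dd_onset_hazard:
        Map ``(sex, age_band) -> annual hazard`` of a first observable DD
        presentation, per person-year, before care-seeking multipliers.
    care_seeking_multiplier:
        Map ``year -> multiplicative factor`` on the first-presentation
        hazard (years absent from the map use 1.0).
    p_code_given_dd_contact:
        Probability that a DD contact carries ICPC L99.03.
    p_followup_contact:
        Per-year probability of a repeat DD contact after the first.
    note_mix:
        Probabilities over note templates.  ``positive`` is the probability
        that a true DD contact's note uses a positive template; the
        remaining keys (``negated``, ``family_history``, ``distractor``,
        ``unrelated``) are renormalised to form the background-note mix.
    background_contact_rate:
        Non-DD contacts per person-year (note drawn from the background
        mix).  No registry statistic for this is published; the default is
        a plausible invention (see the package methods note).
    comorbidity_prevalence:
        Map ``ICPC code -> prevalence among DD cases``.
    comorbidity_noncase_factor:
        Multiplier on case prevalences for non-cases.
    duplicate_rate:
        Probability that a patient is split into two pseudonym records.
    alt_pseudonym_coverage:
        Fraction of patients with a second pseudonym recorded (all have a
        fee-record key).
    language:
        ``"nl"`` or ``"en"`` note-template set.
    seed:
        Base seed; every generator operation derives its stream from it.
    """

    n_patients: int
    year_range: tuple[int, int]
    sex_ratio_male: float
    age_distribution: tuple[tuple[str, float], ...]
    practice_onboarding: tuple[tuple[str, int], ...]
    dd_onset_hazard: Mapping[tuple[str, str], float]
    care_seeking_multiplier: Mapping[int, float]
    p_code_given_dd_contact: float
    p_followup_contact: float
    note_mix: Mapping[str, float]
    comorbidity_prevalence: Mapping[str, float]
    duplicate_rate: float
    lookback_years: int = 5
    late_registration_fraction: float = 0.10
    deregistration_hazard: float = 0.012
    background_contact_rate: float = 0.15
    comorbidity_noncase_factor: float = 0.5
    alt_pseudonym_coverage: float = 0.80
    language: str = "nl"
    seed: int = 0

    # -- validation ----------------------------------------------------
    def validate(self, *, for_prevalence: bool = False) -> None:
        """Check all invariants; raise :class:`ConfigurationError` naming the field."""
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        first, last = self.year_range
        if last < first:
            raise ConfigurationError("year_range must be (first, last) with first <= last")
        if for_prevalence and last - first + 1 < 12:
            raise ConfigurationError(
                "year_range must span >= 12 years for the 10-year run-in prevalence analysis"
            )
        for name in (
            "sex_ratio_male",
            "p_code_given_dd_contact",
            "p_followup_contact",
            "duplicate_rate",
            "late_registration_fraction",
            "alt_pseudonym_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v}")
        wsum = sum(w for _, w in self.age_distribution)
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigurationError(f"age_distribution weights must sum to 1, got {wsum}")
        for band, w in self.age_distribution:
            if w < 0:
                raise ConfigurationError(f"age_distribution weight for {band} is negative")
            lo, hi = _parse_age_band(band)
            if not 0 <= lo < hi:
                raise ConfigurationError(f"age_distribution band {band!r} is malformed")
        if not self.practice_onboarding:
            raise ConfigurationError("practice_onboarding must list at least one practice")
        for sex in SEXES:
            for band in HAZARD_BANDS:
                if (sex, band) not in self.dd_onset_hazard:
                    raise ConfigurationError(f"dd_onset_hazard missing stratum ({sex}, {band})")
        for key, h in self.dd_onset_hazard.items():
            if h < 0:
                raise ConfigurationError(f"dd_onset_hazard[{key}] must be non-negative")
        for y, m in self.care_seeking_multiplier.items():
            if m < 0:
                raise ConfigurationError(f"care_seeking_multiplier[{y}] must be non-negative")
        for cat, p in self.note_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"note_mix[{cat!r}] must be in [0, 1]")
        bg = sum(p for cat, p in self.note_mix.items() if cat != "positive")
        if bg <= 0:
            raise ConfigurationError("note_mix background categories must have positive mass")
        for code, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"comorbidity_prevalence[{code!r}] must be in [0, 1]")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))

    def with_n_patients(self, n: int) -> "ScenarioConfig":
        return replace(self, n_patients=int(n))


def _parse_age_band(band: str) -> tuple[int, int]:
    lo, hi = band.split("-")
    return int(lo), int(hi)


# ---------------------------------------------------------------------------
# The calibrated 'paper2021' scenario.
#
# Hazards are annual first-observable-presentation probabilities (per
# person-year).  The age shape rises to a peak in the 60-80 bands and
# declines afterwards; the male:female scale ratio (~1.67) reproduces the
# male/female prevalence split.  Care-seeking multipliers: pre-2017 years
# carry a common factor that sets the cumulative caseload (hence the 2021
# prevalence); 2020 carries the COVID dip 1.41/1.72; 2021 a partial
# recovery.  p_code_given_dd_contact sets the fraction of cases
# retrievable from ICPC codes alone (code-only prevalence ~1.38% vs 1.99%).
# ---------------------------------------------------------------------------

_AGE_SHAPE = {
    "<40": 0.060,
    "40-50": 0.90,
    "50-60": 2.10,
    "60-70": 3.50,
    "70-80": 3.80,
    "80-90": 2.60,
    "90+": 1.40,
}  # per 1000 person-years, unisex shape

_MALE_SCALE = 1.420
_FEMALE_SCALE = 0.865

_PAPER2021_HAZARDS = {
    (sex, band): scale * shape / 1000.0
    for sex, scale in (("male", _MALE_SCALE), ("female", _FEMALE_SCALE))
    for band, shape in _AGE_SHAPE.items()
}

_PRE2017_MULTIPLIER = 1.64
_PAPER2021_MULTIPLIERS = {
    **{y: _PRE2017_MULTIPLIER for y in range(2010, 2017)},
    2017: 1.00,
    2018: 1.00,
    2019: 1.00,
    2020: 1.41 / 1.72,
    2021: 0.85,
}

#: Adult age structure on 1 July 2021 (roughly Dutch adult demography).
_PAPER2021_AGES = (
    ("18-30", 0.180),
    ("30-40", 0.155),
    ("40-50", 0.155),
    ("50-60", 0.175),
    ("60-70", 0.150),
    ("70-80", 0.115),
    ("80-90", 0.055),
    ("90-105", 0.015),
)

#: 12 practices onboarding 2015-2017; with the 5-year lookback their data
#: windows start 2010-2012, giving 2021 a >= 10-year run-in everywhere.
_PAPER2021_PRACTICES = tuple(
    (f"PR{i:02d}", 2015 + (i % 3)) for i in range(12)
)

#: Comorbidity prevalences among DD cases (ICPC-1 codes): diabetes
#: mellitus T90, tobacco abuse P17, chronic alcohol abuse P15, lipid
#: disorder T93, obesity T82, epilepsy N88.
_PAPER2021_COMORBIDITY = {
    "T90": 0.195,
    "P17": 0.102,
    "P15": 0.027,
    "T93": 0.189,
    "T82": 0.075,
    "N88": 0.020,
}


def paper2021(n_patients: int = 200_000, seed: int = 0) -> ScenarioConfig:
    """The calibrated registry-emulation scenario (2010-2021, 200k patients)."""
    cfg = ScenarioConfig(
        n_patients=n_patients,
        year_range=(2010, 2021),
        sex_ratio_male=0.49,
        age_distribution=_PAPER2021_AGES,
        practice_onboarding=_PAPER2021_PRACTICES,
        dd_onset_hazard=dict(_PAPER2021_HAZARDS),
        care_seeking_multiplier=dict(_PAPER2021_MULTIPLIERS),
        p_code_given_dd_contact=0.453,
        p_followup_contact=0.25,
        note_mix={
            "positive": 1.0,
            "negated": 0.05,
            "family_history": 0.03,
            "distractor": 0.12,
            "unrelated": 0.80,
        },
        comorbidity_prevalence=dict(_PAPER2021_COMORBIDITY),
        duplicate_rate=0.02,
        seed=seed,
    )
    cfg.validate(for_prevalence=True)
    return cfg


#: Configured truth values the 'paper2021' scenario is calibrated to
#: recover (pipeline outputs, on the printed scales).
PAPER2021_TRUTH = {
    "prevalence_2021_percent": 1.99,
    "prevalence_2021_male_percent": 2.50,
    "prevalence_2021_female_percent": 1.50,
    "incidence_2019_per_1000py": 1.72,
    "incidence_2020_per_1000py": 1.41,
    "prevalence_2021_code_only_percent": 1.38,
}


_SCENARIOS = {"paper2021": paper2021}


def get_scenario(name: str, **kwargs) -> ScenarioConfig:
    """Look up a named scenario factory."""
    try:
        factory = _SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        ) from None
    return factory(**kwargs)
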