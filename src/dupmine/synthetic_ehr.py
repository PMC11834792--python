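"""Synthetic primary-care registry generator with known ground truth.

Emulates the statistical structure of a Dutch GP research registry: a
dynamic adult population registered with practices that onboard over a few
years and supply five years of historical data, an age- and sex-dependent
hazard of a first observable Dupuytren's-disease (DD) presentation,
coded-vs-free-text-only registration of DD contacts, background contacts
whose notes contain negations, family-history mentions and 'dup'-prefix
distractors, comorbidity ICPC codes, and injected duplicate patient
records.

The first-presentation process runs *inside* each patient's registration
window only: the event simulated is "first DD contact observable in the
registry", which is exactly the quantity the downstream pipeline
estimates.  All outputs are deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import ScenarioConfig, ConfigurationError, HAZARD_BANDS, _parse_age_band
from .templates import note_templates, CATEGORIES, COMORBIDITY_NOTES, UNRELATED_ICPC

__all__ = [
    "SyntheticDataset",
    "generate_population",
    "generate_dd_histories",
    "generate_contacts",
    "inject_duplicates",
    "generate_dataset",
    "write_dataset",
    "read_truth",
]

DD_ICPC = "L99.03"

_PATIENT_COLUMNS = [
    "patient_id", "alt_pseudonym", "fee_key", "birth_date", "sex",
    "registration_start", "registration_end", "practice_id",
]
_CONTACT_COLUMNS = ["contact_id", "patient_id", "contact_date", "icpc_code", "note_text"]
_TRUTH_COLUMNS = [
    "patient_id", "true_dd", "true_onset_date", "true_first_presentation_date", "duplicate_of",
]

# distinct RNG substreams per operation so each op is independently
# deterministic for a given config seed
_STREAM = {"population": 1, "histories": 2, "contacts": 3, "duplicates": 4}


def _rng(config: ScenarioConfig, op: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[op]])


def _mid_year(year: int) -> np.datetime64:
    return np.datetime64(f"{year}-07-01", "D")


def _jan1(year: int) -> np.datetime64:
    return np.datetime64(f"{year}-01-01", "D")


def _dec31(year: int) -> np.datetime64:
    return np.datetime64(f"{year}-12-31", "D")


def _band_index_for_age(age: np.ndarray) -> np.ndarray:
    """Map ages to indices into HAZARD_BANDS (<40, then decades, 90+)."""
    edges = np.array([40, 50, 60, 70, 80, 90], dtype=float)
    return np.digitize(age, edges, right=False)


@dataclass
class SyntheticDataset:
    """One generated registry extract plus its ground truth."""

    patients: pd.DataFrame
    contacts: pd.DataFrame
    truth: pd.DataFrame          # per patient
    contact_truth: pd.DataFrame  # per contact: true_dd_contact
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the patient table and an (event-free) ground-truth table.

    Ages are drawn from ``config.age_distribution`` (age on 1 July of the
    last simulated year), sex from ``sex_ratio_male``, practice uniformly.
    A practice onboarding in year ``Y`` supplies data from
    ``Y - lookback_years``; most patients are registered from that data
    start, a ``late_registration_fraction`` register later.  Registration
    ends early with a constant annual deregistration hazard, otherwise at
    the study end (open-ended, stored as missing).
    """
    config.validate()
    n = config.n_patients
    rng = _rng(config, "population")
    first_year, last_year = config.year_range
    ref = _mid_year(last_year)
    study_end = _dec31(last_year)

    patient_id = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    sex = np.where(rng.random(n) < config.sex_ratio_male, "male", "female").astype(object)

    bands = [b for b, _ in config.age_distribution]
    weights = np.array([w for _, w in config.age_distribution], dtype=float)
    weights = weights / weights.sum()
    band_idx = rng.choice(len(bands), size=n, p=weights)
    lohi = np.array([_parse_age_band(b) for b in bands], dtype=float)
    age = lohi[band_idx, 0] + rng.random(n) * (lohi[band_idx, 1] - lohi[band_idx, 0])
    birth_date = ref - (age * 365.25).astype("timedelta64[D]")

    n_prac = len(config.practice_onboarding)
    prac_idx = rng.integers(0, n_prac, size=n)
    prac_ids = np.array([p for p, _ in config.practice_onboarding], dtype=object)
    data_start_year = np.array(
        [max(y - config.lookback_years, first_year) for _, y in config.practice_onboarding]
    )[prac_idx]
    data_start = np.array([_jan1(y) for y in data_start_year.tolist()], dtype="datetime64[D]")

    late = rng.random(n) < config.late_registration_fraction
    span = (study_end - data_start).astype(int)
    reg_start = data_start.copy()
    reg_start[late] = data_start[late] + (
        rng.random(late.sum()) * span[late]
    ).astype("timedelta64[D]")

    # exponential time to deregistration, censored at study end (open)
    if config.deregistration_hazard > 0:
        t_out = rng.exponential(1.0 / config.deregistration_hazard, size=n)
    else:
        t_out = np.full(n, np.inf)
    reg_end = reg_start + np.where(
        np.isinf(t_out), 10**6, np.maximum(t_out * 365.25, 1.0)
    ).astype("timedelta64[D]")
    open_ended = reg_end > study_end
    reg_end = np.minimum(reg_end, study_end)

    alt = np.array([f"A{i:07d}" for i in range(n)], dtype=object)
    alt[rng.random(n) >= config.alt_pseudonym_coverage] = ""
    fee = np.array([f"F{i:07d}" for i in range(n)], dtype=object)

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "alt_pseudonym": alt,
            "fee_key": fee,
            "birth_date": pd.to_datetime(birth_date).astype("datetime64[ns]"),
            "sex": sex,
            "registration_start": pd.to_datetime(reg_start).astype("datetime64[ns]"),
            "registration_end": pd.to_datetime(
                np.where(open_ended, np.datetime64("NaT"), reg_end)
            ).astype("datetime64[ns]"),
            "practice_id": prac_ids[prac_idx],
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": patient_id,
            "true_dd": np.zeros(n, dtype=bool),
            "true_onset_date": pd.Series([pd.NaT] * n, dtype="datetime64[ns]"),
            "true_first_presentation_date": pd.Series([pd.NaT] * n, dtype="datetime64[ns]"),
            "duplicate_of": np.array([""] * n, dtype=object),
        }
    )
    return patients, truth


def _effective_end(patients: pd.DataFrame, study_end: np.datetime64) -> np.ndarray:
    end = patients["registration_end"].to_numpy("datetime64[D]")
    return np.where(np.isnat(end), study_end, end)


# ---------------------------------------------------------------------------
# DD histories
# ---------------------------------------------------------------------------

def generate_dd_histories(patients: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Simulate first observable DD presentations (discrete annual hazard).

    For each calendar year inside a patient's registration window a
    Bernoulli draw with probability ``hazard[sex, age_band] *
    care_seeking_multiplier[year] * fraction_of_year_registered`` decides
    the first presentation; the event date is uniform within the
    registered part of that year.  Onset is identified with the first
    observable presentation (see the methods note).
    """
    config.validate()
    rng = _rng(config, "histories")
    first_year, last_year = config.year_range
    n = len(patients)

    hz = np.zeros((2, len(HAZARD_BANDS)))
    for si, sex in enumerate(("male", "female")):
        for bi, band in enumerate(HAZARD_BANDS):
            try:
                hz[si, bi] = config.dd_onset_hazard[(sex, band)]
            except KeyError:
                raise ConfigurationError(f"dd_onset_hazard missing stratum ({sex}, {band})")

    sex_idx = (patients["sex"].to_numpy() == "female").astype(int)
    birth = patients["birth_date"].to_numpy("datetime64[D]")
    reg_start = patients["registration_start"].to_numpy("datetime64[D]")
    reg_end = _effective_end(patients, _dec31(last_year))

    event_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    at_large = np.ones(n, dtype=bool)  # not yet presented

    for year in range(first_year, last_year + 1):
        y0, y1 = _jan1(year), _dec31(year)
        days_in_year = (y1 - y0).astype(int) + 1
        w_start = np.maximum(reg_start, y0)
        w_end = np.minimum(reg_end, y1)
        w_days = (w_end - w_start).astype(int) + 1
        in_window = w_days > 0
        frac = np.clip(w_days, 0, None) / days_in_year

        age = ((_mid_year(year) - birth).astype(int)) / 365.25
        bi = _band_index_for_age(age)
        mult = config.care_seeking_multiplier.get(year, 1.0)
        p = hz[sex_idx, bi] * mult * frac

        u = rng.random(n)
        hit = at_large & in_window & (u < p)
        if hit.any():
            offs = (rng.random(n) * np.clip(w_days, 1, None))[hit].astype(int)
            event_date[hit] = w_start[hit] + offs.astype("timedelta64[D]")
            at_large[hit] = False

    truth = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "true_dd": ~at_large,
            "true_onset_date": pd.to_datetime(event_date).astype("datetime64[ns]"),
            "true_first_presentation_date": pd.to_datetime(event_date).astype("datetime64[ns]"),
            "duplicate_of": np.array([""] * n, dtype=object),
        }
    )
    return truth


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def generate_contacts(
    patients: pd.DataFrame, truth: pd.DataFrame, config: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the contact table (DD, background and comorbidity contacts).

    DD contacts comprise the first presentation plus yearly follow-up
    contacts (probability ``p_followup_contact`` per registered year after
    the first).  Each DD contact carries ICPC L99.03 with probability
    ``p_code_given_dd_contact``; its note uses a positive template with
    probability ``note_mix['positive']``, otherwise an unrelated one.
    Background contacts arrive at ``background_contact_rate`` per
    person-year with notes from the background mix; comorbidity contacts
    carry their ICPC code once per affected patient.
    """
    config.validate()
    rng = _rng(config, "contacts")
    first_year, last_year = config.year_range
    n = len(patients)
    templates = note_templates(config.language)
    study_end = _dec31(last_year)

    reg_start = patients["registration_start"].to_numpy("datetime64[D]")
    reg_end = _effective_end(patients, study_end)
    pid = patients["patient_id"].to_numpy()

    rows_pid: list[np.ndarray] = []
    rows_date: list[np.ndarray] = []
    rows_code: list[np.ndarray] = []
    rows_note: list[np.ndarray] = []
    rows_dd: list[np.ndarray] = []

    pos_templates = np.array(templates["positive"], dtype=object)
    unrel_templates = np.array(templates["unrelated"], dtype=object)

    def _dd_notes_codes(k: int) -> tuple[np.ndarray, np.ndarray]:
        coded = rng.random(k) < config.p_code_given_dd_contact
        codes = np.where(coded, DD_ICPC, "").astype(object)
        positive = rng.random(k) < config.note_mix.get("positive", 1.0)
        notes = np.where(
            positive,
            pos_templates[rng.integers(0, len(pos_templates), k)],
            unrel_templates[rng.integers(0, len(unrel_templates), k)],
        ).astype(object)
        return codes, notes

    # -- first presentations
    has_dd = truth["true_dd"].to_numpy()
    first_date = truth["true_first_presentation_date"].to_numpy("datetime64[D]")
    idx_dd = np.flatnonzero(has_dd)
    k = len(idx_dd)
    if k:
        codes, notes = _dd_notes_codes(k)
        rows_pid.append(pid[idx_dd])
        rows_date.append(first_date[idx_dd])
        rows_code.append(codes)
        rows_note.append(notes)
        rows_dd.append(np.ones(k, dtype=bool))

    # -- follow-up DD contacts, year by year after the event year
    if k:
        ev_year = first_date[idx_dd].astype("datetime64[Y]").astype(int) + 1970
        for year in range(first_year, last_year + 1):
            y0, y1 = _jan1(year), _dec31(year)
            w_start = np.maximum(reg_start[idx_dd], y0)
            w_end = np.minimum(reg_end[idx_dd], y1)
            w_days = (w_end - w_start).astype(int) + 1
            ok = (ev_year < year) & (w_days > 0)
            m = ok.sum()
            if not m:
                continue
            fu = rng.random(k) < config.p_followup_contact
            sel = ok & fu
            m = sel.sum()
            if not m:
                continue
            offs = (rng.random(m) * w_days[sel]).astype(int)
            codes, notes = _dd_notes_codes(m)
            rows_pid.append(pid[idx_dd][sel])
            rows_date.append(w_start[sel] + offs.astype("timedelta64[D]"))
            rows_code.append(codes)
            rows_note.append(notes)
            rows_dd.append(np.ones(m, dtype=bool))

    # -- background contacts
    window_start = np.maximum(reg_start, _jan1(first_year))
    window_days = np.clip((reg_end - window_start).astype(int) + 1, 0, None)
    py = window_days / 365.25
    counts = rng.poisson(config.background_contact_rate * py)
    total = int(counts.sum())
    if total:
        owner = np.repeat(np.arange(n), counts)
        offs = (rng.random(total) * window_days[owner]).astype(int)
        dates = window_start[owner] + offs.astype("timedelta64[D]")
        bg_cats = [c for c in CATEGORIES if c != "positive"]
        bg_p = np.array([config.note_mix.get(c, 0.0) for c in bg_cats], dtype=float)
        bg_p = bg_p / bg_p.sum()
        cat = rng.choice(len(bg_cats), size=total, p=bg_p)
        notes = np.empty(total, dtype=object)
        codes = np.full(total, "", dtype=object)
        for ci, cname in enumerate(bg_cats):
            mask = cat == ci
            mcount = int(mask.sum())
            if not mcount:
                continue
            tpl = np.array(templates[cname], dtype=object)
            notes[mask] = tpl[rng.integers(0, len(tpl), mcount)]
            if cname == "unrelated":
                codes[mask] = np.array(UNRELATED_ICPC, dtype=object)[
                    rng.integers(0, len(UNRELATED_ICPC), mcount)
                ]
        rows_pid.append(pid[owner])
        rows_date.append(dates)
        rows_code.append(codes)
        rows_note.append(notes)
        rows_dd.append(np.zeros(total, dtype=bool))

    # -- comorbidity contacts (one coded contact per affected patient)
    note_c = COMORBIDITY_NOTES[config.language]
    for code, p_case in config.comorbidity_prevalence.items():
        p = np.where(has_dd, p_case, p_case * config.comorbidity_noncase_factor)
        sel = (rng.random(n) < p) & (window_days > 0)
        m = int(sel.sum())
        if not m:
            continue
        offs = (rng.random(m) * window_days[sel]).astype(int)
        rows_pid.append(pid[sel])
        rows_date.append(window_start[sel] + offs.astype("timedelta64[D]"))
        rows_code.append(np.full(m, code, dtype=object))
        rows_note.append(np.full(m, note_c, dtype=object))
        rows_dd.append(np.zeros(m, dtype=bool))

    if rows_pid:
        all_pid = np.concatenate(rows_pid)
        all_date = np.concatenate(rows_date)
        all_code = np.concatenate(rows_code)
        all_note = np.concatenate(rows_note)
        all_dd = np.concatenate(rows_dd)
    else:
        all_pid = np.array([], dtype=object)
        all_date = np.array([], dtype="datetime64[D]")
        all_code = np.array([], dtype=object)
        all_note = np.array([], dtype=object)
        all_dd = np.array([], dtype=bool)

    order = np.lexsort((all_date.astype("datetime64[D]").astype(int), all_pid.astype(str)))
    all_pid, all_date, all_code, all_note, all_dd = (
        a[order] for a in (all_pid, all_date, all_code, all_note, all_dd)
    )
    contact_id = np.array([f"C{i:08d}" for i in range(len(all_pid))], dtype=object)

    contacts = pd.DataFrame(
        {
            "contact_id": contact_id,
            "patient_id": all_pid,
            "contact_date": pd.to_datetime(all_date).astype("datetime64[ns]"),
            "icpc_code": all_code,
            "note_text": all_note,
        }
    )
    contact_truth = pd.DataFrame({"contact_id": contact_id, "true_dd_contact": all_dd})
    return contacts, contact_truth


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------

def inject_duplicates(
    patients: pd.DataFrame,
    contacts: pd.DataFrame,
    config: ScenarioConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a random subset of patients into two pseudonym records.

    Each selected patient's registration interval is cut at a random
    interior date; contacts after the cut move to the new record.  Half
    the splits abut (second record starts the day after the cut), half
    overlap the original interval by up to 90 days.  Both records keep the
    same secondary pseudonym and fee key, so key-based deduplication can
    undo the split.  Returns ``(patients, contacts, duplicate_map)`` where
    ``duplicate_map`` has columns ``patient_id`` (new record) and
    ``duplicate_of`` (original).  Total contact count is conserved.
    """
    config.validate()
    rng = _rng(config, "duplicates")
    n = len(patients)
    study_end = _dec31(config.year_range[1])
    if n == 0 or config.duplicate_rate == 0:
        empty = pd.DataFrame({"patient_id": [], "duplicate_of": []}, dtype=object)
        return patients.copy(), contacts.copy(), empty

    reg_start = patients["registration_start"].to_numpy("datetime64[D]")
    reg_end = _effective_end(patients, study_end)
    span = (reg_end - reg_start).astype(int)
    eligible = span >= 60
    chosen = (rng.random(n) < config.duplicate_rate) & eligible
    idx = np.flatnonzero(chosen)
    if len(idx) == 0:
        empty = pd.DataFrame({"patient_id": [], "duplicate_of": []}, dtype=object)
        return patients.copy(), contacts.copy(), empty

    cut_off = (30 + rng.random(len(idx)) * (span[idx] - 59)).astype(int)
    cut = reg_start[idx] + cut_off.astype("timedelta64[D]")
    overlap = rng.random(len(idx)) < 0.5
    back = np.where(overlap, (rng.random(len(idx)) * 90).astype(int), -1)
    b_start = cut - back.astype("timedelta64[D]")
    b_start = np.maximum(b_start, reg_start[idx])

    patients = patients.copy()
    contacts = contacts.copy()
    orig_ids = patients["patient_id"].to_numpy()[idx]
    new_ids = np.array([f"{p}D" for p in orig_ids], dtype=object)
    was_open = patients["registration_end"].isna().to_numpy()[idx]

    # truncate originals at the cut
    end_col = patients.columns.get_loc("registration_end")
    patients.iloc[idx, end_col] = pd.to_datetime(cut).astype("datetime64[ns]")

    new_rows = patients.iloc[idx].copy()
    new_rows["patient_id"] = new_ids
    new_rows["registration_start"] = pd.to_datetime(b_start).astype("datetime64[ns]")
    # the new record inherits the original end (open-ended stays open)
    new_rows["registration_end"] = pd.to_datetime(
        np.where(was_open, np.datetime64("NaT"), reg_end[idx])
    ).astype("datetime64[ns]")
    patients = pd.concat([patients, new_rows], ignore_index=True)

    # move contacts dated after the cut to the new record
    cut_by_pid = dict(zip(orig_ids, pd.to_datetime(cut)))
    newid_by_pid = dict(zip(orig_ids, new_ids))
    cmask = contacts["patient_id"].isin(orig_ids).to_numpy()
    if cmask.any():
        sub = contacts.loc[cmask]
        cuts = sub["patient_id"].map(cut_by_pid)
        move = (sub["contact_date"] > cuts).to_numpy()
        moved_ids = sub.loc[move, "patient_id"].map(newid_by_pid)
        contacts.loc[sub.index[move], "patient_id"] = moved_ids.to_numpy()

    dup_map = pd.DataFrame({"patient_id": new_ids, "duplicate_of": orig_ids})
    if truth is not None:
        truth = truth.copy()
    return patients, contacts, dup_map


# ---------------------------------------------------------------------------
# end-to-end + IO
# ---------------------------------------------------------------------------

def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Run all generator stages for ``config`` and return the dataset."""
    patients, truth = generate_population(config)
    truth = generate_dd_histories(patients, config)
    contacts, contact_truth = generate_contacts(patients, truth, config)
    patients, contacts, dup_map = inject_duplicates(patients, contacts, config)
    if len(dup_map):
        # per-patient truth stays with the original record; split-off
        # records are flagged via duplicate_of only
        m = len(dup_map)
        extra = pd.DataFrame(
            {
                "patient_id": dup_map["patient_id"].to_numpy(),
                "true_dd": np.zeros(m, dtype=bool),
                "true_onset_date": pd.Series([pd.NaT] * m, dtype="datetime64[ns]"),
                "true_first_presentation_date": pd.Series([pd.NaT] * m, dtype="datetime64[ns]"),
                "duplicate_of": dup_map["duplicate_of"].to_numpy(),
            }
        )
        # dtypes of extra match truth exactly; the all-NaT date columns
        # trip pandas' empty-entry concat deprecation spuriously
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            truth = pd.concat([truth, extra], ignore_index=True)[_TRUTH_COLUMNS]
    return SyntheticDataset(patients, contacts, truth, contact_truth, config)


def write_dataset(
    patients: pd.DataFrame,
    contacts: pd.DataFrame,
    truth: pd.DataFrame,
    directory: str | os.PathLike,
    contact_truth: pd.DataFrame | None = None,
) -> None:
    """Write patients.csv, contacts.csv, truth.csv (+ truth_contacts.csv).

    Dates are serialised ISO-8601 (YYYY-MM-DD), UTF-8, comma-separated,
    header row mandatory; missing dates (open registration end) are empty
    fields.  Round-trips losslessly with the ingest readers.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)

    def _dates_iso(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        out = df.copy()
        for c in cols:
            if c in out.columns:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d").fillna("")
        return out

    _dates_iso(patients[_PATIENT_COLUMNS], ["birth_date", "registration_start", "registration_end"]).to_csv(
        os.path.join(directory, "patients.csv"), index=False, encoding="utf-8"
    )
    _dates_iso(contacts[_CONTACT_COLUMNS], ["contact_date"]).to_csv(
        os.path.join(directory, "contacts.csv"), index=False, encoding="utf-8"
    )
    _dates_iso(truth[_TRUTH_COLUMNS], ["true_onset_date", "true_first_presentation_date"]).to_csv(
        os.path.join(directory, "truth.csv"), index=False, encoding="utf-8"
    )
    if contact_truth is not None:
        contact_truth.to_csv(
            os.path.join(directory, "truth_contacts.csv"), index=False, encoding="utf-8"
        )


def read_truth(directory: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read truth.csv (and truth_contacts.csv if present) back."""
    directory = os.fspath(directory)
    truth = pd.read_csv(
        os.path.join(directory, "truth.csv"),
        dtype={"patient_id": str, "duplicate_of": str},
        keep_default_na=False,
        na_values=[],
    )
    truth["true_dd"] = truth["true_dd"].astype(str).str.lower().isin(("true", "1"))
    for c in ("true_onset_date", "true_first_presentation_date"):
        truth[c] = pd.to_datetime(truth[c].replace("", pd.NaT), errors="coerce")
    path_ct = os.path.join(directory, "truth_contacts.csv")
    contact_truth = None
    if os.path.exists(path_ct):
        contact_truth = pd.read_csv(path_ct, dtype={"contact_id": str})
        contact_truth["true_dd_contact"] = (
            contact_truth["true_dd_contact"].astype(str).str.lower().isin(("true", "1"))
        )
    return truth, contact_truth
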