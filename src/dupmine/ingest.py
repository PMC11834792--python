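"""Registry table readers, patient eligibility filters and deduplication.

Mirrors the data-cleaning stage of a GP-registry analysis: read the
patient and contact tables, exclude records with coding errors (missing
registration dates, registration before birth, deregistration dates past
the year after data extraction, age outside 18-105), and merge duplicate
patient records identified through a second pseudonym or the fee-record
key.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_patients",
    "read_contacts",
    "filter_valid_patients",
    "deduplicate_patients",
]

PATIENT_SCHEMA = [
    "patient_id", "alt_pseudonym", "fee_key", "birth_date", "sex",
    "registration_start", "registration_end", "practice_id",
]
CONTACT_SCHEMA = ["contact_id", "patient_id", "contact_date", "icpc_code", "note_text"]

EXCLUSION_REASONS = (
    "missing_registration_date",
    "registration_before_birth",
    "deregistration_past_2022",
    "age_out_of_range",
)


class SchemaError(ValueError):
    """A file's header does not match the expected schema."""


def _read_csv(path: str | os.PathLike, schema: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[], encoding="utf-8")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{os.fspath(path)}: missing columns {missing}")
    return df[schema]


def read_patients(path: str | os.PathLike) -> pd.DataFrame:
    """Read and type patients.csv.

    Unparseable or empty dates become missing (NaT) rather than dropping
    the row; an empty ``registration_end`` means the patient was still
    registered at study end (open interval).
    """
    df = _read_csv(path, PATIENT_SCHEMA)
    for c in ("birth_date", "registration_start", "registration_end"):
        df[c] = pd.to_datetime(df[c].replace("", None), format="%Y-%m-%d", errors="coerce")
    return df


def read_contacts(path: str | os.PathLike, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and type contacts.csv; empty notes stay empty strings.

    If ``patients`` is given, contacts referencing unknown patient ids are
    kept and flagged in a boolean ``orphan`` column.
    """
    df = _read_csv(path, CONTACT_SCHEMA)
    df["contact_date"] = pd.to_datetime(
        df["contact_date"].replace("", None), format="%Y-%m-%d", errors="coerce"
    )
    df["note_text"] = df["note_text"].fillna("")
    if patients is not None:
        known = set(patients["patient_id"])
        df["orphan"] = ~df["patient_id"].isin(known)
    return df


# ---------------------------------------------------------------------------
# eligibility filtering
# ---------------------------------------------------------------------------

def filter_valid_patients(
    patients: pd.DataFrame,
    study_end: str | pd.Timestamp = "2021-12-31",
    *,
    min_age: float = 18.0,
    max_age: float = 105.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply coding-error and age-window exclusions.

    Excluded are patients with a missing registration start date, a
    registration start before birth, a deregistration date after 31
    December of the year following ``study_end`` (impossible given the
    extraction date, hence a coding error), and patients outside the
    18-105 age window.  The age window is evaluated per analysis year: a
    patient is eligible if aged >= 18 on 1 July of the last year they
    contribute and <= 105 on 1 July of the first.  Returns
    ``(retained, exclusion_log)``; the log has one row per patient per
    triggered reason.  Filtering never raises on content and is
    idempotent.
    """
    study_end = pd.Timestamp(study_end)
    dereg_cutoff = pd.Timestamp(year=study_end.year + 1, month=12, day=31)
    df = patients

    missing_reg = df["registration_start"].isna()
    before_birth = (~missing_reg) & df["birth_date"].notna() & (
        df["registration_start"] < df["birth_date"]
    )
    past_cutoff = df["registration_end"].notna() & (df["registration_end"] > dereg_cutoff)

    end_eff = df["registration_end"].fillna(study_end).clip(upper=study_end)
    first_year = df["registration_start"].dt.year
    last_year = end_eff.dt.year
    mid = lambda y: pd.to_datetime(dict(year=y, month=7, day=1), errors="coerce")
    age_last = (mid(last_year) - df["birth_date"]).dt.days / 365.25
    age_first = (mid(first_year) - df["birth_date"]).dt.days / 365.25
    bad_age = df["birth_date"].isna() | (age_last < min_age) | (age_first > max_age)

    reasons = {
        "missing_registration_date": missing_reg,
        "registration_before_birth": before_birth,
        "deregistration_past_2022": past_cutoff,
        "age_out_of_range": bad_age & ~missing_reg,
    }
    logs = []
    for reason, mask in reasons.items():
        mask = mask.fillna(False)
        if mask.any():
            logs.append(
                pd.DataFrame(
                    {
                        "patient_id": df.loc[mask, "patient_id"],
                        "reason": reason,
                        "detail": "",
                    }
                )
            )
    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["patient_id", "reason", "detail"])
    )
    excluded = log["patient_id"].unique() if len(log) else []
    retained = df.loc[~df["patient_id"].isin(excluded)].reset_index(drop=True)
    return retained, log


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _union_find_groups(patients: pd.DataFrame) -> list[list[int]]:
    """Group row indices that share a non-empty alt_pseudonym or fee_key."""
    parent = list(range(len(patients)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    touched: set[int] = set()
    for key in ("alt_pseudonym", "fee_key"):
        col = patients[key].fillna("").astype(str)
        shared = col[(col != "") & col.duplicated(keep=False)]
        for _, idxs in shared.groupby(shared).groups.items():
            idxs = list(idxs)
            touched.update(idxs)
            for j in idxs[1:]:
                union(idxs[0], j)

    groups: dict[int, list[int]] = {}
    for i in touched:
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in groups.values() if len(g) > 1]


def deduplicate_patients(
    patients: pd.DataFrame, contacts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Merge patient records that share a pseudonym or fee-record key.

    Records sharing a non-empty ``alt_pseudonym`` or ``fee_key`` with
    identical birth date and sex are merged into the lexicographically
    smallest ``patient_id``.  The merged registration interval is the
    union when the intervals overlap or abut (gap <= 1 day), otherwise
    earliest start / latest end with a gap flag.  Contacts are remapped
    to the surviving id.  Candidate pairs with conflicting birth date or
    sex are left unmerged and logged as conflicts.  Idempotent; total
    contact count is conserved.

    Returns ``(patients, contacts, merge_log)``; the log has columns
    ``surviving_id, merged_id, action ('merged'|'conflict'), gap_flag``.
    """
    patients = patients.reset_index(drop=True)
    groups = _union_find_groups(patients)
    log_rows = []
    drop_rows: list[int] = []
    remap: dict[str, str] = {}
    patients = patients.copy()

    start = patients["registration_start"]
    end = patients["registration_end"]
    open_end = end.isna()

    for group in groups:
        sub = patients.iloc[group]
        consistent = (
            sub["birth_date"].nunique(dropna=False) == 1 and sub["sex"].nunique() == 1
        )
        ids = sorted(sub["patient_id"])
        survivor = ids[0]
        if not consistent:
            for other in ids[1:]:
                log_rows.append((survivor, other, "conflict", False))
            continue
        si = sub.index[sub["patient_id"] == survivor][0]
        s_start = sub["registration_start"].min()
        s_end = pd.NaT if sub["registration_end"].isna().any() else sub["registration_end"].max()
        # gap check: sort intervals, look for > 1 day between consecutive
        ivs = sorted(
            (r["registration_start"], r["registration_end"])
            for _, r in sub.iterrows()
            if pd.notna(r["registration_start"])
        )
        gap = False
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            a_end = a1 if pd.notna(a1) else pd.Timestamp.max
            if pd.notna(b0) and (b0 - a_end).days > 1:
                gap = True
        patients.loc[si, "registration_start"] = s_start
        patients.loc[si, "registration_end"] = s_end
        for other in ids[1:]:
            oi = sub.index[sub["patient_id"] == other][0]
            drop_rows.append(oi)
            remap[other] = survivor
            log_rows.append((survivor, other, "merged", gap))

    merged = patients.drop(index=drop_rows).reset_index(drop=True)
    contacts = contacts.copy()
    if remap:
        contacts["patient_id"] = contacts["patient_id"].map(lambda p: remap.get(p, p))
    log = pd.DataFrame(
        log_rows, columns=["surviving_id", "merged_id", "action", "gap_flag"]
    )
    return merged, contacts, log
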