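"""Rule-based identification of Dupuytren's-disease (DD) contacts.

Case ascertainment is a two-stage funnel:

1. *Candidate extraction* — a contact is a candidate iff its ICPC code is
   L99.03 ('Dupuytren's contracture') or its free-text note contains the
   substring ``dup`` (case-insensitively).
2. *Classification* — a candidate is a DD contact iff it carries the
   L99.03 code, or its note matches a positive Dupuytren pattern that is
   not negated, not inside a family-history scope and not a 'dup'-prefix
   distractor (duplo, duplex, duplicate...).

The classifier is a pure, deterministic function of ``(text, rules)``:
tokens are lowercased words; a positive pattern matches a token span by
prefix on each token; negation and family-history cues suppress a match
when they occur within ``negation_window`` tokens before it.  Disabling
the text branch (``mode="code_only"``) reproduces code-based retrieval,
which by construction finds a subset of the combined cases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RuleSet",
    "default_ruleset",
    "candidate_rulesets",
    "tokenize",
    "extract_candidates",
    "classify_note",
    "classify_contact",
    "label_contacts",
    "summarize_patients",
    "case_patients",
]

DD_ICPC = "L99.03"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class RuleSet:
    """Token-level rules for classifying a free-text note.

    ``positive_patterns`` may be multiword; each pattern token matches a
    note token by prefix (so ``dupuytren`` also matches ``dupuytrense``).
    ``negation_cues`` are matched by token equality, ``family_history_cues``
    by prefix (``familie`` also hits ``familieanamnese``).  A match is
    suppressed when a cue lies within ``negation_window`` tokens before
    it, or when the matched stem token starts with a ``distractor_stem``.
    """

    name: str = "default"
    positive_patterns: tuple[str, ...] = ()
    negation_cues: tuple[str, ...] = ()
    family_history_cues: tuple[str, ...] = ()
    distractor_stems: tuple[str, ...] = ()
    negation_window: int = 4

    def __post_init__(self):
        if not self.positive_patterns:
            raise ValueError("positive_patterns must be non-empty")
        if self.negation_window < 1:
            raise ValueError("negation_window must be >= 1")

    # -- serialisation -------------------------------------------------
    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in payload.items()}
        text = yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RuleSet":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        for k in ("positive_patterns", "negation_cues", "family_history_cues", "distractor_stems"):
            if k in payload:
                payload[k] = tuple(payload[k])
        return cls(**payload)


def default_ruleset() -> RuleSet:
    """The default reconstruction of the DD free-text rules."""
    return RuleSet(
        name="negation+family+distractor",
        positive_patterns=(
            "dupuytren", "dupuytren's", "m. dupuytren", "ziekte van dupuytren", "dupuytrense",
        ),
        negation_cues=("geen", "niet", "uitgesloten", "no", "not", "without"),
        family_history_cues=(
            "vader", "moeder", "familie", "broer", "zus",
            "family", "father", "mother", "brother", "sister",
        ),
        distractor_stems=("duplo", "duplex", "duplicaat", "duplicate", "dupe"),
        negation_window=4,
    )


def candidate_rulesets() -> list[RuleSet]:
    """Ordered candidate rulesets for the tuning protocol (naive -> full)."""
    full = default_ruleset()
    naive = RuleSet(
        name="positive-only",
        positive_patterns=full.positive_patterns,
        negation_cues=(),
        family_history_cues=(),
        distractor_stems=full.distractor_stems,
        negation_window=full.negation_window,
    )
    negated = RuleSet(
        name="positive+negation",
        positive_patterns=full.positive_patterns,
        negation_cues=full.negation_cues,
        family_history_cues=(),
        distractor_stems=full.distractor_stems,
        negation_window=full.negation_window,
    )
    return [naive, negated, full]


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens (punctuation-insensitive)."""
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def extract_candidates(contacts: pd.DataFrame) -> pd.DataFrame:
    """Return the candidate contacts (code L99.03 or 'dup' in the note).

    The result carries an ``is_candidate`` column (all True); non-candidate
    contacts are dropped from the DD path.
    """
    code = contacts["icpc_code"].fillna("").astype(str)
    note = contacts["note_text"].fillna("").astype(str)
    mask = (code == DD_ICPC) | note.str.lower().str.contains("dup", regex=False)
    out = contacts.loc[mask].copy()
    out["is_candidate"] = True
    return out


# ---------------------------------------------------------------------------
# note classification
# ---------------------------------------------------------------------------

def classify_note(note_text: str, rules: RuleSet) -> tuple[bool, str | None]:
    """Classify one note; returns ``(is_dd_text, matched_rule)``.

    Positive iff some positive pattern matches at a position with no
    negation cue and no family-history cue within ``negation_window``
    tokens before it, and the matched stem token is not a distractor.
    """
    tokens = tokenize(note_text)
    if not tokens:
        return False, None
    w = rules.negation_window
    for pattern in rules.positive_patterns:
        p_toks = tokenize(pattern)
        if not p_toks:
            continue
        for i in range(len(tokens) - len(p_toks) + 1):
            if not all(tokens[i + j].startswith(p_toks[j]) for j in range(len(p_toks))):
                continue
            stem = tokens[i + len(p_toks) - 1]
            if any(stem.startswith(d) for d in rules.distractor_stems):
                continue
            window = tokens[max(0, i - w):i]
            if any(t in rules.negation_cues for t in window):
                continue
            if any(t.startswith(c) for t in window for c in rules.family_history_cues):
                continue
            return True, pattern
    return False, None


def _classify_series(notes: pd.Series, rules: RuleSet) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised classify over a note column (cached per unique string)."""
    uniq, inv = np.unique(notes.fillna("").astype(str).to_numpy(), return_inverse=True)
    pos = np.zeros(len(uniq), dtype=bool)
    rule = np.full(len(uniq), None, dtype=object)
    for k, text in enumerate(uniq):
        pos[k], rule[k] = classify_note(text, rules)
    return pos[inv], rule[inv]


def classify_contact(contact, label_stub=None, rules: RuleSet | None = None) -> dict:
    """Classify one candidate contact into a DD label.

    ``contact`` is a mapping with ``contact_id``, ``icpc_code`` and
    ``note_text``.  Raises ``ValueError`` when called on a non-candidate.
    The L99.03 code takes precedence in the reported evidence; a coded
    contact is a DD contact even when its note is negated.
    """
    rules = rules or default_ruleset()
    code = str(contact.get("icpc_code") or "")
    note = str(contact.get("note_text") or "")
    is_code = code == DD_ICPC
    if not is_code and "dup" not in note.lower():
        raise ValueError(f"contact {contact.get('contact_id')} is not a candidate")
    text_pos, matched = classify_note(note, rules)
    is_dd = is_code or text_pos
    evidence = "icpc_code" if is_code else ("text_positive" if text_pos else "")
    return {
        "contact_id": contact.get("contact_id"),
        "is_candidate": True,
        "is_dd": is_dd,
        "evidence": evidence,
        "matched_rule": matched if text_pos else None,
    }


def label_contacts(
    contacts: pd.DataFrame,
    rules: RuleSet | None = None,
    mode: str = "code_and_text",
) -> pd.DataFrame:
    """Label every contact; returns a DDLabel table.

    Columns: ``contact_id, patient_id, contact_date, is_candidate, is_dd,
    evidence, matched_rule``.  ``mode="code_only"`` disables the text
    branch (the resulting DD set is a subset of the combined one).
    """
    if mode not in ("code_and_text", "code_only"):
        raise ValueError(f"unknown mode {mode!r}")
    rules = rules or default_ruleset()
    cand = extract_candidates(contacts)
    code_hit = cand["icpc_code"].fillna("").astype(str).to_numpy() == DD_ICPC
    if mode == "code_and_text" and len(cand):
        text_pos, matched = _classify_series(cand["note_text"], rules)
    else:
        text_pos = np.zeros(len(cand), dtype=bool)
        matched = np.full(len(cand), None, dtype=object)
    is_dd = code_hit | text_pos
    evidence = np.where(code_hit, "icpc_code", np.where(text_pos, "text_positive", ""))
    labels = pd.DataFrame(
        {
            "contact_id": cand["contact_id"].to_numpy(),
            "patient_id": cand["patient_id"].to_numpy(),
            "contact_date": cand["contact_date"].to_numpy(),
            "is_candidate": True,
            "is_dd": is_dd,
            "evidence": evidence,
            "matched_rule": np.where(text_pos & ~code_hit, matched, None),
        }
    )
    return labels


# ---------------------------------------------------------------------------
# per-patient summaries
# ---------------------------------------------------------------------------

def summarize_patients(
    labels: pd.DataFrame, patient_ids=None
) -> pd.DataFrame:
    """Per-patient DD summary from a label table.

    Returns columns ``patient_id, has_dd, first_dd_date, n_dd_contacts``
    with ``first_dd_date`` the earliest DD-labelled contact date.  When
    ``patient_ids`` is given the result covers exactly those ids (zero
    rows for patients without DD contacts); otherwise only patients with
    at least one DD contact appear.
    """
    dd = labels.loc[labels["is_dd"]]
    grouped = dd.groupby("patient_id").agg(
        first_dd_date=("contact_date", "min"), n_dd_contacts=("contact_id", "size")
    )
    if patient_ids is not None:
        grouped = grouped.reindex(pd.Index(patient_ids, name="patient_id"))
        grouped["n_dd_contacts"] = grouped["n_dd_contacts"].fillna(0).astype(int)
    out = grouped.reset_index()
    out["has_dd"] = out["n_dd_contacts"] > 0
    return out[["patient_id", "has_dd", "first_dd_date", "n_dd_contacts"]]


def case_patients(
    contacts: pd.DataFrame, rules: RuleSet | None = None, mode: str = "code_and_text"
) -> set[str]:
    """Set of patient ids with at least one DD contact under ``mode``.

    The ``code_only`` set is a subset of the ``code_and_text`` set.
    """
    labels = label_contacts(contacts, rules, mode=mode)
    return set(labels.loc[labels["is_dd"], "patient_id"])
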