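"""Candidate extraction and rule-based note classification.

Includes an independent brute-force classifier (exhaustive enumeration of
pattern/position/scope combinations) used as an oracle on short notes.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dupmine.textmine import (
    RuleSet,
    case_patients,
    classify_contact,
    classify_note,
    default_ruleset,
    extract_candidates,
    label_contacts,
    summarize_patients,
    tokenize,
)

RULES = default_ruleset()


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate every (pattern, position) combination and
# check the scopes by explicit list scans
# ---------------------------------------------------------------------------

def brute_force_classify(text: str, rules: RuleSet) -> bool:
    toks = tokenize(text)
    hits = []
    for pattern in rules.positive_patterns:
        ptoks = tokenize(pattern)
        if not ptoks:
            continue
        for start in range(len(toks)):
            span = toks[start:start + len(ptoks)]
            if len(span) < len(ptoks):
                continue
            if all(t.startswith(p) for t, p in zip(span, ptoks)):
                hits.append((pattern, start, start + len(ptoks) - 1))
    for pattern, start, stem_pos in hits:
        stem = toks[stem_pos]
        if any(stem.startswith(d) for d in rules.distractor_stems):
            continue
        window = toks[max(0, start - rules.negation_window):start]
        negated = any(w in rules.negation_cues for w in window)
        family = any(w.startswith(c) for w in window for c in rules.family_history_cues)
        if not negated and not family:
            return True
    return False


class TestCandidateExtraction:
    def test_coded_contact_with_empty_note_is_candidate(self):
        df = pd.DataFrame([dict(contact_id="C1", patient_id="P1",
                                contact_date=pd.Timestamp("2019-01-01"),
                                icpc_code="L99.03", note_text="")])
        assert len(extract_candidates(df)) == 1

    def test_dup_substring_is_candidate_even_if_distractor(self):
        df = pd.DataFrame([dict(contact_id="C1", patient_id="P1",
                                contact_date=pd.Timestamp("2019-01-01"),
                                icpc_code="", note_text="duplo bepaling aangevraagd")])
        assert len(extract_candidates(df)) == 1

    def test_unrelated_contact_not_candidate(self):
        df = pd.DataFrame([dict(contact_id="C1", patient_id="P1",
                                contact_date=pd.Timestamp("2019-01-01"),
                                icpc_code="K86", note_text="handklachten")])
        assert len(extract_candidates(df)) == 0


class TestClassifyNote:
    @pytest.mark.parametrize(
        "note, expected",
        [
            ("M. Dupuytren li hand, nodus palmair", True),
            ("geen aanwijzingen voor Dupuytren", False),
            ("", False),
            ("vader had dupuytren", False),
            ("duplo bepaling aangevraagd", False),
            ("niet passend bij dupuytren", False),
            ("DUPUYTRENSE contractuur re", True),          # case-insensitive
            ("nodus; past bij Dupuytren!", True),          # punctuation-insensitive
            ("vader had dupuytren maar nu zelf ook dupuytren li hand", True),
        ],
    )
    def test_examples(self, note, expected):
        assert classify_note(note, RULES)[0] is expected
        assert brute_force_classify(note, RULES) is expected

    def test_negation_outside_window_does_not_suppress(self):
        # cue 5 tokens before the stem, window is 4
        note = "geen pijn of zwelling vandaag dupuytren besproken"
        assert classify_note(note, RULES)[0] is True

    def test_matched_rule_reported(self):
        positive, rule = classify_note("ziekte van Dupuytren li", RULES)
        assert positive and rule in RULES.positive_patterns

    def test_determinism(self):
        note = "M. Dupuytren li hand"
        assert classify_note(note, RULES) == classify_note(note, RULES)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from(
            ["dupuytren", "dupuytrense", "geen", "niet", "vader", "familie",
             "duplo", "duplex", "hand", "nodus", "controle", "m", "ziekte",
             "van", "bij", "no", "not", "dup", "dupe", "contractuur"]
        ),
        min_size=0, max_size=20,
    )
)
def test_classifier_agrees_with_brute_force_on_short_notes(tokens):
    note = " ".join(tokens)
    assert classify_note(note, RULES)[0] == brute_force_classify(note, RULES)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from(["dupuytren", "geen", "vader", "hand", "duplo", "niet"]),
        min_size=0, max_size=12,
    )
)
def test_adding_positive_patterns_never_removes_a_positive(tokens):
    note = " ".join(tokens)
    wider = RuleSet(
        name="wider",
        positive_patterns=RULES.positive_patterns + ("nodus",),
        negation_cues=RULES.negation_cues,
        family_history_cues=RULES.family_history_cues,
        distractor_stems=RULES.distractor_stems,
        negation_window=RULES.negation_window,
    )
    if classify_note(note, RULES)[0]:
        assert classify_note(note, wider)[0]


class TestClassifyContact:
    def test_code_outweighs_negated_note(self):
        label = classify_contact(
            dict(contact_id="C1", icpc_code="L99.03", note_text="geen Dupuytren"),
            rules=RULES,
        )
        assert label["is_dd"] and label["evidence"] == "icpc_code"

    def test_text_positive_without_code(self):
        label = classify_contact(
            dict(contact_id="C2", icpc_code="", note_text="M. Dupuytren li hand"),
            rules=RULES,
        )
        assert label["is_dd"] and label["evidence"] == "text_positive"

    def test_family_history_not_a_case(self):
        label = classify_contact(
            dict(contact_id="C3", icpc_code="", note_text="vader had Dupuytren"),
            rules=RULES,
        )
        assert not label["is_dd"]

    def test_non_candidate_raises(self):
        with pytest.raises(ValueError, match="not a candidate"):
            classify_contact(dict(contact_id="C4", icpc_code="", note_text="rugpijn"),
                             rules=RULES)


class TestSummaries:
    def _labels(self, rows):
        return pd.DataFrame(
            rows, columns=["contact_id", "patient_id", "contact_date",
                           "is_candidate", "is_dd", "evidence", "matched_rule"]
        )

    def test_first_dd_date_is_earliest(self):
        labels = self._labels([
            ("C1", "P1", pd.Timestamp("2019-03-01"), True, True, "icpc_code", None),
            ("C2", "P1", pd.Timestamp("2017-05-02"), True, True, "text_positive", "dupuytren"),
        ])
        s = summarize_patients(labels).iloc[0]
        assert s["first_dd_date"] == pd.Timestamp("2017-05-02")
        assert s["n_dd_contacts"] == 2 and s["has_dd"]

    def test_no_dd_contacts_null_summary(self):
        labels = self._labels([
            ("C1", "P1", pd.Timestamp("2019-03-01"), True, False, "", None),
        ])
        s = summarize_patients(labels, patient_ids=["P1"]).iloc[0]
        assert not s["has_dd"] and pd.isna(s["first_dd_date"]) and s["n_dd_contacts"] == 0

    def test_singleton(self):
        labels = self._labels([
            ("C1", "P1", pd.Timestamp("2018-01-05"), True, True, "icpc_code", None),
        ])
        s = summarize_patients(labels).iloc[0]
        assert s["n_dd_contacts"] == 1 and s["first_dd_date"] == pd.Timestamp("2018-01-05")


class TestCaseSets:
    def _contacts(self):
        return pd.DataFrame([
            dict(contact_id="C1", patient_id="Ptext", contact_date=pd.Timestamp("2019-01-01"),
                 icpc_code="", note_text="M. Dupuytren li hand"),
            dict(contact_id="C2", patient_id="Pcode", contact_date=pd.Timestamp("2019-02-01"),
                 icpc_code="L99.03", note_text=""),
            dict(contact_id="C3", patient_id="Pneg", contact_date=pd.Timestamp("2019-03-01"),
                 icpc_code="", note_text="geen dupuytren"),
        ])

    def test_text_only_patient_in_combined_not_code_only(self):
        contacts = self._contacts()
        combined = case_patients(contacts, RULES, "code_and_text")
        code_only = case_patients(contacts, RULES, "code_only")
        assert combined == {"Ptext", "Pcode"}
        assert code_only == {"Pcode"}
        assert code_only <= combined

    def test_disabling_text_branch_never_adds_cases(self, small_dataset):
        combined = case_patients(small_dataset.contacts, RULES, "code_and_text")
        code_only = case_patients(small_dataset.contacts, RULES, "code_only")
        assert code_only <= combined


def test_per_contact_sensitivity_specificity_against_truth(small_dataset):
    """Default rules recover ground-truth DD contacts at >= 0.95 sens/spec."""
    ds = small_dataset
    labels = label_contacts(ds.contacts, RULES).set_index("contact_id")["is_dd"]
    truth = ds.contact_truth.set_index("contact_id")["true_dd_contact"]
    pred = labels.reindex(truth.index, fill_value=False)
    tp = (pred & truth).sum()
    tn = (~pred & ~truth).sum()
    sens = tp / truth.sum()
    spec = tn / (~truth).sum()
    assert sens >= 0.95 and spec >= 0.95


def test_ruleset_yaml_round_trip(tmp_path):
    path = tmp_path / "rules.yaml"
    RULES.to_yaml(path)
    assert RuleSet.from_yaml(path) == RULES
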