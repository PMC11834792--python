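"""Free-text note templates for the synthetic registry.

Each category is a finite set of pre-expanded strings with parameterised
phrasing (hand side, digit, wording variants) so a classifier cannot key on
one literal sentence.  Structural guarantees the generator relies on:

* every ``positive`` note mentions a Dupuytren stem with no negation or
  family-history cue in the four tokens before it;
* every ``negated`` note places a negation cue within four tokens before
  the stem;
* every ``family_history`` note places a family cue within four tokens
  before the stem;
* ``distractor`` notes contain "dup" only inside non-Dupuytren words
  (duplo, duplex, duplicaat / duplicate);
* ``unrelated`` notes never contain the substring "dup".

Dutch (``nl``) is the default corpus; ``en`` is an English alias set with
the same structure.
"""

from __future__ import annotations

from itertools import product

__all__ = ["note_templates", "CATEGORIES"]

CATEGORIES = ("positive", "negated", "family_history", "distractor", "unrelated")

_SIDES_NL = ("li", "re", "links", "rechts")
_SIDES_EN = ("left", "right")
_DIGITS = ("3", "4", "5")


def _positive_nl() -> list[str]:
    out = []
    for side in _SIDES_NL:
        out += [
            f"M. Dupuytren {side} hand, nodus palmair",
            f"ziekte van Dupuytren {side}, streng in handpalm",
            f"beginnende dupuytren {side} hand, beleid besproken",
            f"dupuytrense contractuur {side}, verwijzing plastisch chirurg",
        ]
    for d in _DIGITS:
        out.append(f"contractuur dig {d} bij M. Dupuytren, flexiestand toegenomen")
    out += [
        "controle M. Dupuytren, stabiel beeld",
        "nodus handpalm, past bij dupuytren; expectatief",
        "bekend met morbus dupuytren, nu toename klachten",
    ]
    return out


def _negated_nl() -> list[str]:
    out = []
    for side in _SIDES_NL[:2]:
        out += [
            f"geen aanwijzingen voor Dupuytren {side} hand",
            f"niet passend bij dupuytren, {side} hand soepel",
        ]
    out += [
        "handklachten, geen dupuytren palpabel",
        "onderzoek: geen tekenen van dupuytren",
        "bij palpatie niet verdacht voor dupuytren",
    ]
    return out


def _family_nl() -> list[str]:
    return [
        "vader had dupuytren, zelf geen klachten",
        "familieanamnese: moeder ziekte van Dupuytren",
        "broer bekend met dupuytren, patient bezorgd",
        "in familie komt dupuytren voor, vraag over erfelijkheid",
        "zus heeft dupuytren, ter geruststelling onderzocht",
    ]


def _distractor_nl() -> list[str]:
    return [
        "lab in duplo bepaald, uitslag volgt",
        "duplex onderzoek beide benen aangevraagd",
        "duplicaat recept verstrekt",
        "CRP in duplo gecontroleerd wegens twijfel",
        "duplexscan carotiden: geen stenose",
    ]


def _unrelated_nl() -> list[str]:
    return [
        "hoesten sinds drie dagen, auscultatie schoon",
        "controle bloeddruk, 135/85, beleid ongewijzigd",
        "rugpijn na tillen, advies en paracetamol",
        "migraine aanval, triptaan herhaald",
        "enkeldistorsie, RICE advies",
        "keelpijn, geen koorts, expectatief",
        "herhaalrecept omeprazol",
        "moeheid, lab aangevraagd",
        "eczeem elleboogplooien, hydrocortison",
        "vaccinatie influenza gegeven",
    ]


def _positive_en() -> list[str]:
    out = []
    for side in _SIDES_EN:
        out += [
            f"Dupuytren disease {side} hand, palmar nodule",
            f"early dupuytren {side} hand, discussed management",
            f"dupuytren contracture {side}, referral hand surgeon",
        ]
    for d in _DIGITS:
        out.append(f"flexion contracture digit {d} due to Dupuytren")
    out += [
        "review of Dupuytren, stable appearance",
        "palmar nodule consistent with dupuytren; watchful waiting",
    ]
    return out


def _negated_en() -> list[str]:
    return [
        "no evidence of Dupuytren left hand",
        "not consistent with dupuytren, palm supple",
        "examination shows no dupuytren",
        "hand complaints without dupuytren features",
    ]


def _family_en() -> list[str]:
    return [
        "father had dupuytren, patient asymptomatic",
        "family history of Dupuytren discussed",
        "mother known with dupuytren, reassured",
        "brother has dupuytren, patient worried",
    ]


def _distractor_en() -> list[str]:
    return [
        "duplicate prescription issued",
        "duplex scan both legs requested",
        "bloods repeated in duplicate",
        "carotid duplex: no stenosis",
    ]


def _unrelated_en() -> list[str]:
    return [
        "cough for three days, chest clear",
        "blood pressure review 135/85, no change",
        "back pain after lifting, advice given",
        "migraine attack, triptan repeated",
        "sore throat, no fever, watchful waiting",
        "repeat prescription omeprazole",
        "fatigue, bloods requested",
    ]


_CORPORA = {
    "nl": {
        "positive": _positive_nl(),
        "negated": _negated_nl(),
        "family_history": _family_nl(),
        "distractor": _distractor_nl(),
        "unrelated": _unrelated_nl(),
    },
    "en": {
        "positive": _positive_en(),
        "negated": _negated_en(),
        "family_history": _family_en(),
        "distractor": _distractor_en(),
        "unrelated": _unrelated_en(),
    },
}

#: Generic note texts for comorbidity-coded contacts (never contain "dup").
COMORBIDITY_NOTES = {
    "nl": "controle chronische aandoening, beleid ongewijzigd",
    "en": "chronic condition review, no change in management",
}

#: ICPC codes drawn for 'unrelated' background contacts.
UNRELATED_ICPC = ("R05", "K86", "L03", "N01", "D84", "S87", "A04", "R74")


def note_templates(language: str = "nl") -> dict[str, list[str]]:
    """Return the template corpus for ``language`` (``"nl"`` or ``"en"``)."""
    try:
        return _CORPORA[language]
    except KeyError:
        raise ValueError(f"unknown template language {language!r}; use 'nl' or 'en'") from None
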