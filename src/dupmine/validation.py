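"""Three-step validation protocol for the DD text classifier.

Mirrors a double-rater validation design: (1) two raters score a random
5% sample of candidate contacts and their agreement is measured with
Cohen's kappa; (2) the rule-based classifier is adjusted — here, selected
from an ordered list of candidate rulesets — until its kappa against the
reference labels reaches a threshold; (3) the chosen ruleset is confirmed
once on a disjoint holdout sample, after which no further tuning is
permitted.  In simulation the reference labels are the generator's
ground-truth contact flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .textmine import RuleSet, label_contacts

__all__ = [
    "KappaResult",
    "cohens_kappa",
    "sample_contacts",
    "tune_rules",
    "holdout_validate",
    "ValidationProtocol",
    "ProtocolViolation",
]


class ProtocolViolation(RuntimeError):
    """The tuning/holdout discipline was broken (overlap or re-tuning)."""


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its 2x2 confusion table and agreement terms."""

    n11: int  # both positive
    n10: int  # A only
    n01: int  # B only
    n00: int  # both negative
    p_o: float
    p_e: float
    kappa: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Chance-corrected agreement between two binary label sequences.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_e`` from the marginal
    products; when both raters agree perfectly on a constant sequence
    (``p_e = 1``), kappa is 1 by convention and flagged degenerate.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labels_a and labels_b must be equal-length 1-d sequences")
    n = a.size
    if n < 1:
        raise ValueError("label sequences must have length >= 1")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    p_o = (n11 + n00) / n
    pa1, pb1 = (n11 + n10) / n, (n11 + n01) / n
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e == 1.0:
        return KappaResult(n11, n10, n01, n00, p_o, p_e, 1.0 if p_o == 1.0 else 0.0,
                           degenerate=True)
    kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(n11, n10, n01, n00, p_o, p_e, kappa)


def sample_contacts(candidate_ids, fraction: float, seed: int, exclude=()) -> list:
    """Simple random sample (without replacement) of candidate contact ids.

    Size is ``round(fraction * N)`` with ``N`` the total number of
    candidates, at least 1; the sample is disjoint from ``exclude``;
    deterministic given ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(candidate_ids)
    n_total = len(ids)
    pool = [i for i in ids if i not in set(exclude)]
    size = max(1, round(fraction * n_total))
    if not pool:
        raise ValueError("no candidates left to sample after exclusions")
    if size > len(pool):
        raise ValueError(
            f"sample of {size} requested but only {len(pool)} candidates remain"
        )
    rng = np.random.default_rng(seed)
    return list(np.asarray(pool, dtype=object)[rng.permutation(len(pool))[:size]])


def _algorithm_labels(contacts: pd.DataFrame, ruleset: RuleSet) -> pd.Series:
    labels = label_contacts(contacts, ruleset, mode="code_and_text")
    return labels.set_index("contact_id")["is_dd"]


def _reference_series(reference_labels) -> pd.Series:
    if isinstance(reference_labels, pd.DataFrame):
        return reference_labels.set_index("contact_id")["true_dd_contact"]
    return pd.Series(reference_labels)


def tune_rules(
    candidate_rulesets: list[RuleSet],
    tuning_sample: pd.DataFrame,
    reference_labels,
    threshold: float = 0.95,
) -> tuple[RuleSet, pd.DataFrame, bool]:
    """Evaluate rulesets in order until one reaches ``threshold`` kappa.

    Returns ``(chosen, trail, reached)``; when no ruleset reaches the
    threshold the argmax is returned with ``reached=False``.  ``trail``
    has one row per evaluated ruleset (id, kappa, p_o, p_e, n).
    """
    if not candidate_rulesets:
        raise ValueError("candidate_rulesets must be non-empty")
    if len(tuning_sample) == 0:
        raise ValueError("tuning sample is empty")
    ref = _reference_series(reference_labels)
    ref_sample = ref.loc[tuning_sample["contact_id"]]
    rows, results = [], []
    for rs in candidate_rulesets:
        alg = _algorithm_labels(tuning_sample, rs).reindex(ref_sample.index, fill_value=False)
        res = cohens_kappa(alg.to_numpy(), ref_sample.to_numpy())
        rows.append(dict(ruleset=rs.name, kappa=res.kappa, p_o=res.p_o, p_e=res.p_e, n=res.n))
        results.append(res)
        if res.kappa >= threshold:
            return rs, pd.DataFrame(rows), True
    best = int(np.argmax([r.kappa for r in results]))
    return candidate_rulesets[best], pd.DataFrame(rows), False


def holdout_validate(
    ruleset: RuleSet,
    holdout_sample: pd.DataFrame,
    reference_labels,
    tuning_ids=(),
) -> KappaResult:
    """Single confirmatory kappa on an untouched holdout sample.

    Raises :class:`ProtocolViolation` if the holdout overlaps the tuning
    sample.
    """
    overlap = set(holdout_sample["contact_id"]) & set(tuning_ids)
    if overlap:
        raise ProtocolViolation(
            f"holdout sample overlaps tuning sample ({len(overlap)} contacts)"
        )
    ref = _reference_series(reference_labels).loc[holdout_sample["contact_id"]]
    alg = _algorithm_labels(holdout_sample, ruleset).reindex(ref.index, fill_value=False)
    return cohens_kappa(alg.to_numpy(), ref.to_numpy())


@dataclass
class ValidationProtocol:
    """Stateful driver enforcing the tuning-then-holdout discipline."""

    tuning_fraction: float = 0.05
    holdout_fraction: float = 0.025
    threshold: float = 0.95
    seed: int = 0
    tuning_ids: list = field(default_factory=list)
    holdout_done: bool = False
    trail: pd.DataFrame | None = None
    chosen: RuleSet | None = None
    reached_threshold: bool = False
    holdout_result: KappaResult | None = None

    def __post_init__(self):
        for name in ("tuning_fraction", "holdout_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def run_tuning(self, candidates: pd.DataFrame, reference_labels, rulesets) -> RuleSet:
        if self.holdout_done:
            raise ProtocolViolation("tuning after holdout validation is not permitted")
        self.tuning_ids = sample_contacts(
            candidates["contact_id"], self.tuning_fraction, self.seed
        )
        sample = candidates.loc[candidates["contact_id"].isin(self.tuning_ids)]
        self.chosen, self.trail, self.reached_threshold = tune_rules(
            rulesets, sample, reference_labels, self.threshold
        )
        return self.chosen

    def run_holdout(self, candidates: pd.DataFrame, reference_labels) -> KappaResult:
        if self.chosen is None:
            raise ProtocolViolation("run_tuning must precede run_holdout")
        if self.holdout_done:
            raise ProtocolViolation("holdout validation may run only once")
        holdout_ids = sample_contacts(
            candidates["contact_id"], self.holdout_fraction, self.seed + 1,
            exclude=self.tuning_ids,
        )
        sample = candidates.loc[candidates["contact_id"].isin(holdout_ids)]
        self.holdout_result = holdout_validate(
            self.chosen, sample, reference_labels, self.tuning_ids
        )
        self.holdout_done = True
        return self.holdout_result
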