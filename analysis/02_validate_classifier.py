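#!/usr/bin/env python
"""Three-step validation of the free-text Dupuytren classifier.

Mirrors the double-rater protocol: sample 5% of candidate contacts, tune
the ruleset (an ordered list from naive keyword matching to the full
negation/family-history/distractor rules) until agreement with the
reference labels reaches kappa 0.95, then confirm once on a disjoint 2.5%
holdout.  In simulation the reference labels are the generator's
ground-truth contact flags.  Writes results/02_validation_trail.csv.
"""

import os

from dupmine import generate_dataset, paper2021
from dupmine.textmine import candidate_rulesets, extract_candidates
from dupmine.validation import ValidationProtocol

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")


def main():
    ds = generate_dataset(paper2021(n_patients=200_000, seed=1))
    candidates = extract_candidates(ds.contacts)
    print(f"{len(candidates)} candidate contacts "
          f"(code L99.03 or 'dup' in the note) of {len(ds.contacts)} total")

    proto = ValidationProtocol(tuning_fraction=0.05, holdout_fraction=0.025,
                               threshold=0.95, seed=1)
    proto.run_tuning(candidates, ds.contact_truth, candidate_rulesets())
    res = proto.run_holdout(candidates, ds.contact_truth)

    os.makedirs(RESULTS, exist_ok=True)
    proto.trail.to_csv(os.path.join(RESULTS, "02_validation_trail.csv"), index=False)
    print("\ntuning trail (kappa against reference labels):")
    print(proto.trail.to_string(index=False))
    print(f"\nchosen ruleset: {proto.chosen.name}"
          f" (threshold {'reached' if proto.reached_threshold else 'NOT reached'})")
    print(f"holdout: kappa={res.kappa:.3f}, observed agreement={res.p_o:.3f}, n={res.n}")


if __name__ == "__main__":
    main()
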