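#!/usr/bin/env python
"""Code-based vs code+text case retrieval: how much do the codes miss?

Re-runs 2021 mid-year prevalence with the free-text branch disabled, so a
case needs at least one contact carrying ICPC L99.03.  Quantifies the
underestimation from relying on registration codes alone.  Writes
results/04_mode_comparison.csv.
"""

import os

import pandas as pd

from dupmine import generate_dataset, paper2021, run_pipeline

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")


def main():
    ds = generate_dataset(paper2021(n_patients=200_000, seed=1))
    rows = []
    case_sets = {}
    for mode in ("code_and_text", "code_only"):
        rep = run_pipeline(ds, years=[], mode=mode)
        r = rep.prevalence.iloc[0]
        case_sets[mode] = rep.case_ids
        rows.append(dict(mode=mode, cases=r["cases"], population=r["population"],
                         percent=round(r["percent"], 4),
                         ci_low=round(r["ci_low"], 4), ci_high=round(r["ci_high"], 4)))
    out = pd.DataFrame(rows)
    os.makedirs(RESULTS, exist_ok=True)
    out.to_csv(os.path.join(RESULTS, "04_mode_comparison.csv"), index=False)
    print(out.to_string(index=False))

    assert case_sets["code_only"] <= case_sets["code_and_text"]
    missed = len(case_sets["code_and_text"] - case_sets["code_only"])
    total = len(case_sets["code_and_text"])
    print(f"\ncode-only retrieval misses {missed} of {total} DD patients "
          f"({100 * missed / total:.1f}%): these are documented in free text only")


if __name__ == "__main__":
    main()
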