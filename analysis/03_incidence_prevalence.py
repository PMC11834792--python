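#!/usr/bin/env python
"""Incidence and prevalence of Dupuytren's disease in the synthetic registry.

Runs the full pipeline (eligibility filters, deduplication, rule-based
case ascertainment, yearly at-risk sub-cohorts, 2021 mid-year census) on
the 'paper2021' scenario, seed 1, and writes:

  results/03_incidence.csv        yearly rates/1000 py by sex (2017-2021)
  results/03_incidence_by_band.csv  yearly rates by age band
  results/03_prevalence.csv       2021 mid-year prevalence by sex and band
  results/03_standardized.csv     ESP2013 directly standardized prevalence
  results/03_descriptives.csv     Table-1-style case description
  results/figures/*.png           rate-by-year and prevalence-by-band plots
"""

import os

import pandas as pd

from dupmine import generate_dataset, paper2021, run_pipeline

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")
FIGURES = os.path.join(RESULTS, "figures")


def _plots(rep):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping figures")
        return
    os.makedirs(FIGURES, exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 4))
    for sex, marker in (("male", "o"), ("female", "s"), ("all", "^")):
        sub = rep.incidence[rep.incidence["sex"] == sex]
        ax.errorbar(sub["year"], sub["rate_per_1000"],
                    yerr=[sub["rate_per_1000"] - sub["ci_low"],
                          sub["ci_high"] - sub["rate_per_1000"]],
                    marker=marker, capsize=3, label=sex)
    ax.set_xlabel("year"); ax.set_ylabel("first DD presentations / 1000 py")
    ax.set_title("Incidence by year and sex"); ax.legend(); ax.set_ylim(bottom=0)
    fig.tight_layout(); fig.savefig(os.path.join(FIGURES, "incidence_by_year.png"), dpi=150)

    fig, ax = plt.subplots(figsize=(6, 4))
    prev = rep.prevalence
    bands = [b for b in prev["age_band"].unique() if b != "all"]
    for sex, marker in (("male", "o"), ("female", "s")):
        sub = prev[(prev["sex"] == sex) & (prev["age_band"] != "all")]
        ax.plot(range(len(sub)), sub["percent"], marker=marker, label=sex)
    ax.set_xticks(range(len(bands)), bands)
    ax.set_xlabel("age band"); ax.set_ylabel("2021 mid-year prevalence (%)")
    ax.set_title("Prevalence by age band and sex"); ax.legend()
    fig.tight_layout(); fig.savefig(os.path.join(FIGURES, "prevalence_by_band.png"), dpi=150)


def main():
    ds = generate_dataset(paper2021(n_patients=200_000, seed=1))
    rep = run_pipeline(ds, years=range(2017, 2022))

    os.makedirs(RESULTS, exist_ok=True)
    rep.incidence.round(4).to_csv(os.path.join(RESULTS, "03_incidence.csv"), index=False)
    rep.incidence_by_band.round(4).to_csv(
        os.path.join(RESULTS, "03_incidence_by_band.csv"), index=False)
    rep.prevalence.round(4).to_csv(os.path.join(RESULTS, "03_prevalence.csv"), index=False)
    pd.DataFrame([rep.standardized.__dict__]).round(4).to_csv(
        os.path.join(RESULTS, "03_standardized.csv"), index=False)
    rep.descriptives.round(2).to_csv(os.path.join(RESULTS, "03_descriptives.csv"), index=False)

    print(f"patients after filtering and deduplication: {rep.n_patients}")
    print(f"DD patients identified: {len(rep.case_ids)}\n")
    print("incidence per 1000 person-years (all):")
    print(rep.incidence[rep.incidence["sex"] == "all"]
          .round(2)[["year", "events", "rate_per_1000", "ci_low", "ci_high"]]
          .to_string(index=False))
    overall = rep.prevalence.iloc[0]
    print(f"\n2021 mid-year prevalence: {overall['percent']:.2f}% "
          f"(95% CI {overall['ci_low']:.2f}-{overall['ci_high']:.2f}); "
          f"{overall['cases']} cases / {overall['population']} registered")
    for sex in ("male", "female"):
        r = rep.prevalence[(rep.prevalence["sex"] == sex)
                           & (rep.prevalence["age_band"] == "all")].iloc[0]
        print(f"  {sex}: {r['percent']:.2f}% ({r['ci_low']:.2f}-{r['ci_high']:.2f})")
    print(f"age-standardized (ESP2013): {rep.standardized.percent:.2f}% "
          f"({rep.standardized.ci_low:.2f}-{rep.standardized.ci_high:.2f})")

    _plots(rep)
    print(f"\ntables in {os.path.normpath(RESULTS)}")


if __name__ == "__main__":
    main()
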