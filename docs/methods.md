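# Methods and design notes

## Scope and shape

`dupmine` re-implements, as a tested pipeline, a registry analysis that
estimates the incidence and prevalence of Dupuytren's disease (DD) in
primary care from GP electronic health records: rule-based free-text case
ascertainment, dynamic-cohort person-years incidence, mid-year point
prevalence with exact intervals, and a Cohen's-kappa validation protocol.
Because registries of this kind are access-restricted, the package is
organised around a synthetic registry generator whose parameters are the
quantities the pipeline is supposed to estimate; recovery of those
parameters is the package's end-to-end correctness criterion.

## The synthetic registry (`synthetic_ehr`, `scenarios`)

**Population.** Patients carry a sex (P(male) = 0.49), an age drawn from
a banded adult age distribution referenced to 1 July of the last
simulated year (roughly Dutch adult demography), and a practice. Each of
12 practices onboards in 2015–2017 and supplies data from five years
before onboarding, so data windows open in 2010–2012 and the 2021
prevalence year has a >= 10-year run-in everywhere. 90% of patients are
registered from their practice's data start; 10% register later
(uniformly over the window), modelling population turnover, and a
constant deregistration hazard (1.2%/year) ends registration early
(moves, deaths). Open-ended registrations are stored as missing end
dates.

**Disease process.** The simulated event is the *first observable DD
presentation*: a discrete annual Bernoulli process with probability
`hazard(sex, age band) x care-seeking multiplier(year) x fraction of the
year registered`, running only inside the patient's registration window,
with the event date uniform within the registered part of the year.
Onset is identified with first presentation; pre-registration disease
history is deliberately not modelled, because the pipeline (like any
registry analysis) can only see in-window contacts, and simulating
unobservable history would make parameter recovery ill-posed rather than
more realistic. One known consequence carries over from real registry
studies: a "first" contact may in truth have been preceded by an
unobserved earlier one, which is exactly why the prevalence year keeps a
10-year run-in.

**Hazards.** The age shape (per 1000 person-years, unisex) rises from
0.06 (<40) through 0.9 / 2.1 / 3.5 to a 3.8 peak at 70–80, then declines
(2.6 at 80–90, 1.4 at 90+); male and female scale factors are 1.420 and
0.865. Care-seeking multipliers are 1.64 for 2010–2016, 1.0 for
2017–2019, 1.41/1.72 (≈0.82) for 2020 — the COVID access dip — and 0.85
for 2021. These constants were calibrated once, against the generator's
own configured targets, so that the *pipeline output* on the full-scale
scenario reproduces the headline estimates: 2021 mid-year prevalence
1.99% overall (2.50% male, 1.50% female), 2019 incidence 1.72/1000 py,
2020 incidence 1.41/1000 py. The pre-2017 multiplier is the free degree
of freedom that sets the cumulative caseload (prevalence) once the
2017–2019 hazards are pinned by the incidence targets. The male:female
scale ratio (~1.64) follows the prevalence split; the implied male
incidence is then slightly above what a ~1.55 incidence ratio would give
— the two published ratios are not jointly attainable with a single
sex-scale parameter, and the prevalence split was prioritised.

**Contacts and notes.** Each DD presentation produces a contact; later
registered years add follow-up DD contacts with probability 0.25/year.
Every DD contact carries ICPC L99.03 with probability 0.453 — calibrated
so that code-only retrieval finds 1.38/1.99 ≈ 69% of the combined
prevalence — and a positive free-text template. Background contacts
arrive at 0.15 per person-year with notes drawn from
negated (5%) / family-history (3%) / 'dup'-prefix distractor (12%) /
unrelated (80%) templates; comorbidity contacts carry standard ICPC-1
codes (T90 diabetes, P17 tobacco, P15 alcohol, T93 lipids, T82 obesity,
N88 epilepsy) at the published case prevalences, halved for non-cases.
Note templates are Dutch-flavoured parameterised strings (hand side,
digit, phrasing variants) with an English alias corpus selectable in
config; their structural guarantees (cue within four tokens before the
stem, no positive template for non-cases) are what the classifier keys
on. No note-length or contact-frequency statistics exist for the source
setting; the background rate and follow-up probability are invented,
plausible values and are documented as such.

**Duplicates.** 2% of patients are split into two pseudonym records at a
random interior cut date (half abutting, half overlapping by up to 90
days); contacts after the cut move to the new record; both records share
the secondary pseudonym and fee-record key. Contact totals are
conserved.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic clinical language (misspellings,
abbreviations such as "M. Dup.", ambiguous phrasing), rater-specific
disagreement structure, referral pathways, practice-level clustering,
age-dependent deregistration, and pre-window disease history. The
classifier's perfect holdout kappa on synthetic notes reflects the
templates' clean separability, not expected real-world performance; the
published protocol's achieved agreement (0.93–0.95) is the realistic
ceiling.

## Ingest rules (`ingest`)

Coding-error exclusions: missing registration start; registration start
before birth; deregistration after 31 December of the year following the
study end (impossible given the extraction date); age outside 18–105.
The age window is evaluated per analysis year — eligible if >= 18 on 1
July of the last contributed year and <= 105 on 1 July of the first —
since a dynamic cohort has no single natural reference date. Duplicate
records merge when they share a non-empty secondary pseudonym or fee key
*and* agree on birth date and sex; conflicting candidates are logged, not
merged. Merged intervals take the union when they overlap or abut (gap
<= 1 day), otherwise earliest-start/latest-end with a gap flag; the first
DD date after merging is the earliest across both records (the
conservative choice for incidence). Orphan contacts are flagged and
excluded from numerators and denominators. Filtering and deduplication
are idempotent and account for every input patient.

## Text mining (`textmine`)

Tokenization is lowercase alphanumeric word extraction (punctuation
insensitive), no stemming. Positive patterns match token spans by prefix
per token ("dupuytren" also matches "dupuytrense"); negation cues match
by token equality (prefix matching would make "no" swallow "nodus");
family-history cues match by prefix ("familie" covers
"familieanamnese"); both scopes look `negation_window` = 4 tokens before
the match. A matched stem that begins with a distractor stem is
discarded. An L99.03 code makes the contact a DD contact regardless of
the note: the case definition is a disjunction, and no code/text override
is part of it. The `RuleSet` is a YAML-serialisable config object so
alternative reconstructions are drop-in; `candidate_rulesets()` provides
the ordered naive → +negation → full list that the tuning protocol
selects from.

## Cohorts and person-time (`cohort`)

Person-time uses actual calendar day counts (inclusive), divided by the
actual days in the year, so a fully registered year is exactly 1.0 and
leap years are exact. Incident cases contribute time up to the diagnosis
date by default (`truncate_at_diagnosis=False` reproduces full-year
denominators; at ~2/1000 the difference is < 0.1% of the rate). Age for
stratification is computed on 1 July of the analysis year for both
incidence and prevalence, matching the mid-year denominator. Age bands
are half-open `[lower, upper)` decades (<40 … 90+) — the only partition
consistent with overlapping printed band labels — with an alternative
41–50 … 81–90/90+ scheme selectable for figure-style replication;
published band edges are internally inconsistent, so neither scheme is
asserted as "the" truth. The prevalence routine refuses years with fewer
than 10 years of data history unless explicitly overridden.

Two prevalence case definitions are implemented: `ever_diagnosed`
(default; first DD contact on or before 1 July of the prevalence year —
diagnosed status at the census date) and `contact_in_year` (a DD contact
during the calendar year). The generator calibration and all recovery
targets use `ever_diagnosed`; `contact_in_year` gives lower values by
construction since not every prevalent case consults in a given year.

## Estimators (`epi`)

Clopper–Pearson limits use the beta-quantile form of the exact binomial
tail inversion; Poisson (Garwood) limits use chi-square quantiles; both
are verified in the tests against brute-force tail-sum inversion by
bisection (1e-6) and, for the binomial, against
`statsmodels.proportion_confint(method="beta")`. Direct standardization
uses normalized standard weights over the decade bands — default ESP2013
collapsed onto those bands, fully overridable — with Fay–Feuer gamma
limits (the convention of the classical `ageadjust.direct` routine).
Note the collapsed <40 ESP weight includes ages 0–17 while the cohort is
adults only; the standardized figure is therefore a weighting convention,
not a population statement, and the standard is a config object.
Published stratified confidence intervals could not be reconciled with
any single obvious denominator, so the package asserts the correctness
of its own intervals against the tail-sum oracle rather than any printed
bounds. Median/IQR descriptives use linear interpolation between order
statistics (numpy default; R `quantile` type 7).

## Validation protocol (`validation`)

Cohen's kappa is computed from the 2×2 confusion table with chance
agreement from marginal products; `p_e = 1` with perfect agreement is
kappa 1 by convention, flagged degenerate. Sampling is simple random
without replacement at the candidate-contact level for both the 5%
tuning and the 2.5% holdout sample (the published step-3 sampling unit is
ambiguous; one unit keeps the disjointness constraint well-defined).
"Adjusting" the algorithm is modelled as ordered selection over an
explicit candidate-ruleset list, which makes the tuning trail
reproducible; the protocol object enforces tuning-before-holdout,
holdout-once, and no re-tuning afterwards. Ground-truth contact flags
stand in for the human raters' joint judgment; the manual double-rating
step itself is out of software scope, and rater-specific disagreement
(the published 0.93 was scored against a single rater) cannot be
reproduced from a single ground truth.

## Problem sizes and determinism

Full-scale runs use 200,000 patients over 2010–2021 (~365k contacts,
~10 s per replicate); the acceptance script averages 20 replicates and
the test suite's recovery checks reuse the same configuration, with
single-seed assertions at 3 Monte-Carlo standard errors (computed from
the realized counts) and a 20-seed mean-bias assertion at 1 per-seed
standard deviation. All randomness flows through
`numpy.random.default_rng([seed, stream])` with a distinct stream per
generator stage, so every stage is independently deterministic given the
scenario seed, and identical (config, seed) pairs produce byte-identical
datasets.

## Known limitations

* The text classifier is exact on the template corpus; its rule classes
  (negation, family history, distractors) are a reconstruction of a
  described behaviour, not published rules.
* The generator's hazards are *observable-presentation* hazards, not
  biological onset hazards; estimates of "incidence" inherit the
  care-seeking interpretation.
* Deduplication is deterministic key-based merging; probabilistic
  linkage is out of scope.
* Rates are raw yearly estimates; no trend or competing-risk modelling.
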