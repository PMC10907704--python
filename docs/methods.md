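# Methods

This note documents the statistical model behind `pvsignal`, the
conventions chosen where several were defensible, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Counting model

The unit of analysis is the deduplicated safety report (one CASEID).
Spontaneous-report databases carry several versions of a case (follow-ups
share the CASEID under new PRIMARYIDs); we keep, per CASEID, the version
with the maximal FDA_DT and break FDA_DT ties by the maximal PRIMARYID,
comparing numerically when both values parse as integers and
lexicographically otherwise.  The rule is idempotent and independent of
input row order, and every removal is written to an audit log.

Within a report, a preferred term contributes at most once per drug group
(set semantics), the standard disproportionality convention; report counts,
not mention counts, fill the 2×2 tables.  Exposure to a drug group requires
at least one suspect-role mention (ROLE_COD PS or SS) whose verbatim name
matched the synonym dictionary.  Reports naming a study drug only as
concomitant (C) or interacting (I) contribute no exposure to that group but
remain in the background — this is the "adjusted" disproportionality that
discounts co-medication: no further covariate adjustment is applied, since
a spontaneous-report 2×2 table supports none without a regression model,
which is out of scope.

The background for b and d is every deduplicated report supplied to the
pipeline, not just reports of the study drugs.  With a full-database
background the statistics match published full-FAERS analyses in kind;
with a restricted bundle they are interpretable only relative to that
bundle.

## Estimators

For a table (a, b, c, d), N = a+b+c+d:

- ROR = ad/bc with the Woolf interval
  exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)).  Any zero cell makes ROR and its
  CI non-estimable (reported as NaN), mirroring how such rows are printed
  as "–"; a 0.5 continuity-correction mode exists for sensitivity analysis
  but is off by default.
- PRR = (a/(a+c))/(b/(b+d)); non-estimable when b = 0 or a margin is
  empty.  χ² is the four-cell Pearson statistic with expecteds from the
  margins (E for the a-cell = (a+b)(a+c)/N), without Yates correction by
  default — the χ² ≥ 4 criterion descends from the uncorrected statistic —
  with Yates available behind a switch.
- IC = log₂[a·N/((a+c)(a+b))], the log ratio of observed to expected
  co-reporting.  The point estimate is computed by default with a + γ₁₁ in
  place of a so that a = 0 remains finite (disable `ic_smoothing` for the
  raw formula).  IC025 = E(IC) − 2√V(IC) from the closed-form posterior
  moments of the Beta/Dirichlet model with priors
  (γ₁₁, α₁, β₁, α, β) = (1, 1, 1, 2, 2), the classical choice that makes
  the prior expectation of IC zero on an empty database.  A Monte-Carlo
  posterior-quantile estimator (`ic025_method="monte_carlo"`) is provided
  for sensitivity analysis; at moderate counts it sits slightly below the
  moment-based bound because the posterior of IC is left-skewed.

Signal criteria: ROR — CI lower bound > 1 and a ≥ 2; PRR — PRR ≥ 2, χ² ≥ 4
and a ≥ 3; BCPNN — IC025 > 0.  Non-estimable statistics never flag.
Verified properties: IC025 ≤ IC everywhere; IC and IC025 are non-decreasing
in a at fixed margins; ROR is strictly increasing in d at fixed a, b, c.

## Time-to-onset

Onset is the day count from the start of suspect therapy to the event
date, emitted only when both dates are complete (8-digit) and the event
does not precede the start; negative intervals are logged and dropped,
and partial dates are excluded rather than imputed — imputation would
manufacture onsets in a field where date precision is already the weakest
link.  When a report carries several therapy rows for a group, the
earliest complete start date is used (a latest-start-before-event rule is
available for multi-course records).

Summaries report the median with quartiles by linear interpolation (Tukey
hinges behind a switch — the convention must be pinned for IQRs to be
auditable), the arithmetic mean of days, and the pooled mean rank.  Both
mean flavours are emitted because report tables in this field label a
"Mean" column as a rank average; the mean rank is also the quantity the
rank tests actually compare.  Two eligible groups are compared with the
Mann–Whitney U test (normal approximation with tie and continuity
correction); three or more with Kruskal–Wallis; groups with fewer than
`min_onset_n` (default 2) records are excluded first, and with fewer than
two eligible groups the comparison is marked not performed.  Significance
is two-sided at 0.05 with no multiplicity adjustment across PTs.

## Outcomes and characteristics

Outcome codes (DE, DS, HO, LT, RI, CA, OT) are counted once per report per
category; percentages use the group's total report count as denominator,
and reports with no outcome row are tallied as "unknown".  Between-group
comparisons test each category-vs-rest 2×2 with Pearson's χ², falling back
to Fisher's exact test when any expected cell is below 5 (the textbook
threshold).

The descriptive table uses age bands <18 / 18–64 / ≥65 with both
boundary ages in the middle band, reporting-year bands 2004–2007 through
2020–2022, and AGE_COD conversions YR ×1, MON ÷12, DEC ×10, DY ÷365.25,
WK ÷52.18; hour-coded and unrecognized ages are treated as unknown
(WT_COD: KG ×1, LBS ×0.45359, GMS ÷1000).  Percentages are printed to two
decimals with half-up rounding and always recomputed from counts.

## Synthetic reporting model

The generator samples, per case: independent drug-group intake with the
configured marginal probabilities; a suspect/concomitant role per study
mention (demotion probability `concomitant_drug_rate`); and each
background PT with probability p tilted on the odds scale — an exposed
report's odds are multiplied by the planted θ of the (group, PT) pair, so
the true reporting odds ratio equals θ exactly and recovery assertions are
clean.  Onset days are log-normal (μ, σ) per pair; therapy start dates
anchor event dates so intervals are never negative by construction.  A
configurable fraction of cases is emitted as 2–3 DEMO versions with
increasing FDA_DT (30% of those with a tied FDA_DT, so the tie rule is
exercised); versions differ only in PRIMARYID/FDA_DT.  Dates are truncated
to month or year precision and demographics blanked at configured rates.
Closed-form expected contingency cells are available for every pair by
enumeration over intake patterns, including the demotion leak into the
background.

Default scale: 20,000 reports, exposure 8%/5%/3% for the three formulation
groups, baseline PT probabilities 0.2–3%, duplication 20%, partial dates
20%, missing demographics 30%, concomitant demotion 10%, receipt years
2004–2022 — chosen to mimic the density of an oncology drug-cohort extract
at a size where planted signal cells reach double digits.  A documented
toy quarter (200 cases, 3 groups, 10 PTs, seed 42) is checked into
`tests/data/synthetic_toy_quarter` with frozen golden outputs.

What the generator does **not** emulate: correlated co-reporting between
PTs, the MedDRA hierarchy beyond a flat PT→SOC lookup, drug-name
misspellings and free text, masking/competition between signals, secular
reporting trends, and country- or reporter-dependent reporting behaviour.
Passing recovery tests therefore demonstrates correctness of the
estimators and plumbing under the stated sampling model, not robustness to
those real-data pathologies.

## Validation problem sizes

The validation suite compares the vectorized estimators with independent
longhand evaluation over all 6.25 million tables with cells in [1, 50]
(tolerance 1e-10 relative), checks flag logic on 10,000 random tables,
recovers planted θ ∈ {1, 2, 4, 8} within 15% in the median over 200
cohorts of 20,000 reports (null ROR flag rate ≤ 10%), calibrates the
Mann–Whitney comparison over 1,000 null simulations (type-I error within
[0.03, 0.07]) with U checked against exhaustive pairwise enumeration, and
verifies deduplication against a brute-force survivor rule on bundles with
30% planted duplication.  `scripts/acceptance.py` reruns all of this from
one seed.

## Known limitations

- Only the modern (2012+) FAERS ASCII layout is supported, in a single
  encoding (Latin-1 by default); the XML dialect and the legacy pre-2012
  column layout are out of scope.
- Duplicate detection is exactly the CASEID rule; probabilistic record
  linkage across CASEIDs is not attempted.
- One caveat of the dialect: FAERS does not escape the `$` delimiter, so
  an embedded dollar sign in free text genuinely splits a field; the
  writer refuses values that could not round-trip.
- Disproportionality measures association in a reporting stream, not
  incidence or risk; no causal reading is implied, and no shrinkage
  regression (extended ROR with covariates) or MGPS/EBGM estimator is
  included.
- Table-1-style denominators depend on which subset of reports a study
  describes; this package uses one convention throughout — the
  deduplicated report count of the analyzed bundle.
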