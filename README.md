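# pvsignal

Disproportionality signal detection for spontaneous adverse-event reports
in the FDA Adverse Event Reporting System (FAERS) quarterly ASCII format.

Pharmacovigilance teams screen spontaneous-report databases for drug–event
pairs that are reported more often than the rest of the database predicts.
`pvsignal` implements that desk workflow end to end for FAERS-style data —
from the raw dollar-delimited quarterly files to the four tables such a
study reports — and ships a synthetic FAERS-style data generator with
planted ground truth, so every stage is testable without downloading and
redistributing FAERS itself.

The package was built around a three-group oncology use case (conventional
doxorubicin vs. the pegylated and non-pegylated liposomal formulations),
but the drug groups, event lists and dictionaries are all configuration.

## What it computes

For a drug group and a MedDRA preferred term (PT), the database collapses
to a 2×2 table of deduplicated report counts:

|              | event  | other events |
|--------------|--------|--------------|
| drug         | a      | c            |
| other drugs  | b      | d            |

with N = a+b+c+d.  Three classical signal statistics are computed:

- **ROR** (reporting odds ratio): `ROR = (a/b)/(c/d)`, 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`; signal when the CI lower bound
  exceeds 1 and a ≥ 2.
- **PRR** (proportional reporting ratio): `PRR = (a/(a+c))/(b/(b+d))` with
  the four-cell Pearson χ² = Σ(O−E)²/E; signal when PRR ≥ 2, χ² ≥ 4 and
  a ≥ 3.
- **BCPNN information component**: `IC = log₂[a·N/((a+c)(a+b))]`, with
  IC025 the lower 95% credibility bound from the closed-form Beta/Dirichlet
  posterior moments (E(IC) − 2√V(IC)); signal when IC025 > 0.

Around the statistics sit the standard preprocessing and comparison steps:

- **Deduplication**: one report per CASEID — the version with the latest
  FDA_DT, ties broken by the larger PRIMARYID; every removal is logged.
- **Drug-name normalization**: verbatim DRUGNAME text matched against a
  synonym dictionary (generic/brand names, abbreviations) with dosage-form
  suffix stripping and longest-synonym-wins containment; exposure is
  restricted to suspect roles (PS/SS) — concomitant/interacting mentions
  stay in the background.
- **Time-to-onset**: days from suspect-therapy start to event date
  (complete dates only), compared across groups with Mann–Whitney U
  (two groups) or Kruskal–Wallis H (three or more).
- **Outcomes**: per-group seriousness-outcome counts and percentages,
  compared with Pearson's χ² or Fisher's exact test when expected counts
  fall below 5.
- **Synthetic data**: a generator that plants drug–event signals on the
  odds scale (so the true ROR of a pair equals the planted multiplier θ),
  duplicate case versions, log-normal onset distributions, partial dates
  and missing demographics — plus closed-form expected contingency cells
  for validation.

## Worked example

```python
from pvsignal import ContingencyTable, compute_ror, compute_prr, compute_ic

t = ContingencyTable(a=10, b=20, c=30, d=240)
print(compute_ror(t))   # (4.0, 1.7119, 9.3463)
print(compute_prr(t))   # (3.25, 11.5385)
print(compute_ic(t))    # (1.4594, 0.0150)
```

The event is reported with the drug four times more often than the
background odds predict (ROR 4.0, 95% CI 1.71–9.35); PRR 3.25 with χ²
11.54 clears the PRR criterion, and the shrinkage-based IC025 of 0.015
sits just above zero — a signal by all three algorithms.  The same numbers
are available from the shell:

```bash
pvsignal stats --table 10,20,30,240
```

Longer narratives live in `examples/`: single-table statistics, synthetic
quarter generation, signal screening, onset/outcome comparison, and a full
pipeline run.  A complete run is one call (or `pvsignal run`):

```python
from pvsignal import RunConfig, run
result = run(RunConfig(input_dir="tests/data/synthetic_toy_quarter",
                       dict_path="tests/data/doxorubicin_synonyms.tsv",
                       out_dir="report"))
```

which writes `characteristics.csv`, `signals.csv`, `onset.csv`,
`outcomes.csv`, `outcome_tests.csv` and an audit trail (`audit.json`,
`removal_log.csv`, `dropped_onsets.csv`).  On the bundled 200-case toy
quarter this keeps 200 of 262 DEMO rows after deduplication and flags the
planted pairs (e.g. DOXIL / palmar-plantar erythrodysaesthesia, ROR 23.0
at a = 14).

## Layout

- `src/pvsignal/faers_io.py` — dollar-delimited FAERS dialect, partial dates
- `src/pvsignal/preprocess.py` — dedup, synonym matching, dataset assembly
- `src/pvsignal/signal_stats.py` — ROR / PRR / BCPNN and flags
- `src/pvsignal/onset_outcome.py` — time-to-onset, outcome comparisons
- `src/pvsignal/synthetic.py` — ground-truth generator
- `src/pvsignal/pipeline.py`, `cli.py` — orchestration and the `pvsignal` CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
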