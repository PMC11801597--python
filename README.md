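# pvsignal

Disproportionality signal detection for spontaneous adverse-event reports.

`pvsignal` is a Python library (plus a thin `pv-signal` command line) for
pharmacovigilance analysts who work with FAERS-style quarterly extracts:
dollar-delimited DEMO/DRUG/REAC/OUTC/THER tables, case versioning, free-text
drug names, and MedDRA preferred terms.  It implements the complete workflow
behind a drug–event association study — here, drug-induced autoimmune-like
hepatitis (DI-ALH) — and ships a synthetic FAERS generator with planted
effects so every stage can be validated without downloading the database.

## What it computes

For each drug the database is collapsed to a 2×2 table against a target
preferred term:

|          | event | no event |
|----------|-------|----------|
| drug     | a     | b        |
| no drug  | c     | d        |

with N = a+b+c+d deduplicated reports, and four disproportionality
statistics are derived:

- **ROR** = (a/c)/(b/d), 95% CI `exp(ln ROR ± 1.96·SE)`,
  `SE² = 1/a + 1/b + 1/c + 1/d`;
- **PRR** = [a/(a+b)]/[c/(c+d)], log-normal CI with
  `SE² = 1/a − 1/(a+b) + 1/c − 1/(c+d)`, plus the Yates-corrected χ²;
- **BCPNN information component** IC = log₂ of observed-over-expected
  reporting with Bayesian shrinkage: closed-form posterior E[IC] and V[IC]
  under the standard prior (γ₁₁ = α₁ = β₁ = 1, α = β = 2), signal bound
  IC025 = E[IC] − 2√V[IC];
- **EBGM** in its relative-reporting-ratio closed form aN/((a+b)(a+c)) with
  a log-normal interval (EBGM05, EBGM95).

A drug is a **consensus signal** when, with at least 3 co-reports, the lower
ROR and PRR confidence bounds exceed 1, IC025 > 0 and EBGM05 > 2.

Around the statistics the package provides: FAERS ingestion for both the
legacy (ISR-keyed) and modern (primaryid-keyed) layouts, case deduplication
(latest case version wins), dictionary-based drug-name normalization with
salt/dose/brand handling, a cohort profiler (sex/age/reporter/country/outcome
distributions, medians with quartiles, yearly counts), and a seeded synthetic
corpus generator with known ground truth.

## Worked example

Plant a tenfold event risk on one drug in a 20,000-report synthetic corpus
(with 10% duplicate case versions injected), write it as FAERS files, and
run the full pipeline (`examples/02_simulate_and_detect.py`):

```text
reports after dedup : 20000 (10% duplicate versions were injected and removed)
target-event reports: 154
drugs with >=3 cases: 33

top 5 by ROR:
    drug  a  ror  ror_lo  ror_hi  ic025  ebgm05  consensus
drug_100 45 8.29    5.82   11.81   1.92    4.16       True
drug_040  3 2.74    0.86    8.68  -0.58    0.84      False
drug_067  6 2.18    0.96    4.97  -0.27    0.93      False
drug_044  3 2.11    0.67    6.68  -0.78    0.65      False
drug_063  4 2.02    0.74    5.51  -0.60    0.73      False
```

The planted drug ranks first with 45 co-reports; its interval
(5.82, 11.81) covers the model-implied odds ratio of 10.47 (background event
rate 0.005 × relative risk 10 gives a 5% event rate among exposed reports),
and it is the only drug reaching four-method consensus — the null drugs
hover around ROR 1 and fail the criteria.  The other examples show the
closed-form statistics on a toy table, the cohort profiler, and the
classification of the bundled published top-50 DI-ALH reference table (all
50 drugs are consensus-positive under the standard thresholds).

Command-line equivalent:

```bash
pv-signal simulate --config sim.toml --out corpus/ --duplicate-rate 0.1
pv-signal run --config pipeline.toml --out report/
```

## Layout

- `src/pvsignal/` — `ingest`, `normalize`, `contingency`, `stats`,
  `cohort`, `simulate`, `pipeline`, `cli`
- `src/pvsignal/data/` — bundled drug dictionary and published DI-ALH
  reference tables
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, conventions, numerical choices, limitations
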