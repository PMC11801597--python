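# Methods

This note documents the models, conventions and numerical choices behind
`pvsignal`, in the order the pipeline applies them, together with what the
synthetic-data studies do and do not demonstrate.

## Data model and ingestion

FAERS quarterly extracts are dollar-delimited text tables with a header
row.  Two layout eras are supported: the legacy ISR-keyed layout (through
2012Q3; the ISR becomes the report key, `case_version` is 0) and the modern
primaryid-keyed layout.  Parsing never drops a row for a malformed value:

- **Dates** come in 4/6/8-digit forms (YYYY, YYYYMM, YYYYMMDD).  Partial
  dates resolve to the first day of the stated period; impossible dates
  become missing.
- **Ages** convert to years by unit code — DEC×10, YR×1, MON÷12, WK÷52,
  DY÷365.25, HR÷8766 — and values outside [0, 120] years are set to
  missing, because FAERS contains implausible entries that would poison
  medians.
- **Weights** are normalized to kg (LBS×0.453592, GMS÷1000).
- Outcome codes fold into a per-report *set* of outcome labels; therapy
  start dates join onto drug mentions by (report, drug sequence).

**Deduplication.** FAERS re-publishes a case whenever it is amended.  One
row per `caseid` is kept: the largest `(case_version, fda_receipt_date,
primaryid)` key, with primaryids compared numerically when both parse as
integers.  This mirrors standard FDA guidance; the operation is idempotent
and order-independent.

**Event cohort.** Reports listing the target MedDRA preferred term are
selected by exact match after case folding and whitespace normalization.
No MedDRA hierarchy traversal is attempted; the PT string is an opaque
label.

## Drug-name normalization

Free-text drug strings are mapped to canonical ingredient labels by a
curated dictionary: queries and patterns are case-folded, punctuation is
collapsed (slashes preserved, so combination products such as
amoxicillin/clavulanic acid stay one label), and dose, formulation and
salt tokens are stripped before an exact lookup.  Brand and generic forms
collapse to one ingredient.  Unresolved strings are tagged, counted in a
coverage report, and excluded from contingency tables — never silently
dropped.  This dictionary approach is transparent and auditable; it does
not attempt spelling correction or fuzzy matching, so coverage on raw
real-world data depends on the dictionary supplied.  The bundled
dictionary covers the 50 drugs of the reference DI-ALH signal table plus
common synonyms.

## Contingency tables

Counting is report-level: a report with five mentions of one drug counts
once for that drug; a report listing k distinct drugs contributes to k
tables.  By default only suspect roles (PS, SS) are counted — the
concomitant/interacting roles are configurable — and the comparator is the
whole deduplicated database in the window, so a+b+c+d = N for every drug.
Drugs with fewer than 3 co-reports are dropped before statistics (the
conventional minimum; configurable).  No stratification is applied: the
statistics are crude, as is standard for first-pass signal detection.

## The four statistics

Formulas as in the README.  Numerical conventions:

- z = 1.96 for all 95% intervals; intervals are computed on the log scale.
- **χ²** uses the Yates continuity correction
  N(|ad−bc|−N/2)²/((a+b)(c+d)(a+c)(b+d)), floored at 0 when |ad−bc| ≤ N/2.
- **Zero cells** make the ratio statistics undefined; the default is an
  explicit error naming the offending cell.  An optional Haldane–Anscombe
  correction (+0.5 to all four cells) can be enabled; the a ≥ 3 floor means
  the default pipeline never hits this case for a, though b or c can in
  principle be 0 in tiny databases.
- **BCPNN** uses the closed-form posterior moments of the information
  component under the standard prior γ₁₁ = α₁ = β₁ = 1, α = β = 2 (which
  makes E[IC] exactly 0 for a perfectly balanced table) and the
  two-standard-deviation bound IC025 = E[IC] − 2√V[IC], not Monte-Carlo
  posterior quantiles.  Shrinkage pulls IC toward 0 in the sparse regime
  the method targets (drug and event margins small relative to N).  Note
  that |E[IC]| ≤ |IC_raw| is *not* a theorem: for tables whose margins are
  comparable to N the prior can push the posterior slightly past the raw
  value (worst observed excess ≈0.006 in the sparse regime, larger for
  dense tables), and the property tests are scoped accordingly.
- **EBGM** is implemented in its relative-reporting-ratio closed form with
  a log-normal interval.  This is the form conventionally tabulated next to
  ROR/PRR/IC in signal-detection studies; a full MGPS gamma-mixture
  empirical-Bayes fit is deliberately out of scope, so for very small
  counts this EBGM shrinks less than MGPS would.
- **Monotonicity caveat.** ROR and PRR increase strictly in a (b, c, d
  fixed); the relative reporting ratio aN/((a+b)(a+c)) — and hence raw IC
  and EBGM — does so only while bc > a², which always holds in the sparse
  surveillance regime but fails when one drug dominates the event margin.
- No multiple-testing correction is applied, matching standard
  disproportionality practice; the consensus-of-four rule is the only
  guard against spurious flags.

**Signal rules.** All inequalities are strict.  The PRR criterion defaults
to "lower 95% bound > 1" with the classical "PRR > 2 and χ² > 4"
selectable.  Report-facing tables are rounded half-up at 2 decimals;
internal computation is full precision.

## Cohort profiler

Single-valued variables (sex, age stratum, reporter occupation, country)
use the report count as denominator and carry an explicit "unknown" level,
so their percentages sum to ~100.  Outcomes are multi-valued per report,
so outcome percentages use the total number of outcome entries as
denominator.  Age strata are left-closed/right-open ([19,45), [45,65), …;
a 45-year-old falls in 45–65), a documented choice where published strata
labels are ambiguous.  Medians and quartiles use linear-interpolation
(type-7) quantiles by default — the convention of most statistical
software — with the inverse-CDF method selectable.  The top five reporting
countries are kept verbatim and all others grouped as "other".  Time to
onset is event date minus the earliest suspect-drug therapy start;
negative values and latencies over 20 years are treated as data errors and
set to missing.

## Synthetic corpus generator

The generator emulates the joint structure of spontaneous reports, not
their full epidemiology.  Per report: each catalog drug is present
independently with its marginal probability (default catalog: 100 drugs,
probabilities log-spaced 0.002–0.05); the target event occurs with
probability `background_rate · λ`, where λ is the maximum planted relative
risk among the drugs present (max, not product, keeps λ interpretable as a
per-drug risk ratio); demographics, outcomes, countries and dates are
drawn independently from category distributions resembling a hepatic-event
reporting cohort.  Defaults: 200,000 reports, background rate 0.005,
window 2004Q1–2024Q1.  Everything derives from one seeded generator;
file output is byte-identical across reruns.

Because exposure and event are Bernoulli, each planted drug has an exact
implied 2×2 structure.  The truth table records λ, the implied odds ratio
(pe/(1−pe))/(p0/(1−p0)) with pe = background·λ, expected cells, and the
exactly tallied cells of the realized draw.  With background 0.005 and
λ = 10 the implied odds ratio is 10.47, not 10 — the rare-event
approximation identifies the two only as the exposed event rate → 0 — so
recovery is assessed against the implied odds ratio, the generator's exact
estimand.  (Expected cells and implied odds ratios treat planted drugs as
non-co-occurring; with independently drawn rare drugs the co-occurrence
correction is second-order.)

Duplicate injection re-emits a chosen fraction of cases as an amended
version (incremented `case_version`, fresh primaryid, same fields),
exercising the deduplication path with a known post-dedup count.

A cell-level fast path (`simulate_tables`) draws exposure and event under
the identical model and tallies the 2×2 cells directly, skipping
demographics and file I/O; Monte-Carlo studies use it so that dozens of
200,000-report corpora run in seconds, while the end-to-end checks use the
full file-writing path at 20,000 reports.

**What the synthetic studies do and do not show.**  They validate the
statistical machinery: interval coverage at nominal level (95%-CI coverage
of the implied odds ratio is ~95%, tested as ≥90% over 50 corpora), null
calibration (with no planted effects the lower-CI>1 ROR rule is
asymptotically a one-sided 2.5% test; among drugs passing the a ≥ 3 floor
the observed flag rate is ~3%, the Wald-type log interval being mildly
anti-conservative at single-digit co-report counts — exactly zero flags at
a ≤ 5, where discreteness keeps the bound below 1, and ~4–5% at a around
10–20), and exact agreement between generator tallies and pipeline cells
through ingestion, deduplication and normalization.  They do not model
reporting trends over time, stimulated reporting, masking by competing
signals, duplicate reports with conflicting fields, or free-text noise
beyond simple dose/salt decorations — so passing them demonstrates
correctness of the pipeline, not robustness to every pathology of real
spontaneous data.

## Reference tables

Two small published reference tables for DI-ALH in FAERS (2004Q1–2024Q1)
ship with the package: the cohort characteristic counts (N = 5,723
reports; 8,018 outcome entries) and the top-50 signal table (statistics
only; the underlying b/c/d cells are not public).  They serve as desk
checks: the percentage arithmetic must reproduce the published 2-dp shares
exactly, and the four criteria must classify all 50 rows positive on every
method.  Reproducing the statistics themselves would require the full
FAERS corpus and is out of scope.

## Known limitations

- The dictionary normalizer resolves only what its dictionary covers; the
  published study used an NLP system (MedEx) whose exact behaviour is not
  reproduced.
- EBGM is the closed-form relative reporting ratio, not MGPS.
- IC025 is a moment approximation, not a posterior quantile.
- Crude (unstratified) statistics only.
- The legacy-layout reader harmonizes ISR-keyed files into the modern data
  model but cannot recover fields the legacy format never carried
  (case versions).
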