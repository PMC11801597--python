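"""Profile the target-event cohort of a synthetic corpus.

Builds the clinical-characteristics summary (sex, age strata, reporters,
countries, outcomes, medians with quartiles) and the yearly report series
for the reports listing the target preferred term.
"""

from pvsignal import SyntheticConfig, filter_event
from pvsignal.cohort import summarize, time_to_onset
from pvsignal.simulate import generate_frames

data = generate_frames(SyntheticConfig(n_reports=20_000, seed=7,
                                       planted_effects={"drug_100": 10.0}))
event_ids = filter_event(data.reactions, "autoimmune hepatitis")
cohort = data.reports[data.reports["primaryid"].isin(event_ids)]
tto = time_to_onset(cohort, data.mentions)

s = summarize(cohort, tto_days=tto)
print(f"event cohort: {s.n_reports} reports, "
      f"{s.n_outcome_entries} outcome entries")
print(f"median age   : {s.median_age:.2f} years "
      f"(Q1 {s.age_q1:.2f}, Q3 {s.age_q3:.2f})")
print(f"time to onset: {s.median_tto:.2f} days "
      f"(Q1 {s.tto_q1:.2f}, Q3 {s.tto_q3:.2f})")
print()
print("sex distribution (percent of cohort):")
print(s.sex.to_string(index=False))
print()
print("outcomes (percent of outcome entries, multi-valued per report):")
print(s.outcomes.to_string(index=False))
print()
print(f"reports span {s.yearly_counts['year'].min()}-"
      f"{s.yearly_counts['year'].max()}; counts sum to the cohort size "
      f"({int(s.yearly_counts['count'].sum())}).")
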