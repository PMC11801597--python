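"""Classify the published top-50 reference statistics with the four criteria.

The bundled reference table carries, for the 50 drugs most strongly
associated with drug-induced autoimmune-like hepatitis in FAERS, the
published ROR/PRR intervals, chi-square, IC025 and EBGM05.  Applying the
standard thresholds (lower ROR/PRR CI > 1 with >=3 cases, IC025 > 0,
EBGM05 > 2) should flag every row on every method.
"""

from pvsignal import Thresholds
from pvsignal.cohort import load_reference_cohort_counts, percent
from pvsignal.stats import classify_reference, load_reference_signals

ref = load_reference_signals()
flagged = classify_reference(ref, Thresholds())
print(f"reference drugs          : {len(flagged)}")
for col in ["ror_pos", "prr_pos", "bcpnn_pos", "ebgm_pos", "consensus"]:
    print(f"{col:<25}: {int(flagged[col].sum())}")
print()
print("strongest and weakest signals by ROR:")
cols = ["drug", "a", "ror", "ror_lo", "ic025", "ebgm05"]
print(flagged.nlargest(3, "ror")[cols].to_string(index=False))
print(flagged.nsmallest(2, "ror")[cols].to_string(index=False))
print()
counts = load_reference_cohort_counts().set_index(["variable", "level"])
us = counts.loc[("country", "United States")]
print(f"cohort arithmetic check: {int(us['count'])} of {int(us['denom'])} "
      f"reports from the United States = {percent(int(us['count']), int(us['denom']))}%")
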