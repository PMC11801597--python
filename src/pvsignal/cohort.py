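"""Descriptive profile of the event cohort.

Reproduces the usual clinical-characteristics table of a pharmacovigilance
study: sex / age-stratum / reporter-occupation / country / outcome counts
with percentages, medians with quartiles for age, weight and time to onset,
and the yearly report-count series.

Conventions (documented because published tables rarely state them):

* percentages are printed half-up at 2 decimals;
* single-valued variables (sex, reporter, country, age stratum) use the
  report count N as denominator and include an explicit "unknown" level,
  so each such table sums to N and to ~100%;
* outcomes are multi-valued per report, so outcome percentages use the
  total number of outcome entries as denominator;
* age strata are left-closed, right-open ([19, 45) etc.), the last stratum
  closed above by +inf;
* medians and quartiles are computed on non-missing values with
  linear-interpolation (type-7) quantiles by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import UndefinedResultError, round_half_up

DEFAULT_AGE_CUTS = (19.0, 45.0, 65.0, 75.0)
DEFAULT_TOP_COUNTRIES = 5
TTO_MAX_DAYS = 20 * 365.25  # onset latencies beyond 20 years are implausible

SUSPECT_ROLES = frozenset({"PS", "SS"})


def percent(count: int, denom: int) -> float:
    """100*count/denom, rounded half-up to 2 decimals."""
    if denom <= 0:
        raise UndefinedResultError("percentage denominator must be positive")
    if not 0 <= count <= denom:
        raise ValueError(f"count {count} outside [0, {denom}]")
    return round_half_up(100.0 * count / denom, 2)


@dataclass
class CohortSummary:
    """Category tables, distribution summaries and the yearly series."""

    n_reports: int
    sex: pd.DataFrame
    age: pd.DataFrame
    reporter: pd.DataFrame
    country: pd.DataFrame
    outcomes: pd.DataFrame
    n_outcome_entries: int
    median_age: float
    age_q1: float
    age_q3: float
    median_weight: float
    weight_q1: float
    weight_q3: float
    median_tto: float
    tto_q1: float
    tto_q3: float
    yearly_counts: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-form table mirroring the usual Table-of-characteristics."""
        blocks = []
        for name, tab in [("sex", self.sex), ("age", self.age),
                          ("reporter", self.reporter),
                          ("country", self.country),
                          ("outcome", self.outcomes)]:
            b = tab.copy()
            b.insert(0, "variable", name)
            blocks.append(b)
        cat = pd.concat(blocks, ignore_index=True)
        med = pd.DataFrame(
            {
                "variable": ["median_age", "median_weight", "median_tto"],
                "level": ["years", "kg", "days"],
                "count": [np.nan] * 3,
                "percent": [np.nan] * 3,
                "median": [self.median_age, self.median_weight, self.median_tto],
                "q1": [self.age_q1, self.weight_q1, self.tto_q1],
                "q3": [self.age_q3, self.weight_q3, self.tto_q3],
            }
        )
        return pd.concat([cat, med], ignore_index=True)


def _category_table(values: pd.Series, order: Sequence[str], denom: int
                    ) -> pd.DataFrame:
    counts = values.value_counts()
    levels = list(order) + [lv for lv in counts.index if lv not in order]
    rows = [(lv, int(counts.get(lv, 0))) for lv in levels]
    return pd.DataFrame(
        {
            "level": [lv for lv, _ in rows],
            "count": [n for _, n in rows],
            "percent": [percent(n, denom) for _, n in rows],
        }
    )


def _quartiles(values: pd.Series, method: str) -> tuple[float, float, float]:
    v = pd.to_numeric(values, errors="coerce").dropna().to_numpy(float)
    if v.size == 0:
        return (float("nan"),) * 3
    q1, med, q3 = np.percentile(v, [25, 50, 75], method=method)
    return (round_half_up(float(med), 2), round_half_up(float(q1), 2),
            round_half_up(float(q3), 2))


def age_strata(age_years: pd.Series, cuts: Sequence[float] = DEFAULT_AGE_CUTS
               ) -> pd.Series:
    """Assign left-closed age bins; missing ages map to 'unknown'."""
    cuts = list(cuts)
    labels = ([f"<{cuts[0]:g}"]
              + [f"{lo:g}~{hi:g}" for lo, hi in zip(cuts[:-1], cuts[1:])]
              + [f">={cuts[-1]:g}"])
    edges = [-np.inf] + cuts + [np.inf]
    binned = pd.cut(age_years, bins=edges, labels=labels, right=False)
    return binned.astype(object).where(age_years.notna(), "unknown")


def summarize(
    reports: pd.DataFrame,
    age_cuts: Sequence[float] = DEFAULT_AGE_CUTS,
    tto_days: pd.Series | None = None,
    top_countries: int = DEFAULT_TOP_COUNTRIES,
    quantile_method: str = "linear",
) -> CohortSummary:
    """Build the full cohort summary from deduplicated reports.

    ``tto_days`` is the per-report time-to-onset series from
    :func:`time_to_onset`; omitted, the time-to-onset block is missing.
    ``quantile_method`` is passed to numpy (``"linear"`` = type-7,
    ``"inverted_cdf"`` = type-1).
    """
    n = len(reports)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")

    sex = _category_table(reports["sex"], ["female", "male", "unknown"], n)

    strata = age_strata(reports["age_years"], age_cuts)
    stratum_order = [lv for lv in strata.dropna().unique()]
    cuts = list(age_cuts)
    canonical = ([f"<{cuts[0]:g}"]
                 + [f"{lo:g}~{hi:g}" for lo, hi in zip(cuts[:-1], cuts[1:])]
                 + [f">={cuts[-1]:g}", "unknown"])
    age = _category_table(strata, canonical, n)

    reporter = _category_table(
        reports["reporter_occupation"],
        ["Physician", "Other health-professional", "Consumer", "Pharmacist",
         "Lawyer", "Registered Nurse", "unknown"],
        n,
    )

    country_raw = reports["reporter_country"].astype(str)
    known = country_raw[country_raw != "unknown"]
    top = list(known.value_counts().head(top_countries).index)
    grouped = country_raw.where(country_raw.isin(top), "other")
    country = _category_table(grouped, top + ["other"], n)
    country = country.sort_values("count", ascending=False, kind="mergesort",
                                  ignore_index=True)

    entries = [(label,) for outs in reports["outcomes"] for label in outs]
    n_entries = len(entries)
    if n_entries:
        outcome_series = pd.Series([e[0] for e in entries])
        outcomes = _category_table(outcome_series, [], n_entries)
        outcomes = outcomes.sort_values("count", ascending=False,
                                        kind="mergesort", ignore_index=True)
    else:
        outcomes = pd.DataFrame(columns=["level", "count", "percent"])

    med_age, age_q1, age_q3 = _quartiles(reports["age_years"], quantile_method)
    med_wt, wt_q1, wt_q3 = _quartiles(reports["weight_kg"], quantile_method)
    if tto_days is not None:
        med_tto, tto_q1, tto_q3 = _quartiles(tto_days, quantile_method)
    else:
        med_tto = tto_q1 = tto_q3 = float("nan")

    years = reports["fda_receipt_date"].dt.year.dropna().astype(int)
    yearly = (years.value_counts().sort_index().rename_axis("year")
              .reset_index(name="count"))

    return CohortSummary(
        n_reports=n, sex=sex, age=age, reporter=reporter, country=country,
        outcomes=outcomes, n_outcome_entries=n_entries,
        median_age=med_age, age_q1=age_q1, age_q3=age_q3,
        median_weight=med_wt, weight_q1=wt_q1, weight_q3=wt_q3,
        median_tto=med_tto, tto_q1=tto_q1, tto_q3=tto_q3,
        yearly_counts=yearly,
    )


def time_to_onset(reports: pd.DataFrame, mentions: pd.DataFrame) -> pd.Series:
    """Days from earliest suspect-drug start to event onset, per report.

    Negative latencies (event before the drug) and latencies above 20 years
    are treated as data errors and set to missing.
    """
    suspects = mentions[
        mentions["role"].isin(SUSPECT_ROLES) & mentions["start_date"].notna()
    ]
    first_start = suspects.groupby("primaryid")["start_date"].min()
    ev = reports.set_index("primaryid")["event_date"]
    days = (ev - ev.index.map(first_start)).dt.days.astype(float)
    days[(days < 0) | (days > TTO_MAX_DAYS)] = np.nan
    days.name = "tto_days"
    return days


def write_summary(summary: CohortSummary, path: Path | str) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_yearly_counts(summary: CohortSummary, path: Path | str) -> None:
    summary.yearly_counts.to_csv(path, sep="\t", index=False, lineterminator="\n")


def plot_yearly(summary: CohortSummary, path: Path | str) -> None:
    """Bar chart of reports per year (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    ax.bar(summary.yearly_counts["year"], summary.yearly_counts["count"],
           color="#4878a8")
    ax.set_xlabel("year of FDA receipt")
    ax.set_ylabel("reports")
    ax.set_title("Target-event reports per year")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def load_reference_cohort_counts() -> pd.DataFrame:
    """Published reference cohort counts bundled with the package."""
    ref = resources.files("pvsignal.data") / "dialh_cohort_reference.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
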