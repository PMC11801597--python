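"""Per-drug 2x2 contingency tables for a target adverse event.

For each drug the four cells count deduplicated reports:

    a  reports mentioning the drug AND listing the target event
    b  reports mentioning the drug, without the event
    c  reports with the event, without the drug
    d  reports with neither

Counting is report-level: a report with five mentions of one drug counts
once for that drug, while a report listing k distinct drugs contributes to
k different tables.  The comparator is the whole deduplicated database in
the analysis window (a + b + c + d = N for every drug).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Collection, Set

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ROLES = frozenset({"PS", "SS"})

TABLE_COLUMNS = ["drug", "a", "b", "c", "d", "N"]


def build_tables(
    reports: pd.DataFrame,
    mentions: pd.DataFrame,
    event_ids: Set[str],
    roles: Collection[str] = DEFAULT_ROLES,
) -> pd.DataFrame:
    """Build one 2x2 table per canonical drug.

    Parameters
    ----------
    reports
        Deduplicated report table; its length is the denominator N.
    mentions
        Drug mentions carrying a ``normalized_name`` column; unresolved
        mentions (None) and mentions with excluded role codes are ignored.
    event_ids
        primaryids of reports listing the target preferred term.
    roles
        Role codes to count, default suspect drugs only ({PS, SS}).

    Returns
    -------
    DataFrame with columns drug, a, b, c, d, N, sorted by drug label.
    """
    if reports.empty:
        warnings.warn("no reports in scope; contingency output is empty", stacklevel=2)
        return pd.DataFrame(columns=TABLE_COLUMNS)

    report_ids = set(reports["primaryid"])
    n_total = len(report_ids)
    if n_total != len(reports):
        raise ValueError("reports are not deduplicated: primaryid not unique")
    event_in_scope = event_ids & report_ids
    n_event = len(event_in_scope)

    m = mentions[
        mentions["normalized_name"].notna()
        & mentions["role"].isin(set(roles))
        & mentions["primaryid"].isin(report_ids)
    ]
    # report-level: one row per (drug, report)
    m = m.drop_duplicates(["normalized_name", "primaryid"])

    if m.empty:
        warnings.warn("no qualifying drug mentions; contingency output is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=TABLE_COLUMNS)

    is_event = m["primaryid"].isin(event_in_scope)
    g = (
        pd.DataFrame({"drug": m["normalized_name"], "event": is_event})
        .groupby("drug", sort=True)["event"]
        .agg(["sum", "size"])
    )
    a = g["sum"].astype(int)
    ab = g["size"].astype(int)
    tables = pd.DataFrame(
        {
            "drug": g.index,
            "a": a.to_numpy(),
            "b": (ab - a).to_numpy(),
            "c": n_event - a.to_numpy(),
            "d": n_total - ab.to_numpy() - (n_event - a.to_numpy()),
            "N": n_total,
        }
    ).reset_index(drop=True)
    logger.info(
        "build_tables: %d drugs, N=%d reports, %d event reports",
        len(tables), n_total, n_event,
    )
    return tables


def min_case_filter(tables: pd.DataFrame, threshold: int = 3) -> pd.DataFrame:
    """Keep drugs with at least `threshold` co-reports (cell a).

    Disproportionality statistics on one or two co-reports are dominated by
    noise; the conventional floor, and the default here, is three.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    kept = tables[tables["a"] >= threshold].reset_index(drop=True)
    logger.info(
        "min_case_filter(a >= %d): removed %d of %d drugs",
        threshold, len(tables) - len(kept), len(tables),
    )
    return kept


def write_contingency(tables: pd.DataFrame, path: Path | str) -> None:
    tables[TABLE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_contingency(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing contingency columns {missing}")
    return df[TABLE_COLUMNS]
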