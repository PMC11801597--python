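"""Reading FAERS-style quarterly ASCII extracts into the internal data model.

FAERS quarterly extracts are dollar-sign-delimited text tables (DEMO, DRUG,
REAC, OUTC, THER) in two layout eras: the legacy ISR-keyed layout used up to
2012Q3 and the modern primaryid-keyed layout used from 2012Q4 on.  This module
parses either era into three tidy pandas DataFrames:

``reports``
    one row per case-report version: demographics, receipt/event dates,
    reporter occupation and country, and the (set-valued) outcome codes
    folded in from OUTC;
``mentions``
    one row per drug mention, with the FAERS role code (PS/SS/C/I) and the
    therapy start date folded in from THER;
``reactions``
    one row per (report, MedDRA preferred term) pair.

Dates come in 4-, 6- or 8-digit forms (YYYY / YYYYMM / YYYYMMDD); partial
dates resolve to the first day of the stated period and unparseable dates
become missing — rows are never dropped for a bad date.  Ages are converted
to years from the FAERS unit codes and implausible values (outside 0–120
years) are set to missing.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._util import SchemaError

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: multiplicative factor from FAERS age unit code to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
AGE_PLAUSIBLE_YEARS = (0.0, 120.0)

SEX_CODES = {"F": "female", "M": "male"}
OCCUPATION_CODES = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "HP": "Other health-professional",
    "CN": "Consumer",
    "LW": "Lawyer",
    "RN": "Registered Nurse",
}
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}
ROLE_CODES = ("PS", "SS", "C", "I")

# Mandatory raw columns per table for each layout era.  Optional columns are
# filled with missing values when absent.
LAYOUTS: dict[str, dict[str, dict[str, list[str]]]] = {
    "modern": {
        "demo": {
            "required": ["primaryid", "caseid", "fda_dt"],
            "optional": [
                "caseversion", "event_dt", "age", "age_cod", "sex",
                "wt", "wt_cod", "occp_cod", "reporter_country",
            ],
        },
        "drug": {
            "required": ["primaryid", "drugname", "role_cod"],
            "optional": ["drug_seq"],
        },
        "reac": {"required": ["primaryid", "pt"], "optional": []},
        "outc": {"required": ["primaryid", "outc_cod"], "optional": []},
        "ther": {
            "required": ["primaryid", "start_dt"],
            "optional": ["dsg_drug_seq"],
        },
    },
    "legacy": {
        "demo": {
            "required": ["isr", "case", "fda_dt"],
            "optional": [
                "event_dt", "age", "age_cod", "gndr_cod",
                "wt", "wt_cod", "occp_cod", "reporter_country",
            ],
        },
        "drug": {
            "required": ["isr", "drugname", "role_cod"],
            "optional": ["drug_seq"],
        },
        "reac": {"required": ["isr", "pt"], "optional": []},
        "outc": {"required": ["isr", "outc_cod"], "optional": []},
        "ther": {"required": ["isr", "start_dt"], "optional": ["drug_seq"]},
    },
}

REPORT_COLUMNS = [
    "primaryid", "caseid", "case_version", "fda_receipt_date", "event_date",
    "sex", "age_value", "age_unit", "age_years", "weight_kg",
    "reporter_occupation", "reporter_country", "outcomes",
]
MENTION_COLUMNS = [
    "primaryid", "drug_seq", "raw_name", "role", "start_date",
]
REACTION_COLUMNS = ["primaryid", "pt"]


class QuarterData(NamedTuple):
    """Parsed content of one FAERS quarter (or a concatenation of quarters)."""

    reports: pd.DataFrame
    mentions: pd.DataFrame
    reactions: pd.DataFrame


# ---------------------------------------------------------------------------
# low-level parsing

def parse_faers_dates(raw: pd.Series) -> pd.Series:
    """Parse FAERS 4/6/8-digit date strings to Timestamps.

    YYYY resolves to Jan 1, YYYYMM to the 1st of the month.  Anything else
    (including impossible calendar dates) becomes NaT.
    """
    s = raw.fillna("").astype(str).str.strip()
    s = s.where(s.str.fullmatch(r"\d{4}|\d{6}|\d{8}"), "")
    s = s.mask(s.str.len() == 4, s + "0101")
    s = s.mask(s.str.len() == 6, s + "01")
    out = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    n_bad = int((out.isna() & (raw.fillna("").astype(str).str.strip() != "")).sum())
    if n_bad:
        logger.info("date parsing: %d value(s) unparseable, set to missing", n_bad)
    return out


def age_to_years(value: float, unit: str | None) -> float:
    """Convert a FAERS (age, unit-code) pair to years.

    Unknown unit codes and values outside the plausible 0–120-year range
    yield NaN; FAERS contains implausible ages and these must not poison
    medians.
    """
    if value is None or value != value:
        return float("nan")
    factor = AGE_UNIT_TO_YEARS.get((unit or "").strip().upper())
    if factor is None:
        return float("nan")
    years = float(value) * factor
    lo, hi = AGE_PLAUSIBLE_YEARS
    if not (lo <= years <= hi):
        return float("nan")
    return years


def _read_delimited(path: Path, chunksize: int = 200_000) -> pd.DataFrame:
    """Stream a $-delimited table with a header row into one DataFrame.

    Reading is chunked so that a full multi-quarter load never requires the
    raw file in memory twice; chunks are accumulated because downstream
    operations need the whole (much smaller) parsed table.
    """
    chunks = []
    try:
        with pd.read_csv(
            path, sep=DELIMITER, dtype=str, chunksize=chunksize,
            keep_default_na=False, na_values=[""], engine="c",
        ) as reader:
            for chunk in reader:
                chunk.columns = [c.strip().lower() for c in chunk.columns]
                chunks.append(chunk)
    except pd.errors.EmptyDataError:
        pass
    if not chunks:
        warnings.warn(f"{path}: empty file, producing empty table", stacklevel=3)
        return pd.DataFrame()
    return pd.concat(chunks, ignore_index=True)


def _prepare(df: pd.DataFrame, table: str, layout: str) -> pd.DataFrame:
    schema = LAYOUTS[layout][table]
    for col in schema["required"]:
        if not df.empty and col not in df.columns:
            raise SchemaError(
                f"{table.upper()} table ({layout} layout) is missing mandatory "
                f"column '{col}'"
            )
    if df.empty:
        df = pd.DataFrame(columns=schema["required"] + schema["optional"])
    for col in schema["optional"]:
        if col not in df.columns:
            df[col] = pd.Series(pd.NA, index=df.index, dtype="object")
    return df


def _to_float(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s, errors="coerce")


# ---------------------------------------------------------------------------
# public reader

def read_quarter(
    paths: Mapping[str, Path | str],
    layout: str = "modern",
    chunksize: int = 200_000,
) -> QuarterData:
    """Read one quarter's DEMO/DRUG/REAC(/OUTC/THER) files.

    Parameters
    ----------
    paths
        Mapping with keys ``demo``, ``drug``, ``reac`` and optionally
        ``outc`` and ``ther``, each naming one $-delimited file.
    layout
        ``"modern"`` (primaryid-keyed, 2012Q4 on) or ``"legacy"``
        (ISR-keyed, up to 2012Q3).

    Returns
    -------
    QuarterData
        ``reports`` / ``mentions`` / ``reactions`` DataFrames.  Outcome codes
        are folded into ``reports.outcomes`` as frozensets of outcome labels
        and therapy start dates into ``mentions.start_date``.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected 'modern' or 'legacy'")
    for key in ("demo", "drug", "reac"):
        if key not in paths:
            raise SchemaError(f"paths mapping is missing the mandatory {key!r} table")

    raw = {
        key: _prepare(_read_delimited(Path(p), chunksize), key, layout)
        for key, p in paths.items()
        if key in LAYOUTS[layout]
    }
    demo = raw["demo"]

    if layout == "legacy":
        pid = demo["isr"].str.strip()
        caseid = demo["case"].str.strip()
        version = pd.Series(0, index=demo.index)
        sex_raw = demo["gndr_cod"]
    else:
        pid = demo["primaryid"].str.strip()
        caseid = demo["caseid"].str.strip()
        version = _to_float(demo["caseversion"]).fillna(0).astype(int)
        sex_raw = demo["sex"]

    age_value = _to_float(demo["age"])
    age_unit = demo["age_cod"].astype("string").str.strip().str.upper()
    age_years = np.array(
        [age_to_years(v, u if u is not pd.NA else None)
         for v, u in zip(age_value, age_unit)]
    )

    wt = _to_float(demo["wt"])
    wt_cod = demo["wt_cod"].astype("string").str.strip().str.upper().fillna("")
    weight_kg = np.where(
        wt_cod == "LBS", wt * 0.453592, np.where(wt_cod == "GMS", wt / 1000.0, wt)
    )
    weight_kg = np.where(weight_kg > 0, weight_kg, np.nan)

    occ = (
        demo["occp_cod"].astype("string").str.strip().str.upper()
        .map(OCCUPATION_CODES).fillna("unknown")
    )
    country = demo["reporter_country"].astype("string").str.strip()
    country = country.where(country.notna() & (country != ""), "unknown")

    outcomes = _fold_outcomes(raw.get("outc"), pid, layout)

    reports = pd.DataFrame(
        {
            "primaryid": pid,
            "caseid": caseid,
            "case_version": version,
            "fda_receipt_date": parse_faers_dates(demo["fda_dt"]),
            "event_date": parse_faers_dates(demo["event_dt"]),
            "sex": sex_raw.astype("string").str.strip().str.upper()
            .map(SEX_CODES).fillna("unknown"),
            "age_value": age_value,
            "age_unit": age_unit.where(age_unit.isin(AGE_UNIT_TO_YEARS), pd.NA),
            "age_years": age_years,
            "weight_kg": weight_kg,
            "reporter_occupation": occ,
            "reporter_country": country.astype(object),
            "outcomes": pid.map(outcomes).apply(
                lambda v: v if isinstance(v, frozenset) else frozenset()
            ),
        }
    )

    drug = raw["drug"]
    dpid = (drug["isr"] if layout == "legacy" else drug["primaryid"]).str.strip()
    role = drug["role_cod"].astype("string").str.strip().str.upper()
    seq_col = "drug_seq" if "drug_seq" in drug.columns else None
    mentions = pd.DataFrame(
        {
            "primaryid": dpid,
            "drug_seq": _to_float(drug[seq_col]) if seq_col else np.nan,
            "raw_name": drug["drugname"].astype(object),
            "role": role.where(role.isin(ROLE_CODES), pd.NA).astype(object),
            "start_date": pd.NaT,
        }
    )
    mentions = _fold_therapy(mentions, raw.get("ther"), layout)

    reac = raw["reac"]
    rpid = (reac["isr"] if layout == "legacy" else reac["primaryid"]).str.strip()
    reactions = pd.DataFrame({"primaryid": rpid, "pt": reac["pt"].astype(object)})
    reactions = reactions[reactions["pt"].notna() & (reactions["pt"].str.strip() != "")]
    reactions = reactions.drop_duplicates(ignore_index=True)

    logger.info(
        "read_quarter(%s): %d reports, %d drug mentions, %d reactions",
        layout, len(reports), len(mentions), len(reactions),
    )
    return QuarterData(reports, mentions, reactions.reset_index(drop=True))


def _fold_outcomes(outc: pd.DataFrame | None, pids: pd.Series, layout: str) -> dict:
    if outc is None or outc.empty:
        return {}
    key = "isr" if layout == "legacy" else "primaryid"
    codes = outc["outc_cod"].astype("string").str.strip().str.upper()
    labels = codes.map(OUTCOME_CODES)
    ok = labels.notna()
    grouped = (
        pd.DataFrame({"pid": outc[key].str.strip()[ok], "label": labels[ok]})
        .groupby("pid")["label"]
        .agg(frozenset)
    )
    return grouped.to_dict()


def _fold_therapy(
    mentions: pd.DataFrame, ther: pd.DataFrame | None, layout: str
) -> pd.DataFrame:
    if ther is None or ther.empty:
        return mentions
    key = "isr" if layout == "legacy" else "primaryid"
    seq_key = "drug_seq" if layout == "legacy" else "dsg_drug_seq"
    t = pd.DataFrame(
        {
            "primaryid": ther[key].str.strip(),
            "drug_seq": _to_float(ther[seq_key]) if seq_key in ther.columns else np.nan,
            "start_date": parse_faers_dates(ther["start_dt"]),
        }
    )
    # one therapy row per (report, drug_seq); keep the earliest start
    t = (
        t.dropna(subset=["start_date"])
        .sort_values("start_date")
        .drop_duplicates(["primaryid", "drug_seq"], keep="first")
    )
    merged = mentions.drop(columns="start_date").merge(
        t, on=["primaryid", "drug_seq"], how="left"
    )
    return merged[MENTION_COLUMNS]


# ---------------------------------------------------------------------------
# writing (round-trip support and synthetic-data output)

def write_quarter(data: QuarterData, outdir: Path | str, layout: str = "modern") -> dict:
    """Write parsed tables back to the FAERS $-delimited dialect.

    The inverse of :func:`read_quarter` up to unit normalisation (weights are
    re-emitted in kg); re-reading the written files reproduces the parsed
    field values.  Returns the mapping of table name to file path.
    """
    if layout != "modern":
        raise ValueError("writing is supported in the modern layout only")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r = data.reports

    def fmt_date(s: pd.Series) -> pd.Series:
        return s.dt.strftime("%Y%m%d").fillna("")

    def fmt_num(s: pd.Series) -> pd.Series:
        return pd.Series(
            ["" if v != v else f"{v:g}" for v in s], index=s.index, dtype=object
        )

    inv_sex = {v: k for k, v in SEX_CODES.items()}
    inv_occ = {
        "Physician": "MD", "Pharmacist": "PH", "Other health-professional": "OT",
        "Consumer": "CN", "Lawyer": "LW", "Registered Nurse": "RN",
    }
    demo = pd.DataFrame(
        {
            "primaryid": r["primaryid"],
            "caseid": r["caseid"],
            "caseversion": r["case_version"].astype(int),
            "fda_dt": fmt_date(r["fda_receipt_date"]),
            "event_dt": fmt_date(r["event_date"]),
            "age": fmt_num(r["age_value"]),
            "age_cod": r["age_unit"].fillna(""),
            "sex": r["sex"].map(inv_sex).fillna(""),
            "wt": fmt_num(r["weight_kg"]),
            "wt_cod": ["KG" if v == v else "" for v in r["weight_kg"]],
            "occp_cod": r["reporter_occupation"].map(inv_occ).fillna(""),
            "reporter_country": r["reporter_country"].replace("unknown", ""),
        }
    )

    m = data.mentions
    drug = pd.DataFrame(
        {
            "primaryid": m["primaryid"],
            "drug_seq": fmt_num(m["drug_seq"]),
            "role_cod": m["role"].fillna(""),
            "drugname": m["raw_name"].fillna(""),
        }
    )
    reac = data.reactions[["primaryid", "pt"]]

    inv_out = {v: k for k, v in OUTCOME_CODES.items()}
    outc_rows = [
        (pid, inv_out[label])
        for pid, outs in zip(r["primaryid"], r["outcomes"])
        for label in sorted(outs)
    ]
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"])

    has_start = m["start_date"].notna()
    ther = pd.DataFrame(
        {
            "primaryid": m.loc[has_start, "primaryid"],
            "dsg_drug_seq": fmt_num(m.loc[has_start, "drug_seq"]),
            "start_dt": m.loc[has_start, "start_date"].dt.strftime("%Y%m%d"),
        }
    )

    paths = {}
    for name, df in [
        ("demo", demo), ("drug", drug), ("reac", reac), ("outc", outc), ("ther", ther),
    ]:
        path = outdir / f"{name.upper()}.txt"
        df.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# case-level operations

def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per caseid: the latest case version.

    FAERS re-publishes a case each time it is amended; standard practice is
    to analyse only the latest version.  Ties on ``case_version`` break by
    latest ``fda_receipt_date``, then largest ``primaryid`` (numeric
    comparison when both ids are numeric).
    """
    if reports.empty:
        return reports.copy()
    pid_num = pd.to_numeric(reports["primaryid"], errors="coerce")
    order = reports.assign(_pid_num=pid_num).sort_values(
        ["caseid", "case_version", "fda_receipt_date", "_pid_num", "primaryid"],
        kind="mergesort", na_position="first",
    )
    deduped = order.drop_duplicates("caseid", keep="last").drop(columns="_pid_num")
    removed = len(reports) - len(deduped)
    logger.info("deduplicate: removed %d superseded case version(s)", removed)
    return deduped.sort_index().reset_index(drop=True)


def filter_event(reactions: pd.DataFrame, target_pt: str) -> set[str]:
    """Return primaryids of reports listing the target preferred term.

    Matching is exact after case folding and whitespace normalisation —
    no MedDRA hierarchy traversal.
    """
    if not target_pt or not target_pt.strip():
        raise ValueError("target_pt must be a non-empty preferred term")
    norm = _norm_pt(target_pt)
    if reactions.empty:
        return set()
    pts = reactions["pt"].astype(str).map(_norm_pt)
    return set(reactions.loc[pts == norm, "primaryid"])


def _norm_pt(s: str) -> str:
    return " ".join(s.split()).casefold()


def quarter_bounds(quarter: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last day of a quarter label like '2004Q1'."""
    period = pd.Period(quarter, freq="Q")
    return period.start_time.normalize(), period.end_time.normalize()


def filter_window(
    reports: pd.DataFrame, start_quarter: str, end_quarter: str
) -> pd.DataFrame:
    """Restrict reports to an FDA-receipt-date window of whole quarters."""
    lo, _ = quarter_bounds(start_quarter)
    _, hi = quarter_bounds(end_quarter)
    if lo > hi:
        raise ValueError(f"window start {start_quarter} is after end {end_quarter}")
    mask = reports["fda_receipt_date"].between(lo, hi)
    return reports[mask].reset_index(drop=True)


def concat_quarters(quarters: Iterable[QuarterData]) -> QuarterData:
    """Concatenate several parsed quarters into one QuarterData."""
    qs = list(quarters)
    return QuarterData(
        pd.concat([q.reports for q in qs], ignore_index=True),
        pd.concat([q.mentions for q in qs], ignore_index=True),
        pd.concat([q.reactions for q in qs], ignore_index=True),
    )
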