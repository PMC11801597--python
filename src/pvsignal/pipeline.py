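"""End-to-end orchestration: ingest → normalize → contingency → signals.

The pipeline mirrors how a disproportionality study is actually run: read
the quarterly extracts in scope, restrict to the reporting window, keep the
latest version of each case, normalize drug names, pull the target-event
cohort, build per-drug 2x2 tables against the whole-database comparator,
compute the four statistics with their signal flags, and emit the cohort
summary plus the full and top-N ranked signal tables as TSV files.

Every run logs row counts at each stage and a hash of the configuration, so
two runs with the same inputs and config are provably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort, contingency, ingest, normalize, stats
from ._util import ConfigurationError, PvSignalError

logger = logging.getLogger(__name__)

SIGNAL_FILE_COLUMNS = [
    "drug", "a", "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi",
    "chisq", "ic", "ic025", "ebgm", "ebgm05",
    "ror_pos", "prr_pos", "bcpnn_pos", "ebgm_pos", "consensus",
]


class PipelineStageError(PvSignalError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: Path
    target_pt: str = "Autoimmune hepatitis"
    layout: str = "modern"
    dictionary: Path | None = None  # None -> bundled dictionary
    start_quarter: str = "2004Q1"
    end_quarter: str = "2024Q1"
    roles: frozenset[str] = frozenset({"PS", "SS"})
    thresholds: stats.Thresholds = field(default_factory=stats.Thresholds)
    prior: stats.BcpnnPrior = field(default_factory=stats.BcpnnPrior)
    correction: bool = False
    top_n: int = 50
    rank_by: str = "ror"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")
        s = pd.Period(self.start_quarter, freq="Q")
        e = pd.Period(self.end_quarter, freq="Q")
        if s > e:
            raise ConfigurationError("window start quarter is after end quarter")
        if not self.roles <= set(ingest.ROLE_CODES):
            raise ConfigurationError(f"unknown role codes {set(self.roles)}")

    @classmethod
    def from_toml(cls, path: Path | str) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text(encoding="utf-8"))
        inp = raw.get("input", {})
        ana = raw.get("analysis", {})
        thr = raw.get("thresholds", {})
        pri = raw.get("bcpnn_prior", {})
        return cls(
            input_dir=Path(inp.get("dir", ".")),
            layout=inp.get("layout", "modern"),
            dictionary=Path(inp["dictionary"]) if "dictionary" in inp else None,
            target_pt=ana.get("target_pt", "Autoimmune hepatitis"),
            start_quarter=ana.get("start_quarter", "2004Q1"),
            end_quarter=ana.get("end_quarter", "2024Q1"),
            roles=frozenset(ana.get("roles", ["PS", "SS"])),
            correction=bool(ana.get("correction", False)),
            top_n=int(ana.get("top_n", 50)),
            rank_by=ana.get("rank_by", "ror"),
            thresholds=stats.Thresholds(**thr),
            prior=stats.BcpnnPrior(**pri),
        )

    def config_hash(self) -> str:
        payload = {
            "input_dir": str(self.input_dir), "target_pt": self.target_pt,
            "layout": self.layout,
            "dictionary": str(self.dictionary) if self.dictionary else None,
            "window": [self.start_quarter, self.end_quarter],
            "roles": sorted(self.roles),
            "thresholds": vars(self.thresholds) | {},
            "prior": vars(self.prior) | {},
            "correction": self.correction,
            "top_n": self.top_n, "rank_by": self.rank_by,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything a run produces, in memory plus on disk."""

    config_hash: str
    n_reports: int
    n_event_reports: int
    data: ingest.QuarterData
    event_ids: set[str]
    tables: pd.DataFrame
    signals: pd.DataFrame
    top_signals: pd.DataFrame
    summary: cohort.CohortSummary
    coverage: normalize.CoverageReport
    paths: dict[str, Path]


def discover_quarters(input_dir: Path | str) -> list[dict[str, Path]]:
    """Group FAERS files in a directory into per-quarter path mappings.

    Files are matched by prefix (DEMO/DRUG/REAC/OUTC/THER, any case); the
    remainder of the stem is the quarter tag, so DEMO24Q1.txt pairs with
    DRUG24Q1.txt and a lone DEMO.txt with DRUG.txt.
    """
    input_dir = Path(input_dir)
    found: dict[str, dict[str, Path]] = {}
    for path in sorted(input_dir.glob("*.txt")):
        stem = path.stem.upper()
        for table in ("demo", "drug", "reac", "outc", "ther"):
            if stem.startswith(table.upper()):
                tag = stem[len(table):]
                found.setdefault(tag, {})[table] = path
                break
    quarters = []
    for tag in sorted(found):
        mapping = found[tag]
        missing = {"demo", "drug", "reac"} - set(mapping)
        if missing:
            raise ConfigurationError(
                f"quarter tag {tag or '<none>'!r} is missing tables {sorted(missing)}"
            )
        quarters.append(mapping)
    if not quarters:
        raise ConfigurationError(f"no FAERS tables found under {input_dir}")
    return quarters


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PvSignalError:
            raise
        except Exception as e:  # noqa: BLE001 - stage name must propagate
            raise PipelineStageError(name, e) from e
    return wrap


def run(config: PipelineConfig, outdir: Path | str) -> ReportBundle:
    """Execute the full pipeline and write the report bundle to `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline run, config hash %s", chash)

    try:
        quarters = discover_quarters(config.input_dir)
        data = ingest.concat_quarters(
            ingest.read_quarter(q, layout=config.layout) for q in quarters
        )
    except PvSignalError:
        raise
    except Exception as e:
        raise PipelineStageError("ingest", e) from e
    logger.info("ingest: %d report rows", len(data.reports))

    reports = _stage("window")(
        ingest.filter_window, data.reports, config.start_quarter,
        config.end_quarter,
    )
    reports = _stage("deduplicate")(ingest.deduplicate, reports)
    in_scope = set(reports["primaryid"])
    mentions = data.mentions[data.mentions["primaryid"].isin(in_scope)]
    reactions = data.reactions[data.reactions["primaryid"].isin(in_scope)]
    logger.info("window+dedup: %d reports in scope", len(reports))

    dictionary = (
        normalize.DrugDictionary.from_file(config.dictionary)
        if config.dictionary else normalize.default_dictionary()
    )
    mentions = _stage("normalize")(
        normalize.normalize_mentions, mentions, dictionary
    )
    coverage = normalize.coverage_report(mentions, dictionary)
    logger.info("normalize: %.1f%% of %d mentions resolved",
                100 * coverage.fraction_resolved, coverage.n_mentions)

    event_ids = _stage("event-filter")(
        ingest.filter_event, reactions, config.target_pt
    )
    event_reports = reports[reports["primaryid"].isin(event_ids)]
    logger.info("event cohort: %d reports", len(event_reports))

    tables = _stage("contingency")(
        contingency.build_tables, reports, mentions, event_ids, config.roles
    )
    tables = contingency.min_case_filter(tables, config.thresholds.min_cases)

    signals = _stage("signals")(
        stats.compute_signals, tables, config.thresholds, config.prior,
        config.correction,
    )
    ranked = stats.rank_signals(signals, by=config.rank_by)
    top = ranked.head(config.top_n)

    tto = cohort.time_to_onset(event_reports, mentions)
    summary = _stage("cohort")(
        cohort.summarize, event_reports, cohort.DEFAULT_AGE_CUTS, tto
    )

    paths = {
        "contingency": outdir / "contingency.tsv",
        "signals": outdir / "signals.tsv",
        "top_signals": outdir / "top_signals.tsv",
        "cohort_summary": outdir / "cohort_summary.tsv",
        "yearly_counts": outdir / "yearly_counts.tsv",
        "run_info": outdir / "run_info.json",
    }
    contingency.write_contingency(tables, paths["contingency"])
    stats.write_signals(ranked[SIGNAL_FILE_COLUMNS], paths["signals"])
    stats.write_signals(
        stats.format_signals(top)[SIGNAL_FILE_COLUMNS], paths["top_signals"]
    )
    cohort.write_summary(summary, paths["cohort_summary"])
    cohort.write_yearly_counts(summary, paths["yearly_counts"])
    run_info = {
        "config_hash": chash,
        "n_report_rows": int(len(data.reports)),
        "n_reports_in_scope": int(len(reports)),
        "n_event_reports": int(len(event_reports)),
        "n_drugs_tabulated": int(len(tables)),
        "fraction_mentions_resolved": coverage.fraction_resolved,
    }
    paths["run_info"].write_text(json.dumps(run_info, indent=2) + "\n")

    return ReportBundle(
        config_hash=chash,
        n_reports=len(reports),
        n_event_reports=len(event_reports),
        data=ingest.QuarterData(reports, mentions, reactions),
        event_ids=event_ids,
        tables=tables,
        signals=ranked,
        top_signals=top,
        summary=summary,
        coverage=coverage,
        paths=paths,
    )
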