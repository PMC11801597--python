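"""Synthetic FAERS-style data with known ground truth.

The generator emulates the joint structure of spontaneous case reports —
one demographic row per case version, several drug mentions and reaction
preferred terms per report, multi-valued outcomes — under a simple, fully
specified model:

* each catalog drug appears on a report independently with its marginal
  reporting probability;
* the target event occurs with probability ``background_event_rate · λ``,
  where λ is the largest planted relative risk among the drugs on the
  report (λ = 1 when none is planted); combining by max rather than by
  product keeps λ interpretable as a per-drug risk ratio;
* demographics, outcomes, dates and countries are drawn independently from
  configurable category distributions whose defaults mirror a typical
  hepatic-event reporting cohort.

Because exposure is a Bernoulli mixture and the event is a Bernoulli given
exposure, every planted drug has a closed-form implied 2x2 table: the truth
table reports λ, the model-implied odds ratio, expected cell counts, and the
exactly tallied cells of the realized draw.  The file writer emits the
modern FAERS dialect plus a drug dictionary covering the catalog, so the
whole pipeline (ingest → normalize → contingency → statistics) can be
exercised end-to-end and compared against the generator's own tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ingest
from ._util import ConfigurationError
from .normalize import DrugDictionary

BACKGROUND_PTS = (
    "Nausea", "Headache", "Fatigue", "Rash", "Dizziness",
    "Pyrexia", "Diarrhoea", "Vomiting",
)

_SEX_LEVELS = ("F", "M", "")
_SEX_PROBS = (0.61, 0.29, 0.10)

_COUNTRIES = (
    "United States", "Germany", "Japan", "France", "United Kingdom",
    "Canada", "Italy", "Spain", "Brazil", "China", "India", "Australia",
    "Netherlands", "Sweden", "Switzerland", "Poland", "Mexico", "Argentina",
    "Korea",
)
_COUNTRY_PROBS = (0.26, 0.07, 0.06, 0.06, 0.05) + (0.5 / 14,) * 14

_OCCUPATIONS = ("MD", "OT", "CN", "PH", "", "LW", "RN")
_OCC_PROBS = (0.44, 0.20, 0.16, 0.15, 0.043, 0.005, 0.002)

_OUTCOMES = ("OT", "HO", "DE", "LT", "DS", "RI", "CA")
_OUTCOME_PROBS = (0.5437, 0.3209, 0.0559, 0.0504, 0.0232, 0.0055, 0.0004)

_NAME_DECORATIONS = ("", " 10MG", " 20MG TABLET", " HCL", " CAPSULES")


def default_drug_catalog(n_drugs: int = 100) -> tuple[tuple[str, float], ...]:
    """Catalog of `n_drugs` labels with log-spaced marginal probabilities.

    Probabilities run from 0.002 to 0.05 — a realistic spread between a
    rarely reported and a blockbuster drug in a spontaneous database.
    """
    probs = np.geomspace(0.002, 0.05, n_drugs)
    return tuple(
        (f"drug_{i + 1:03d}", float(p)) for i, p in enumerate(probs)
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; the defaults are the reference study scale."""

    n_reports: int = 200_000
    drug_catalog: tuple[tuple[str, float], ...] = field(
        default_factory=default_drug_catalog
    )
    target_pt: str = "Autoimmune hepatitis"
    background_event_rate: float = 0.005
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    start_quarter: str = "2004Q1"
    end_quarter: str = "2024Q1"
    event_date_missing_rate: float = 0.10
    therapy_start_missing_rate: float = 0.20

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        if not 0.0 <= self.background_event_rate <= 1.0:
            raise ConfigurationError("background_event_rate must be in [0, 1]")
        labels = [d for d, _ in self.drug_catalog]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("drug catalog labels must be unique")
        for drug, p in self.drug_catalog:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"marginal probability for {drug!r} outside [0, 1]"
                )
        for drug, lam in self.planted_effects.items():
            if drug not in set(labels):
                raise ConfigurationError(f"planted drug {drug!r} not in catalog")
            if not (np.isfinite(lam) and lam >= 1.0):
                raise ConfigurationError(
                    f"relative risk for {drug!r} must be finite and >= 1"
                )
            if self.background_event_rate * lam > 1.0:
                raise ConfigurationError(
                    f"background_event_rate * lambda > 1 for {drug!r}"
                )


@dataclass
class SyntheticData:
    """Generated tables plus the ground truth they were drawn from."""

    reports: pd.DataFrame
    mentions: pd.DataFrame
    reactions: pd.DataFrame
    truth: pd.DataFrame
    n_unique_cases: int
    dictionary: DrugDictionary

    def as_quarter(self) -> ingest.QuarterData:
        return ingest.QuarterData(self.reports, self.mentions, self.reactions)


# ---------------------------------------------------------------------------
# core draw

def _draw_exposure_events(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli drug-presence matrix and event indicator vector."""
    n = config.n_reports
    k = len(config.drug_catalog)
    present = np.empty((n, k), dtype=bool)
    for j, (_, p) in enumerate(config.drug_catalog):
        present[:, j] = rng.random(n) < p
    lam = np.ones(n)
    labels = [d for d, _ in config.drug_catalog]
    for drug, l in config.planted_effects.items():
        j = labels.index(drug)
        lam = np.maximum(lam, np.where(present[:, j], l, 1.0))
    p_event = np.minimum(1.0, config.background_event_rate * lam)
    event = rng.random(n) < p_event
    return present, event


def _tally_cells(
    config: SyntheticConfig, present: np.ndarray, event: np.ndarray
) -> pd.DataFrame:
    n = config.n_reports
    n_event = int(event.sum())
    a = (present & event[:, None]).sum(axis=0).astype(int)
    nd = present.sum(axis=0).astype(int)
    return pd.DataFrame(
        {
            "drug": [d for d, _ in config.drug_catalog],
            "a": a,
            "b": nd - a,
            "c": n_event - a,
            "d": n - nd - (n_event - a),
            "N": n,
        }
    )


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Analytic ground truth per catalog drug.

    ``true_or`` is the model-implied odds ratio
    (pe/(1-pe)) / (p0/(1-p0)) with pe = background·λ and p0 = background;
    expected cells use the same marginal rates.  Both are exact when planted
    drugs do not co-occur and a close approximation otherwise (co-occurrence
    of independently drawn rare drugs is second-order).
    """
    bg = config.background_event_rate
    rows = []
    for drug, p in config.drug_catalog:
        lam = config.planted_effects.get(drug, 1.0)
        pe = min(1.0, bg * lam)
        if 0 < pe < 1 and 0 < bg < 1:
            true_or = (pe / (1 - pe)) / (bg / (1 - bg))
        else:
            true_or = float("nan")
        n = config.n_reports
        rows.append(
            {
                "drug": drug, "prob": p, "lam": lam, "true_or": true_or,
                "expected_a": n * p * pe,
                "expected_b": n * p * (1 - pe),
                "expected_c": n * (1 - p) * bg,
                "expected_d": n * (1 - p) * (1 - bg),
            }
        )
    return pd.DataFrame(rows)


def simulate_tables(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw once and return (tallied contingency tables, truth table).

    A cell-level shortcut of the same generative model used by
    :func:`generate_frames` — exposure and event are drawn identically but
    demographics and file structure are skipped, so large Monte-Carlo
    studies (calibration, parameter recovery) run in seconds.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    present, event = _draw_exposure_events(config, rng)
    return _tally_cells(config, present, event), truth_table(config)


# ---------------------------------------------------------------------------
# full report-level generation

def generate_frames(config: SyntheticConfig) -> SyntheticData:
    """Generate the full parsed-table representation of one synthetic corpus."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    present, event = _draw_exposure_events(config, rng)
    tallies = _tally_cells(config, present, event)

    pid = np.char.add("1", np.char.zfill((np.arange(n) + 1).astype(str), 8))
    caseid = np.char.add("5", np.char.zfill((np.arange(n) + 1).astype(str), 8))

    lo, hi = ingest.quarter_bounds(config.start_quarter)[0], \
        ingest.quarter_bounds(config.end_quarter)[1]
    day_span = (hi - lo).days
    receipt = lo + pd.to_timedelta(rng.integers(0, day_span + 1, n), unit="D")
    event_lag = rng.integers(0, 181, n)
    event_date = pd.Series(receipt - pd.to_timedelta(event_lag, unit="D"))
    event_missing = rng.random(n) < config.event_date_missing_rate
    event_date[event_missing] = pd.NaT

    sex = rng.choice(_SEX_LEVELS, size=n, p=_SEX_PROBS)
    age = np.clip(rng.normal(55.0, 18.0, n), 0.5, 100.0).round(0)
    age_missing = rng.random(n) < 0.20
    age = np.where(age_missing, np.nan, age)
    weight = np.exp(rng.normal(np.log(70.0), 0.25, n)).round(1)
    weight = np.where(rng.random(n) < 0.40, np.nan, weight)
    occ = rng.choice(_OCCUPATIONS, size=n, p=_OCC_PROBS)
    country = rng.choice(_COUNTRIES, size=n, p=np.array(_COUNTRY_PROBS))

    first = rng.choice(_OUTCOMES, size=n, p=np.array(_OUTCOME_PROBS))
    second = rng.choice(_OUTCOMES, size=n, p=np.array(_OUTCOME_PROBS))
    has_second = (rng.random(n) < 0.40) & (second != first)
    outcomes = [
        frozenset(
            {ingest.OUTCOME_CODES[f]} | ({ingest.OUTCOME_CODES[s]} if h else set())
        )
        for f, s, h in zip(first, second, has_second)
    ]

    reports = pd.DataFrame(
        {
            "primaryid": pid,
            "caseid": caseid,
            "case_version": 1,
            "fda_receipt_date": pd.Series(receipt),
            "event_date": event_date,
            "sex": pd.Series(sex).map(ingest.SEX_CODES).fillna("unknown"),
            "age_value": age,
            "age_unit": np.where(np.isnan(age), pd.NA, "YR"),
            "age_years": age,
            "weight_kg": weight,
            "reporter_occupation": pd.Series(occ).map(ingest.OCCUPATION_CODES)
            .fillna("unknown"),
            "reporter_country": country,
            "outcomes": outcomes,
        }
    )

    rows, cols = np.nonzero(present)
    labels = np.array([d for d, _ in config.drug_catalog])
    seq = np.empty(len(rows), dtype=int)
    start = 0
    for i, cnt in zip(*np.unique(rows, return_counts=True)):
        seq[start:start + cnt] = np.arange(1, cnt + 1)
        start += cnt
    deco = rng.choice(_NAME_DECORATIONS, size=len(rows))
    raw_names = np.char.add(np.char.upper(labels[cols]), deco.astype(str))
    start_lag = rng.integers(1, 366, len(rows))
    m_event_date = event_date.to_numpy()[rows]
    start_date = pd.Series(m_event_date) - pd.to_timedelta(start_lag, unit="D")
    start_missing = rng.random(len(rows)) < config.therapy_start_missing_rate
    start_date[start_missing] = pd.NaT
    mentions = pd.DataFrame(
        {
            "primaryid": pid[rows],
            "drug_seq": seq.astype(float),
            "raw_name": raw_names,
            "role": np.where(seq == 1, "PS", "SS"),
            "start_date": start_date,
        }
    )

    bg_pt = rng.choice(BACKGROUND_PTS, size=n)
    reactions = pd.DataFrame({"primaryid": pid, "pt": bg_pt})
    target_rows = pd.DataFrame(
        {"primaryid": pid[event], "pt": config.target_pt}
    )
    reactions = pd.concat([reactions, target_rows], ignore_index=True)
    reactions = reactions.sort_values(
        ["primaryid", "pt"], kind="mergesort", ignore_index=True
    )

    truth = truth_table(config).merge(
        tallies.rename(columns={c: f"realized_{c}" for c in "abcd"}),
        on="drug",
    )

    dictionary = DrugDictionary.from_pairs(
        [(label, label) for label in labels]
    )
    return SyntheticData(
        reports=reports, mentions=mentions, reactions=reactions,
        truth=truth, n_unique_cases=n, dictionary=dictionary,
    )


def inject_duplicates(
    data: SyntheticData, rate: float, seed: int = 0
) -> SyntheticData:
    """Re-emit a fraction of cases as an amended (higher) case version.

    Exactly ``round(rate * n)`` cases gain a second row with incremented
    ``case_version`` and a fresh primaryid; their mentions and reactions are
    re-emitted under the new id, and the new version carries the same field
    values, so deduplication must restore the original counts exactly.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("duplicate rate must be in [0, 1)")
    n = len(data.reports)
    k = int(round(rate * n))
    if k == 0:
        return data
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))

    dup = data.reports.iloc[idx].copy()
    old_pid = dup["primaryid"].to_numpy()
    max_pid = pd.to_numeric(data.reports["primaryid"]).max()
    new_pid = (max_pid + 1 + np.arange(k)).astype(np.int64).astype(str)
    dup["primaryid"] = new_pid
    dup["case_version"] = dup["case_version"] + 1
    reports = pd.concat([data.reports, dup], ignore_index=True)

    remap = dict(zip(old_pid, new_pid))
    dup_mentions = data.mentions[data.mentions["primaryid"].isin(remap)].copy()
    dup_mentions["primaryid"] = dup_mentions["primaryid"].map(remap)
    mentions = pd.concat([data.mentions, dup_mentions], ignore_index=True)

    dup_reac = data.reactions[data.reactions["primaryid"].isin(remap)].copy()
    dup_reac["primaryid"] = dup_reac["primaryid"].map(remap)
    reactions = pd.concat([data.reactions, dup_reac], ignore_index=True)

    return replace(
        data, reports=reports, mentions=mentions, reactions=reactions,
        n_unique_cases=data.n_unique_cases,
    )


def generate(
    config: SyntheticConfig,
    outdir: Path | str,
    duplicate_rate: float = 0.0,
) -> dict:
    """Write a synthetic corpus as modern-dialect FAERS files.

    Emits DEMO/DRUG/REAC/OUTC/THER.txt, ``truth.tsv`` and a
    ``drug_dictionary.tsv`` covering the catalog.  Output is byte-identical
    across reruns with the same configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_frames(config)
    if duplicate_rate:
        data = inject_duplicates(data, duplicate_rate, seed=config.seed)
    paths = ingest.write_quarter(data.as_quarter(), outdir, layout="modern")

    truth = data.truth.copy()
    truth["expected_n_after_dedup"] = data.n_unique_cases
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = truth_path

    dict_path = outdir / "drug_dictionary.tsv"
    lines = ["# identity dictionary for the synthetic drug catalog"]
    lines += [f"{label}\t{label}" for label, _ in config.drug_catalog]
    dict_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["dictionary"] = dict_path
    return paths
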