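"""Dictionary-based drug-name normalization.

Free-text drug strings in spontaneous reports mix brand and generic names,
salts, doses and formulations ("LIPITOR 20MG TABLET", "Atorvastatin calcium").
This module maps such strings to canonical ingredient labels through a curated
pattern dictionary: the query is case-folded, punctuation is collapsed, and
dose / formulation / salt tokens are stripped before an exact lookup.
Unresolved strings are returned as such (``None``) and surface in the
coverage report — they are never silently dropped.

The bundled dictionary covers the drugs most strongly associated with
drug-induced autoimmune-like hepatitis plus common brand and salt synonyms;
it is a deliberate, inspectable stand-in for full NLP-based normalization
(RxNorm mapping, spelling correction and fuzzy matching are out of scope).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from ._util import ConfigurationError

_PUNCT_RE = re.compile(r"[^\w/]+")
_DOSE_RE = re.compile(
    r"^\d+(\.\d+)?(mg|mcg|ug|g|kg|ml|l|iu|meq|mmol|units?|%)?$"
)

#: tokens dropped during cleaning: doses/forms/routes and common salt names
STOP_TOKENS = frozenset(
    """
    mg mcg ug g ml iu meq unit units tab tabs tablet tablets cap caps capsule
    capsules injection inj infusion solution suspension syrup cream ointment
    gel patch spray drops oral iv im sc topical film coated chewable
    extended delayed release er xr sr cr la xl depot kit prefilled pen
    hcl hydrochloride dihydrochloride hydrobromide bromide chloride nitrate
    sodium disodium potassium calcium magnesium zinc
    sulfate sulphate bisulfate mesylate besylate tosylate
    tartrate bitartrate maleate fumarate succinate citrate
    phosphate diphosphate acetate propionate valerate dipropionate
    stearate palmitate pamoate lactate gluconate carbonate
    monohydrate dihydrate trihydrate hemihydrate anhydrous
    """.split()
)


def clean_drug_string(raw: str) -> str:
    """Lower-case, collapse punctuation and strip dose/form/salt tokens.

    Slashes are preserved as token separators so combination products keep
    both ingredients ("amoxicillin/clavulanic acid").
    """
    s = _PUNCT_RE.sub(" ", raw.casefold())
    s = s.replace("/", " / ")
    tokens = [
        t for t in s.split()
        if t == "/" or (t not in STOP_TOKENS and not _DOSE_RE.match(t))
    ]
    # drop slashes left dangling at the edges after token stripping
    while tokens and tokens[0] == "/":
        tokens.pop(0)
    while tokens and tokens[-1] == "/":
        tokens.pop()
    return " ".join(tokens)


@dataclass(frozen=True)
class DrugDictionary:
    """Mapping from cleaned name patterns to canonical drug labels."""

    entries: dict[str, str] = field(default_factory=dict)

    @property
    def canonical_labels(self) -> frozenset[str]:
        return frozenset(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DrugDictionary":
        entries: dict[str, str] = {}
        for pattern, canonical in pairs:
            key = clean_drug_string(pattern)
            if not key:
                raise ConfigurationError(f"pattern {pattern!r} cleans to nothing")
            if key in entries and entries[key] != canonical:
                raise ConfigurationError(
                    f"pattern {pattern!r} maps to both {entries[key]!r} "
                    f"and {canonical!r}"
                )
            entries[key] = canonical
        return cls(entries)

    @classmethod
    def from_file(cls, path: Path | str) -> "DrugDictionary":
        """Load a UTF-8, tab-separated ``pattern<TAB>canonical`` file.

        Lines starting with '#' and blank lines are ignored.
        """
        pairs = []
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 'pattern<TAB>canonical', "
                    f"got {line!r}"
                )
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)


def default_dictionary() -> DrugDictionary:
    """The dictionary bundled with the package."""
    ref = resources.files("pvsignal.data") / "drug_dictionary.tsv"
    with resources.as_file(ref) as path:
        return DrugDictionary.from_file(path)


def normalize(raw_name: str | None, dictionary: DrugDictionary) -> str | None:
    """Map one free-text drug string to its canonical label, or None.

    Lookup order: the cleaned string as-is, then (already implied by
    cleaning) nothing further — cleaning strips salts and doses, so
    "ATORVASTATIN CALCIUM 20MG" and "atorvastatin" share the same key.
    """
    if not dictionary.entries:
        raise ConfigurationError("drug dictionary is empty")
    if raw_name is None or not str(raw_name).strip():
        return None
    return dictionary.entries.get(clean_drug_string(str(raw_name)))


def normalize_mentions(
    mentions: pd.DataFrame, dictionary: DrugDictionary
) -> pd.DataFrame:
    """Add a ``normalized_name`` column (None where unresolved)."""
    if not dictionary.entries:
        raise ConfigurationError("drug dictionary is empty")
    uniq = mentions["raw_name"].dropna().unique()
    mapping = {raw: normalize(raw, dictionary) for raw in uniq}
    out = mentions.copy()
    out["normalized_name"] = mentions["raw_name"].map(mapping)
    return out


class CoverageReport(NamedTuple):
    fraction_resolved: float
    n_mentions: int
    top_unresolved: list[tuple[str, int]]


def coverage_report(
    mentions: pd.DataFrame, dictionary: DrugDictionary, top: int = 20
) -> CoverageReport:
    """Fraction of mentions resolved plus the most frequent unresolved strings.

    Unresolved strings are sorted by descending frequency, ties alphabetical.
    With no mentions at all the fraction is vacuously 1.0.
    """
    normalized = normalize_mentions(mentions, dictionary)
    n = len(normalized)
    if n == 0:
        return CoverageReport(1.0, 0, [])
    unresolved = normalized.loc[normalized["normalized_name"].isna(), "raw_name"]
    counts = unresolved.fillna("<missing>").value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return CoverageReport(1.0 - len(unresolved) / n, n, ranked)
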