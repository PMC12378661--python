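"""Taxonomic name resolution against a marine-registry dump.

Occurrence names are matched exactly (after whitespace normalization,
case-folding and authorship stripping) against a WoRMS-style registry dump
of accepted and unaccepted names with a marine flag.  Records resolve to an
accepted marine name directly, through a synonym, or through a manually
revised override list; everything else is dropped and counted.  No fuzzy
matching is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

RANK_SPECIES_LABELS = frozenset({"species"})

REGISTRY_COLUMNS = [
    "scientificName",
    "taxonomicStatus",
    "acceptedName",
    "isMarine",
    "taxonRank",
]

RESOLVE_OUTCOMES = (
    "accepted-direct",
    "synonym-resolved",
    "override-resolved",
    "non-marine-dropped",
    "unmatched-dropped",
)

_AUTHORSHIP = re.compile(r"^(\S+(?:\s+[a-z][\w.-]*)+?)(?=\s+[A-Z(\[]|\s*$)")


def normalize_name(name: str) -> str:
    """Canonical lookup key: collapsed whitespace, case-folded."""
    return " ".join(str(name).split()).casefold()


def strip_authorship(name: str) -> str:
    """Drop the authorship tail of a scientific name.

    The canonical name is the leading genus token plus following lowercase
    epithets; the authorship begins at the first subsequent token starting
    with an uppercase letter or a parenthesis (e.g. ``"Abra alba (W. Wood,
    1802)"`` → ``"Abra alba"``).
    """
    s = " ".join(str(name).split())
    m = _AUTHORSHIP.match(s)
    return m.group(1) if m else s


class ConfigError(ValueError):
    """Raised when a registry/override configuration is inconsistent."""


@dataclass
class RegistryEntry:
    status: str          # "accepted" | "unaccepted"
    accepted_name: str
    is_marine: bool
    rank: str


class TaxonRegistry:
    """Name → (status, accepted name, marine flag, rank) lookup.

    Lookup keys are whitespace-normalized and case-insensitive.  When a dump
    carries homonym rows (the same name listed both marine and non-marine),
    the marine interpretation wins and the collision is recorded in
    ``homonyms``.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"registry dump missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.entries: dict[str, RegistryEntry] = {}
        self.homonyms: list[str] = []
        for row in frame.itertuples(index=False):
            key = normalize_name(row.scientificName)
            entry = RegistryEntry(
                status=str(row.taxonomicStatus).strip().lower(),
                accepted_name=str(row.acceptedName),
                is_marine=_as_bool(row.isMarine),
                rank=str(row.taxonRank),
            )
            prev = self.entries.get(key)
            if prev is None:
                self.entries[key] = entry
            elif entry.is_marine and not prev.is_marine:
                self.entries[key] = entry   # marine homonym wins
                self.homonyms.append(key)
            elif prev.is_marine and not entry.is_marine:
                self.homonyms.append(key)
        for key, entry in self.entries.items():
            if entry.status != "accepted":
                acc = self.entries.get(normalize_name(entry.accepted_name))
                if acc is None or acc.status != "accepted":
                    raise ConfigError(
                        f"unaccepted name {key!r} points at a non-registry or "
                        f"non-accepted name {entry.accepted_name!r}"
                    )

    def __len__(self) -> int:
        return len(self.frame)

    def lookup(self, name: str) -> RegistryEntry | None:
        return self.entries.get(normalize_name(name))

    def is_accepted_marine(self, name: str) -> bool:
        e = self.lookup(name)
        return e is not None and e.status == "accepted" and e.is_marine

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "TaxonRegistry":
        frame = pd.read_csv(path, sep=sep, engine="python")
        return cls(frame)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "t"}
    return bool(value)


class ManualOverrideList:
    """Manually revised (raw name → accepted marine name) validation pairs.

    Every target name must exist in the registry as accepted and marine;
    violations are configuration errors raised at load time.
    """

    def __init__(self, pairs: dict[str, str], registry: TaxonRegistry) -> None:
        self.pairs = {normalize_name(k): v for k, v in pairs.items()}
        for raw, target in self.pairs.items():
            if not registry.is_accepted_marine(target):
                raise ConfigError(
                    f"override {raw!r} -> {target!r}: target is not an "
                    "accepted marine name in the registry"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, name: str) -> str | None:
        return self.pairs.get(normalize_name(name))

    @classmethod
    def read(
        cls, path: str | Path, registry: TaxonRegistry, sep: str | None = None
    ) -> "ManualOverrideList":
        frame = pd.read_csv(path, sep=sep, engine="python")
        raw_col, acc_col = frame.columns[:2]
        return cls(dict(zip(frame[raw_col], frame[acc_col])), registry)


def filter_species_rank(
    table: pd.DataFrame,
    rank_labels: frozenset[str] | set[str] = RANK_SPECIES_LABELS,
) -> tuple[pd.DataFrame, int]:
    """Keep only records whose taxonRank is the species level
    (case-insensitive; the accepted label set is configurable).  Records
    with a missing rank are dropped and counted."""
    rank = table["taxonRank"].astype("string").str.strip().str.lower()
    keep = rank.isin({r.lower() for r in rank_labels})
    kept = table.loc[keep.fillna(False)]
    return kept, len(table) - len(kept)


def resolve_marine(
    table: pd.DataFrame,
    registry: TaxonRegistry,
    overrides: ManualOverrideList | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach accepted marine names; drop everything that does not resolve.

    A record is retained when its (authorship-stripped) name matches an
    accepted marine registry entry, an unaccepted entry whose accepted name
    is marine, or an override pair.  The report counts records per outcome:
    accepted-direct, synonym-resolved, override-resolved,
    non-marine-dropped, unmatched-dropped.
    """
    names = table["scientificName"].astype("string")
    unique = names.dropna().unique()
    accepted: dict[str, str | None] = {}
    outcome: dict[str, str] = {}
    for raw in unique:
        canonical = strip_authorship(raw)
        entry = registry.lookup(canonical)
        if entry is not None and entry.is_marine:
            if entry.status == "accepted":
                accepted[raw], outcome[raw] = canonical, "accepted-direct"
            else:
                acc = registry.lookup(entry.accepted_name)
                if acc is not None and acc.is_marine:
                    accepted[raw] = entry.accepted_name
                    outcome[raw] = "synonym-resolved"
                else:
                    accepted[raw], outcome[raw] = None, "non-marine-dropped"
            continue
        if entry is not None:   # matched but non-marine
            accepted[raw], outcome[raw] = None, "non-marine-dropped"
            continue
        target = overrides.get(canonical) if overrides is not None else None
        if target is not None:
            accepted[raw], outcome[raw] = target, "override-resolved"
        else:
            accepted[raw], outcome[raw] = None, "unmatched-dropped"

    out_series = names.map(outcome).fillna("unmatched-dropped")
    report = {k: 0 for k in RESOLVE_OUTCOMES}
    for k, v in out_series.value_counts().items():
        report[str(k)] = int(v)
    kept = table.loc[names.map(accepted).notna()].copy()
    kept["accepted_name"] = names.loc[kept.index].map(accepted)
    return kept, report
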