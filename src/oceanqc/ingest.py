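"""Reading occurrence tables in their source dialects and harmonizing them.

Each supported dialect (GBIF-like, OBIS-like, EMODnet-like exports, plus
the digitized-expedition fixture format) names its record-id column
differently; on ingest the id is mapped to ``record_id``, numeric fields
are coerced with row-level warnings rather than row drops, and the many
spellings of "no depth" ("", "NA", null, "NaN") collapse onto one canonical
missing marker.  Depth is meters positive down throughout; a dialect that
exports negative-down elevations declares ``negate_depth`` and is flipped
here, once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: unified column order (the Darwin Core subset carried through the pipeline)
UNIFIED_COLUMNS = [
    "record_id",
    "source",
    "decimalLatitude",
    "decimalLongitude",
    "coordinateUncertaintyInMeters",
    "coordinatePrecision",
    "depth",
    "depthAccuracy",
    "kingdom",
    "class",
    "family",
    "scientificName",
    "taxonRank",
    "individualCount",
    "dateIdentified",
    "day",
    "month",
    "year",
    "eventDate",
    "basisOfRecord",
    "catalogNumber",
    "collectionCode",
    "issue",
    "flags",
    "dataset",
]

NUMERIC_COLUMNS = [
    "decimalLatitude",
    "decimalLongitude",
    "coordinateUncertaintyInMeters",
    "coordinatePrecision",
    "depth",
    "depthAccuracy",
    "individualCount",
    "day",
    "month",
    "year",
]

MANDATORY_COLUMNS = ["decimalLatitude", "decimalLongitude", "scientificName", "taxonRank"]

MISSING_MARKERS = {"", "na", "nan", "null", "none", "n/a"}


@dataclass(frozen=True)
class Dialect:
    name: str
    id_column: str
    sep: str | None = None          # None → sniff
    negate_depth: bool = False      # source reports negative-down elevations


DIALECTS: dict[str, Dialect] = {
    "gbif-like": Dialect("gbif-like", "gbifID", sep="\t"),
    "obis-like": Dialect("obis-like", "id", sep=","),
    "emodnet-like": Dialect("emodnet-like", "occurrenceID", sep=","),
}

EXPEDITION_YEARS = (1876, 1878)


def read_occurrence_table(path: str | Path, dialect: str | Dialect) -> pd.DataFrame:
    """Read one delimited occurrence file into the unified schema.

    Missing mandatory columns (coordinates, scientificName, taxonRank) are a
    hard error naming them; an unparseable numeric cell produces a logged
    warning and a missing value, with the row retained.  Unknown columns are
    preserved (suffix-free passthrough).
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}") from None
    path = Path(path)
    raw = pd.read_csv(
        path,
        sep=dialect.sep,
        engine="python" if dialect.sep is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing mandatory columns: {', '.join(missing)}"
        )
    table = raw.copy()
    if dialect.id_column in table.columns:
        table = table.rename(columns={dialect.id_column: "record_id"})
    elif "record_id" not in table.columns:
        table["record_id"] = [f"{dialect.name}:{i}" for i in range(len(table))]
    table["source"] = dialect.name

    for col in NUMERIC_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
            continue
        cell = table[col].astype(str).str.strip()
        is_missing = cell.str.lower().isin(MISSING_MARKERS)
        coerced = pd.to_numeric(cell, errors="coerce")
        bad = coerced.isna() & ~is_missing
        if bad.any():
            log.warning(
                "%s: %d unparseable %s cell(s) set to missing (e.g. %r)",
                path.name, int(bad.sum()), col, cell[bad].iloc[0],
            )
        table[col] = coerced
    if dialect.negate_depth:
        table["depth"] = -table["depth"]

    for col in UNIFIED_COLUMNS:
        if col not in table.columns:
            table[col] = pd.NA
    extras = [c for c in table.columns if c not in UNIFIED_COLUMNS]
    table = table[UNIFIED_COLUMNS + extras]
    log.info("%s: read %d row(s) as %s", path.name, len(table), dialect.name)
    return table


def read_expedition_records(path: str | Path) -> pd.DataFrame:
    """Read a digitized expedition fixture table (station, latitude,
    longitude, depth, scientificName, year).

    Records are tagged ``source="expedition"``; rows with years outside the
    1876–1878 sampling window are flagged out-of-window and excluded; rows
    without coordinates are dropped with the count reported in the log.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in raw.columns}
    need = ["station", "latitude", "longitude", "depth", "scientificname", "year"]
    missing = [c for c in need if c not in lower]
    if missing:
        raise ValueError(f"{path.name}: missing expedition columns: {missing}")

    table = pd.DataFrame(
        {
            "record_id": "exp:" + raw[lower["station"]].astype(str)
            + ":" + pd.Series(range(len(raw)), dtype=str),
            "source": "expedition",
            "decimalLatitude": pd.to_numeric(raw[lower["latitude"]], errors="coerce"),
            "decimalLongitude": pd.to_numeric(raw[lower["longitude"]], errors="coerce"),
            "depth": pd.to_numeric(raw[lower["depth"]], errors="coerce"),
            "scientificName": raw[lower["scientificname"]],
            "taxonRank": "Species",
            "year": pd.to_numeric(raw[lower["year"]], errors="coerce"),
            "catalogNumber": raw[lower["station"]],
        }
    )
    no_coords = table["decimalLatitude"].isna() | table["decimalLongitude"].isna()
    if no_coords.any():
        log.warning(
            "%s: dropped %d station row(s) without coordinates",
            path.name, int(no_coords.sum()),
        )
    table = table.loc[~no_coords]
    in_window = table["year"].between(*EXPEDITION_YEARS)
    if (~in_window).any():
        log.warning(
            "%s: %d row(s) with year outside %d-%d flagged out-of-window "
            "and excluded from the expedition set",
            path.name, int((~in_window).sum()), *EXPEDITION_YEARS,
        )
    table = table.loc[in_window.fillna(False)]
    for col in UNIFIED_COLUMNS:
        if col not in table.columns:
            table[col] = pd.NA
    return table[UNIFIED_COLUMNS].reset_index(drop=True)


def harmonize(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate unified tables with provenance preserved.

    Row conservation holds (output length is the sum of input lengths) and
    record ids are only unique within a source — colliding ids across
    sources are both retained.
    """
    if not tables:
        return pd.DataFrame(columns=UNIFIED_COLUMNS)
    out = pd.concat(tables, ignore_index=True, sort=False)
    for col in UNIFIED_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    extras = [c for c in out.columns if c not in UNIFIED_COLUMNS]
    return out[UNIFIED_COLUMNS + extras]


def source_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-source row counts (feeds the attrition table)."""
    return {str(k): int(v) for k, v in table["source"].value_counts().items()}


def write_unified(table: pd.DataFrame, path: str | Path) -> None:
    """Write the unified table as tab-delimited UTF-8, fixed column order."""
    cols = [c for c in UNIFIED_COLUMNS if c in table.columns]
    extras = [c for c in table.columns if c not in UNIFIED_COLUMNS]
    table[cols + extras].to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_unified(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_unified` (lossless for the
    unified columns)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = table.replace("", pd.NA)
    for col in NUMERIC_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table
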