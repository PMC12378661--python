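"""Decade bins, latitude-band/depth-zone summaries, accumulation curves.

The time axis is 14 decade bins spanning 1876–2025: a long opening bin
(1876–1899) covering the early expedition era, twelve calendar decades,
and a closing bin (2020–2025).  Species richness is the number of distinct
accepted names in a stratum, occurrences the record count, and abundance
the sum of per-record individual counts (a record with a missing or zero
individualCount contributes 1 occurrence and, by default, 0 individuals —
the rule is configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: (first_year, last_year) of the 14 decade bins, in order
DECADE_BINS: tuple[tuple[int, int], ...] = (
    (1876, 1899),
    *((y, y + 9) for y in range(1900, 2020, 10)),
    (2020, 2025),
)
DECADE_LABELS = tuple(f"{a}-{b}" for a, b in DECADE_BINS)
OUT_OF_WINDOW = "out-of-window"

DATASET_STRATA = (
    "shallow",
    "deep",
    "shallow-planktonic",
    "shallow-benthic",
    "deep-planktonic",
    "deep-benthic",
)


def assign_decade(year) -> pd.Series | str | None:
    """Decade-bin label for a year; None (scalar) / <NA> (vector) when the
    year is missing or outside 1876–2025 (such records are excluded from
    per-decade outputs but remain in overall totals)."""
    scalar = np.isscalar(year) or year is None
    years = pd.to_numeric(pd.Series([year] if scalar else year), errors="coerce")
    edges = [a for a, _ in DECADE_BINS] + [DECADE_BINS[-1][1] + 1]
    idx = pd.cut(years, bins=edges, labels=False, right=False)
    labels = idx.map(lambda i: DECADE_LABELS[int(i)] if pd.notna(i) else pd.NA)
    labels = labels.astype("string")
    if scalar:
        v = labels.iloc[0]
        return None if pd.isna(v) else str(v)
    labels.index = year.index if isinstance(year, pd.Series) else labels.index
    return labels


def assign_lat_band(lat, lat_min: float, width: float = 1.0) -> pd.Series:
    """Latitude-band index (0 at ``lat_min``, increasing northwards),
    half-open bands of ``width`` degrees."""
    if width <= 0:
        raise ValueError("band width must be positive")
    lat = pd.to_numeric(pd.Series(lat), errors="coerce")
    band = np.floor((lat - lat_min) / width)
    return pd.Series(pd.array(band, dtype="Int64"), index=lat.index, name="lat_band")


def summarize(
    table: pd.DataFrame,
    axis: str,
    strata_columns: tuple[str, ...] = ("dataset", "decade"),
    abundance_missing: str = "zero",
) -> pd.DataFrame:
    """Richness / occurrences / abundance per (stratum, axis bin).

    ``axis`` is ``"lat_band"`` or ``"depth_zone"`` (a column of the table).
    Abundance sums individualCount per record; missing or zero counts
    contribute 0 when ``abundance_missing="zero"`` (default) or 1 when
    ``"one"``.  Rows with a missing axis or stratum value are omitted.
    """
    if axis not in ("lat_band", "depth_zone"):
        raise ValueError(f"unknown summary axis: {axis!r}")
    if abundance_missing not in ("zero", "one"):
        raise ValueError("abundance_missing must be 'zero' or 'one'")
    if "dataset" in strata_columns:
        bad = set(table["dataset"].dropna().unique()) - set(DATASET_STRATA)
        if bad:
            raise ValueError(f"unknown dataset strata: {sorted(bad)}")
    cols = [*strata_columns, axis]
    work = table.dropna(subset=cols).copy()
    count = pd.to_numeric(work.get("individualCount"), errors="coerce")
    fill = 0.0 if abundance_missing == "zero" else 1.0
    work["_abund"] = count.replace(0, np.nan).fillna(fill)
    grouped = work.groupby(cols, observed=True)
    out = grouped.agg(
        richness=("accepted_name", "nunique"),
        occurrences=("accepted_name", "size"),
        abundance=("_abund", "sum"),
    ).reset_index()
    return out


def accumulation_curve(
    table: pd.DataFrame,
    band_column: str = "lat_band",
    name_column: str = "accepted_name",
) -> pd.DataFrame:
    """Cumulative distinct accepted names over ordered latitude bands
    (south → north).  The curve is non-decreasing and its final value is
    the stratum's total richness.  Bands with no records appear with the
    running total carried forward."""
    work = table.dropna(subset=[band_column])
    if work.empty:
        return pd.DataFrame(columns=[band_column, "cumulative_richness"])
    bands = np.arange(int(work[band_column].min()), int(work[band_column].max()) + 1)
    seen: set = set()
    rows = []
    by_band = {b: g[name_column].dropna() for b, g in work.groupby(band_column)}
    for b in bands:
        if b in by_band:
            seen.update(by_band[b])
        rows.append({band_column: int(b), "cumulative_richness": len(seen)})
    return pd.DataFrame(rows)
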