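"""Exact deduplication, outlier exclusion, and attrition accounting.

Duplicates are rows agreeing on the 7-column key (decimalLatitude,
decimalLongitude, depth, day, month, year, scientificName); the first row
in stable input order is kept.  Missing values participate in the key as a
single canonical missing marker, so two rows both lacking depth can still
be duplicates of each other.  Outliers are records outside the AOI polygon
(geographic) or deeper than the region's deepest point, 5569 m (depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geospatial import AOIMask

DEDUP_KEY = [
    "decimalLatitude",
    "decimalLongitude",
    "depth",
    "day",
    "month",
    "year",
    "scientificName",
]

MAX_DEPTH = 5569.0


def deduplicate(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep exactly one record per distinct 7-tuple key (first in stable
    input order); return the deduplicated table and the number removed.

    Missing values compare equal to each other within the key, matching the
    canonical-missing-marker convention used at ingest.
    """
    missing = [c for c in DEDUP_KEY if c not in table.columns]
    if missing:
        raise KeyError(f"dedup key columns absent: {missing}")
    keep = ~table.duplicated(subset=DEDUP_KEY, keep="first")
    return table.loc[keep], int((~keep).sum())


def remove_outliers(
    table: pd.DataFrame,
    mask: AOIMask,
    max_depth: float = MAX_DEPTH,
) -> tuple[pd.DataFrame, int, int]:
    """Exclude geographic outliers (outside the AOI polygon) and depth
    outliers (recorded depth > ``max_depth``); counted separately.

    A record failing both checks counts as a geographic outlier."""
    lat = pd.to_numeric(table["decimalLatitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(table["decimalLongitude"], errors="coerce").to_numpy()
    pts = shapely.points(lon, lat)
    shapely.prepare(mask.aoi_polygon)
    inside = shapely.covers(mask.aoi_polygon, pts)
    geo_out = ~inside
    depth = pd.to_numeric(table.get("depth"), errors="coerce").to_numpy(dtype=float)
    depth_out = np.isfinite(depth) & (depth > max_depth) & inside
    kept = table.loc[~(geo_out | depth_out)]
    return kept, int(geo_out.sum()), int(depth_out.sum())


@dataclass
class AttritionReport:
    """Stage-by-stage accounting of records retained vs excluded.

    Each stage records rows_in, rows_out and a bucket breakdown of the
    exclusions; consecutive stages must chain (rows_in of stage k+1 equals
    rows_out of stage k) and every stage must balance
    (rows_out = rows_in − rows_excluded).
    """

    stages: list[dict] = field(default_factory=list)

    def add_stage(
        self, name: str, rows_in: int, rows_out: int, buckets: dict[str, int] | None = None
    ) -> None:
        buckets = {k: int(v) for k, v in (buckets or {}).items()}
        excluded = rows_in - rows_out
        if excluded != sum(buckets.values()) and buckets:
            raise ValueError(
                f"stage {name!r}: buckets sum to {sum(buckets.values())}, "
                f"but rows_in - rows_out = {excluded}"
            )
        if excluded < 0:
            raise ValueError(f"stage {name!r}: rows_out exceeds rows_in")
        if self.stages and self.stages[-1]["rows_out"] != rows_in:
            raise ValueError(
                f"stage {name!r}: rows_in={rows_in} does not chain from "
                f"previous rows_out={self.stages[-1]['rows_out']}"
            )
        self.stages.append(
            {
                "stage": name,
                "rows_in": int(rows_in),
                "rows_out": int(rows_out),
                "rows_excluded": int(excluded),
                "buckets": buckets,
            }
        )

    @property
    def total_excluded(self) -> int:
        return sum(s["rows_excluded"] for s in self.stages)

    def bucket_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.stages:
            for k, v in s["buckets"].items():
                out[k] = out.get(k, 0) + v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            base = {k: s[k] for k in ("stage", "rows_in", "rows_out", "rows_excluded")}
            if s["buckets"]:
                for bucket, n in s["buckets"].items():
                    rows.append({**base, "bucket": bucket, "bucket_rows": n})
            else:
                rows.append({**base, "bucket": "", "bucket_rows": 0})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
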