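"""Seeded synthetic occurrence tables, registries, bathymetry and masks.

The generator emulates the structure of a multi-source occurrence export
over a marine study region with a pronounced continental shelf break: a
shelf shallower than 500 m east of ``shelf_break_lon``, a slope, and a
basin deeper than 500 m to the west, never exceeding the region's deepest
point (5569 m).  Controlled fractions of records are planted with known
anomalies — missing depth, missing coordinates, on-land and out-of-area
points, exact duplicates under the 7-column key, non-marine and unaccepted
names, below-seafloor depths, depth outliers, and geographically misplaced
deep records over the shelf — so that every record's fate through the
quality-control pipeline (exclusion bucket, contour and raster labels, grid
cell, decade, depth zone) is known by construction and written to a truth
sidecar table.

All randomness flows from one explicitly passed seeded generator; identical
seed and configuration give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geospatial import AOIMask
from .ingest import DIALECTS, UNIFIED_COLUMNS
from .raster import BathymetryGrid
from .taxonomy import REGISTRY_COLUMNS, TaxonRegistry

#: anomaly classes the generator can plant, as proportions of n_records.
#: The first nine are planted record placements that a QC stage must catch
#: or classify; the last two are attributes painted onto retained records.
FRACTION_KEYS = (
    "missing_depth",
    "on_land",
    "outside_aoi",
    "duplicate",
    "non_marine_name",
    "unaccepted_synonym",
    "below_seafloor",
    "depth_outlier",
    "missing_individual_count",
    "missing_coordinates",
    "south_of_ridge",
    "shallow_from_deep",
    "coastal_gap",
    "non_species_rank",
)

#: study-condition defaults; several anchored to the proportions the source
#: datasets show (about half of retained records lacking depth, ~8%
#: duplicates, ~13% missing individual counts, below-seafloor depths the
#: largest single depth-quality problem).
DEFAULT_FRACTIONS: dict[str, float] = {
    "missing_depth": 0.25,
    "on_land": 0.05,
    "outside_aoi": 0.04,
    "duplicate": 0.08,
    "non_marine_name": 0.06,
    "unaccepted_synonym": 0.05,
    "below_seafloor": 0.10,
    "depth_outlier": 0.002,
    "missing_individual_count": 0.13,
    "missing_coordinates": 0.01,
    "south_of_ridge": 0.03,
    "shallow_from_deep": 0.005,
    "coastal_gap": 0.01,
    "non_species_rank": 0.05,
}

#: relative sampling intensity of the 14 decade bins (oldest → newest),
#: mirroring the steep growth of digitized occurrence data over time.
DEFAULT_DECADE_WEIGHTS = (
    7.5, 28.3, 8.0, 14.3, 24.2, 9.2, 84.4,
    73.9, 346.3, 846.9, 1880.4, 2578.4, 3541.6, 1877.3,
)

TRUTH_COLUMNS = [
    "record_id",
    "true_contour_label",
    "true_raster_label",
    "true_cell_id",
    "true_decade",
    "true_depth_zone",
    "is_duplicate",
    "is_marine",
    "exclusion_bucket",
]

_PLACEMENTS = (
    "missing_coordinates",
    "outside_aoi",
    "south_of_ridge",
    "on_land",
    "non_species_rank",
    "non_marine_name",
    "shallow_from_deep",
    "below_seafloor",
    "depth_outlier",
    "coastal_gap",
    "missing_depth",
    "duplicate",
)

_MARGIN = 0.05  # degrees kept clear of strip edges when planting


def zero_fractions() -> dict[str, float]:
    """An all-zero fraction map (every record clean)."""
    return {k: 0.0 for k in FRACTION_KEYS}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic run.

    ``aoi_bounds`` is (lat_min, lat_max, lon_min, lon_max) in degrees.
    ``fractions`` entries override :data:`DEFAULT_FRACTIONS`; unknown keys
    are rejected.  ``shelf_break_lon`` is the longitude east of which the
    synthetic seafloor is shallower than 500 m (default: mid-AOI).
    ``resolution`` is the raster pixel size in degrees (default 15
    arc-seconds).  ``land_lon`` marks the synthetic coastline (land east of
    it); ``raster_gap_lon`` is where raster coverage already ends, slightly
    seaward of the coastline, leaving a coastal strip that is marine by the
    vector mask but uncovered by the raster — the situation the coastal
    fallback rule exists for.
    """

    seed: int = 0
    n_records: int = 5000
    aoi_bounds: tuple[float, float, float, float] = (60.0, 64.0, 0.0, 8.0)
    fractions: dict[str, float] = field(default_factory=dict)
    benthic_fraction: float = 0.05
    decade_weights: tuple[float, ...] = DEFAULT_DECADE_WEIGHTS
    shelf_break_lon: float | None = None
    resolution: float = 1.0 / 240.0
    default_tolerance: float = 10.0
    max_depth: float = 5540.0
    ridge_lat: float | None = None
    land_lon: float | None = None
    raster_gap_lon: float | None = None
    grid_cell_size: float = 0.1
    depth_accuracy_fraction: float = 0.5
    coordinate_uncertainty_fraction: float = 0.39
    n_marine_names: int = 150
    n_nonmarine_names: int = 40
    n_synonym_names: int = 50

    def __post_init__(self) -> None:
        lat0, lat1, lon0, lon1 = self.aoi_bounds
        if not (lat1 > lat0 and lon1 > lon0):
            raise ValueError("degenerate aoi_bounds: zero or negative extent")
        unknown = set(self.fractions) - set(FRACTION_KEYS)
        if unknown:
            raise ValueError(f"unknown fraction keys: {sorted(unknown)}")
        merged = {**DEFAULT_FRACTIONS, **self.fractions}
        for k, v in merged.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {k!r} = {v} outside [0, 1]")
        self.fractions = merged
        if not 0.0 <= self.benthic_fraction <= 1.0:
            raise ValueError("benthic_fraction outside [0, 1]")
        if len(self.decade_weights) != 14:
            raise ValueError("decade_weights must have exactly 14 entries")
        if any(w < 0 for w in self.decade_weights):
            raise ValueError("decade_weights must be nonnegative")
        if self.max_depth > 5569.0:
            raise ValueError("max synthetic seafloor depth cannot exceed 5569 m")
        if self.shelf_break_lon is None:
            self.shelf_break_lon = (lon0 + lon1) / 2.0
        if self.ridge_lat is None:
            self.ridge_lat = lat0 + 0.1 * (lat1 - lat0)
        if self.land_lon is None:
            self.land_lon = lon1 - 0.05 * (lon1 - lon0)
        if self.raster_gap_lon is None:
            self.raster_gap_lon = self.land_lon - 0.025 * (lon1 - lon0)
        if not lon0 < self.shelf_break_lon < self.raster_gap_lon < self.land_lon <= lon1:
            raise ValueError(
                "longitudes must order as lon_min < shelf_break_lon < "
                "raster_gap_lon < land_lon <= lon_max"
            )


def make_masks(config: SyntheticConfig) -> AOIMask:
    """AOI rectangle plus the synthetic ridge and coastline masks."""
    lat0, lat1, lon0, lon1 = config.aoi_bounds
    return AOIMask(
        aoi_polygon=box(lon0, lat0, lon1, lat1),
        ridge_polygon=box(lon0, lat0, lon1, config.ridge_lat),
        land_polygons=box(config.land_lon, lat0, lon1, lat1),
        bbox=(lat0, lat1, lon0, lon1),
    )


def generate_bathymetry(config: SyntheticConfig) -> BathymetryGrid:
    """Seeded shelf–slope–basin seafloor over the AOI.

    The surface is a smooth parametric ramp in longitude (shelf east of the
    break, basin west of it) plus low-amplitude seeded sinusoidal noise,
    then clipped so that every marine pixel east of ``shelf_break_lon`` is
    strictly shallower than 500 m and every pixel west of it is at least
    500 m deep — the ground truth must be analytically known.  Pixels east
    of ``raster_gap_lon`` (the coastal strip and the land) carry no data.
    """
    lat0, lat1, lon0, lon1 = config.aoi_bounds
    res = config.resolution
    nrows = math.ceil(round((lat1 - lat0) / res, 9))
    ncols = math.ceil(round((lon1 - lon0) / res, 9))
    lats = lat1 - (np.arange(nrows) + 0.5) * res
    lons = lon0 + (np.arange(ncols) + 0.5) * res
    lon_g, lat_g = np.meshgrid(lons, lats)

    brk = config.shelf_break_lon
    e_span = max(config.raster_gap_lon - brk, 1e-9)
    w_span = max(brk - lon0, 1e-9)
    east = 460.0 - 420.0 * (lon_g - brk) / e_span
    west = 520.0 + (config.max_depth - 40.0 - 520.0) * (brk - lon_g) / w_span
    base = np.where(lon_g > brk, east, west)

    rng = np.random.default_rng([config.seed, 101])
    noise = np.zeros_like(base)
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 3.0, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        noise += rng.uniform(2.0, 6.0) * np.sin(
            fx * (lon_g - lon0) + px
        ) * np.sin(fy * (lat_g - lat0) + py)

    depth = base + noise
    is_east = lon_g > brk
    depth = np.where(is_east, np.clip(depth, 40.0, 499.0), depth)
    depth = np.where(~is_east, np.clip(depth, 500.0, config.max_depth), depth)
    depth[lon_g > config.raster_gap_lon] = np.nan   # coastal gap + land
    return BathymetryGrid(depth=depth, lat_min=lat0, lon_min=lon0, cellsize=res)


# ----------------------------------------------------------------- registry

_GENUS_SYL = ("Abr", "Cal", "Nep", "Ophi", "Tha", "Myt", "Lim", "Sab",
              "Hya", "Pol", "Ast", "Gon")
_GENUS_TAIL = ("a", "anus", "ella", "ia", "odes", "ura", "ina", "ops")
_EPITHET_SYL = ("al", "bor", "mar", "nor", "pro", "ten", "vul", "gla",
                "fus", "lat", "min", "seg")
_EPITHET_TAIL = ("ba", "cialis", "funda", "tus", "rei", "icus", "osa", "ens")
_AUTHORS = ("Sars", "M. Sars", "Danielssen", "Friele", "Mohn", "Storm")


def _make_names(rng: np.random.Generator, n: int, used: set[str]) -> list[str]:
    names: list[str] = []
    while len(names) < n:
        genus = rng.choice(_GENUS_SYL) + rng.choice(_GENUS_TAIL)
        epithet = rng.choice(_EPITHET_SYL) + rng.choice(_EPITHET_TAIL)
        name = f"{genus} {epithet.lower()}"
        if name not in used:
            used.add(name)
            names.append(name)
    return names


def generate_registry(
    n_marine: int, n_nonmarine: int, n_synonyms: int, seed: int
) -> TaxonRegistry:
    """Registry dump with accepted marine names, accepted non-marine names,
    and unaccepted synonyms each pointing at an accepted marine name."""
    if min(n_marine, n_nonmarine, n_synonyms) < 0:
        raise ValueError("registry composition counts must be nonnegative")
    if n_synonyms > 0 and n_marine == 0:
        raise ValueError("synonyms need at least one accepted marine name")
    rng = np.random.default_rng([seed, 202])
    used: set[str] = set()
    marine = _make_names(rng, n_marine, used)
    nonmarine = _make_names(rng, n_nonmarine, used)
    synonyms = _make_names(rng, n_synonyms, used)
    rows = []
    for name in marine:
        rows.append((name, "accepted", name, True, "Species"))
    for name in nonmarine:
        rows.append((name, "accepted", name, False, "Species"))
    for name in synonyms:
        target = marine[int(rng.integers(len(marine)))]
        rows.append((name, "unaccepted", target, True, "Species"))
    frame = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    return TaxonRegistry(frame)


# -------------------------------------------------------------- occurrences

def generate_occurrences(
    config: SyntheticConfig,
    bathy: BathymetryGrid,
    registry: TaxonRegistry,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence table plus its complete truth sidecar.

    Every planted anomaly count is ``round(fraction * n_records)``, so the
    realized fraction differs from the requested one by less than
    ``1 / n_records``.  Records are shuffled into a seeded random order and
    assigned per-source sequential ids afterwards, so duplicates are
    interleaved with everything else; within each planted duplicate family
    the first record in final order is the one the keep-first rule retains,
    and the truth table marks the others.
    """
    lat0, lat1, lon0, lon1 = config.aoi_bounds
    if not (
        bathy.lat_min <= lat0 and bathy.lat_max >= lat1
        and bathy.lon_min <= lon0 and bathy.lon_max >= lon1
    ):
        raise ValueError("bathymetry raster does not cover aoi_bounds")
    n = config.n_records
    f = config.fractions
    counts = {k: round(f[k] * n) for k in _PLACEMENTS}
    n_clean = n - sum(counts.values())
    if n_clean < 0:
        raise ValueError(
            "fractions sum to an unsatisfiable composition: planted "
            f"records ({sum(counts.values())}) exceed n_records ({n})"
        )
    n_retained_seed = n_clean + counts["missing_depth"] + counts["coastal_gap"]
    if counts["duplicate"] > 0 and n_retained_seed == 0:
        raise ValueError("duplicates need at least one retained record to copy")
    n_syn = round(f["unaccepted_synonym"] * n)
    if n_syn > n_retained_seed:
        raise ValueError("unaccepted_synonym fraction exceeds retained records")

    rng = np.random.default_rng([config.seed, 303])
    marine_names = [
        r.scientificName
        for r in registry.frame.itertuples()
        if r.taxonomicStatus == "accepted" and bool(r.isMarine)
    ]
    nonmarine_names = [
        r.scientificName for r in registry.frame.itertuples() if not bool(r.isMarine)
    ]
    synonym_names = [
        r.scientificName
        for r in registry.frame.itertuples()
        if r.taxonomicStatus == "unaccepted"
    ]
    if not marine_names:
        raise ValueError("registry holds no accepted marine names")
    if counts["non_marine_name"] > 0 and not nonmarine_names:
        raise ValueError("non_marine_name fraction > 0 but registry has none")
    if n_syn > 0 and not synonym_names:
        raise ValueError("unaccepted_synonym fraction > 0 but registry has none")
    marine_w = 1.0 / np.arange(1, len(marine_names) + 1)
    marine_w /= marine_w.sum()

    brk, gap, land = config.shelf_break_lon, config.raster_gap_lon, config.land_lon
    ridge = config.ridge_lat
    m = min(_MARGIN, 0.2 * (gap - brk), 0.2 * (land - gap), 0.2 * (ridge - lat0))
    if bathy.cellsize >= 2 * m:
        raise ValueError(
            "raster resolution too coarse relative to the planting margins: "
            "pixel centers could cross the shelf break or coverage edges"
        )
    clean_lat = (ridge + m, lat1 - m)
    clean_lon = (lon0 + m, gap - m)
    w_span = brk - lon0

    def uni(lo, hi, k):
        return rng.uniform(lo, hi, size=k)

    frames: list[pd.DataFrame] = []

    def base_frame(k: int, bucket: str | None, lat, lon) -> pd.DataFrame:
        d = pd.DataFrame(index=range(k))
        d["decimalLatitude"] = lat
        d["decimalLongitude"] = lon
        d["depth"] = np.nan
        d["depthAccuracy"] = np.nan
        d["scientificName"] = rng.choice(marine_names, size=k, p=marine_w)
        d["taxonRank"] = rng.choice(["Species", "SPECIES", "species"], size=k)
        d["exclusion_bucket"] = bucket
        d["is_marine"] = True
        d["true_contour_label"] = None
        d["true_raster_label"] = None
        d["_retained"] = False
        d["_dup_group"] = -1
        return d

    def clean_placement(k):
        return uni(*clean_lat, k), uni(*clean_lon, k)

    # --- excluded at masking -------------------------------------------
    k = counts["missing_coordinates"]
    d = base_frame(k, "no_coordinates", np.full(k, np.nan), np.full(k, np.nan))
    frames.append(d)

    k = counts["outside_aoi"]
    d = base_frame(k, "outside_aoi", uni(lat1 + 0.2, lat1 + 1.0, k), uni(lon0, lon1, k))
    frames.append(d)

    k = counts["south_of_ridge"]
    d = base_frame(k, "south_of_ridge", uni(lat0 + m / 2, ridge - m, k),
                   uni(lon0 + m, gap - m, k))
    frames.append(d)

    k = counts["on_land"]
    d = base_frame(k, "on_land", uni(ridge + m, lat1 - m, k),
                   uni(land + m / 2, lon1 - m / 2, k))
    frames.append(d)

    # --- excluded at taxonomy ------------------------------------------
    k = counts["non_species_rank"]
    d = base_frame(k, "non_species_rank", *clean_placement(k))
    d["taxonRank"] = rng.choice(["Genus", "GENUS", "Family", ""], size=k)
    frames.append(d)

    k = counts["non_marine_name"]
    d = base_frame(k, "non_marine", *clean_placement(k))
    if k:
        d["scientificName"] = rng.choice(nonmarine_names, size=k)
    d["is_marine"] = False
    frames.append(d)

    # --- excluded at depth analysis ------------------------------------
    k = counts["shallow_from_deep"]
    lat = uni(*clean_lat, k)
    lon = uni(brk + m, gap - m, k)          # over the shelf (< 500 m)
    d = base_frame(k, "shallow_from_deep_set", lat, lon)
    d["depth"] = uni(500.0, 1500.0, k)      # contradicts the shallow location
    d["true_contour_label"] = "shallowFromDeepSet"
    frames.append(d)

    k = counts["below_seafloor"]
    lat = uni(*clean_lat, k)
    lon = uni(lon0 + 0.1 * w_span + m, brk - m, k)   # basin, seafloor <= ~5100 m
    acc = np.where(rng.random(k) < config.depth_accuracy_fraction,
                   uni(2.0, 20.0, k), np.nan)
    tau = np.where(np.isfinite(acc), acc, config.default_tolerance)
    s = bathy.sample(lat, lon)
    d = base_frame(k, "below_depth", lat, lon)
    d["depth"] = s + tau + uni(2.0, 40.0, k)
    d["depthAccuracy"] = acc
    d["true_contour_label"] = "matchDeep"
    d["true_raster_label"] = "tiffBelowDepth"
    frames.append(d)

    # --- excluded at outlier removal ------------------------------------
    # depth outliers are planted in the coastal raster gap: with no raster
    # pixel they cannot be caught as below-seafloor, so they reach (and
    # must be caught by) the depth-outlier filter.
    k = counts["depth_outlier"]
    d = base_frame(k, "depth_outlier", uni(*clean_lat, k), uni(gap + m / 2, land - m / 2, k))
    d["depth"] = uni(5570.0, 6800.0, k)
    d["true_contour_label"] = "matchShallow"
    d["true_raster_label"] = "noRasterCoverage"
    frames.append(d)

    # --- retained records ----------------------------------------------
    k = counts["coastal_gap"]
    d = base_frame(k, None, uni(*clean_lat, k), uni(gap + m / 2, land - m / 2, k))
    d["depth"] = uni(5.0, 300.0, k)
    d["true_contour_label"] = "matchShallow"
    d["true_raster_label"] = "noRasterCoverage"
    d["_retained"] = True
    frames.append(d)

    k = counts["missing_depth"]
    lat, lon = clean_placement(k)
    s = bathy.sample(lat, lon)
    d = base_frame(k, None, lat, lon)
    d["true_contour_label"] = np.where(s < 500.0, "matchShallow", "matchDeep")
    d["_retained"] = True
    d["_seafloor"] = s
    frames.append(d)

    k = n_clean
    lat, lon = clean_placement(k)
    s = bathy.sample(lat, lon)
    acc = np.where(rng.random(k) < config.depth_accuracy_fraction,
                   uni(2.0, 20.0, k), np.nan)
    tau = np.where(np.isfinite(acc), acc, config.default_tolerance)
    benthic = rng.random(k) < config.benthic_fraction
    depth = np.where(
        benthic,
        s + (rng.random(k) * 1.8 - 0.9) * tau,     # |d - s| <= 0.9 tau < tau
        uni(0.5, 1.0, k) * np.maximum(s - tau - 2.0, 1.0),
    )
    depth = np.clip(depth, 0.1, None)
    d = base_frame(k, None, lat, lon)
    d["depth"] = depth
    d["depthAccuracy"] = acc
    d["true_contour_label"] = np.where(s < 500.0, "matchShallow", "matchDeep")
    d["true_raster_label"] = np.where(benthic, "tiffBenthos", "tiffPlankton")
    d["_retained"] = True
    d["_seafloor"] = s
    frames.append(d)

    table = pd.concat(frames, ignore_index=True)

    # synonym names painted onto a random subset of retained records
    retained_idx = table.index[table["_retained"]].to_numpy()
    if n_syn:
        syn_idx = rng.choice(retained_idx, size=n_syn, replace=False)
        table.loc[syn_idx, "scientificName"] = rng.choice(synonym_names, size=n_syn)

    # authorship strings appended to a fifth of all names (the registry
    # keys on canonical binomials; resolution must strip these)
    with_auth = rng.random(len(table)) < 0.2
    authors = rng.choice(_AUTHORS, size=len(table))
    years = rng.integers(1850, 1950, size=len(table))
    table.loc[with_auth, "scientificName"] = [
        f"{nm} ({au}, {yr})"
        for nm, au, yr in zip(
            table.loc[with_auth, "scientificName"],
            authors[with_auth],
            years[with_auth],
        )
    ]

    # --- dates, counts, provenance --------------------------------------
    k = len(table)
    weights = np.asarray(config.decade_weights, dtype=float)
    weights = weights / weights.sum()
    from .summaries import DECADE_BINS, DECADE_LABELS

    dec_idx = rng.choice(len(DECADE_BINS), size=k, p=weights)
    y0 = np.asarray([DECADE_BINS[i][0] for i in dec_idx])
    y1 = np.asarray([DECADE_BINS[i][1] for i in dec_idx])
    table["year"] = rng.integers(y0, y1 + 1)
    table["month"] = rng.integers(1, 13, size=k)
    table["day"] = rng.integers(1, 29, size=k)
    table["eventDate"] = [
        f"{y:04d}-{mo:02d}-{dy:02d}"
        for y, mo, dy in zip(table["year"], table["month"], table["day"])
    ]
    table["dateIdentified"] = table["eventDate"]
    table["true_decade"] = [DECADE_LABELS[i] for i in dec_idx]

    n_noic = min(round(f["missing_individual_count"] * n), k)
    ic = 1.0 + rng.poisson(3.0, size=k)
    noic_idx = rng.choice(k, size=n_noic, replace=False)
    ic[noic_idx] = np.where(rng.random(n_noic) < 0.5, np.nan, 0.0)
    table["individualCount"] = ic

    has_cu = rng.random(k) < config.coordinate_uncertainty_fraction
    table["coordinateUncertaintyInMeters"] = np.where(
        has_cu, np.round(uni(1.0, 1000.0, k)), np.nan
    )
    table["coordinatePrecision"] = np.nan
    table["kingdom"] = "Animalia"
    table["class"] = rng.choice(["Polychaeta", "Copepoda", "Gastropoda", "Asteroidea"], size=k)
    table["family"] = rng.choice(["Nephtyidae", "Calanidae", "Buccinidae", "Asteriidae"], size=k)
    table["basisOfRecord"] = rng.choice(
        ["HumanObservation", "PreservedSpecimen", "MaterialSample"], size=k
    )
    table["collectionCode"] = rng.choice(["SIM-A", "SIM-B"], size=k)
    table["catalogNumber"] = [f"CAT{i:07d}" for i in range(k)]
    table["flags"] = np.where(table["depth"].isna(), "NO_DEPTH", "")
    table["issue"] = ""
    table["source"] = rng.choice(["gbif-like", "obis-like"], size=k, p=[0.65, 0.35])
    table["dataset"] = "synthetic-" + table["source"]

    # --- duplicates: exact copies of retained records under the 7-key ---
    n_dup = counts["duplicate"]
    if n_dup:
        src = rng.choice(retained_idx, size=n_dup, replace=True)
        copies = table.loc[src].copy()
        group_of_src = {int(s): g for g, s in enumerate(dict.fromkeys(src.tolist()))}
        table.loc[list(group_of_src), "_dup_group"] = [
            group_of_src[int(s)] for s in group_of_src
        ]
        copies["_dup_group"] = [group_of_src[int(s)] for s in src]
        # copies stay in their original's source: the keep-first rule is
        # then decided by within-source order, which the per-dialect files
        # preserve, so the planted "removed" member is well defined
        table = pd.concat([table, copies], ignore_index=True)

    # --- seeded shuffle, then ids and duplicate bookkeeping --------------
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table["is_duplicate"] = False
    grouped = table.index[table["_dup_group"] >= 0]
    for _, idx in table.loc[grouped].groupby("_dup_group").groups.items():
        later = list(idx)[1:]   # keep-first: only later copies are removed
        table.loc[later, "is_duplicate"] = True
        table.loc[later, "exclusion_bucket"] = "duplicate"
        table.loc[later, "_retained"] = False

    ids = np.empty(len(table), dtype=object)
    prefix = {"gbif-like": "G", "obis-like": "O"}
    for src_name, idx in table.groupby("source").groups.items():
        p = prefix[str(src_name)]
        ids[np.asarray(idx)] = [f"{p}{j + 1:07d}" for j in range(len(idx))]
    table["record_id"] = ids

    # --- remaining truth columns ----------------------------------------
    ncols_grid = math.ceil(round((lon1 - lon0) / config.grid_cell_size, 9))
    latv = table["decimalLatitude"].to_numpy(dtype=float)
    lonv = table["decimalLongitude"].to_numpy(dtype=float)
    row = np.floor((latv - lat0) / config.grid_cell_size)
    col = np.floor((lonv - lon0) / config.grid_cell_size)
    cell = row * ncols_grid + col
    depth_v = table["depth"].to_numpy(dtype=float)
    sea = table.get("_seafloor", pd.Series(np.nan, index=table.index)).to_numpy(dtype=float)
    zsrc = np.where(np.isfinite(depth_v), depth_v, sea)
    zone = np.where(
        zsrc < 500.0, 0.0, np.minimum(np.floor(zsrc / 500.0), 11.0)
    )
    retained = table["_retained"].to_numpy(dtype=bool)
    table["true_cell_id"] = pd.array(
        np.where(retained, cell, np.nan), dtype="Int64"
    )
    table["true_depth_zone"] = pd.array(
        np.where(retained & np.isfinite(zsrc), zone, np.nan), dtype="Int64"
    )
    table.loc[~retained, "true_decade"] = pd.NA

    truth = table[TRUTH_COLUMNS].copy()
    occurrence = table[UNIFIED_COLUMNS].copy()
    return occurrence, truth


# ------------------------------------------------------------------ writers

def write_occurrence_files(
    table: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Write the table as per-source dialect files (differing id columns and
    delimiters, as the real exports do).  Returns source → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ext = {"\t": "tsv", ",": "csv"}
    for source, part in table.groupby("source"):
        dialect = DIALECTS[str(source)]
        out = part.drop(columns=["source"]).rename(
            columns={"record_id": dialect.id_column}
        )
        sep = dialect.sep or ","
        path = outdir / f"occurrences_{str(source).split('-')[0]}.{ext[sep]}"
        out.to_csv(path, sep=sep, index=False, encoding="utf-8")
        paths[str(source)] = path
    return paths


def write_synthetic_inputs(
    config: SyntheticConfig, outdir: str | Path
) -> dict[str, object]:
    """Generate and write the full synthetic input bundle.

    Produces the bathymetry (ASCII grid), masks (GeoJSON), registry dump and
    empty override list (delimited), per-dialect occurrence files, and the
    truth sidecar; returns the in-memory objects plus the file map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bathy = generate_bathymetry(config)
    registry = generate_registry(
        config.n_marine_names,
        config.n_nonmarine_names,
        config.n_synonym_names,
        config.seed,
    )
    masks = make_masks(config)
    occurrence, truth = generate_occurrences(config, bathy, registry)

    paths: dict[str, Path] = {}
    paths["bathymetry"] = outdir / "bathymetry.asc"
    bathy.write_ascii(paths["bathymetry"])
    paths["masks"] = outdir / "masks.geojson"
    masks.to_geojson(paths["masks"])
    paths["registry"] = outdir / "registry.tsv"
    registry.write(paths["registry"])
    paths["overrides"] = outdir / "overrides.tsv"
    paths["overrides"].write_text("rawName\tacceptedName\n", encoding="utf-8")
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    for source, p in write_occurrence_files(occurrence, outdir).items():
        paths[source] = p
    return {
        "bathymetry": bathy,
        "registry": registry,
        "masks": masks,
        "occurrences": occurrence,
        "truth": truth,
        "paths": paths,
    }
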