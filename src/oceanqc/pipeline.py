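"""Config-driven, seeded, one-command execution of the full QC pipeline.

Stage order: ingest → ridge/land/AOI masking → species-rank filter → marine
name resolution → contour classification (drop ``shallowFromDeepSet``) →
raster classification (drop ``tiffBelowDepth``) → deduplication →
geographic/depth outliers → grid assignment → summaries.  Every stage logs
rows in/out and feeds the attrition report; a synthetic run additionally
writes a truth-vs-recovered comparison with per-label agreement rates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth import (
    MATCH_DEEP,
    MATCH_SHALLOW,
    SHALLOW_FROM_DEEP,
    TIFF_BELOW_DEPTH,
    TIFF_BENTHOS,
    TIFF_PLANKTON,
    classify_contour,
    classify_raster,
    derive_zone_polygons,
)
from .geospatial import (
    AOIMask,
    assign_cells,
    build_grid,
    category_histogram,
    mask_to_marine_aoi,
)
from .ingest import (
    harmonize,
    read_expedition_records,
    read_occurrence_table,
    source_counts,
    write_unified,
)
from .qc import AttritionReport, deduplicate, remove_outliers
from .raster import BathymetryGrid
from .summaries import (
    DATASET_STRATA,
    accumulation_curve,
    assign_decade,
    assign_lat_band,
    summarize,
)
from .synthetic import SyntheticConfig, write_synthetic_inputs
from .taxonomy import (
    ManualOverrideList,
    TaxonRegistry,
    filter_species_rank,
    resolve_marine,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the exit diagnostics."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs: either real input paths or a synthetic
    block (never neither), the analysis parameters, an output directory and
    the seed.  For a synthetic run the pipeline seed overrides the seed
    inside the synthetic block, so one number controls the whole run."""

    outdir: str
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    occurrence_files: list[dict] = field(default_factory=list)  # {path, dialect}
    expedition_file: str | None = None
    registry_file: str | None = None
    overrides_file: str | None = None
    bathymetry_file: str | None = None
    masks_file: str | None = None
    cell_size: float = 0.1
    zone_interval: float = 500.0
    default_tolerance: float = 10.0
    band_width: float = 1.0
    abundance_missing: str = "zero"
    max_outlier_depth: float = 5569.0
    species_rank_labels: tuple[str, ...] = ("species",)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synthetic is None and not self.occurrence_files:
            raise ValueError(
                "config must provide either occurrence_files or a synthetic block"
            )
        if self.synthetic is not None and self.occurrence_files:
            raise ValueError("synthetic block and occurrence_files are exclusive")
        for p in (self.cell_size, self.zone_interval, self.band_width):
            if p <= 0:
                raise ValueError("cell_size, zone_interval and band_width must be > 0")
        if self.default_tolerance < 0:
            raise ValueError("default_tolerance must be >= 0")
        if self.abundance_missing not in ("zero", "one"):
            raise ValueError("abundance_missing must be 'zero' or 'one'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if doc.get("synthetic") is not None:
            syn = dict(doc["synthetic"])
            for key in ("aoi_bounds", "decade_weights"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            doc["synthetic"] = SyntheticConfig(**syn)
        if "species_rank_labels" in doc:
            doc["species_rank_labels"] = tuple(doc["species_rank_labels"])
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    labeled: pd.DataFrame
    attrition: AttritionReport
    categories: pd.DataFrame
    summaries: pd.DataFrame
    curves: pd.DataFrame
    comparison: pd.DataFrame | None
    manifest: dict


def _stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    base, _, sub = stratum.partition("-")
    m = df["dataset"] == base
    if sub == "planktonic":
        m &= df["tiffmatch"] == TIFF_PLANKTON
    elif sub == "benthic":
        m &= df["tiffmatch"] == TIFF_BENTHOS
    return m


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        inputs = write_synthetic_inputs(synth, outdir / "inputs")
        bathy: BathymetryGrid = inputs["bathymetry"]
        registry: TaxonRegistry = inputs["registry"]
        mask: AOIMask = inputs["masks"]
        truth = inputs["truth"]
        overrides = None
        occ_files = [
            {"path": str(p), "dialect": src}
            for src, p in sorted(inputs["paths"].items())
            if src in ("gbif-like", "obis-like", "emodnet-like")
        ]
        expedition_file = None
        default_tolerance = synth.default_tolerance
    else:
        for name in ("registry_file", "bathymetry_file", "masks_file"):
            if getattr(config, name) is None:
                raise PipelineError("config", f"{name} is required for a real run")
        bathy = BathymetryGrid.read_ascii(config.bathymetry_file)
        registry = TaxonRegistry.read(config.registry_file)
        mask = AOIMask.from_geojson(config.masks_file)
        overrides = (
            ManualOverrideList.read(config.overrides_file, registry)
            if config.overrides_file
            else None
        )
        occ_files = config.occurrence_files
        expedition_file = config.expedition_file
        default_tolerance = config.default_tolerance

    attrition = AttritionReport()

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:   # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    # ---- ingest --------------------------------------------------------
    def _ingest():
        tables = [
            read_occurrence_table(spec["path"], spec["dialect"]) for spec in occ_files
        ]
        if expedition_file:
            tables.append(read_expedition_records(expedition_file))
        return harmonize(tables)

    table = stage("ingest", _ingest).reset_index(drop=True)
    n0 = len(table)
    per_source = source_counts(table) if n0 else {}
    attrition.add_stage("ingest", n0, n0, {})
    log.info("ingest: %d rows from %s", n0, per_source)
    # per-record exclusion bucket, keyed by ingest row; NA = still retained
    bucket_of = pd.Series(pd.NA, index=table.index, dtype="object")
    record_ids = table["record_id"].copy()

    # ---- masking -------------------------------------------------------
    retained, buckets = stage("masking", lambda: mask_to_marine_aoi(table, mask))
    for name, part in buckets.items():
        bucket_of.loc[part.index] = name
    attrition.add_stage(
        "ridge_land_aoi_mask",
        n0,
        len(retained),
        {k: len(v) for k, v in buckets.items()},
    )
    table = retained

    # ---- taxonomy ------------------------------------------------------
    rows_in = len(table)
    prev_index = table.index
    table, n_rank_dropped = stage(
        "rank_filter",
        lambda: filter_species_rank(table, set(config.species_rank_labels)),
    )
    bucket_of.loc[prev_index.difference(table.index)] = "non_species_rank"
    attrition.add_stage(
        "species_rank_filter", rows_in, len(table), {"non_species_rank": n_rank_dropped}
    )

    rows_in = len(table)
    prev_index = table.index
    resolve_input = table
    table, resolve_report = stage(
        "marine_resolution", lambda: resolve_marine(resolve_input, registry, overrides)
    )
    bucket_of.loc[prev_index.difference(table.index)] = "non_marine"
    attrition.add_stage(
        "marine_resolution",
        rows_in,
        len(table),
        {
            "non_marine": resolve_report["non-marine-dropped"],
            "unmatched": resolve_report["unmatched-dropped"],
        },
    )

    # ---- depth analysis ------------------------------------------------
    zones = stage(
        "contour_classification",
        lambda: derive_zone_polygons(bathy, config.zone_interval),
    )
    table = table.copy()
    table["matchContour"] = stage(
        "contour_classification", lambda: classify_contour(table, zones)
    )
    contour_labels = table["matchContour"].copy()
    rows_in = len(table)
    misplaced = table["matchContour"] == SHALLOW_FROM_DEEP
    bucket_of.loc[table.index[misplaced]] = "shallow_from_deep_set"
    table = table.loc[~misplaced]
    attrition.add_stage(
        "contour_classification",
        rows_in,
        len(table),
        {"shallow_from_deep_set": int(misplaced.sum())},
    )

    table = table.copy()
    table["tiffmatch"] = stage(
        "raster_classification",
        lambda: classify_raster(table, bathy, default_tolerance),
    )
    raster_labels = table["tiffmatch"].copy()
    rows_in = len(table)
    below = table["tiffmatch"] == TIFF_BELOW_DEPTH
    bucket_of.loc[table.index[below]] = "below_depth"
    table = table.loc[~below]
    attrition.add_stage(
        "raster_classification", rows_in, len(table), {"below_depth": int(below.sum())}
    )

    # ---- dedup + outliers ---------------------------------------------
    rows_in = len(table)
    prev_index = table.index
    dedup_input = table
    table, n_dup = stage("deduplication", lambda: deduplicate(dedup_input))
    bucket_of.loc[prev_index.difference(table.index)] = "duplicate"
    attrition.add_stage("deduplication", rows_in, len(table), {"duplicate": n_dup})

    rows_in = len(table)
    prev_index = table.index
    outlier_input = table
    table, n_geo, n_depth = stage(
        "outliers",
        lambda: remove_outliers(outlier_input, mask, config.max_outlier_depth),
    )
    out_idx = prev_index.difference(table.index)
    depth_vals = pd.to_numeric(outlier_input.loc[out_idx, "depth"], errors="coerce")
    bucket_of.loc[out_idx] = np.where(
        depth_vals > config.max_outlier_depth, "depth_outlier", "geo_outlier"
    )
    attrition.add_stage(
        "outliers", rows_in, len(table),
        {"geo_outlier": n_geo, "depth_outlier": n_depth},
    )

    # ---- grid + derived columns ----------------------------------------
    grid = stage("grid", lambda: build_grid(mask, config.cell_size))
    table = table.copy()
    table["cell_id"] = stage("grid", lambda: assign_cells(table, grid))
    n_uncelled = int(table["cell_id"].isna().sum())
    if n_uncelled:
        log.warning("%d retained record(s) fall in no grid cell", n_uncelled)

    table["dataset"] = table["matchContour"].map(
        {MATCH_SHALLOW: "shallow", MATCH_DEEP: "deep"}
    )
    table["decade"] = assign_decade(table["year"])
    lat_min = mask.bbox[0]
    table["lat_band"] = assign_lat_band(
        table["decimalLatitude"], lat_min, config.band_width
    )
    depth_v = pd.to_numeric(table["depth"], errors="coerce").to_numpy(dtype=float)
    seafloor = bathy.sample(
        pd.to_numeric(table["decimalLatitude"], errors="coerce").to_numpy(),
        pd.to_numeric(table["decimalLongitude"], errors="coerce").to_numpy(),
    )
    zsrc = np.where(np.isfinite(depth_v), depth_v, seafloor)
    zone = np.where(zsrc < 500.0, 0.0, np.minimum(np.floor(zsrc / 500.0), 11.0))
    # no depth and no raster: the coastal fallback put these in the shallow
    # dataset, whose zone is 0 by definition
    zone = np.where(
        np.isfinite(zsrc),
        zone,
        np.where(table["dataset"] == "shallow", 0.0, np.nan),
    )
    table["depth_zone"] = pd.array(zone, dtype="Int64")

    # ---- summaries -----------------------------------------------------
    def _summaries():
        parts = []
        for axis in ("lat_band", "depth_zone"):
            for stratum in DATASET_STRATA:
                sel = table.loc[_stratum_mask(table, stratum)].copy()
                sel["dataset"] = stratum
                if sel.empty:
                    continue
                out = summarize(
                    sel, axis, ("dataset", "decade"), config.abundance_missing
                )
                out.insert(0, "axis", axis)
                parts.append(out.rename(columns={axis: "bin"}))
        cols = ["axis", "dataset", "decade", "bin",
                "richness", "occurrences", "abundance"]
        if not parts:
            return pd.DataFrame(columns=cols)
        return pd.concat(parts, ignore_index=True)[cols]

    summaries = stage("summaries", _summaries)

    def _curves():
        rows = []
        for stratum in ("shallow", "deep"):
            sel = table.loc[_stratum_mask(table, stratum)]
            groups = [("all", sel)] + [
                (str(d), g) for d, g in sel.groupby("decade", observed=True)
            ]
            for decade, part in groups:
                curve = accumulation_curve(part, "lat_band")
                curve.insert(0, "decade", decade)
                curve.insert(0, "dataset", stratum)
                rows.append(curve)
        cols = ["dataset", "decade", "lat_band", "cumulative_richness"]
        if not rows:
            return pd.DataFrame(columns=cols)
        return pd.concat(rows, ignore_index=True)[cols]

    curves = stage("curves", _curves)

    def _categories():
        rows = []
        for stratum in DATASET_STRATA:
            sel = table.loc[_stratum_mask(table, stratum)].dropna(subset=["cell_id"])
            groups = [("all", sel)] + [
                (str(d), g) for d, g in sel.groupby("decade", observed=True)
            ]
            for decade, part in groups:
                hist = category_histogram(part.groupby("cell_id").size())
                for letter, n_cells in hist.items():
                    rows.append(
                        {
                            "dataset": stratum,
                            "decade": decade,
                            "category": letter,
                            "n_cells": n_cells,
                        }
                    )
        return pd.DataFrame(rows, columns=["dataset", "decade", "category", "n_cells"])

    categories = stage("categories", _categories)

    # ---- truth comparison (synthetic runs) -----------------------------
    comparison = None
    if truth is not None:
        contour_map = pd.Series(
            contour_labels.to_numpy(),
            index=record_ids.loc[contour_labels.index].to_numpy(),
        )
        raster_map = pd.Series(
            raster_labels.to_numpy(),
            index=record_ids.loc[raster_labels.index].to_numpy(),
        )
        bucket_map = pd.Series(
            bucket_of.to_numpy(), index=record_ids.to_numpy()
        )
        comparison = stage(
            "truth_comparison",
            lambda: _compare_truth(
                truth, table, bucket_map, contour_map, raster_map
            ),
        )

    manifest = {
        "tool": "oceanqc",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "rows_ingested": n0,
        "rows_retained": len(table),
        "per_source_rows": per_source,
        "bucket_totals": attrition.bucket_totals(),
        "n_grid_cells": grid.n_cells,
        "resolve_report": resolve_report,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    return ReportBundle(
        labeled=table,
        attrition=attrition,
        categories=categories,
        summaries=summaries,
        curves=curves,
        comparison=comparison,
        manifest=manifest,
    )


def _compare_truth(
    truth: pd.DataFrame,
    table: pd.DataFrame,
    bucket_map: pd.Series,
    contour_map: pd.Series,
    raster_map: pd.Series,
) -> pd.DataFrame:
    """Per-label agreement rates between planted truth and recovery.

    Contour and raster labels are compared for every record that reached the
    respective classification stage (including records excluded later);
    grid cell, decade and depth zone only exist for finally retained
    records, where the truth defines them.
    """
    merged = truth.merge(
        table[["record_id", "cell_id", "decade", "depth_zone"]],
        on="record_id",
        how="left",
    )
    merged["rec_bucket"] = (
        merged["record_id"].map(bucket_map).fillna("retained")
    )
    merged["true_bucket"] = merged["exclusion_bucket"].fillna("retained")
    merged["rec_contour"] = merged["record_id"].map(contour_map)
    merged["rec_raster"] = merged["record_id"].map(raster_map)

    rows = []

    def add(label, truth_col, rec_col):
        comparable = merged[truth_col].notna()
        n = int(comparable.sum())
        agree = int(
            (
                merged.loc[comparable, truth_col].astype("string")
                == merged.loc[comparable, rec_col].astype("string")
            ).sum()
        )
        rows.append(
            {
                "label": label,
                "n_comparable": n,
                "n_agree": agree,
                "agreement": 1.0 if n == 0 else agree / n,
            }
        )

    add("exclusion_bucket", "true_bucket", "rec_bucket")
    add("contour_label", "true_contour_label", "rec_contour")
    add("raster_label", "true_raster_label", "rec_raster")
    add("cell_id", "true_cell_id", "cell_id")
    add("decade", "true_decade", "decade")
    add("depth_zone", "true_depth_zone", "depth_zone")
    return pd.DataFrame(rows)


def write_report(bundle: ReportBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the report bundle under fixed file names; returns the file map."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("", encoding="utf-8")
        probe.unlink()
    except OSError as exc:
        raise PipelineError("report", f"output directory not writable: {exc}")
    paths = {
        "occurrences_labeled": outdir / "occurrences_labeled.tsv",
        "attrition": outdir / "attrition.csv",
        "categories": outdir / "categories.csv",
        "summaries": outdir / "summaries.csv",
        "curves": outdir / "curves.csv",
        "manifest": outdir / "manifest.json",
    }
    write_unified(bundle.labeled, paths["occurrences_labeled"])
    bundle.attrition.to_csv(paths["attrition"])
    bundle.categories.to_csv(paths["categories"], index=False)
    bundle.summaries.to_csv(paths["summaries"], index=False)
    bundle.curves.to_csv(paths["curves"], index=False)
    paths["manifest"].write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    if bundle.comparison is not None:
        paths["truth_comparison"] = outdir / "truth_comparison.csv"
        bundle.comparison.to_csv(paths["truth_comparison"], index=False)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj
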