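# Methods

This note documents the models, conventions and numerical choices behind
`oceanqc`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Study design

The pipeline assumes a high-latitude study region whose continental shelf
break coincides closely with the 500 m isobath, making 500 m — rather than
the conventional 200 m — the ecologically meaningful boundary between the
*shallow* and *deep* datasets.  The deep water column is sliced into eleven
further 500-m depth zones down to the region's deepest point (5569 m), so
zones 0–11 tile the whole marine volume.  Oceanic provinces
(sublittoral/epipelagic 0–200 m, sublittoral-bathyal/mesopelagic
200–1000 m, bathyal/bathypelagic 1000–4000 m, abyssal/abyssopelagic
4000–6000 m) are available as a coarser depth partition; both binnings are
lower-bound-inclusive.

Stage order is fixed: ingest → ridge mask → land mask → AOI polygon →
species-rank filter → marine name resolution → contour classification →
raster classification → deduplication → outliers → grid assignment →
summaries.  Deduplication deliberately runs *after* the depth analyses, so
the label columns exist on the retained representative of each duplicate
family; the effect of moving it earlier would only change which bucket a
doubly-faulty record lands in, never the retained set's labels.

## Ingest and harmonization

Each source dialect differs in its record-id column (`gbifID`, `id`,
`occurrenceID`) and delimiter; ingest maps ids onto `record_id`, tags
provenance, coerces numeric columns (bad cells become missing with a
logged warning; the row is kept), and collapses every spelling of "no
value" ("", "NA", "null", …) onto one canonical missing marker.  Depth is
meters positive down throughout; a dialect exporting negative-down
elevations declares `negate_depth` and is flipped once at ingest.  The
`year` column is authoritative for decade binning.  `coordinatePrecision`
is ingested and preserved but unused downstream.  Digitized expedition
tables (station, latitude, longitude, depth, scientificName, year) are
restricted to the 1876–1878 sampling window; rows without coordinates are
dropped and counted.

## Taxonomic resolution

Matching is exact on the canonical binomial: whitespace-normalized,
case-folded, with authorship stripped (the tail starting at the first
token after the epithets that begins with an uppercase letter or
parenthesis).  A record is retained when its name is an accepted marine
registry entry, an unaccepted entry whose accepted name is marine, or a
pair in the manually revised override list (whose targets are validated
against the registry at load time).  No fuzzy matching is attempted;
unmatched names are dropped and counted.  When a dump contains marine and
non-marine homonym rows for one name, the marine interpretation wins and
the collision is logged.

## Depth classification

- **Benthic tolerance.** A record is benthic when its recorded depth is
  within τ of the seafloor, with τ the record's own `depthAccuracy` when
  recorded and a configurable default (10 m) otherwise, applied
  symmetrically.  The default is explicit because depth accuracy is absent
  from most records, and 10 m is a conservative figure for modern
  single-beam/CTD depths over shelf and slope.
- **Pixel lookup.** The seafloor depth is read from the raster pixel
  containing the coordinate — no interpolation and no nearest-neighbour
  search.  Points on the raster's north/east boundary belong to the edge
  pixel, so the raster extent is fully covered.
- **Partition closure.** Records with recorded depth < 500 m over shallow
  seafloor are `matchShallow`; records with any recorded depth over deep
  seafloor are `matchDeep` (the main datasets are defined geographically
  in map view, and only the converse case — deep depth over shallow
  seafloor — is flagged as misplaced).  Points covered by no zone polygon
  fall back into the shallow dataset: in practice these are coastal points
  where the raster's coastline disagrees with the vector land mask.
- **Zone polygons** are derived by classifying each marine pixel into
  `floor(depth/500)` (capped at 11), run-length-encoding each raster row
  into boxes and unioning them per zone.  The construction is exact (no
  simplification), deterministic, and fast enough for sub-arc-minute
  rasters.  A point exactly on a shared zone boundary resolves to the
  shallower zone, deterministically; the probability of this occurring
  with continuous coordinates is zero.
- One bathymetry raster per run; multi-raster precedence is out of scope.

## Deduplication and outliers

Duplicates are exact matches on the 7-column key; missing values compare
equal within the key, and coordinates are compared at full stored
precision (no rounding, to avoid merging near-duplicates that the key
definition would keep).  The first record in stable input order is kept —
the choice of representative is arbitrary but must be deterministic.
Outliers are records outside the AOI polygon (geographic) and records
deeper than 5569 m (depth); a record failing both counts as geographic.

## Grid, categories and summaries

The analysis grid tiles the AOI bounding box with 0.1° squares in
geographic coordinates; cells are kept when they intersect the AOI
polygon, and ids are `row * ncols + col` from the south-west corner.  Cell
membership of a point is half-open with the AOI's top/right boundary
closed, so every in-AOI point belongs to exactly one cell.  No equal-area
reprojection is applied: cell areas shrink with latitude, which is a
property of the map-view occupancy statistic itself.

Occupancy categories are A = [1, 10] then left-open/right-closed decades
(B = (10, 10²], …, F = (10⁵, 10⁶]): the printed ranges overlap at the
powers of ten and a partition is required, and "1–10" is inclusive for A.
Counts above 10⁶ are rejected rather than silently clamped.

Richness is the number of distinct accepted names; abundance sums
`individualCount` per record, with missing or zero counts contributing 1
occurrence and 0 individuals by default (configurable to 1, since records
with uncounted individuals demonstrably contain at least one).  The time
axis has 14 bins: 1876–1899, twelve calendar decades, 2020–2025.
Latitude bands default to 1° (whole-degree bands match how richness peaks
are usually reported); the width is configurable.  Accumulation curves
run south → north over latitude bands and report the running count of
distinct accepted names; bands without records carry the running total
forward.  Planktonic/benthic summaries include only records labelled
`tiffPlankton`/`tiffBenthos` — they are depth-bearing by construction.
Rarefaction and extrapolation estimators are intentionally not
implemented.

For depth-zone summaries, a record's zone comes from its recorded depth
when present, else from the seafloor depth at its position; records with
neither (coastal fallback without depth) sit in zone 0 by virtue of their
shallow-dataset membership.

## Synthetic data

The generator emulates a multi-source export over a rectangular AOI
(default 60–64° N, 0–8° E) with a parametric shelf–slope–basin seafloor: a
linear ramp in longitude, crossing 500 m exactly at the configured shelf
break, plus low-amplitude seeded sinusoidal noise, clipped so the shallow
side stays strictly below 500 m and the deep side at or above it (ground
truth must be analytically known, so real bathymetry is out).  Maximum
depth is capped at 5540 m so that planted benthic depths can never stray
past the 5569 m outlier cap.  A strip of missing raster pixels seaward of
the vector coastline reproduces the coastal raster/vector mismatch that
motivates the shallow fallback rule.

Anomalies are planted as exact counts `round(fraction × n)`, so realized
fractions differ from requested ones by less than 1/n.  Default fractions
are chosen to mirror the proportions large public-export audits show:
about half of retained records lacking depth, ~8% exact duplicates, ~13%
missing individual counts, below-seafloor depths as the dominant
depth-quality problem (~10% here), and rare misplaced-deep records and
depth outliers (0.5% and 0.2%).  Decade sampling weights follow the steep
growth of digitized data over the fourteen bins.  Depth outliers are
planted in the coastal raster gap — the only placement from which a
\>5569 m depth can reach the outlier filter, since anywhere with raster
coverage it would already be excluded as below-seafloor.  Benthic records
are planted with |d − s| ≤ 0.9τ and planktonic ones with d ≤ s − τ − 2 m,
so every label is recovered exactly rather than probabilistically.
Duplicate copies stay in their original's source file, which makes the
keep-first representative well defined under per-source ingest order.
All randomness flows from one `numpy` generator seeded from the run seed;
identical seed and configuration give byte-identical outputs (the run
manifest differs only by the output path it records).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: realistic species-abundance distributions
(species are drawn with a simple 1/rank weighting), spatial autocorrelation
of sampling effort (placement is uniform), vessel-track clustering, real
coastline geometry, cross-source duplicate records, or registry errors
beyond homonyms and dangling synonyms.  Expedition-format files are
exercised by crafted fixtures in the test suite rather than by the
generator.

## Problem sizes

The test suite runs the full pipeline at 1,500 and 50,000 records on a
0.02° raster (200 × 400 pixels over the default AOI), plus twenty 300-record
runs with randomized anomaly mixes; the acceptance script uses the
50,000-record configuration and a 12,000-point classifier-vs-oracle
comparison.  These sizes exercise every code path while keeping a full
run in seconds; nothing in the implementation is specific to them, and the
raster resolution default (15 arc-seconds) matches common gridded
bathymetry products.

## Known limitations

- The AOI polygon of any particular study is an input; cell counts are not
  comparable across differently drawn polygons.
- Coordinate uncertainty is ingested and reported but not propagated into
  classification.
- Cross-source record linkage (the same physical record appearing in two
  databases under different ids) is handled only insofar as the 7-column
  key catches it.
- Category bins stop at 10⁶ occurrences per cell.
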