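import numpy as np
import pandas as pd
import pytest

from oceanqc.pipeline import PipelineConfig, run_pipeline
from oceanqc.synthetic import (
    SyntheticConfig,
    generate_bathymetry,
    generate_occurrences,
    generate_registry,
    make_masks,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    # coarse raster keeps the polygonization cheap while staying well under
    # the planting margins
    return SyntheticConfig(seed=11, n_records=1500, resolution=0.02)


@pytest.fixture(scope="session")
def bathy(small_config):
    return generate_bathymetry(small_config)


@pytest.fixture(scope="session")
def registry():
    return generate_registry(n_marine=60, n_nonmarine=15, n_synonyms=20, seed=11)


@pytest.fixture(scope="session")
def synth(small_config, bathy, registry):
    occ, truth = generate_occurrences(small_config, bathy, registry)
    return occ, truth


@pytest.fixture(scope="session")
def masks(small_config):
    return make_masks(small_config)


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        outdir=str(outdir), seed=small_config.seed, synthetic=small_config
    )
    return run_pipeline(config)


def make_table(**columns) -> pd.DataFrame:
    """Tiny unified-ish occurrence table for crafted unit tests."""
    n = max(len(v) for v in columns.values() if hasattr(v, "__len__"))
    base = {
        "record_id": [f"r{i}" for i in range(n)],
        "source": "gbif-like",
        "decimalLatitude": 61.0,
        "decimalLongitude": 2.0,
        "depth": np.nan,
        "depthAccuracy": np.nan,
        "scientificName": "Abra alba",
        "taxonRank": "Species",
        "individualCount": 1,
        "day": 1,
        "month": 1,
        "year": 2000,
    }
    base.update(columns)
    return pd.DataFrame(base)
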