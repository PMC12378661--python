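import logging

import numpy as np
import pandas as pd
import pytest

from oceanqc.ingest import (
    UNIFIED_COLUMNS,
    harmonize,
    read_expedition_records,
    read_occurrence_table,
    read_unified,
    write_unified,
)

GBIF_HEADER = "gbifID\tdecimalLatitude\tdecimalLongitude\tdepth\tscientificName\ttaxonRank\tyear\n"


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


def test_gbif_like_id_column_maps_to_record_id(tmp_path):
    p = write(
        tmp_path / "g.tsv",
        GBIF_HEADER
        + "101\t61.0\t2.0\t50\tAbra alba\tSpecies\t1990\n"
        + "102\t61.5\t2.5\tNA\tAbra alba\tSpecies\t1991\n"
        + "103\t62.0\t3.0\t\tCalanus finmarchicus\tSpecies\t1992\n",
    )
    table = read_occurrence_table(p, "gbif-like")
    assert len(table) == 3
    assert list(table.record_id) == ["101", "102", "103"]
    assert table.source.eq("gbif-like").all()
    # "" and "NA" both collapse onto the canonical missing marker
    assert table.depth.isna().tolist() == [False, True, True]


def test_empty_file_with_header_gives_empty_table(tmp_path):
    p = write(tmp_path / "empty.tsv", GBIF_HEADER)
    table = read_occurrence_table(p, "gbif-like")
    assert len(table) == 0
    assert "record_id" in table.columns


def test_missing_mandatory_columns_is_hard_error(tmp_path):
    p = write(tmp_path / "bad.tsv", "gbifID\tdepth\n1\t50\n")
    with pytest.raises(ValueError, match="decimalLatitude"):
        read_occurrence_table(p, "gbif-like")


def test_unparseable_numeric_cell_warns_and_retains_row(tmp_path, caplog):
    p = write(
        tmp_path / "g.tsv",
        GBIF_HEADER + "7\t61.0\t2.0\tabc\tAbra alba\tSpecies\t1990\n",
    )
    with caplog.at_level(logging.WARNING):
        table = read_occurrence_table(p, "gbif-like")
    assert len(table) == 1
    assert table.depth.isna().all()
    assert any("depth" in r.message for r in caplog.records)


def test_unknown_columns_are_preserved(tmp_path):
    p = write(
        tmp_path / "g.tsv",
        "gbifID\tdecimalLatitude\tdecimalLongitude\tscientificName\ttaxonRank\tweirdExtra\n"
        "1\t61\t2\tAbra alba\tSpecies\tkeep-me\n",
    )
    table = read_occurrence_table(p, "gbif-like")
    assert table["weirdExtra"].iloc[0] == "keep-me"


def test_negate_depth_dialect(tmp_path):
    from oceanqc.ingest import Dialect

    p = write(
        tmp_path / "e.csv",
        "occurrenceID,decimalLatitude,decimalLongitude,depth,scientificName,taxonRank\n"
        "1,61,2,-350,Abra alba,Species\n",
    )
    dialect = Dialect("emodnet-like", "occurrenceID", sep=",", negate_depth=True)
    table = read_occurrence_table(p, dialect)
    assert table.depth.iloc[0] == 350.0


class TestExpedition:
    HEADER = "station,latitude,longitude,depth,scientificName,year\n"

    def test_valid_row(self, tmp_path):
        p = write(
            tmp_path / "exp.csv",
            self.HEADER + "18,63.1,5.2,412,Nephtys sp.,1877\n",
        )
        table = read_expedition_records(p)
        assert len(table) == 1
        assert table.source.iloc[0] == "expedition"
        assert table.depth.iloc[0] == 412.0

    def test_out_of_window_year_excluded(self, tmp_path, caplog):
        p = write(
            tmp_path / "exp.csv",
            self.HEADER
            + "18,63.1,5.2,412,Nephtys sp.,1877\n"
            + "19,63.2,5.3,200,Abra alba,1890\n",
        )
        with caplog.at_level(logging.WARNING):
            table = read_expedition_records(p)
        assert len(table) == 1
        assert any("out-of-window" in r.message for r in caplog.records)

    def test_rows_without_coordinates_dropped(self, tmp_path, caplog):
        p = write(
            tmp_path / "exp.csv",
            self.HEADER
            + "18,,5.2,412,Nephtys sp.,1877\n"
            + "19,63.2,5.3,200,Abra alba,1877\n",
        )
        with caplog.at_level(logging.WARNING):
            table = read_expedition_records(p)
        assert len(table) == 1

    def test_five_valid_rows(self, tmp_path):
        rows = "".join(
            f"{i},63.{i},5.{i},100,Abra alba,1876\n" for i in range(5)
        )
        table = read_expedition_records(write(tmp_path / "e.csv", self.HEADER + rows))
        assert len(table) == 5


class TestHarmonize:
    def test_row_conservation(self, tmp_path):
        a = read_occurrence_table(
            write(
                tmp_path / "a.tsv",
                GBIF_HEADER
                + "1\t61\t2\t5\tAbra alba\tSpecies\t1990\n"
                + "2\t61\t2\t5\tAbra alba\tSpecies\t1990\n",
            ),
            "gbif-like",
        )
        b = read_occurrence_table(
            write(
                tmp_path / "b.csv",
                "id,decimalLatitude,decimalLongitude,depth,scientificName,taxonRank,year\n"
                + "1,61,2,5,Abra alba,Species,1990\n" * 3,
            ),
            "obis-like",
        )
        merged = harmonize([a, b])
        assert len(merged) == 5
        assert merged.source.value_counts().to_dict() == {
            "obis-like": 3,
            "gbif-like": 2,
        }

    def test_single_table_identity(self, tmp_path):
        a = read_occurrence_table(
            write(tmp_path / "a.tsv", GBIF_HEADER + "1\t61\t2\t5\tX y\tSpecies\t1990\n"),
            "gbif-like",
        )
        pd.testing.assert_frame_equal(harmonize([a]), a)

    def test_colliding_ids_across_sources_both_retained(self, tmp_path):
        a = read_occurrence_table(
            write(tmp_path / "a.tsv", GBIF_HEADER + "42\t61\t2\t5\tX y\tSpecies\t1990\n"),
            "gbif-like",
        )
        b = read_occurrence_table(
            write(
                tmp_path / "b.csv",
                "id,decimalLatitude,decimalLongitude,depth,scientificName,taxonRank,year\n"
                "42,62,3,7,Z w,Species,1991\n",
            ),
            "obis-like",
        )
        merged = harmonize([a, b])
        assert len(merged) == 2
        assert (merged.record_id == "42").all()

    def test_empty_input(self):
        assert len(harmonize([])) == 0


def test_unified_round_trip_is_lossless(tmp_path, synth):
    occ, _ = synth
    path = tmp_path / "unified.tsv"
    write_unified(occ, path)
    back = read_unified(path)
    for col in UNIFIED_COLUMNS:
        a, b = occ[col], back[col]
        if pd.api.types.is_numeric_dtype(a):
            np.testing.assert_allclose(
                pd.to_numeric(a, errors="coerce").astype(float),
                pd.to_numeric(b, errors="coerce").astype(float),
                equal_nan=True,
            )
        else:
            a = a.astype("string").replace("", pd.NA)
            assert a.fillna("<NA>").tolist() == b.astype("string").fillna("<NA>").tolist()
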