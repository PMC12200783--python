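"""CSV schemas: round trips, validation errors, permissive-row policy."""

import logging

import pytest

from armrec import data_io, reference
from armrec.comparative import DivergencePoint
from armrec.cyto_rates import CellRecord, GenomeSize
from armrec.data_io import RowError, SchemaError
from armrec.simulate import default_db_params, simulate_armadillo_cells, simulate_db


class TestCellCounts:
    def test_round_trip(self, tmp_path):
        cells = simulate_armadillo_cells(seed=2)
        path = tmp_path / "cells.csv"
        data_io.write_cell_counts(cells, path)
        assert data_io.read_cell_counts(path) == cells

    def test_header_only_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "cells.csv"
        path.write_text("species_id,animal_id,cell_id,foci_total,per_bivalent\n")
        assert data_io.read_cell_counts(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "cells.csv"
        path.write_text("species_id,animal_id,cell_id\nX,a,c\n")
        with pytest.raises(SchemaError, match="foci_total"):
            data_io.read_cell_counts(path)

    @pytest.mark.parametrize("bad", ["-3", "2.5", "many"])
    def test_bad_counts_report_row_number(self, tmp_path, bad):
        path = tmp_path / "cells.csv"
        path.write_text(
            "species_id,animal_id,cell_id,foci_total\nX,a,c1,40\n" f"X,a,c2,{bad}\n"
        )
        with pytest.raises(RowError, match="row 2"):
            data_io.read_cell_counts(path)

    def test_per_bivalent_sum_mismatch_rejected(self, tmp_path):
        path = tmp_path / "cells.csv"
        biv = ";".join(["1"] * 34 + ["2"])  # sums to 36
        path.write_text(
            "species_id,animal_id,cell_id,foci_total,per_bivalent\n"
            f"X,a,c1,37,{biv}\n"
        )
        with pytest.raises(RowError, match="sum"):
            data_io.read_cell_counts(path)

    def test_permissive_mode_skips_and_reports(self, tmp_path, caplog):
        path = tmp_path / "cells.csv"
        path.write_text(
            "species_id,animal_id,cell_id,foci_total\n"
            "X,a,c1,40\nX,a,c2,-1\nX,a,c3,38\n"
        )
        with caplog.at_level(logging.WARNING, logger="armrec.data_io"):
            records = data_io.read_cell_counts(path, permissive=True)
        # records out = rows in minus reported rejects
        assert len(records) == 2
        assert any("row 2" in m for m in caplog.messages)


class TestKaryotypes:
    def test_round_trip_and_derived_autosomes(self, tmp_path):
        path = tmp_path / "kary.csv"
        data_io.write_karyotypes(list(reference.KARYOTYPES.values()), path)
        back = {k.species_id: k for k in data_io.read_karyotypes(path)}
        assert back == reference.KARYOTYPES
        assert back["D_hybridus"].autosome_haploid_aN2 == 31
        assert back["C_villosus"].autosome_haploid_aN2 == 29

    def test_odd_diploid_number_rejected(self, tmp_path):
        path = tmp_path / "kary.csv"
        path.write_text("species_id,diploid_2n,arm_haploid_aFN2\nX,63,40\n")
        with pytest.raises(RowError, match="odd"):
            data_io.read_karyotypes(path)

    def test_fewer_arms_than_chromosomes_rejected(self, tmp_path):
        path = tmp_path / "kary.csv"
        path.write_text("species_id,diploid_2n,arm_haploid_aFN2\nX,64,30\n")
        with pytest.raises(RowError):
            data_io.read_karyotypes(path)


class TestGenomeSizes:
    def test_pg_conversion(self, tmp_path):
        path = tmp_path / "genomes.csv"
        path.write_text("species_id,c_value_pg,size_mbp\nDhy,4.89,\nUnit,1.0,\n")
        sizes = {g.species_id: g for g in data_io.read_genome_sizes(path)}
        assert sizes["Dhy"].size_mbp == pytest.approx(4782.42)
        assert sizes["Unit"].size_mbp == pytest.approx(978.0)

    def test_both_units_missing_rejected(self, tmp_path):
        path = tmp_path / "genomes.csv"
        path.write_text("species_id,c_value_pg,size_mbp\nX,,\n")
        with pytest.raises(RowError):
            data_io.read_genome_sizes(path)

    def test_inconsistent_units_warn_and_keep_mbp(self, tmp_path, caplog):
        path = tmp_path / "genomes.csv"
        path.write_text("species_id,c_value_pg,size_mbp\nX,4.89,5200\n")
        with caplog.at_level(logging.WARNING, logger="armrec.data_io"):
            (g,) = data_io.read_genome_sizes(path)
        assert g.size_mbp == 5200
        assert any("disagree" in m for m in caplog.messages)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "genomes.csv"
        records = list(reference.genome_sizes().values()) + [GenomeSize("NoPg", 3100.0)]
        data_io.write_genome_sizes(records, path)
        assert data_io.read_genome_sizes(path) == records


class TestRecombDb:
    def test_round_trip_preserves_collection(self, tmp_path):
        records, _ = simulate_db(default_db_params(seed=4))
        path = tmp_path / "db.csv"
        data_io.write_recomb_db(records, path)
        back = data_io.read_recomb_db(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.species_id == b.species_id
            assert a.method == b.method
            assert a.included == b.included
            assert b.rate_cm_per_mb == pytest.approx(a.rate_cm_per_mb)

    def test_unknown_method_lists_allowed_tokens(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text(
            "species_id,order,superorder,method,crossover_count,genome_mbp\n"
            "X,O,S,foci,20,3000\n"
        )
        with pytest.raises(RowError, match="chiasmata"):
            data_io.read_recomb_db(path)

    def test_shallow_linkage_rows_flagged_excluded(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text(
            "species_id,order,superorder,method,map_cm,genome_mbp,deep_coverage\n"
            "X,O,S,linkage,1400,3500,false\n"
            "Y,O,S,linkage,1400,3500,true\n"
        )
        shallow, deep = data_io.read_recomb_db(path)
        assert not shallow.included
        assert deep.included

    def test_non_positive_genome_rejected(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text(
            "species_id,order,superorder,method,crossover_count,genome_mbp\nX,O,S,mlh1,20,0\n"
        )
        with pytest.raises(RowError, match="genome"):
            data_io.read_recomb_db(path)

    def test_pg_column_accepted_for_genome_size(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text(
            "species_id,order,superorder,method,crossover_count,c_value_pg\nX,O,S,mlh1,20,1.0\n"
        )
        (r,) = data_io.read_recomb_db(path)
        assert r.genome_mbp == pytest.approx(978.0)


class TestDivergence:
    def test_round_trip(self, tmp_path):
        points = [DivergencePoint("Marsupialia", 159.0), DivergencePoint("Rodentia", 66.0)]
        path = tmp_path / "div.csv"
        data_io.write_divergence(points, path)
        assert data_io.read_divergence(path) == points

    def test_non_positive_time_rejected(self, tmp_path):
        path = tmp_path / "div.csv"
        path.write_text("group_label,divergence_mya\nX,-5\n")
        with pytest.raises(RowError):
            data_io.read_divergence(path)


def test_unknown_columns_are_preserved_but_ignored(tmp_path):
    path = tmp_path / "cells.csv"
    path.write_text(
        "species_id,animal_id,cell_id,foci_total,microscope\nX,a,c1,40,leica\n"
    )
    (record,) = data_io.read_cell_counts(path)
    assert record.foci_total == 40
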