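import textwrap

import numpy as np
import pytest

from ecospace.data_model import (
    EcologicalMode,
    GenusRecord,
    GeologicStage,
    ModeCountVector,
    TableFormatError,
    Timescale,
    TimescaleError,
    ValidationError,
    build_timescale,
    era_group,
    range_through,
    read_genus_table,
    stage_mode_counts,
    write_genus_table,
)
from ecospace.synthetic_data import ScenarioConfig, simulate_dataset

from conftest import make_record


class TestGeologicStage:
    def test_midpoint_is_mean_of_bounds(self):
        s = GeologicStage("Changhsingian", 252.2, 251.2)
        assert s.midpoint == pytest.approx(251.7)

    def test_inverted_ages_rejected(self):
        with pytest.raises(TimescaleError):
            GeologicStage("bad", 10.0, 20.0)

    @pytest.mark.parametrize(
        "period,era,expected",
        [
            ("Cambrian", "Paleozoic", "Cambrian"),
            ("Permian", "Paleozoic", "Palaeozoic_postCambrian"),
            ("Jurassic", "Mesozoic", "Mesozoic"),
            ("Neogene", "Cenozoic", "Cenozoic"),
            ("Period_2", "Era_2", "Era_2"),
        ],
    )
    def test_era_grouping(self, period, era, expected):
        assert era_group(period, era) == expected


class TestTimescale:
    def test_gap_between_stages_rejected(self):
        with pytest.raises(TimescaleError, match="gap or overlap"):
            Timescale([GeologicStage("X", 110, 100), GeologicStage("Y", 95, 90)])

    def test_non_monotone_ages_rejected(self):
        with pytest.raises(TimescaleError):
            Timescale([GeologicStage("X", 50, 40), GeologicStage("Y", 60, 50)])

    def test_duplicate_names_rejected(self):
        with pytest.raises(TimescaleError, match="duplicate"):
            Timescale([GeologicStage("X", 50, 40), GeologicStage("X", 40, 30)])

    def test_interval_selection_uses_midpoints(self, five_stage_timescale):
        names = [s.name for s in five_stage_timescale.stages_in_interval(50, 24)]
        assert names == ["A", "B", "C"]  # midpoints 45, 35, 25
        # a midpoint exactly at the younger bound is excluded
        names = [s.name for s in five_stage_timescale.stages_in_interval(50, 35)]
        assert names == ["A"]


class TestBuildTimescale:
    def _write(self, tmp_path, body):
        path = tmp_path / "ts.csv"
        path.write_text(textwrap.dedent(body))
        return path

    def test_reads_and_validates(self, tmp_path):
        path = self._write(
            tmp_path,
            """\
            name,base_age,top_age,period,era
            A,50,40,P1,Palaeozoic
            B,40,30,P1,Palaeozoic
            """,
        )
        ts = build_timescale(path)
        assert ts.names == ["A", "B"] and ts.stage("A").midpoint == 45

    def test_holocene_exclusion_drops_terminal_bin(self, tmp_path):
        path = self._write(
            tmp_path,
            """\
            name,base_age,top_age,period,era
            Pleistocene,2.58,0.117,Quaternary,Cenozoic
            Holocene,0.117,0,Quaternary,Cenozoic
            """,
        )
        ts = build_timescale(path, exclude_holocene=True)
        assert ts.names == ["Pleistocene"] and ts[-1].top_age == 0.117

    def test_cambrian_epoch_binning_merges_groups(self, tmp_path):
        path = self._write(
            tmp_path,
            """\
            name,base_age,top_age,period,era,epoch_group
            Fortunian,541,529,Cambrian,Paleozoic,Terreneuvian
            Stage 2,529,521,Cambrian,Paleozoic,Terreneuvian
            Stage 3,521,514,Cambrian,Paleozoic,Epoch 2
            Stage 4,514,509,Cambrian,Paleozoic,Epoch 2
            Wuliuan,509,504.5,Cambrian,Paleozoic,
            """,
        )
        ts = build_timescale(path, cambrian_epoch_binning=True)
        assert ts.names == ["Terreneuvian", "Epoch 2", "Wuliuan"]
        merged = ts.stage("Terreneuvian")
        assert (merged.base_age, merged.top_age) == (541, 521)
        assert merged.bin_level == "epoch"

    def test_contiguity_error_reported(self, tmp_path):
        path = self._write(
            tmp_path,
            """\
            name,base_age,top_age,period,era
            A,100,95,P,E
            B,90,85,P,E
            """,
        )
        with pytest.raises(TimescaleError, match="gap or overlap"):
            build_timescale(path)


class TestGenusTableIO:
    HEADER = "taxon_name,phylum,class,fad_age,fad_int,lad_age,lad_int,tiering,motility,feeding,eco_ref\n"

    def test_reads_documented_columns(self, tmp_path, five_stage_timescale):
        path = tmp_path / "g.csv"
        path.write_text(self.HEADER + "Turritella,Mollusca,Gastropoda,50,A,0,E,4,2,1,ref1\n")
        (rec,) = read_genus_table(path, five_stage_timescale)
        assert rec.mode == EcologicalMode(4, 2, 1)
        assert rec.phylum == "Mollusca" and rec.class_ == "Gastropoda"

    def test_accepts_spaced_alias_columns(self, tmp_path, five_stage_timescale):
        path = tmp_path / "g.csv"
        path.write_text(
            "taxon_name,fad_age,fad_int,lad_age,lad_int,tiering,motility,feeding,ecological mode\n"
            "Gx,40,B,30,B,1,1,1,1.1.1\n"
        )
        (rec,) = read_genus_table(path, five_stage_timescale)
        assert rec.taxon_name == "Gx"

    def test_header_only_file_yields_no_records(self, tmp_path, five_stage_timescale):
        path = tmp_path / "g.csv"
        path.write_text(self.HEADER)
        assert read_genus_table(path, five_stage_timescale) == []

    def test_missing_required_column_is_format_error(self, tmp_path, five_stage_timescale):
        path = tmp_path / "g.csv"
        path.write_text("taxon_name,fad_age\nGx,50\n")
        with pytest.raises(TableFormatError, match="missing required"):
            read_genus_table(path, five_stage_timescale)

    @pytest.mark.parametrize(
        "row,message",
        [
            ("Gx,,Gastropoda,10,E,40,B,1,1,1,", "younger"),  # fad below lad
            ("Gy,,Gastropoda,50,A,0,E,7,1,1,", "outside 1-6"),
            ("Gz,,Gastropoda,50,Nowhere,0,E,1,1,1,", "not in the active timescale"),
        ],
    )
    def test_invalid_rows_reported_with_row_numbers(
        self, tmp_path, five_stage_timescale, row, message
    ):
        path = tmp_path / "g.csv"
        path.write_text(self.HEADER + row + "\n")
        with pytest.raises(ValidationError) as err:
            read_genus_table(path, five_stage_timescale)
        assert "row 2" in str(err.value) and message in str(err.value)

    def test_duplicate_taxon_names_warn(self, tmp_path, five_stage_timescale):
        path = tmp_path / "g.csv"
        path.write_text(
            self.HEADER
            + "Ga,,,50,A,40,A,1,1,1,\nGa,,,40,B,30,B,1,1,1,\n"
        )
        with pytest.warns(UserWarning, match="duplicate taxon_name"):
            read_genus_table(path, five_stage_timescale)

    def test_round_trip_preserves_records(self, tmp_path):
        sim = simulate_dataset(ScenarioConfig(n_stages=8, origination=6, seed=42))
        path = tmp_path / "rt.csv"
        write_genus_table(sim.records, path)
        back = read_genus_table(path, sim.timescale)
        assert back == sim.records


class TestRangeThrough:
    def test_span_lengths(self, five_stage_timescale):
        ts = five_stage_timescale
        single = make_record("G1", "C", "C", (1, 1, 1), ts)
        span = make_record("G2", "B", "E", (1, 1, 1), ts)
        occ = range_through([single, span], ts)
        assert len(occ.stage_frame("C")) == 2
        assert (occ.frame["taxon_name"] == "G1").sum() == 1
        assert (occ.frame["taxon_name"] == "G2").sum() == 4  # B..E inclusive

    def test_total_rows_equal_sum_of_stage_counts(self, small_occurrences):
        _, occ = small_occurrences
        assert occ.genus_counts().sum() == len(occ)

    def test_simulated_dataset_row_count_matches_span_sum(self):
        sim = simulate_dataset(ScenarioConfig(n_stages=12, seed=7))
        occ = range_through(sim.records, sim.timescale)
        spans = [
            sim.timescale.index(r.lad_int) - sim.timescale.index(r.fad_int) + 1
            for r in sim.records
        ]
        assert len(occ) == sum(spans)

    def test_empty_input_gives_empty_table(self, five_stage_timescale):
        occ = range_through([], five_stage_timescale)
        assert len(occ) == 0 and occ.genus_counts().sum() == 0


class TestStageModeCounts:
    def test_shared_and_distinct_modes(self, five_stage_timescale):
        ts = five_stage_timescale
        shared = [make_record(f"G{i}", "A", "A", (1, 1, 1), ts) for i in range(3)]
        occ = range_through(shared, ts)
        counts = stage_mode_counts(occ, "A")
        assert (counts.S, counts.N) == (1, 3)

        distinct = [
            make_record(f"H{i}", "B", "B", (1, 1, i + 1), ts) for i in range(4)
        ]
        occ = range_through(distinct, ts)
        counts = stage_mode_counts(occ, "B")
        assert (counts.S, counts.N) == (4, 4)

    def test_empty_stage(self, five_stage_timescale):
        occ = range_through(
            [make_record("G1", "A", "A", (1, 1, 1), five_stage_timescale)],
            five_stage_timescale,
        )
        counts = stage_mode_counts(occ, "E")
        assert (counts.S, counts.N) == (0, 0)

    def test_unknown_stage_raises(self, small_occurrences):
        _, occ = small_occurrences
        with pytest.raises(TimescaleError):
            stage_mode_counts(occ, "Nowhere")


class TestModeTypes:
    def test_mode_equality_is_triple_equality(self):
        assert EcologicalMode(1, 2, 3) == EcologicalMode(1, 2, 3)
        assert EcologicalMode(1, 2, 3) != EcologicalMode(3, 2, 1)
        assert str(EcologicalMode.from_string("4.2.1")) == "4.2.1"

    def test_mode_code_bounds(self):
        with pytest.raises(ValidationError):
            EcologicalMode(0, 1, 1)
        with pytest.raises(ValidationError):
            EcologicalMode(1, 1, 7)

    def test_record_age_ordering_enforced(self, five_stage_timescale):
        with pytest.raises(ValidationError, match="younger"):
            GenusRecord(
                taxon_name="G",
                fad_age=50.0,
                fad_int="A",
                lad_age=60.0,
                lad_int="A",
                mode=EcologicalMode(1, 1, 1),
            )

    def test_mode_count_vector_totals(self):
        v = ModeCountVector(
            {EcologicalMode(1, 1, 1): 3, EcologicalMode(2, 1, 1): 1, EcologicalMode(3, 1, 1): 0}
        )
        assert (v.S, v.N) == (2, 4)
        assert np.array_equal(np.sort(v.counts_array()), [1, 3])
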