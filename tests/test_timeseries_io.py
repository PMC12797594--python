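"""Grouped-CSV parsing, label-based grouping, and results round-trip."""

import numpy as np
import pytest

from circastat import (
    CSVFormatError,
    CSVParseError,
    EmptyStudyError,
    RhythmResult,
    TimeOrderError,
    TimeSeries,
    align_groups,
    load_csv,
    read_results,
    write_results,
)


def _series(label, times=(0, 1, 2, 3, 4), values=None, slot=1):
    t = np.asarray(times, dtype=float)
    v = np.arange(t.size, dtype=float) if values is None else np.asarray(values, float)
    return TimeSeries(t, v, label=label, source_slot=slot)


class TestTimeSeries:
    def test_validation_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="at least 4"):
            TimeSeries([0, 1, 2], [1, 2, 3], label="x")
        with pytest.raises(ValueError):
            TimeSeries([0, 1, 2, 3], [1, 2, 3], label="x")
        with pytest.raises(TimeOrderError):
            TimeSeries([0, 1, 1, 2], [1, 2, 3, 4], label="x")  # duplicate time
        with pytest.raises(TimeOrderError):
            TimeSeries([0, 2, 1, 3], [1, 2, 3, 4], label="x")

    def test_regularity_and_intervals(self):
        assert _series("a", [0, 2, 4, 6, 8]).is_regular()
        irr = _series("a", [0, 2, 3, 7, 24])
        assert not irr.is_regular()
        assert irr.median_interval == 3.0  # median of gaps 2, 1, 4, 17


class TestLoadCSV:
    def test_duplicate_labels_preserved_in_column_order(self, write_csv, grouped_csv_text):
        series = load_csv(write_csv(grouped_csv_text))
        assert [s.label for s in series] == ["A", "A", "B"]
        assert all(s.n == 48 for s in series)

    def test_wrong_index_label_is_format_error(self, write_csv):
        path = write_csv("Hours,A\n0,1\n1,2\n2,3\n3,4\n")
        with pytest.raises(CSVFormatError, match="Time"):
            load_csv(path, time_label="Time")

    def test_irregular_times_kept_unmodified(self, write_csv):
        path = write_csv("Time,A\n0,1\n2,2\n3,3\n7,4\n24,5\n")
        (s,) = load_csv(path)
        assert np.array_equal(s.times, [0, 2, 3, 7, 24])

    def test_empty_cells_dropped_pairwise_per_series(self, write_csv):
        path = write_csv("Time,A,B\n0,1,5\n1,,6\n2,3,7\n3,4,8\n4,5,9\n")
        a, b = load_csv(path)
        assert np.array_equal(a.times, [0, 2, 3, 4])
        assert np.array_equal(b.times, [0, 1, 2, 3, 4])

    def test_non_numeric_cell_names_row_and_column(self, write_csv):
        path = write_csv("Time,A\n0,1\n1,2\n2,oops\n3,4\n")
        with pytest.raises(CSVParseError, match=r"row 3.*'A'"):
            load_csv(path)

    def test_non_increasing_times_rejected(self, write_csv):
        path = write_csv("Time,A\n0,1\n2,2\n1,3\n3,4\n")
        with pytest.raises(TimeOrderError):
            load_csv(path)

    def test_values_parse_losslessly(self, write_csv):
        path = write_csv("Time,A\n0,0.123456789012345\n1,2\n2,3\n3,4\n")
        (s,) = load_csv(path)
        assert s.values[0] == 0.123456789012345


class TestAlignGroups:
    def test_reference_slot_defines_groups_and_drops_unmatched(self):
        slot1 = [_series("WT"), _series("WT"), _series("KO")]
        slot2 = [_series("KO"), _series("WT"), _series("XX")]
        study = align_groups(slot1, slot2)
        assert study.labels == ["WT", "KO"]
        assert len(study.members("WT", 1)) == 2
        assert len(study.members("WT", 2)) == 1
        assert len(study.members("KO", 1)) == 1
        assert len(study.members("KO", 2)) == 1
        assert "XX" not in study.groups

    def test_distinct_labels_give_singleton_groups(self):
        study = align_groups([_series("a"), _series("b"), _series("c")])
        assert study.labels == ["a", "b", "c"]
        assert all(len(study.members(lab)) == 1 for lab in study.labels)

    def test_vacuous_match_keeps_empty_slot(self):
        study = align_groups([_series("A")], [])
        assert study.members("A", 2) == []

    def test_empty_reference_slot_is_error(self):
        with pytest.raises(EmptyStudyError):
            align_groups([])

    def test_independent_of_later_slot_order_and_idempotent(self):
        s1 = [_series("A"), _series("B")]
        s2 = [_series("A", values=[9, 9, 9, 9, 9])]
        s3 = [_series("B", values=[7, 7, 7, 7, 7])]
        a = align_groups(s1, s2, s3)
        b = align_groups(s1, s3, s2)
        assert a.labels == b.labels
        for lab in a.labels:
            counts_a = sorted(len(a.members(lab, s)) for s in (2, 3))
            counts_b = sorted(len(b.members(lab, s)) for s in (2, 3))
            assert counts_a == counts_b
        again = align_groups(s1, s2, s3)
        assert again.labels == a.labels

    def test_member_series_carry_group_label(self):
        study = align_groups([_series("A"), _series("A")])
        assert all(ts.label == "A" for ts in study.members("A"))

    def test_group_average_requires_shared_grid(self):
        study = align_groups([_series("A", values=[1, 2, 3, 4, 5]),
                              _series("A", values=[3, 4, 5, 6, 7])])
        avg = study.averaged("A")
        assert np.allclose(avg.values, [2, 3, 4, 5, 6])
        mixed = align_groups([_series("A"), _series("A", times=[0, 1, 2, 3])])
        with pytest.raises(ValueError, match="differing time grids"):
            mixed.averaged("A")


class TestResultsCSV:
    def _records(self):
        return [
            RhythmResult(label="g1", method="jtk", period=24.0,
                         amplitude=1.234567, acrophase=6.5,
                         p_raw=1.5e-7, adj_p=3.2e-4, bh_q=None),
            RhythmResult(label="g2", method="jtk", period=22.5,
                         amplitude=0.5, acrophase=0.0,
                         p_raw=0.02, adj_p=0.8, bh_q=0.04),
        ]

    def test_round_trip_is_field_identical(self, tmp_path):
        path = tmp_path / "res.csv"
        write_results(self._records(), path)
        back = read_results(path)
        for orig, rt in zip(self._records(), back):
            assert rt.label == orig.label and rt.method == orig.method
            for f in ("period", "amplitude", "acrophase", "p_raw", "adj_p"):
                assert getattr(rt, f) == pytest.approx(getattr(orig, f), rel=1e-6)
        assert back[0].bh_q is None
        assert back[1].bh_q == pytest.approx(0.04)

    def test_unset_bh_q_is_empty_cell_not_nan_text(self, tmp_path):
        path = tmp_path / "res.csv"
        write_results(self._records()[:1], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[0] == "label,METHOD,PER,AMP,ACROPHASE,P,ADJ.P,BH.Q"
        assert lines[1].endswith(",")
        assert "NaN" not in lines[1] and "nan" not in lines[1]

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results([], tmp_path / "res.csv")
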