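"""Plate-reader file parsing, condition maps and results tables."""

import json

import numpy as np
import pytest

from growthscore.curves import GrowthParameters, logistic
from growthscore.fitting import fit_logistic
from growthscore.metrics import growth_score, score_curve
from growthscore.plate_io import (
    normalize_well,
    read_condition_map,
    read_long_table,
    read_wide_csv,
    write_results,
    write_wide_csv,
)
from growthscore.simulation import SimulationConfig, simulate_cohort


def _long_table(tmp_path, rows, header="sample\twell\ttime\tod"):
    path = tmp_path / "plate.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestLongTable:
    def test_minimal_single_well(self, tmp_path):
        path = _long_table(
            tmp_path,
            [f"s1\tA1\t{t}\t0.1" for t in (0, 1, 2, 3)],
        )
        dataset = read_long_table(path)
        assert len(dataset.curves) == 1
        curve = dataset.curves[0]
        assert len(curve) == 4
        assert curve.well_id == "A01"  # normalized
        assert curve.sample == "s1"

    def test_grouping_two_samples_two_wells(self, tmp_path):
        rows = [
            f"{s}\t{w}\t{t}\t0.2"
            for s in ("s1", "s2")
            for w in ("A01", "B02")
            for t in (0, 1, 2)
        ]
        dataset = read_long_table(_long_table(tmp_path, rows))
        keys = {(c.sample, c.well_id) for c in dataset.curves}
        assert keys == {("s1", "A01"), ("s1", "B02"), ("s2", "A01"), ("s2", "B02")}

    def test_duplicate_time_point_names_the_key(self, tmp_path):
        rows = ["s1\tA01\t0\t0.1", "s1\tA01\t1\t0.1", "s1\tA01\t1\t0.2", "s1\tA01\t2\t0.1"]
        with pytest.raises(ValueError, match=r"s1.*A01.*1"):
            read_long_table(_long_table(tmp_path, rows))

    def test_missing_column_named(self, tmp_path):
        path = _long_table(tmp_path, ["s1\tA01\t0"], header="sample\twell\ttime")
        with pytest.raises(ValueError, match="'od'"):
            read_long_table(path)

    def test_non_numeric_od_names_line(self, tmp_path):
        rows = ["s1\tA01\t0\t0.1", "s1\tA01\t1\toops", "s1\tA01\t2\t0.1"]
        with pytest.raises(ValueError, match="line 3"):
            read_long_table(_long_table(tmp_path, rows))

    def test_unsorted_times_sorted_silently(self, tmp_path, caplog):
        rows = ["s1\tA01\t2\t0.3", "s1\tA01\t0\t0.1", "s1\tA01\t1\t0.2"]
        with caplog.at_level("INFO"):
            dataset = read_long_table(_long_table(tmp_path, rows))
        assert np.array_equal(dataset.curves[0].time, [0.0, 1.0, 2.0])
        assert np.array_equal(dataset.curves[0].od, [0.1, 0.2, 0.3])
        assert any("unsorted" in rec.message for rec in caplog.records)

    def test_minutes_converted_to_hours(self, tmp_path):
        rows = [f"s1\tA01\t{t}\t0.1" for t in (0, 30, 60)]
        dataset = read_long_table(_long_table(tmp_path, rows), time_unit="minutes")
        assert np.allclose(dataset.curves[0].time, [0.0, 0.5, 1.0])


class TestWideCsv:
    def test_two_well_columns(self, tmp_path):
        path = tmp_path / "plate.csv"
        path.write_text("time,A01,B02\n0,0.1,0.2\n1,0.1,0.3\n2,0.2,0.4\n")
        dataset = read_wide_csv(path)
        assert len(dataset.curves) == 2
        assert {c.well_id for c in dataset.curves} == {"A01", "B02"}
        assert not dataset.ragged

    def test_missing_time_header_rejected(self, tmp_path):
        path = tmp_path / "plate.csv"
        path.write_text("hours,A01\n0,0.1\n1,0.2\n2,0.3\n")
        with pytest.raises(ValueError, match="'time'"):
            read_wide_csv(path)

    def test_well_label_validation(self, tmp_path):
        ok = tmp_path / "ok.csv"
        ok.write_text("time,H12\n0,0.1\n1,0.2\n2,0.3\n")
        assert read_wide_csv(ok).curves[0].well_id == "H12"
        bad = tmp_path / "bad.csv"
        bad.write_text("time,I13\n0,0.1\n1,0.2\n2,0.3\n")
        with pytest.raises(ValueError, match="not a 96-well label"):
            read_wide_csv(bad)
        # arbitrary ids allowed in the relaxed mode used for cohort exports
        other = tmp_path / "sim.csv"
        other.write_text("time,sim0001\n0,0.1\n1,0.2\n2,0.3\n")
        assert read_wide_csv(other, well_labels="any").curves[0].well_id == "sim0001"

    def test_empty_column_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "plate.csv"
        path.write_text("time,A01,B02\n0,0.1,\n1,0.2,\n2,0.3,\n")
        with caplog.at_level("WARNING"):
            dataset = read_wide_csv(path)
        assert [c.well_id for c in dataset.curves] == ["A01"]
        assert any("empty" in rec.message for rec in caplog.records)


class TestConditionMap:
    def test_full_plate_map(self, tmp_path):
        rows = "\n".join(
            f"{r}{c:02d}\tmedium-{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)
        )
        path = tmp_path / "conditions.tsv"
        path.write_text("well\tcondition\n" + rows + "\n")
        mapping = read_condition_map(path)
        assert len(mapping) == 96
        assert mapping["A01"] == "medium-A1"
        assert mapping["Z99"] == "unknown"  # absent wells default

    def test_duplicate_well_rejected(self, tmp_path):
        path = tmp_path / "conditions.tsv"
        path.write_text("well\tcondition\nA01\tglucose\nA1\tmaltose\n")
        with pytest.raises(ValueError, match="duplicate well"):
            read_condition_map(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "conditions.tsv"
        path.write_text("well\tcondition\nA01\tglucose\nB02\n")
        with pytest.raises(ValueError, match="line 3"):
            read_condition_map(path)

    @pytest.mark.parametrize("raw,expected", [("A1", "A01"), ("h12", "H12"), ("B09", "B09")])
    def test_well_normalization(self, raw, expected):
        assert normalize_well(raw) == expected

    def test_bad_labels_rejected(self):
        for label in ("I01", "A13", "A0", ""):
            with pytest.raises(ValueError):
                normalize_well(label)


class TestResultsOutput:
    def _results(self):
        t = np.arange(0.0, 48.0, 0.5)
        out = []
        for well, lag in (("A01", 5.0), ("B02", 12.0)):
            p = GrowthParameters(y0=0.05, lag=lag, mu=0.3, A=1.0)
            from growthscore.curves import FitResult

            fit = FitResult(
                params=p, fitted=logistic(p, t), rss=0.0, converged=True, n_points=len(t)
            )
            out.append((("s1", well, "glucose"), fit, score_curve(fit)))
        return out

    def test_tsv_layout_and_determinism(self, tmp_path):
        results = self._results()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_results(p1, results, format="tsv")
        write_results(p2, list(reversed(results)), format="tsv")
        text = p1.read_text()
        lines = text.strip().split("\n")
        assert lines[0].split("\t")[:3] == ["sample", "well", "condition"]
        assert len(lines) == 3
        assert text == p2.read_text()  # byte-identical regardless of input order

    def test_json_mirrors_tsv_fields(self, tmp_path):
        path = tmp_path / "results.json"
        write_results(path, self._results(), format="json")
        records = json.loads(path.read_text())
        assert len(records) == 2
        assert set(records[0]) >= {"sample", "well", "gl", "gs", "gl_class", "gs_class"}

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_results(tmp_path / "x", self._results(), format="xlsx")


class TestRoundtrip:
    def test_wide_csv_roundtrip_preserves_growth_score(self, tmp_path):
        """Cohort -> wide CSV -> parse -> refit recovers GS within 1e-3."""
        cohort = simulate_cohort(
            SimulationConfig(n_curves=12, seed=17, total_time=240.0, dt=0.5)
        )
        curves = [c for _, c in cohort]
        path = tmp_path / "cohort.csv"
        write_wide_csv(path, curves)
        dataset = read_wide_csv(path, well_labels="any")
        assert len(dataset.curves) == 12
        by_id = {c.well_id: c for c in dataset.curves}
        for truth, original in cohort:
            refit = fit_logistic(by_id[original.well_id])
            assert abs(growth_score(refit.params) - growth_score(truth)) < 1e-3
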