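"""Reflection-file, correlation-table, SMV and summary-CSV I/O."""

import numpy as np
import pandas as pd
import pytest

from edbatch.formats import (DatasetHeader, DatasetRecord, FormatError,
                             SmvImage, SummaryRow, UnitCell, read_smv,
                             read_summary_table, read_xds_ascii,
                             read_xscale_lp_correlations, write_smv,
                             write_summary_table, write_xds_ascii)


def _simple_record(n=5, dataset_id="t"):
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "h": rng.integers(-5, 6, n), "k": rng.integers(-5, 6, n),
        "l": rng.integers(1, 6, n),
        "intensity": rng.normal(100, 30, n),
        "sigma": rng.uniform(1, 5, n),
        "frame": rng.uniform(1, 90, n),
    })
    header = DatasetHeader(unit_cell=UnitCell(10, 11, 12, 90, 95, 90),
                           space_group_number=4, frame_range=(1, 90),
                           extra={"CUSTOM_KEY": "kept"})
    return DatasetRecord(dataset_id=dataset_id, header=header, reflections=df)


class TestXdsAscii:
    def test_round_trip_identity(self, tmp_path):
        rec = _simple_record()
        path = tmp_path / "a.HKL"
        write_xds_ascii(rec, path)
        back = read_xds_ascii(path)
        assert back.dataset_id == "t"
        assert back.header.unit_cell.parameters == pytest.approx(
            rec.header.unit_cell.parameters)
        assert back.header.extra["CUSTOM_KEY"] == "kept"
        np.testing.assert_array_equal(back.hkl_array(), rec.hkl_array())
        np.testing.assert_allclose(back.reflections["intensity"],
                                   rec.reflections["intensity"], rtol=1e-4)

    def test_write_read_write_byte_identical(self, tmp_path):
        rec = _simple_record()
        p1, p2 = tmp_path / "a.HKL", tmp_path / "b.HKL"
        write_xds_ascii(rec, p1)
        write_xds_ascii(read_xds_ascii(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_column_order_follows_item_declarations(self, tmp_path):
        # same record content, permuted physical columns
        body = ("!FORMAT=XDS_ASCII    MERGE=FALSE\n"
                "!SPACE_GROUP_NUMBER= 1\n"
                "!UNIT_CELL_CONSTANTS= 10 10 10 90 90 90\n"
                "!X-RAY_WAVELENGTH= 0.0251\n!OSCILLATION_RANGE= 0.23\n"
                "!DATA_RANGE= 1 90\n"
                "!NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD=6\n"
                "!ITEM_H={h}\n!ITEM_K={k}\n!ITEM_L={l}\n!ITEM_IOBS={i}\n"
                "!ITEM_SIGMA(IOBS)={s}\n!ITEM_ZD={z}\n"
                "!END_OF_HEADER\n{row}\n!END_OF_DATA\n")
        p1 = tmp_path / "normal.HKL"
        p1.write_text(body.format(h=1, k=2, l=3, i=4, s=5, z=6,
                                  row="1 2 3 100.0 5.0 10.2"))
        p2 = tmp_path / "permuted.HKL"
        p2.write_text(body.format(h=6, k=5, l=4, i=3, s=2, z=1,
                                  row="10.2 5.0 100.0 3 2 1"))
        r1, r2 = read_xds_ascii(p1), read_xds_ascii(p2)
        for rec in (r1, r2):
            row = rec.reflections.iloc[0]
            assert (row.h, row.k, row.l) == (1, 2, 3)
            assert row.intensity == 100.0 and row.sigma == 5.0
            assert row.frame == 10.2
        pd.testing.assert_frame_equal(r1.reflections, r2.reflections)

    def test_zero_sigma_rejected_with_row(self, tmp_path):
        rec = _simple_record()
        path = tmp_path / "a.HKL"
        write_xds_ascii(rec, path)
        text = path.read_text().replace(
            f"{rec.reflections.sigma.iloc[0]:13.4e}", f"{0.0:13.4e}", 1)
        bad = tmp_path / "bad.HKL"
        bad.write_text(text)
        with pytest.raises(FormatError, match="sigma.*row: 0"):
            read_xds_ascii(bad)

    def test_missing_item_declaration_is_format_error(self, tmp_path):
        p = tmp_path / "x.HKL"
        p.write_text("!ITEM_H=1\n!ITEM_K=2\n!ITEM_L=3\n!ITEM_IOBS=4\n"
                     "!END_OF_HEADER\n!END_OF_DATA\n")
        with pytest.raises(FormatError, match="SIGMA"):
            read_xds_ascii(p)

    def test_non_numeric_record_reports_line(self, tmp_path):
        rec = _simple_record(2)
        path = tmp_path / "a.HKL"
        write_xds_ascii(rec, path)
        lines = path.read_text().splitlines()
        first_data = next(i for i, ln in enumerate(lines)
                          if not ln.startswith("!"))
        lines[first_data] = "1 2 junk 5.0 1.0 3.0"
        bad = tmp_path / "bad.HKL"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match=f"line {first_data + 1}"):
            read_xds_ascii(bad)

    def test_empty_record_round_trip(self, tmp_path):
        rec = _simple_record(0)
        path = tmp_path / "e.HKL"
        write_xds_ascii(rec, path)
        back = read_xds_ascii(path)
        assert back.n_obs == 0

    def test_merged_flag_drops_frame_and_sets_header(self, tmp_path):
        rec = _simple_record()
        path = tmp_path / "m.HKL"
        write_xds_ascii(rec, path, merged=True)
        assert "MERGE=TRUE" in path.read_text()
        back = read_xds_ascii(path)
        assert back.merged and back.frameless

    def test_trailing_junk_warned_and_ignored(self, tmp_path):
        rec = _simple_record()
        path = tmp_path / "a.HKL"
        write_xds_ascii(rec, path)
        with open(path, "a") as fh:
            fh.write("appended garbage not numbers\n")
        with pytest.warns(UserWarning, match="after END_OF_DATA"):
            back = read_xds_ascii(path)
        assert back.n_obs == rec.n_obs


class TestXscaleLp:
    def test_pair_block_parsed(self, tmp_path):
        p = tmp_path / "XSCALE.LP"
        p.write_text(
            "...\n CORRELATIONS BETWEEN INPUT DATA SETS AFTER CORRECTIONS\n\n"
            " DATA SETS  NUMBER OF COMMON  CORRELATION\n"
            "  #i   #j     REFLECTIONS     BETWEEN i,j\n"
            "   1    2         500             0.920\n"
            "   1    3          40             0.500\n"
            "   2    3          80             0.700\n")
        table = read_xscale_lp_correlations(p)
        assert table.dataset_ids == ["1", "2", "3"]
        assert table.cc[0, 1] == table.cc[1, 0] == pytest.approx(0.92)
        assert table.n_common[0, 1] == 500

    def test_missing_block_is_format_error(self, tmp_path):
        p = tmp_path / "XSCALE.LP"
        p.write_text("no correlations here\n")
        with pytest.raises(FormatError, match="block not found"):
            read_xscale_lp_correlations(p)

    def test_conflicting_duplicate_pair_names_pair(self, tmp_path):
        p = tmp_path / "XSCALE.LP"
        p.write_text(" CORRELATIONS BETWEEN INPUT DATA SETS AFTER x\n"
                     "   1    2    500    0.920\n"
                     "   2    1    500    0.850\n")
        with pytest.raises(FormatError, match=r"\(1, 2\)"):
            read_xscale_lp_correlations(p)


class TestSmv:
    def test_zero_image_round_trip(self, tmp_path):
        img = SmvImage(header={"DISTANCE": "958", "OSC_RANGE": "0.23"},
                       pixels=np.zeros((64, 64), dtype=np.uint16))
        p = tmp_path / "z.img"
        write_smv(img, p)
        back = read_smv(p)
        np.testing.assert_array_equal(back.pixels, img.pixels)
        assert back.header["DISTANCE"] == "958"
        assert back.header["OSC_RANGE"] == "0.23"
        assert int(back.header["HEADER_BYTES"]) % 512 == 0

    def test_random_image_bit_exact(self, tmp_path):
        rng = np.random.default_rng(5)
        img = SmvImage(header={"A": "1"},
                       pixels=rng.integers(0, 65536, (48, 32)).astype(np.uint16))
        p = tmp_path / "r.img"
        write_smv(img, p)
        np.testing.assert_array_equal(read_smv(p).pixels, img.pixels)

    def test_overflow_clamped(self, tmp_path, caplog):
        px = np.array([[70000, 10], [20, 30]], dtype=np.int64)
        img = SmvImage(header={}, pixels=px)
        p = tmp_path / "c.img"
        with caplog.at_level("WARNING", logger="edbatch"):
            write_smv(img, p)
        assert "clamping 1" in caplog.text
        assert read_smv(p).pixels[0, 0] == 65535

    def test_truncated_block_reports_byte_counts(self, tmp_path):
        img = SmvImage(header={}, pixels=np.ones((16, 16), dtype=np.uint16))
        p = tmp_path / "t.img"
        write_smv(img, p)
        raw = p.read_bytes()
        p.write_bytes(raw[:-10])
        with pytest.raises(IOError, match="expected 512 bytes, got 502"):
            read_smv(p)


class TestSummaryCsv:
    def _rows(self):
        cell = UnitCell(6.0, 7.027, 21.718, 90, 90, 90)
        return [
            SummaryRow("exp10", 16, cell, isa=7.51, r_meas=0.08,
                       cc_half=98.18, completeness=87.61,
                       resolution_estimate=0.68),
            SummaryRow("exp03", 16, cell, isa=None, r_meas=None,
                       cc_half=None, completeness=43.19,
                       resolution_estimate=None),
        ]

    def test_round_trip_preserves_order_and_values(self, tmp_path):
        p = tmp_path / "summary.csv"
        write_summary_table(self._rows(), p)
        back = read_summary_table(p)
        assert [r.dataset_id for r in back] == ["exp10", "exp03"]
        assert back[0].isa == pytest.approx(7.51)
        assert back[0].cc_half == pytest.approx(98.18)
        assert back[1].isa is None and back[1].completeness == pytest.approx(43.19)

    def test_empty_list_gives_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_summary_table([], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("dataset_id,")


class TestUnitCell:
    def test_volume_matches_gemmi(self):
        import gemmi
        cell = UnitCell(11.2, 13.4, 17.9, 83.0, 97.5, 112.0)
        assert cell.volume == pytest.approx(
            gemmi.UnitCell(*cell.parameters).volume, rel=1e-12)

    def test_d_spacing_matches_gemmi(self):
        import gemmi
        cell = UnitCell(11.2, 13.4, 17.9, 83.0, 97.5, 112.0)
        g = gemmi.UnitCell(*cell.parameters)
        hkl = np.array([[1, 2, 3], [-2, 0, 5], [4, -1, -2]])
        mine = cell.d_spacing(hkl)
        theirs = [g.calculate_d(list(map(int, row))) for row in hkl]
        np.testing.assert_allclose(mine, theirs, rtol=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(a=-1, b=10, c=10), dict(a=10, b=10, c=10, alpha=181),
        dict(a=10, b=10, c=10, alpha=1, beta=1, gamma=170)])
    def test_degenerate_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(**{**dict(a=10, b=10, c=10), **bad})
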