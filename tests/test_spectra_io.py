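"""Spectrum containers, CSV/JCAMP round-trips, and resampling."""

import numpy as np
import pytest

from irpreclass import (
    SpectralDataset,
    Spectrum,
    make_water_reference,
    read_csv_dataset,
    read_jcamp_spectrum,
    read_results_table,
    resample_to_axis,
    write_csv_dataset,
    write_jcamp_spectrum,
    write_results_table,
)
from irpreclass.errors import (
    AxisError,
    ContractViolation,
    IntegrityError,
    ParseError,
    RangeError,
    ShapeError,
    UnsupportedDialectError,
)
from irpreclass.msc import fit_msc, preclassify_dataset


class TestSpectrumInvariants:
    def test_descending_axis_is_canonicalized(self):
        s = Spectrum([1200.0, 1100.0, 1000.0], [1.0, 2.0, 3.0], "s")
        assert np.array_equal(s.wavenumbers, [1000.0, 1100.0, 1200.0])
        assert np.array_equal(s.absorbance, [3.0, 2.0, 1.0])

    def test_duplicate_wavenumber_rejected(self):
        with pytest.raises(AxisError, match="duplicated wavenumber 1000"):
            Spectrum([900.0, 1000.0, 1000.0, 1100.0], [1, 2, 3, 4])

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_absorbance_rejected(self, bad):
        with pytest.raises(AxisError, match="non-finite"):
            Spectrum([900.0, 1000.0], [1.0, bad])

    def test_nonpositive_wavenumber_rejected(self):
        with pytest.raises(AxisError, match="positive"):
            Spectrum([0.0, 1000.0], [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            Spectrum([900.0, 1000.0], [1.0, 2.0, 3.0])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ContractViolation, match="duplicate spectrum id"):
            SpectralDataset([900.0, 1000.0], np.zeros((2, 2)), ["a", "a"])


class TestCSV:
    def test_toy_shape(self, toy_dataset, tmp_path):
        p = tmp_path / "toy.csv"
        write_csv_dataset(toy_dataset, p)
        ds = read_csv_dataset(p)
        assert ds.axis.size == 5
        assert ds.matrix.shape == (3, 5)
        assert ds.ids == ["s1", "s2", "s3"]

    @pytest.mark.parametrize("orientation", ["rows", "columns"])
    def test_round_trip_exact(self, toy_dataset, tmp_path, orientation):
        rng = np.random.default_rng(7)
        ds = SpectralDataset(
            np.sort(rng.uniform(400, 4000, 30)),
            rng.normal(size=(4, 30)),
            [f"s{i}" for i in range(4)],
        )
        p = tmp_path / "rt.csv"
        write_csv_dataset(ds, p, orientation)
        back = read_csv_dataset(p, orientation)
        assert np.max(np.abs(back.axis - ds.axis)) < 1e-12
        assert np.max(np.abs(back.matrix - ds.matrix)) < 1e-12
        assert back.ids == ds.ids

    def test_descending_file_equals_ascending_rewrite(self, tmp_path):
        desc = tmp_path / "desc.csv"
        asc = tmp_path / "asc.csv"
        desc.write_text("id,1200,1100,1000\na,1,2,3\nb,4,5,6\n")
        asc.write_text("id,1000,1100,1200\na,3,2,1\nb,6,5,4\n")
        d1, d2 = read_csv_dataset(desc), read_csv_dataset(asc)
        assert np.array_equal(d1.axis, d2.axis)
        assert np.array_equal(d1.matrix, d2.matrix)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,1000,1100\nspecA,0.1,oops\n")
        with pytest.raises(ParseError, match="'oops'.*'specA'.*'1100'"):
            read_csv_dataset(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("id,1000,1100\na,1,2\nb,1\n")
        with pytest.raises(ShapeError, match="row 3"):
            read_csv_dataset(p)

    def test_nan_cell_rejected(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text("id,1000,1100\na,1,nan\n")
        with pytest.raises(AxisError, match="non-finite"):
            read_csv_dataset(p)


JCAMP_MINIMAL = """\
##TITLE=minimal
##JCAMP-DX=4.24
##XUNITS=1/CM
##YUNITS=ABSORBANCE
##XFACTOR=1
##YFACTOR=0.001
##FIRSTX=1000
##LASTX=1004
##DELTAX=1
##NPOINTS=5
##XYDATA=(X++(Y..Y))
1000 100 200 300
1003 400 500
##END=
"""


class TestJCAMP:
    def test_minimal_yfactor_applied(self, tmp_path):
        p = tmp_path / "m.jdx"
        p.write_text(JCAMP_MINIMAL)
        s = read_jcamp_spectrum(p)
        assert len(s) == 5
        assert np.allclose(s.absorbance, [0.1, 0.2, 0.3, 0.4, 0.5])
        assert np.allclose(s.wavenumbers, [1000, 1001, 1002, 1003, 1004])

    def test_axis_from_firstx_lastx_npoints(self, tmp_path):
        n = 3601
        ys = " ".join(["0"] * 10)
        lines = [
            "##TITLE=axis", "##XFACTOR=1", "##YFACTOR=1",
            "##FIRSTX=400", "##LASTX=4000", f"##NPOINTS={n}",
            "##XYDATA=(X++(Y..Y))",
        ]
        for i in range(0, n, 10):
            k = min(10, n - i)
            lines.append(f"{400 + i} " + " ".join(["0"] * k))
        p = tmp_path / "axis.jdx"
        p.write_text("\n".join(lines) + "\n##END=\n")
        s = read_jcamp_spectrum(p)
        assert len(s) == n
        assert np.allclose(np.diff(s.wavenumbers), 1.0)

    def test_round_trip_of_synthetic_spectrum(self, tmp_path, short_axis):
        ref = make_water_reference(short_axis)
        p = tmp_path / "w.jdx"
        write_jcamp_spectrum(ref, p)
        back = read_jcamp_spectrum(p)
        assert np.max(np.abs(back.wavenumbers - ref.wavenumbers)) < 1e-9
        assert np.max(np.abs(back.absorbance - ref.absorbance)) < 1e-9

    def test_compressed_dialect_rejected(self, tmp_path):
        p = tmp_path / "sqz.jdx"
        p.write_text(
            "##TITLE=sqz\n##FIRSTX=1000\n##LASTX=1004\n##NPOINTS=5\n"
            "##XYDATA=(X++(Y..Y))\n1000 A00 B00 C00 D00 E00\n##END=\n"
        )
        with pytest.raises(UnsupportedDialectError, match="SQZ/DIF/DUP"):
            read_jcamp_spectrum(p)

    def test_npoints_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.jdx"
        p.write_text(
            "##TITLE=bad\n##FIRSTX=1000\n##LASTX=1003\n##NPOINTS=4\n"
            "##XYDATA=(X++(Y..Y))\n1000 1 2 3\n##END=\n"
        )
        with pytest.raises(IntegrityError, match="NPOINTS=4"):
            read_jcamp_spectrum(p)

    def test_xypoints_parsed(self, tmp_path):
        p = tmp_path / "xy.jdx"
        p.write_text(
            "##TITLE=xy\n##XFACTOR=1\n##YFACTOR=2\n##NPOINTS=3\n"
            "##XYPOINTS=(XY..XY)\n1000, 1; 1001, 2\n1002, 3\n##END=\n"
        )
        s = read_jcamp_spectrum(p)
        assert np.allclose(s.wavenumbers, [1000, 1001, 1002])
        assert np.allclose(s.absorbance, [2.0, 4.0, 6.0])


class TestResample:
    def test_identity_axis_passthrough(self, water_ref):
        out = resample_to_axis(water_ref, water_ref.wavenumbers)
        assert np.array_equal(out.absorbance, water_ref.absorbance)

    def test_linear_law_preserved(self):
        ax = np.linspace(800, 1900, 23)
        s = Spectrum(ax, 2.0 * ax + 5.0)
        target = np.linspace(850, 1850, 41)
        out = resample_to_axis(s, target)
        assert np.max(np.abs(out.absorbance - (2.0 * target + 5.0))) < 1e-12

    def test_matches_two_point_interpolation_oracle(self):
        rng = np.random.default_rng(3)
        ax = np.sort(rng.uniform(800, 1900, 40))
        vals = rng.normal(size=40)
        s = Spectrum(ax, vals)
        targets = np.sort(rng.uniform(ax[0], ax[-1], 25))
        out = resample_to_axis(s, targets)
        # brute-force two-point interpolation, one target at a time
        for t, got in zip(targets, out.absorbance):
            j = np.searchsorted(ax, t)
            if ax[j] == t:
                expect = vals[j]
            else:
                x0, x1 = ax[j - 1], ax[j]
                y0, y1 = vals[j - 1], vals[j]
                expect = y0 + (y1 - y0) * (t - x0) / (x1 - x0)
            assert abs(got - expect) < 1e-12

    def test_idempotent(self, water_ref):
        target = np.linspace(700, 1900, 101)
        once = resample_to_axis(water_ref, target)
        twice = resample_to_axis(once, target)
        assert np.array_equal(once.absorbance, twice.absorbance)

    def test_out_of_range_target_rejected(self, water_ref):
        with pytest.raises(RangeError, match="outside source range"):
            resample_to_axis(water_ref, [100.0, 1000.0])


class TestResultsTable:
    def test_empty_list_gives_header_only(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_results_table([], p)
        assert p.read_text() == "id\ta\tb\trmse\tthreshold\tlabel\n"

    def test_round_trip_reproduces_rmse(self, tmp_path, water_ref, cartilage_sig):
        mixed = water_ref.with_absorbance(
            water_ref.absorbance + 0.5 * cartilage_sig.absorbance, "mix"
        )
        ds = SpectralDataset(
            water_ref.wavenumbers,
            np.vstack([water_ref.absorbance, mixed.absorbance]),
            ["w", "mix"],
        )
        results = preclassify_dataset(ds, water_ref, 0.01, (800, 1900))
        p = tmp_path / "res.tsv"
        write_results_table(results, p)
        df = read_results_table(p)
        assert list(df["id"]) == ["w", "mix"]
        assert list(df["label"]) == ["water", "cartilage"]
        for row, r in zip(df.itertuples(), results):
            assert abs(row.rmse - r.fit.rmse) < 1e-9
            assert abs(row.a - r.fit.a) < 1e-9
            assert abs(row.b - r.fit.b) < 1e-9
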