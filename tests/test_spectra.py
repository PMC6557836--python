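import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from foldstab.errors import ParseError, SchemaError, ValidationError
from foldstab.spectra import (
    AxisKind,
    FractionCurve,
    ProbeKind,
    SpectrumSeries,
    UnfoldingCurve,
    read_spectrum_series,
    write_spectrum_series,
)


class TestSpectrumSeriesValidation:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumSeries(
                probe_kind="trp_fluorescence",
                axis_kind="temperature_C",
                condition_values=[1.0, 2.0],
                wavelengths_nm=[310.0, 320.0, 330.0],
                intensities=np.zeros((2, 2)),
            )

    def test_non_monotone_condition_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumSeries(
                probe_kind="trp_fluorescence",
                axis_kind="temperature_C",
                condition_values=[1.0, 3.0, 2.0],
                wavelengths_nm=[310.0, 320.0],
                intensities=np.zeros((3, 2)),
            )

    def test_descending_condition_accepted(self):
        s = SpectrumSeries(
            probe_kind="ans",
            axis_kind="pH",
            condition_values=[7.0, 5.0, 3.0],
            wavelengths_nm=[400.0, 500.0],
            intensities=np.ones((3, 2)),
        )
        assert s.n_conditions == 3

    def test_unsorted_wavelengths_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumSeries(
                probe_kind="rls",
                axis_kind="pH",
                condition_values=[7.0, 5.0],
                wavelengths_nm=[500.0, 400.0],
                intensities=np.ones((2, 2)),
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumSeries(
                probe_kind="far_uv_cd",
                axis_kind="temperature_C",
                condition_values=[20.0, 25.0],
                wavelengths_nm=[208.0, 222.0],
                intensities=np.array([[1.0, np.nan], [1.0, 1.0]]),
            )

    @given(
        corruption=st.sampled_from(
            ["dup_condition", "bad_abs_shape", "inf_wavelength", "empty"]
        )
    )
    def test_randomized_corruptions_rejected(self, corruption):
        kwargs = dict(
            probe_kind="trp_fluorescence",
            axis_kind="temperature_C",
            condition_values=np.array([20.0, 25.0, 30.0]),
            wavelengths_nm=np.array([310.0, 320.0]),
            intensities=np.ones((3, 2)),
        )
        if corruption == "dup_condition":
            kwargs["condition_values"] = np.array([20.0, 20.0, 30.0])
        elif corruption == "bad_abs_shape":
            kwargs["absorbances"] = np.ones((2, 2))
        elif corruption == "inf_wavelength":
            kwargs["wavelengths_nm"] = np.array([310.0, np.inf])
        else:
            kwargs["condition_values"] = np.array([])
            kwargs["intensities"] = np.ones((0, 2))
        with pytest.raises(ValidationError):
            SpectrumSeries(**kwargs)


class TestReadWrite:
    def test_long_format_shape(self, tmp_path):
        path = tmp_path / "long.csv"
        rows = ["condition,wavelength_nm,intensity"]
        for ci, c in enumerate([20, 25, 30]):
            for wi, w in enumerate([310, 320, 330, 340, 350]):
                rows.append(f"{c},{w},{ci * 5 + wi + 1}")
        path.write_text("\n".join(rows) + "\n")
        s = read_spectrum_series(
            path, {"probe_kind": "trp_fluorescence", "axis_kind": "temperature_C"}
        )
        assert s.intensities.shape == (3, 5)
        assert s.intensities[1, 2] == 8.0

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "condition,wavelength_nm,intensity\n"
            "20,340,1\n20,350,2\n20,340,3\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_spectrum_series(
                path, {"probe_kind": "trp_fluorescence", "axis_kind": "temperature_C"}
            )

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("condition,intensity\n20,1\n")
        with pytest.raises(SchemaError):
            read_spectrum_series(
                path, {"probe_kind": "trp_fluorescence", "axis_kind": "temperature_C"}
            )

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "condition,wavelength_nm,intensity\n20,310,1\n20,320,oops\n"
        )
        with pytest.raises(ParseError, match="row 2"):
            read_spectrum_series(
                path, {"probe_kind": "trp_fluorescence", "axis_kind": "temperature_C"}
            )

    def test_wide_format(self, tmp_path):
        path = tmp_path / "wide.tsv"
        path.write_text(
            "temperature\t310\t320\t330\n20\t1\t2\t3\n25\t4\t5\t6\n"
        )
        s = read_spectrum_series(
            path,
            {"format": "wide", "probe_kind": "far_uv_cd", "axis_kind": "temperature_C"},
        )
        assert s.intensities.shape == (2, 3)
        assert s.intensities[1, 0] == 4.0

    def test_round_trip_identity(self, tmp_path, small_series):
        path = tmp_path / "series.csv"
        write_spectrum_series(small_series, path)
        back = read_spectrum_series(path)
        np.testing.assert_allclose(
            back.condition_values, small_series.condition_values, rtol=1e-11
        )
        np.testing.assert_allclose(
            back.wavelengths_nm, small_series.wavelengths_nm, rtol=1e-11
        )
        np.testing.assert_allclose(
            back.intensities, small_series.intensities, rtol=1e-11
        )
        np.testing.assert_allclose(
            back.absorbances, small_series.absorbances, rtol=1e-11
        )
        assert back.probe_kind == small_series.probe_kind
        assert back.axis_kind == small_series.axis_kind
        assert back.excitation_nm == pytest.approx(295.0)

    def test_wide_round_trips_through_long(self, tmp_path):
        wide = tmp_path / "wide.csv"
        wide.write_text("pH,400,500\n7,1.5,2.5\n5,3.5,4.5\n3,5.5,6.5\n")
        s = read_spectrum_series(
            wide, {"format": "wide", "probe_kind": "ans", "axis_kind": "pH"}
        )
        out = tmp_path / "long.csv"
        write_spectrum_series(s, out)
        back = read_spectrum_series(out)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-11)
        np.testing.assert_allclose(back.condition_values, s.condition_values)

    def test_write_requires_nonempty(self, tmp_path):
        with pytest.raises(ValidationError):
            SpectrumSeries(
                probe_kind="rls",
                axis_kind="pH",
                condition_values=[],
                wavelengths_nm=[400.0],
                intensities=np.zeros((0, 1)),
            )

    def test_absorbance_columns_written(self, tmp_path, small_series):
        path = tmp_path / "series.csv"
        write_spectrum_series(small_series, path)
        header = [
            ln for ln in path.read_text().splitlines() if not ln.startswith("#")
        ][0]
        assert "a_ex" in header and "a_em" in header

    @settings(
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        n_cond=st.integers(2, 5),
        n_wl=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_round_trip_random_series(self, tmp_path, n_cond, n_wl, seed):
        rng = np.random.default_rng(seed)
        s = SpectrumSeries(
            probe_kind="trp_fluorescence",
            axis_kind="temperature_C",
            condition_values=np.sort(rng.uniform(10, 90, n_cond)),
            wavelengths_nm=np.sort(rng.uniform(300, 400, n_wl)),
            intensities=rng.uniform(-10, 1e4, size=(n_cond, n_wl)),
        )
        path = tmp_path / f"r{seed}.csv"
        write_spectrum_series(s, path)
        back = read_spectrum_series(path)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-11)
        np.testing.assert_allclose(back.condition_values, s.condition_values, rtol=1e-11)


class TestCurveTypes:
    def test_unfolding_curve_length_mismatch(self):
        with pytest.raises(ValidationError):
            UnfoldingCurve(
                axis_kind=AxisKind.PH, x=[1.0, 2.0], y=[1.0], observable_label="x"
            )

    def test_fraction_curve_bounds(self):
        f = FractionCurve(
            axis_kind=AxisKind.PH, x=[3.0, 2.0, 1.0], f_u=[0.0, 0.5, 1.0]
        )
        assert f.f_u_raw is not None

    def test_fraction_curve_raw_preserved(self):
        f = FractionCurve(
            axis_kind=AxisKind.DENATURANT_M,
            x=[0.0, 1.0],
            f_u=[0.0, 1.0],
            f_u_raw=[-0.02, 1.03],
        )
        assert f.f_u_raw[0] == pytest.approx(-0.02)
        assert f.f_u[0] == 0.0
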