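import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nirtransfer as nt
from nirtransfer.spectra import _fmt


class TestIO:
    def test_write_read_roundtrip_bit_stable(self, small_set, tmp_path):
        """Re-serializing a read file reproduces the text byte for byte."""
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        nt.write_spectra(p1, small_set)
        back = nt.read_spectra(p1)
        assert back == small_set
        nt.write_spectra(p2, back)
        assert p1.read_text() == p2.read_text()

    def test_tsv_dialect(self, small_set, tmp_path):
        p = tmp_path / "a.tsv"
        nt.write_spectra(p, small_set)
        assert "\t" in p.read_text().splitlines()[0]
        assert nt.read_spectra(p) == small_set

    def test_non_monotonic_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,700,650,800\ns1,0.1,0.2,0.3\n")
        with pytest.raises(nt.FormatError, match="column"):
            nt.read_spectra(p)

    def test_ragged_row_names_row_index(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("sample_id,700,750,800\ns1,0.1,0.2,0.3\ns2,0.1,0.2\n")
        with pytest.raises(nt.FormatError, match="row 2"):
            nt.read_spectra(p)

    def test_large_simulated_matrix_roundtrip(self, tmp_path):
        src, _, _ = nt.generate_pair(
            nt.SimulationConfig(n_samples=90, seed=7)
        )
        p = tmp_path / "big.csv"
        nt.write_spectra(p, src)
        back = nt.read_spectra(p)
        np.testing.assert_allclose(back.absorbance, src.absorbance, rtol=1e-12)
        assert back.sample_ids == src.sample_ids

    @given(
        rows=st.lists(
            st.lists(
                st.floats(-10, 10, allow_nan=False, width=64),
                min_size=3,
                max_size=3,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_roundtrip_any_values(self, rows, tmp_path_factory):
        s = nt.SpectrumSet(
            wavelengths=np.array([900.0, 1000.0, 1100.0]),
            absorbance=np.array(rows),
        )
        p = tmp_path_factory.mktemp("h") / "x.csv"
        nt.write_spectra(p, s)
        assert np.array_equal(nt.read_spectra(p).absorbance, s.absorbance)

    def test_fmt_is_shortest_exact_repr(self):
        x = 0.1 + 0.2
        assert float(_fmt(x)) == x


class TestValidation:
    def test_axis_column_mismatch(self):
        with pytest.raises(nt.ShapeError):
            nt.SpectrumSet(
                wavelengths=[1000.0, 1100.0],
                absorbance=np.zeros((2, 3)),
            )

    def test_reference_length_mismatch(self):
        with pytest.raises(nt.ShapeError):
            nt.SpectrumSet(
                wavelengths=[1000.0, 1100.0],
                absorbance=np.zeros((2, 2)),
                references=[1.0],
            )

    def test_nan_absorbance_rejected(self):
        with pytest.raises(nt.FormatError):
            nt.SpectrumSet(
                wavelengths=[1000.0, 1100.0],
                absorbance=np.array([[0.1, np.nan]]),
            )


class TestPreprocess:
    def test_none_is_identity(self, small_set):
        assert nt.apply_preprocess(small_set, nt.PreprocessSpec()) is small_set

    def test_none_rejects_parameters(self):
        with pytest.raises(nt.ParameterError):
            nt.PreprocessSpec(method="none", parameters={"window_length": 5})

    def test_first_derivative_of_ramp_is_constant(self):
        wl = np.linspace(900, 1700, 125)
        a, b = 0.0031, -1.7
        s = nt.SpectrumSet(wavelengths=wl, absorbance=(a * wl + b)[None, :])
        out = nt.apply_preprocess(
            s, nt.PreprocessSpec(method="first_derivative")
        )
        np.testing.assert_allclose(out.absorbance, a, atol=1e-10)
        np.testing.assert_array_equal(out.wavelengths, wl)

    def test_savgol_exact_on_quadratic(self):
        wl = np.arange(1000.0, 1050.0)
        q = 2e-4 * (wl - 1020) ** 2 - 0.3
        s = nt.SpectrumSet(wavelengths=wl, absorbance=q[None, :])
        out = nt.apply_preprocess(
            s,
            nt.PreprocessSpec(
                method="savitzky_golay_smooth",
                parameters={"window_length": 5, "polyorder": 2},
            ),
        )
        np.testing.assert_allclose(out.absorbance[0], q, atol=1e-9)

    def test_savgol_matches_per_window_polyfit(self, rng):
        """Interior smoothed values equal a direct quadratic refit per window."""
        wl = np.arange(100.0, 131.0)
        y = rng.normal(size=wl.size)
        s = nt.SpectrumSet(wavelengths=wl, absorbance=y[None, :])
        out = nt.apply_preprocess(
            s,
            nt.PreprocessSpec(
                method="savitzky_golay_smooth",
                parameters={"window_length": 7, "polyorder": 2},
            ),
        ).absorbance[0]
        for j in range(3, wl.size - 3):
            x = np.arange(-3.0, 4.0)
            coef = np.polyfit(x, y[j - 3 : j + 4], 2)
            assert out[j] == pytest.approx(np.polyval(coef, 0.0), abs=1e-9)

    def test_window_longer_than_axis(self, small_set):
        with pytest.raises(nt.ParameterError):
            nt.apply_preprocess(
                small_set,
                nt.PreprocessSpec(
                    method="savitzky_golay_smooth",
                    parameters={"window_length": 99},
                ),
            )

    def test_snv_rows_standardized(self, small_set):
        out = nt.apply_preprocess(small_set, nt.PreprocessSpec(method="snv"))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1, atol=1e-12)


class TestAxisOps:
    def test_restrict_interval_arithmetic(self):
        s = nt.SpectrumSet(
            wavelengths=[1.0, 2.0, 3.0, 4.0, 5.0],
            absorbance=np.arange(10.0).reshape(2, 5),
        )
        out = nt.restrict_wavelengths(s, 2.5, 4.5)
        np.testing.assert_array_equal(out.wavelengths, [3.0, 4.0])
        np.testing.assert_array_equal(out.absorbance, [[2.0, 3.0], [7.0, 8.0]])

    def test_restrict_full_range_identity(self, small_set):
        out = nt.restrict_wavelengths(small_set, 1000.0, 1400.0)
        assert out == small_set.with_absorbance(small_set.absorbance)

    def test_restrict_drops_noisy_band(self):
        """Tablet-style grid: keeping 600-1792 nm cuts the 1800-1900 region."""
        wl = np.arange(600.0, 1900.0, 2.0)  # 650 points
        s = nt.SpectrumSet(wavelengths=wl, absorbance=np.ones((1, wl.size)))
        out = nt.restrict_wavelengths(s, 600.0, 1792.0)
        assert out.wavelengths[-1] <= 1792.0
        assert out.n_wavelengths == np.sum(wl <= 1792.0)

    def test_restrict_empty_selection(self, small_set):
        with pytest.raises(nt.RangeError):
            nt.restrict_wavelengths(small_set, 2000.0, 2100.0)

    def test_resample_identity(self, small_set):
        out = nt.resample_to_axis(small_set, small_set.wavelengths)
        np.testing.assert_array_equal(out.absorbance, small_set.absorbance)

    def test_resample_linear_exact_at_midpoints(self):
        wl = np.linspace(1000.0, 1100.0, 11)
        ramp = 0.01 * wl - 3.0
        s = nt.SpectrumSet(wavelengths=wl, absorbance=ramp[None, :])
        mid = (wl[:-1] + wl[1:]) / 2
        out = nt.resample_to_axis(s, mid)
        np.testing.assert_allclose(out.absorbance[0], 0.01 * mid - 3.0, atol=1e-12)

    def test_resample_roundtrip_within_curvature_bound(self):
        """Fine -> coarse -> fine error obeys the h^2/8 max|f''| bound."""
        cfg = nt.SimulationConfig(n_samples=1, noise_sd=0.0,
                                  reference_noise_sd=0.0, seed=3)
        src, _, _ = nt.generate_pair(cfg)
        fine = src.wavelengths
        coarse = np.linspace(fine[0], fine[-1], 125)
        down = nt.resample_to_axis(src, coarse)
        back = nt.resample_to_axis(down, fine)
        h_f = fine[1] - fine[0]
        h_c = coarse[1] - coarse[0]
        f2 = np.abs(np.diff(src.absorbance[0], 2)).max() / h_f**2
        bound = 2 * (h_c**2 / 8) * f2  # one interpolation error each way
        assert np.abs(back.absorbance - src.absorbance).max() <= bound

    def test_resample_refuses_extrapolation(self, small_set):
        with pytest.raises(nt.RangeError):
            nt.resample_to_axis(small_set, np.array([900.0, 1200.0]))

    def test_operations_never_reorder_samples(self, small_set):
        for out in (
            nt.restrict_wavelengths(small_set, 1000.0, 1300.0),
            nt.resample_to_axis(small_set, np.array([1050.0, 1200.0, 1350.0])),
            nt.apply_preprocess(small_set, nt.PreprocessSpec(method="snv")),
        ):
            assert out.sample_ids == small_set.sample_ids
            np.testing.assert_array_equal(out.references, small_set.references)

    def test_wavenumber_conversion(self):
        nm, ab = nt.wavenumber_to_wavelength(
            np.array([10000.0, 6000.0, 4000.0]), np.array([[1.0, 2.0, 3.0]])
        )
        np.testing.assert_allclose(nm, [1000.0, 1e7 / 6000, 2500.0])
        np.testing.assert_array_equal(ab, [[1.0, 2.0, 3.0]])
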