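import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amorphotrack.spectra import (
    CompositeGeometry,
    DielectricSpectrum,
    SpectraSeries,
    compose_composite,
    deconvolve_composite,
    normalize_peak,
    read_spectra,
    resample_series,
    write_spectra,
)

from conftest import hn_spectrum
from amorphotrack.synthetic import ArrheniusLaw, ProcessSpec


def _simple_spectrum(T=300.0, n=16, scale=1.0):
    f = np.logspace(-1, 4, n)
    return DielectricSpectrum(
        T=T, freq=f, eps_real=3.0 + 2.0 / (1.0 + f), eps_imag=scale * f / (1.0 + f**2)
    )


class TestValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 8"):
            DielectricSpectrum(300, [1, 2, 3], [1, 1, 1], [0, 0, 0])

    def test_negative_frequency_rejected(self):
        f = np.array([-1.0, 1, 2, 3, 4, 5, 6, 7])
        with pytest.raises(ValueError, match="row"):
            DielectricSpectrum(300, f, np.ones(8), np.zeros(8))

    def test_non_monotone_frequency(self):
        f = np.array([1.0, 2, 3, 3, 4, 5, 6, 7])
        with pytest.raises(ValueError, match="increasing"):
            DielectricSpectrum(300, f, np.ones(8), np.zeros(8))

    def test_negative_loss_kept_but_counted(self):
        f = np.logspace(0, 3, 10)
        ei = np.linspace(-0.01, 1.0, 10)
        s = DielectricSpectrum(300, f, np.ones(10), ei)
        assert s.n_negative_loss == 1
        assert s.eps_imag[0] == pytest.approx(-0.01)

    def test_series_monotone_index(self):
        s1 = _simple_spectrum(300.0)
        s2 = _simple_spectrum(300.0)
        with pytest.raises(ValueError, match="monotone"):
            SpectraSeries([s1, s2])


class TestIO:
    def test_round_trip(self, tmp_path):
        series = SpectraSeries([_simple_spectrum(T) for T in (300.0, 310.0, 320.0)])
        path = tmp_path / "s.csv"
        write_spectra(series, path)
        back = read_spectra(path)
        for a, b in zip(series, back):
            assert b.T == a.T
            np.testing.assert_allclose(b.freq, a.freq, rtol=1e-9)
            np.testing.assert_allclose(b.eps_real, a.eps_real, rtol=1e-9)
            np.testing.assert_allclose(b.eps_imag, a.eps_imag, rtol=1e-9)

    def test_negative_frequency_row_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = ["temp_K,freq_hz,eps_real,eps_imag"]
        rows += [f"300,{f},3.0,0.1" for f in [1, 2, 3, -4, 5, 6, 7, 8]]
        path.write_text("\n".join(rows))
        with pytest.raises(ValueError, match="row"):
            read_spectra(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("temp_K,freq_hz,eps_real\n300,1,3\n")
        with pytest.raises(ValueError, match="eps_imag"):
            read_spectra(path)

    def test_mixed_grids_require_resample(self, tmp_path):
        rows = ["temp_K,freq_hz,eps_real,eps_imag"]
        rows += [f"300,{10**k},3.0,0.1" for k in np.linspace(0, 3, 9)]
        rows += [f"310,{10**k},3.0,0.1" for k in np.linspace(0.1, 3.1, 9)]
        path = tmp_path / "mixed.csv"
        path.write_text("\n".join(rows))
        with pytest.raises(ValueError, match="resample"):
            read_spectra(path)
        series = read_spectra(path, resample="log-linear")
        assert series.uniform_grid()

    def test_resample_interpolation_oracle(self):
        # eps'' = f/(1+f^2) is linear in neither f nor log f, but dense
        # log-linear interpolation must track the analytic curve closely
        s1 = _simple_spectrum(300.0, n=120)
        s2 = DielectricSpectrum(
            T=310.0,
            freq=s1.freq * 1.07,
            eps_real=3.0 + 2.0 / (1.0 + s1.freq * 1.07),
            eps_imag=(s1.freq * 1.07) / (1.0 + (s1.freq * 1.07) ** 2),
        )
        out = resample_series(SpectraSeries([s1, s2]), n=100)
        f = out.spectra[0].freq
        np.testing.assert_allclose(
            out.spectra[0].eps_imag, f / (1.0 + f**2), rtol=2e-3
        )


class TestComposite:
    def test_identity_at_full_fill(self):
        s = _simple_spectrum()
        geom = CompositeGeometry(fill_fraction=1.0, matrix_eps=3.0 + 0.0j)
        out = compose_composite(s, geom)
        np.testing.assert_allclose(out.eps_real, s.eps_real, rtol=1e-15)
        np.testing.assert_allclose(out.eps_imag, s.eps_imag, rtol=1e-15)

    def test_mixing_arithmetic(self):
        # f = 0.5, matrix 3+0i, api 5-2i -> 4-1i
        f = np.logspace(0, 3, 8)
        api = DielectricSpectrum(300, f, np.full(8, 5.0), np.full(8, 2.0))
        geom = CompositeGeometry(fill_fraction=0.5, matrix_eps=3.0 + 0.0j)
        out = compose_composite(api, geom)
        np.testing.assert_allclose(out.eps_real, 4.0)
        np.testing.assert_allclose(out.eps_imag, 1.0)

    def test_lossless_matrix_scales_loss(self):
        s = _simple_spectrum()
        geom = CompositeGeometry(fill_fraction=0.35, matrix_eps=3.8 + 0.0j)
        out = compose_composite(s, geom)
        np.testing.assert_allclose(out.eps_imag, 0.35 * s.eps_imag, rtol=1e-14)

    @pytest.mark.parametrize("fill", [0.1, 0.35, 0.9, 1.0])
    def test_round_trip_machine_precision(self, fill):
        s = _simple_spectrum()
        geom = CompositeGeometry(fill_fraction=fill, matrix_eps=3.8 - 0.05j)
        back = deconvolve_composite(compose_composite(s, geom), geom)
        assert np.max(np.abs(back.eps_real - s.eps_real)) < 1e-12
        assert np.max(np.abs(back.eps_imag - s.eps_imag)) < 1e-12

    @given(fill=st.floats(0.05, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, fill):
        s = _simple_spectrum()
        geom = CompositeGeometry(fill_fraction=fill, matrix_eps=2.5 - 0.1j)
        back = deconvolve_composite(compose_composite(s, geom), geom)
        assert np.max(np.abs(back.eps_imag - s.eps_imag)) < 1e-10

    def test_mixing_preserves_nonnegative_loss(self):
        s = _simple_spectrum()
        geom = CompositeGeometry(fill_fraction=0.4, matrix_eps=3.0 - 0.2j)
        out = compose_composite(s, geom)
        assert np.all(out.eps_imag >= 0)

    def test_invalid_fill_rejected(self):
        with pytest.raises(ValueError, match="fill_fraction"):
            CompositeGeometry(fill_fraction=0.0, matrix_eps=3.0)
        with pytest.raises(ValueError, match="fill_fraction"):
            CompositeGeometry(fill_fraction=1.2, matrix_eps=3.0)

    def test_implausible_geometry_flagged(self):
        s = _simple_spectrum()
        geom = CompositeGeometry(fill_fraction=0.2, matrix_eps=3.0 + 0.0j)
        total = compose_composite(s, geom)
        wrong = CompositeGeometry(fill_fraction=0.01, matrix_eps=30.0 + 0.0j)
        with pytest.warns(UserWarning, match="implausible"):
            out = deconvolve_composite(total, wrong)
        assert out.warnings_

    def test_from_porosity(self):
        geom = CompositeGeometry.from_porosity(0.3, 0.9, 3.8 + 0.0j)
        assert geom.fill_fraction == pytest.approx(0.27)


class TestNormalizePeak:
    def test_debye_fwhm(self):
        proc = ProcessSpec("d", 2.0, 1.0, 1.0, ArrheniusLaw(1.0 / (2 * np.pi), 1e-12))
        s = hn_spectrum([proc], freq=np.logspace(-4, 4, 4001))
        pk = normalize_peak(s)
        above = pk.x[pk.y >= 0.5]
        fwhm = np.log10(above.max() / above.min())
        assert fwhm == pytest.approx(np.log10(7 + 4 * np.sqrt(3)), abs=0.01)

    def test_peak_at_window_edge_rejected(self):
        s = _simple_spectrum()  # peak of f/(1+f^2) at f=1
        with pytest.raises(ValueError, match="interior"):
            normalize_peak(s, window=(2.0, 1e4))

    def test_scale_invariance(self):
        f = np.logspace(-4, 4, 201)
        s1 = hn_spectrum(
            [ProcessSpec("a", 3.0, 0.7, 0.8, ArrheniusLaw(1e-2, 1e-12))], freq=f
        )
        s2 = hn_spectrum(
            [ProcessSpec("a", 3.0, 0.7, 0.8, ArrheniusLaw(1e-4, 1e-12))], freq=f
        )
        p1, p2 = normalize_peak(s1, (1e-3, 1e3)), normalize_peak(s2, (1e-1, 1e5))
        # tau ratio of 100 on a 25-points/decade grid: the normalized grids
        # share exact sample points — compare y there
        l1 = np.round(np.log10(p1.x), 9)
        l2 = np.round(np.log10(p2.x), 9)
        common, i1, i2 = np.intersect1d(l1, l2, return_indices=True)
        assert common.size > 50
        assert np.max(np.abs(p1.y[i1] - p2.y[i2])) < 1e-10
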