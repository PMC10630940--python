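import numpy as np
import pytest

from amorphotrack.fitting import fit_hn, tau_max_from_hn
from amorphotrack.spectra import deconvolve_composite, write_spectra
from amorphotrack.synthetic import (
    ArrheniusLaw,
    CrossoverLaw,
    ProcessSpec,
    VFTLaw,
    annealed_preset,
    default_freq_grid,
    gen_dissolution,
    gen_dsc,
    gen_spectra_series,
    gen_spectrum,
    kissinger_c_k,
    kissinger_tc,
    law_tg,
    preset,
    vft_for_tg,
)
from amorphotrack.thermal import kissinger_fit


class TestLaws:
    def test_vft_for_tg_hits_100s(self):
        law = vft_for_tg(306.7)
        assert law.tau(306.7) == pytest.approx(100.0, rel=1e-10)
        assert law_tg(law) == pytest.approx(306.7, abs=1e-6)

    def test_vft_below_t0_domain_error(self):
        law = VFTLaw(1e-14, 8.0, 250.0)
        proc = ProcessSpec("alpha", 2.0, 0.8, 0.8, law)
        with pytest.raises(ValueError, match="alpha"):
            gen_spectrum([proc], 240.0, default_freq_grid())

    def test_crossover_law_continuous(self):
        law = CrossoverLaw(VFTLaw(1e-14, 8.0, 250.0), 320.0, 150.0)
        assert law.tau(320.0 - 1e-9) == pytest.approx(law.tau(320.0 + 1e-9), rel=1e-6)

    def test_process_invariants(self):
        with pytest.raises(ValueError):
            ProcessSpec("x", -1.0, 0.8, 0.8, VFTLaw(1e-14, 8, 250))
        with pytest.raises(ValueError):
            ProcessSpec("x", 1.0, 1.5, 0.8, VFTLaw(1e-14, 8, 250))


class TestGenSpectrum:
    def test_debye_closed_form(self, debye_process):
        f = default_freq_grid(1e-1, 1e5, 40)
        s = gen_spectrum([debye_process], 300.0, f, 0.0, 0, eps_inf=3.0)
        i = np.argmax(s.eps_imag)
        assert s.eps_imag[i] == pytest.approx(1.0, rel=1e-4)  # delta_eps/2
        assert s.freq[i] == pytest.approx(1.0 / (2 * np.pi * 1e-3), rel=0.05)

    def test_bulk_alpha_round_trip_2pct(self):
        pst = preset("bulk_apz")
        f = default_freq_grid(1e-3, 1e6, 12)
        s = gen_spectrum(
            [pst.processes[0]], 313.0, f, 0.0, 0, eps_inf=pst.eps_inf
        )
        fit = fit_hn(s, 1)
        p = fit.processes[0]
        alpha = pst.processes[0]
        assert p.delta_eps == pytest.approx(alpha.delta_eps, rel=0.02)
        assert p.tau_hn == pytest.approx(alpha.tau(313.0), rel=0.02)
        assert p.alpha == pytest.approx(alpha.alpha, rel=0.02)
        assert p.gamma == pytest.approx(alpha.gamma, rel=0.02)

    def test_sum_rule_quadrature(self, hn_process):
        f = default_freq_grid(1e-10, 1e10, 20)
        s = gen_spectrum([hn_process], 300.0, f, 0.0, 0)
        integral = np.trapezoid(s.eps_imag, np.log(2 * np.pi * s.freq))
        assert integral == pytest.approx(np.pi / 2 * 5.0, rel=0.01)

    def test_noise_reproducible_and_seed_dependent(self, hn_process, freq_grid):
        a = gen_spectrum([hn_process], 300.0, freq_grid, 0.02, seed=5)
        b = gen_spectrum([hn_process], 300.0, freq_grid, 0.02, seed=5)
        c = gen_spectrum([hn_process], 300.0, freq_grid, 0.02, seed=6)
        np.testing.assert_array_equal(a.eps_imag, b.eps_imag)
        assert not np.allclose(a.eps_imag, c.eps_imag)

    def test_negative_noise_rejected(self, hn_process, freq_grid):
        with pytest.raises(ValueError, match="noise"):
            gen_spectrum([hn_process], 300.0, freq_grid, -0.01, 0)


class TestGenSeries:
    def test_bulk_series_count_and_monotone_peak(self):
        series = gen_spectra_series("bulk_apz", 293.0, 337.0, 2.0)
        assert len(series) == 23
        # above Tg the structural peak moves up in frequency with T
        # (locate it on the conductivity-free alpha process)
        alpha = preset("bulk_apz").processes[0]
        f = default_freq_grid()
        peaks = []
        for T in [s.T for s in series if s.T >= 311]:
            s = gen_spectrum([alpha], T, f, 0.0, 0)
            peaks.append(s.freq[np.argmax(s.eps_imag)])
        assert np.all(np.diff(peaks) > 0)

    def test_slow_cool_descending(self):
        series = gen_spectra_series("bulk_apz", 311.0, 321.0, 2.0, "slow_cool")
        assert np.all(np.diff(series.index) < 0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gen_spectra_series("bulk_apz", 320.0, 310.0, 2.0)

    def test_seeded_csv_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        for p in (p1, p2):
            series = gen_spectra_series(
                "bulk_apz", 311.0, 321.0, 2.0, seed=9, noise_rel=0.02
            )
            write_spectra(series, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_confined_composite_peak_recovered_after_deconvolution(self):
        pst = preset("native_sio2")
        f = default_freq_grid(1e-3, 1e6, 12)
        series = gen_spectra_series(pst, 325.0, 331.0, 2.0, freq_grid=f)
        geom = pst.matrix.geometry()
        for s in series:
            api = deconvolve_composite(s, geom)
            m = api.freq >= 0.05
            f_obs = api.freq[m][np.argmax(api.eps_imag[m])]
            from amorphotrack.fitting import HNProcess

            core = pst.processes[0]
            tau_pk = tau_max_from_hn(
                HNProcess(1.0, core.tau(s.T), core.alpha, core.gamma)
            )
            f_true = 1.0 / (2 * np.pi * tau_pk)
            # grid resolution is 12 points/decade
            assert abs(np.log10(f_obs / f_true)) < 1.5 / 12

    def test_annealed_preset_is_bulk_like(self):
        pst = annealed_preset("native_sio2")
        assert len(pst.processes) == 1
        assert law_tg(pst.processes[0].law) == pytest.approx(306.7, abs=1e-6)


class TestGenDSC:
    def test_kissinger_self_consistency(self):
        ck = kissinger_c_k(100.0, 363.0)
        pts = [(r, kissinger_tc(100.0, ck, r)) for r in (2.5, 5, 10, 20)]
        r = kissinger_fit(pts)
        assert r.e_cr_kj == pytest.approx(100.0, rel=1e-3)

    def test_area_scales_with_rate(self):
        spec = preset("bulk_apz").dsc
        a5 = gen_dsc(spec, 5.0)
        a20 = gen_dsc(spec, 20.0)
        # integrate exotherm region relative to rough baseline
        def exo_area(tg, lo, hi):
            m = (tg.T > lo) & (tg.T < hi)
            base = np.linspace(tg.heat_flow[m][0], tg.heat_flow[m][-1], m.sum())
            return np.trapezoid(tg.heat_flow[m] - base, tg.T[m])

        r5 = exo_area(a5, 345, 380)
        r20 = exo_area(a20, 345, 390)
        assert r20 / r5 == pytest.approx(4.0, rel=0.1)

    def test_gibbs_thomson_depression(self):
        from dataclasses import replace

        spec = replace(preset("bulk_apz").dsc, gibbs_thomson_c=80.0)
        plain = gen_dsc(spec, 10.0)
        depressed = gen_dsc(spec, 10.0, pore_diameter_nm=8.0)
        from amorphotrack.thermal import extract_events

        tm0 = extract_events(plain).tm_temps
        tm1 = extract_events(depressed).tm_temps
        assert tm1[0] == pytest.approx(tm0[0] - 10.0, abs=0.2)  # 80/8 = 10 K

    def test_noise_determinism(self):
        spec = preset("bulk_apz").dsc
        a = gen_dsc(spec, 10.0, noise_abs=0.02, seed=3)
        b = gen_dsc(spec, 10.0, noise_abs=0.02, seed=3)
        np.testing.assert_array_equal(a.heat_flow, b.heat_flow)


class TestGenDissolution:
    def test_spring_crash_reference_shape(self):
        # peak ~0.2 mg/mL near 30 min, plateau ~0.1 mg/mL
        t = np.arange(1.0, 181.0, 1.0)
        p = gen_dissolution(
            "spring_crash", preset("bulk_apz").dissolution_params, t, 0.0, 0
        )
        i = np.argmax(p.conc)
        assert p.conc[i] == pytest.approx(0.2, abs=0.05)
        assert 15 <= p.time[i] <= 60
        assert p.conc[-1] == pytest.approx(0.1, abs=0.03)

    def test_prolonged_monotone(self):
        p = gen_dissolution("prolonged", {"c_inf": 0.35, "k": 0.02}, noise_rel=0.0)
        assert np.all(np.diff(p.conc) >= 0)

    def test_negative_param_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gen_dissolution("prolonged", {"c_inf": -0.1, "k": 0.02})

    def test_nonnegative_after_noise(self):
        p = gen_dissolution("flat", {"c": 0.001}, noise_rel=2.0, seed=0)
        assert np.all(p.conc >= 0)


class TestAnnealing:
    def test_tau_drifts_up_and_confinement_erased(self):
        from amorphotrack.relaxmap import TauMap, detect_crossover
        from amorphotrack.spectra import deconvolve_composite
        from amorphotrack.synthetic import gen_annealing_series

        pst = preset("native_sio2")
        ser = gen_annealing_series(pst, t_anneal=305.0, seed=0)
        assert ser.index_kind == "time_h"
        geom = pst.matrix.geometry()
        taus = []
        for s in ser:
            api = deconvolve_composite(s, geom)
            i = np.argmax(api.eps_imag)
            taus.append(1.0 / (2 * np.pi * api.freq[i]))
        # loss peaks shift to lower frequency: tau nondecreasing with time
        assert np.all(np.diff(taus) >= -1e-15)

    def test_annealed_map_no_crossover(self):
        from amorphotrack.relaxmap import TauMap, detect_crossover
        from amorphotrack.synthetic import law_tg

        pst = annealed_preset("native_sio2")
        alpha = pst.processes[0]
        T = np.arange(309.0, 340.01, 1.0)
        taus = np.array([alpha.tau(t) for t in T])
        rng = np.random.default_rng(3)
        lt = np.log10(taus) + 0.05 * rng.standard_normal(T.size)
        r = detect_crossover(TauMap("a", T, 10.0**lt))
        assert not r.detected
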