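import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amorphotrack._constants import EPS0
from amorphotrack.fitting import (
    HNFit,
    HNProcess,
    cm_jg_test,
    fit_hn,
    hn_eval,
    tau_max_from_hn,
)
from amorphotrack.synthetic import ArrheniusLaw, ProcessSpec, gen_spectrum

from conftest import hn_spectrum


def hn_polar_oracle(delta_eps, tau, alpha, gamma, eps_inf, freq):
    """Independent HN evaluation via the polar (modulus/phase) expansion."""
    w = 2 * np.pi * np.asarray(freq)
    wt = (w * tau) ** alpha
    c = np.cos(np.pi * alpha / 2)
    s = np.sin(np.pi * alpha / 2)
    r = (1 + 2 * wt * c + wt**2) ** (-gamma / 2)
    theta = gamma * np.arctan2(wt * s, 1 + wt * c)
    return eps_inf + delta_eps * r * np.cos(theta), delta_eps * r * np.sin(theta)


class TestHNEval:
    def test_debye_closed_form(self):
        fit = HNFit([HNProcess(4.0, 1e-3, 1.0, 1.0)], 3.0)
        f_star = 1.0 / (2 * np.pi * 1e-3)
        eps = hn_eval(fit, np.array([f_star / 100, f_star, f_star * 100]))
        assert -eps.imag[1] == pytest.approx(2.0, rel=1e-12)

    def test_static_limit(self):
        fit = HNFit([HNProcess(4.0, 1e-3, 0.8, 0.7), HNProcess(1.0, 1e-6, 0.6, 1.0)], 3.0)
        eps = hn_eval(fit, np.array([1e-9] * 8 + [1e12]))
        assert eps.real[0] == pytest.approx(8.0, rel=1e-4)
        assert eps.real[-1] == pytest.approx(3.0, rel=1e-4)

    def test_conductivity_term(self):
        fit = HNFit([HNProcess(4.0, 1e-3, 1.0, 1.0)], 3.0, sigma_dc=1e-11)
        f = np.array([1e-3] * 8)
        eps = hn_eval(fit, f)
        expected_cond = 1e-11 / (EPS0 * 2 * np.pi * 1e-3)
        assert -eps.imag[0] == pytest.approx(expected_cond, rel=1e-3)

    def test_matches_polar_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            de = rng.uniform(0.5, 10)
            tau = 10.0 ** rng.uniform(-8, 0)
            a = rng.uniform(0.2, 1.0)
            g = rng.uniform(0.2, 1.0)
            freq = 10.0 ** rng.uniform(-2, 6, size=20)
            fit = HNFit([HNProcess(de, tau, a, g)], 3.0)
            eps = hn_eval(fit, freq)
            er, ei = hn_polar_oracle(de, tau, a, g, 3.0, freq)
            np.testing.assert_allclose(eps.real, er, rtol=1e-12)
            np.testing.assert_allclose(-eps.imag, ei, rtol=1e-12)


class TestTauMax:
    def test_debye_identity(self):
        assert tau_max_from_hn(HNProcess(1, 2e-3, 1.0, 1.0)) == pytest.approx(2e-3)

    def test_cole_cole_symmetric(self):
        assert tau_max_from_hn(HNProcess(1, 5e-4, 0.5, 1.0)) == pytest.approx(5e-4)

    def test_asymmetric_vs_argmax(self):
        p = HNProcess(1.0, 1.0, 1.0, 0.5)
        tm = tau_max_from_hn(p)
        f = np.logspace(-6, 6, 10000)
        ei = -hn_eval(HNFit([p], 3.0), f).imag
        tm_num = 1.0 / (2 * np.pi * f[np.argmax(ei)])
        step = 12.0 / 9999
        assert abs(np.log10(tm / tm_num)) <= step

    @given(a=st.floats(0.15, 1.0), g=st.floats(0.15, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_closed_form_equals_argmax_property(self, a, g):
        p = HNProcess(1.0, 1.0, a, g)
        tm = tau_max_from_hn(p)
        f = np.logspace(-6, 6, 10000)
        ei = -hn_eval(HNFit([p], 3.0), f).imag
        tm_num = 1.0 / (2 * np.pi * f[np.argmax(ei)])
        assert abs(np.log10(tm / tm_num)) <= 12.0 / 9999


class TestFitHN:
    def test_noiseless_recovery(self, freq_grid, hn_process):
        s = gen_spectrum([hn_process], 300, freq_grid, 0.0, 0, eps_inf=3.0)
        fit = fit_hn(s, 1)
        p = fit.processes[0]
        assert p.delta_eps == pytest.approx(5.0, rel=1e-3)
        assert p.tau_hn == pytest.approx(1e-2, rel=1e-3)
        assert p.alpha == pytest.approx(0.8, rel=1e-3)
        assert p.gamma == pytest.approx(0.6, rel=1e-3)
        assert fit.eps_inf == pytest.approx(3.0, rel=1e-3)

    def test_noisy_recovery_with_conductivity(self, freq_grid, hn_process):
        class Sig:
            def sigma(self, proc, T):
                return 1e-11

        for seed in range(5):
            s = gen_spectrum(
                [hn_process], 300, freq_grid, 0.01, seed, eps_inf=3.0, conductivity=Sig()
            )
            fit = fit_hn(s, 1, use_conductivity=True, seed=seed)
            p = fit.processes[0]
            assert p.delta_eps == pytest.approx(5.0, rel=0.05)
            assert p.tau_hn == pytest.approx(1e-2, rel=0.10)
            assert p.alpha == pytest.approx(0.8, rel=0.05)
            assert p.gamma == pytest.approx(0.6, rel=0.05)
            assert fit.sigma_dc == pytest.approx(1e-11, rel=0.05)

    def test_two_processes_resolved_when_separated(self, freq_grid):
        p1 = ProcessSpec("a", 5.0, 0.9, 0.8, ArrheniusLaw(1e-2, 1e-12))
        p2 = ProcessSpec("b", 1.0, 0.6, 1.0, ArrheniusLaw(10 ** (-3.5), 1e-12))
        s = gen_spectrum([p1, p2], 300, freq_grid, 0.01, 0, eps_inf=3.0)
        fit = fit_hn(s, 2, seed=0, max_restarts=7)
        assert not any(p.unresolved for p in fit.processes)
        taus = sorted(p.tau_hn for p in fit.processes)
        assert np.log10(taus[1] / taus[0]) == pytest.approx(1.5, abs=0.2)

    def test_close_processes_flagged_unresolved(self, freq_grid):
        p1 = ProcessSpec("a", 5.0, 0.9, 0.8, ArrheniusLaw(1e-2, 1e-12))
        p2 = ProcessSpec("b", 1.0, 0.6, 1.0, ArrheniusLaw(10 ** (-2.3), 1e-12))
        flagged = 0
        for seed in range(3):
            s = gen_spectrum([p1, p2], 300, freq_grid, 0.01, seed, eps_inf=3.0)
            fit = fit_hn(s, 2, seed=seed, max_restarts=7)
            flagged += any(p.unresolved for p in fit.processes)
        assert flagged >= 2

    def test_too_few_points(self):
        f = np.logspace(-1, 2, 10)
        s = hn_spectrum(
            [ProcessSpec("a", 2.0, 0.8, 0.8, ArrheniusLaw(1e-1, 1e-12))],
            freq=f,
        )
        with pytest.raises(ValueError, match="8 points"):
            fit_hn(s, 2)

    def test_peak_outside_window_rejected(self, freq_grid, hn_process):
        s = gen_spectrum([hn_process], 300, freq_grid, 0.0, 0)
        with pytest.raises(ValueError, match="peak"):
            fit_hn(s, 1, window=(1e4, 1e6))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            HNProcess(-1.0, 1e-3, 0.8, 0.8)
        with pytest.raises(ValueError):
            HNProcess(1.0, 1e-3, 1.2, 0.8)
        with pytest.raises(ValueError):
            HNFit([HNProcess(1.0, 1e-3, 0.8, 0.8)], eps_inf=0.5)


class TestSumRule:
    @given(a=st.floats(0.5, 1.0), g=st.floats(0.5, 1.0), de=st.floats(1.0, 8.0))
    @settings(max_examples=15, deadline=None)
    def test_loss_integral_equals_pi_over_2_strength(self, a, g, de):
        # int eps'' dln(omega) = (pi/2) * delta_eps for conductivity-free HN
        f = np.logspace(-10, 12, 3000)
        ei = -hn_eval(HNFit([HNProcess(de, 1e-3, a, g)], 3.0), f).imag
        integral = np.trapezoid(ei, np.log(2 * np.pi * f))
        assert integral == pytest.approx(np.pi / 2 * de, rel=0.01)


class TestCouplingModel:
    def test_uncoupled_limit(self):
        r = cm_jg_test(1e-2, 1.0)
        assert r.n == 0.0
        assert r.tau0 == pytest.approx(1e-2, rel=1e-12)

    def test_arithmetic_oracle(self):
        # beta 0.56, tau_alpha 100 s, t_c 2e-12 s:
        # log10 tau0 = 0.44*log10(2e-12) + 0.56*2
        r = cm_jg_test(100.0, 0.56, t_c=2e-12)
        expected = 0.44 * np.log10(2e-12) + 0.56 * 2.0
        assert np.log10(r.tau0) == pytest.approx(expected, abs=1e-12)

    def test_verdicts(self):
        r = cm_jg_test(100.0, 0.56, t_c=2e-12)
        assert r.verdict == "untested"
        tau0 = r.tau0
        assert cm_jg_test(100.0, 0.56, tau_beta_observed=tau0 * 3).verdict == "consistent"
        assert (
            cm_jg_test(100.0, 0.56, tau_beta_observed=tau0 * 1e3).verdict
            == "inconsistent"
        )
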