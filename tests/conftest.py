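import numpy as np
import pytest

from amorphotrack.fitting import HNFit, HNProcess, hn_eval
from amorphotrack.spectra import DielectricSpectrum
from amorphotrack.synthetic import ArrheniusLaw, ProcessSpec, default_freq_grid


@pytest.fixture
def freq_grid():
    return default_freq_grid(1e-2, 1e6, 12)


@pytest.fixture
def debye_process():
    """Debye: delta_eps = 2, tau = 1e-3 s, alpha = gamma = 1."""
    return ProcessSpec("debye", 2.0, 1.0, 1.0, ArrheniusLaw(1e-3, 1e-12))


@pytest.fixture
def hn_process():
    return ProcessSpec("alpha", 5.0, 0.8, 0.6, ArrheniusLaw(1e-2, 1e-12))


def hn_spectrum(processes, eps_inf=3.0, freq=None, T=300.0) -> DielectricSpectrum:
    """Noise-free spectrum directly from HN model evaluation."""
    if freq is None:
        freq = default_freq_grid(1e-2, 1e6, 12)
    fit = HNFit(
        processes=[
            HNProcess(p.delta_eps, p.tau(T), p.alpha, p.gamma, name=p.name)
            for p in processes
        ],
        eps_inf=eps_inf,
    )
    eps = hn_eval(fit, freq)
    return DielectricSpectrum(T=T, freq=freq, eps_real=eps.real, eps_imag=-eps.imag)
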