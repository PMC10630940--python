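"""Loss-spectrum fitting: Havriliak-Negami processes, KWW transform, CM test.

The complex permittivity model is a superposition of HN terms plus an
optional dc-conductivity contribution on the loss:

    eps*(w) = eps_inf + sum_k d_eps_k / (1 + (i w tau_k)^a_k)^g_k
              - i sigma_dc / (EPS0 w)

with w = 2 pi f.  Fits are least squares on log10 eps'' inside a frequency
window (keeps the conductivity wing from dominating), augmented with a
relative eps' residual so eps_inf is identifiable.

The KWW loss shape is the one-sided Fourier sine transform of
-d/dt exp[-(t/tau)^beta], evaluated by half-period-partitioned Gauss
quadrature with iterated-averaging acceleration of the alternating tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares, minimize_scalar

from ._constants import EPS0, T_C_DEFAULT
from .spectra import DielectricSpectrum, NormalizedPeak

__all__ = [
    "HNProcess",
    "HNFit",
    "KWWFit",
    "CMResult",
    "hn_eval",
    "hn_eval_process",
    "fit_hn",
    "tau_max_from_hn",
    "kww_loss",
    "kww_ft",
    "fit_kww",
    "cm_jg_test",
]


# ---------------------------------------------------------------------------
# HN model
# ---------------------------------------------------------------------------

@dataclass
class HNProcess:
    """One Havriliak-Negami relaxation process."""

    delta_eps: float
    tau_hn: float
    alpha: float
    gamma: float
    name: str = ""
    stderr: dict = field(default_factory=dict)
    unresolved: bool = False

    def __post_init__(self) -> None:
        if self.delta_eps <= 0:
            raise ValueError("delta_eps must be > 0")
        if self.tau_hn <= 0:
            raise ValueError("tau_hn must be > 0")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")


@dataclass
class HNFit:
    """Fitted HN superposition with shared eps_inf and optional sigma_dc."""

    processes: list
    eps_inf: float
    sigma_dc: float | None = None
    stderr: dict = field(default_factory=dict)
    resid_norm: float = float("nan")
    n_restarts_used: int = 0

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError("eps_inf must be >= 1")
        if self.sigma_dc is not None and self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")


def hn_eval_process(proc: HNProcess, freq: np.ndarray) -> np.ndarray:
    """Complex contribution of one HN process (no eps_inf, no conductivity)."""
    w = 2.0 * np.pi * np.asarray(freq, dtype=float)
    return proc.delta_eps / (1.0 + (1j * w * proc.tau_hn) ** proc.alpha) ** proc.gamma


def hn_eval(fit: HNFit, freq: np.ndarray) -> np.ndarray:
    """Evaluate eps*(f) = eps' - i eps'' for the fitted model."""
    freq = np.asarray(freq, dtype=float)
    out = np.full(freq.shape, fit.eps_inf, dtype=complex)
    for p in fit.processes:
        out = out + hn_eval_process(p, freq)
    if fit.sigma_dc:
        out = out - 1j * fit.sigma_dc / (EPS0 * 2.0 * np.pi * freq)
    return out


def tau_max_from_hn(proc: HNProcess) -> float:
    """Loss-peak relaxation time of one HN process (closed form).

    w_max tau_hn = [sin(pi a /(2+2g)) / sin(pi a g/(2+2g))]^(1/a);
    tau_max = 1/w_max.
    """
    a, g = proc.alpha, proc.gamma
    num = math.sin(math.pi * a / (2.0 + 2.0 * g))
    den = math.sin(math.pi * a * g / (2.0 + 2.0 * g))
    return proc.tau_hn * (den / num) ** (1.0 / a)


# ---------------------------------------------------------------------------
# HN fitting
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, n_proc: int, use_cond: bool) -> HNFit:
    procs = []
    for k in range(n_proc):
        de, lt, a, g = theta[4 * k : 4 * k + 4]
        procs.append(HNProcess(10.0 ** de, 10.0 ** lt, a, g))
    eps_inf = theta[4 * n_proc]
    sigma = 10.0 ** theta[4 * n_proc + 1] if use_cond else None
    return HNFit(processes=procs, eps_inf=max(eps_inf, 1.0), sigma_dc=sigma)


def _window_mask(freq: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones(freq.shape, dtype=bool)
    lo, hi = window
    return (freq >= lo) & (freq <= hi)


def fit_hn(
    spectrum: DielectricSpectrum,
    n_processes: int = 1,
    use_conductivity: bool = False,
    window: tuple | None = None,
    init_policy: str = "auto",
    init: HNFit | None = None,
    real_weight: float = 0.3,
    max_restarts: int = 3,
    seed: int = 0,
) -> HNFit:
    """Fit ``n_processes`` HN terms (+ optional sigma_dc) to a spectrum.

    Residual: log10 eps''(model/data) on the window, plus
    ``real_weight * (eps'_model - eps')/eps'`` so the shared eps_inf is
    determined.  Standard errors come from the Jacobian at the solution; a
    process whose delta_eps standard error exceeds its value is flagged
    ``unresolved``.  Raises ``RuntimeError`` on non-convergence after
    jittered restarts, carrying the best residual.
    """
    mask = _window_mask(spectrum.freq, window)
    f = spectrum.freq[mask]
    if f.size < 8 * n_processes:
        raise ValueError("need >= 8 points per fitted process in window")
    y = spectrum.eps_imag[mask]
    yr = spectrum.eps_real[mask]
    pos = y > 0
    if pos.sum() < 8 * n_processes:
        raise ValueError("too few positive-loss points in window")
    logy = np.log10(y[pos])

    # peak location check on the conductivity-corrected loss: the dc wing is
    # part of the model, so it must not count as "the peak"
    if use_conductivity:
        sig0 = y[0] * EPS0 * 2.0 * np.pi * f[0]
        y_chk = y - sig0 / (EPS0 * 2.0 * np.pi * f)
    else:
        y_chk = y
    imax = int(np.argmax(y_chk))
    if imax == 0 or imax == y.size - 1:
        raise ValueError("loss peak not interior to the fit window")

    def residual(theta):
        m = _unpack(theta, n_processes, use_conductivity)
        eps = hn_eval(m, f)
        model_im = np.clip(-eps.imag, 1e-300, None)
        r1 = np.log10(model_im[pos]) - logy
        r2 = real_weight * (eps.real - yr) / yr
        return np.concatenate([r1, r2])

    # initial guesses
    if init is not None:
        theta0 = _pack(init, use_conductivity)
    else:
        theta0 = _auto_init(f, y, yr, n_processes, use_conductivity)

    lb, ub = _bounds(n_processes, use_conductivity)
    rng = np.random.default_rng(seed)
    best = None
    used = 0
    solutions = []
    for attempt in range(max_restarts + 1):
        t0 = theta0 if attempt == 0 else _jitter(theta0, rng, lb, ub)
        try:
            res = least_squares(
                residual, np.clip(t0, lb, ub), bounds=(lb, ub),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
            )
        except Exception:
            continue
        solutions.append(res)
        if best is None or res.cost < best.cost:
            best = res
            used = attempt
        if best.cost < 1e-12 * logy.size:
            break
    if best is None:
        raise RuntimeError("HN fit failed on all restarts")
    rms = math.sqrt(2.0 * best.cost / max(best.fun.size, 1))
    if rms > 1.0:
        raise RuntimeError(f"HN fit did not converge (rms log residual {rms:.3g})")

    fit = _unpack(best.x, n_processes, use_conductivity)
    fit.resid_norm = rms
    fit.n_restarts_used = used
    _attach_stderr(fit, best, n_processes, use_conductivity)
    if n_processes > 1:
        _flag_unresolved_multimodal(fit, solutions, best, n_processes, use_conductivity)
    return fit


def _flag_unresolved_multimodal(fit, solutions, best, n_processes, use_cond) -> None:
    """Flag processes whose strength is unstable across restart solutions.

    Restarts that reach comparable cost (within 2x of the best) but place a
    process at a very different Delta_eps reveal a multi-modal, hence
    unresolved, decomposition that pointwise curvature cannot see.
    """
    order_best = None
    per_proc: list = [[] for _ in range(n_processes)]
    for res in solutions:
        if res.cost > 2.0 * best.cost + 1e-12:
            continue
        cand = _unpack(res.x, n_processes, use_cond)
        procs = sorted(cand.processes, key=lambda p: p.tau_hn)
        for k, p in enumerate(procs):
            per_proc[k].append(p.delta_eps)
    fit_sorted = sorted(fit.processes, key=lambda p: p.tau_hn)
    for k, p in enumerate(fit_sorted):
        vals = per_proc[k]
        if len(vals) >= 2 and (max(vals) - min(vals)) > p.delta_eps:
            p.unresolved = True


def _pack(fit: HNFit, use_cond: bool) -> np.ndarray:
    theta = []
    for p in fit.processes:
        theta += [math.log10(p.delta_eps), math.log10(p.tau_hn), p.alpha, p.gamma]
    theta.append(fit.eps_inf)
    if use_cond:
        theta.append(math.log10(fit.sigma_dc if fit.sigma_dc else 1e-15))
    return np.array(theta)


def _bounds(n_proc: int, use_cond: bool):
    lb, ub = [], []
    for _ in range(n_proc):
        lb += [-4.0, -14.0, 0.05, 0.05]
        ub += [4.0, 8.0, 1.0, 1.0]
    lb.append(1.0)
    ub.append(200.0)
    if use_cond:
        lb.append(-20.0)
        ub.append(2.0)
    return np.array(lb), np.array(ub)


def _jitter(theta0, rng, lb, ub):
    t = theta0 + rng.normal(0, 0.25, size=theta0.size)
    return np.clip(t, lb, ub)


def _auto_init(f, y, yr, n_proc, use_cond) -> np.ndarray:
    if use_cond:
        sig0 = y[0] * EPS0 * 2.0 * np.pi * f[0]
        y = np.clip(y - sig0 / (EPS0 * 2.0 * np.pi * f), 1e-12, None)
    i = int(np.argmax(y))
    tau0 = 1.0 / (2.0 * np.pi * f[i])
    # strength from the sum rule integral (2/pi) int eps'' dln w
    de0 = max((2.0 / np.pi) * np.trapezoid(np.clip(y, 0, None), np.log(f)), 2.0 * y[i])
    theta = []
    for k in range(n_proc):
        # stagger extra processes two decades apart
        theta += [math.log10(de0 / n_proc), math.log10(tau0) + 2.0 * k, 0.8, 0.8]
    theta.append(max(1.0, yr[-1] * 0.95))
    if use_cond:
        sig0 = max(y[0], 1e-12) * EPS0 * 2.0 * np.pi * f[0]
        theta.append(math.log10(sig0))
    return np.array(theta)


def _attach_stderr(fit: HNFit, res, n_proc: int, use_cond: bool) -> None:
    m, n = res.fun.size, res.x.size
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        # SVD without cutoff: near-singular directions must blow the errors
        # up (that is exactly what flags an unresolved process), so no pinv
        _, sv, vt = np.linalg.svd(res.jac, full_matrices=False)
        sv = np.clip(sv, sv.max() * 1e-14, None)
        cov = (vt.T / sv ** 2) @ vt * s2
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        err = np.full(n, np.nan)
    ln10 = math.log(10.0)
    for k, p in enumerate(fit.processes):
        e = err[4 * k : 4 * k + 4]
        p.stderr = {
            "delta_eps": p.delta_eps * ln10 * e[0],
            "tau_hn": p.tau_hn * ln10 * e[1],
            "alpha": e[2],
            "gamma": e[3],
        }
        if np.isfinite(e[0]) and p.stderr["delta_eps"] > p.delta_eps:
            p.unresolved = True
    fit.stderr = {"eps_inf": err[4 * n_proc]}
    if use_cond and fit.sigma_dc is not None:
        fit.stderr["sigma_dc"] = fit.sigma_dc * ln10 * err[4 * n_proc + 1]


# ---------------------------------------------------------------------------
# KWW one-sided Fourier transform
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(24)
_VMAX = 45.0


def _euler_tail(terms: np.ndarray) -> float:
    """Iterated averaging of partial sums of an alternating tail."""
    s = np.cumsum(terms)
    while s.size > 1:
        s = 0.5 * (s[:-1] + s[1:])
    return float(s[0])


def _halfwave_sums(x: float, beta: float, nwaves: int) -> np.ndarray:
    """Integrals of e^-v sin(x v^(1/b)) over the first ``nwaves`` half-waves.

    All panels (half-waves subdivided to width <= 2) are evaluated in one
    vectorized Gauss-Legendre pass.
    """
    j = np.arange(nwaves + 1)
    edges = np.minimum((j * math.pi / x) ** beta, _VMAX)
    widths = np.diff(edges)
    nsub = np.maximum(np.ceil(widths / 2.0).astype(int), 1)
    nsub[widths <= 0] = 1
    # panel edges for every half-wave
    panel_a, panel_b, owner = [], [], []
    for k in range(nwaves):
        if widths[k] <= 0:
            continue
        sub = np.linspace(edges[k], edges[k + 1], nsub[k] + 1)
        panel_a.append(sub[:-1])
        panel_b.append(sub[1:])
        owner.append(np.full(nsub[k], k))
    if not panel_a:
        return np.zeros(nwaves)
    a = np.concatenate(panel_a)
    b = np.concatenate(panel_b)
    owner = np.concatenate(owner)
    mid = 0.5 * (a + b)[:, None]
    half = 0.5 * (b - a)[:, None]
    v = mid + half * _GL_NODES[None, :]
    fv = np.exp(-v) * np.sin(x * v ** (1.0 / beta))
    panel_int = (fv @ _GL_WEIGHTS) * half[:, 0]
    out = np.zeros(nwaves)
    np.add.at(out, owner, panel_int)
    return out


def kww_ft(x: float, beta: float, ncap: int = 240, ntail: int = 80) -> float:
    """F(x) = int_0^inf beta u^(b-1) e^(-u^b) sin(x u) du, x = omega tau_K.

    Substituting v = u^b gives int_0^inf e^-v sin(x v^(1/b)) dv, partitioned
    at the sine zeros; the alternating half-wave series is summed directly
    when it terminates within the e^-v decay range, otherwise its tail is
    accelerated by iterated averaging.  Relative accuracy ~1e-7 over at
    least x in [1e-3, 1e3] for beta in [0.3, 1].
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must be in (0, 1]")
    if x == 0.0:
        return 0.0
    if beta == 1.0:
        return x / (1.0 + x * x)
    jmax = x * _VMAX ** (1.0 / beta) / math.pi
    nwaves = int(min(jmax + 1, ncap)) + 1
    terms = _halfwave_sums(x, beta, nwaves)
    if jmax + 1 <= ncap:
        return float(np.sum(terms))
    head, tail = terms[:-ntail], terms[-ntail:]
    return float(np.sum(head)) + _euler_tail(tail)


def _kww_peak_x(beta: float) -> float:
    """Location x of the maximum of the KWW loss F(x)."""
    if beta == 1.0:
        return 1.0
    r = minimize_scalar(
        lambda lx: -kww_ft(10.0 ** lx, beta),
        bounds=(-2.5, 1.5),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return 10.0 ** r.x


def kww_loss(beta: float, tau_k: float, freq: np.ndarray) -> np.ndarray:
    """Normalized (unit-maximum) KWW loss evaluated at ``freq`` [Hz]."""
    if tau_k <= 0:
        raise ValueError("tau_k must be > 0")
    freq = np.asarray(freq, dtype=float)
    x = 2.0 * np.pi * freq * tau_k
    vals = np.array([kww_ft(xx, beta) for xx in x])
    peak = kww_ft(_kww_peak_x(beta), beta)
    return vals / peak


# master-curve cache for fitting: beta -> (log10 x grid, log10 K, peak log10 x)
_KWW_CACHE: dict = {}
_KWW_LX_GRID = np.linspace(-4.0, 4.0, 161)


def _kww_curve(beta: float):
    key = round(beta, 4)
    if key not in _KWW_CACHE:
        vals = np.array([kww_ft(10.0 ** lx, beta) for lx in _KWW_LX_GRID])
        lk = np.log10(np.clip(vals, 1e-300, None))
        pk = float(lk.max())
        _KWW_CACHE[key] = (lk - pk, _KWW_LX_GRID[int(np.argmax(lk))])
    return _KWW_CACHE[key]


@dataclass
class KWWFit:
    """Stretched-exponential loss-shape fit of a normalized master curve."""

    beta_kww: float
    tau_k: float
    amplitude: float
    resid_norm: float
    beta_stderr: float = float("nan")
    poor_fit: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.beta_kww <= 1.0):
            raise ValueError("beta_kww must be in (0, 1]")
        if self.tau_k <= 0:
            raise ValueError("tau_k must be > 0")


def _kww_sse_at_beta(beta: float, lx_data: np.ndarray, logy: np.ndarray):
    """Best (shift, amplitude) SSE for one beta via golden search on the shift.

    The model in log-log space is a rigid translate of the cached master
    curve: log10 y = log amp + K(log10 x + shift); amp is profiled exactly.
    """
    lk, lx_pk = _kww_curve(beta)

    def sse_of_shift(shift):
        model = np.interp(lx_data + shift, _KWW_LX_GRID, lk)
        amp = float(np.mean(logy - model))
        r = model + amp - logy
        return float(r @ r), amp

    r = minimize_scalar(
        lambda s: sse_of_shift(s)[0], bounds=(lx_pk - 2.5, lx_pk + 2.5),
        method="bounded", options={"xatol": 1e-8},
    )
    sse, amp = sse_of_shift(r.x)
    return sse, float(r.x), amp


def fit_kww(peak: NormalizedPeak, poor_fit_rms: float = 0.05) -> KWWFit:
    """Fit (beta, tau_K, amplitude) to a normalized loss master curve.

    Least squares on log10 of the loss (points above 1% of maximum): beta is
    scanned on a fine grid with the time shift and amplitude profiled out at
    each value, then refined by parabolic interpolation.  If the rms log
    residual exceeds ``poor_fit_rms`` the result carries ``poor_fit=True`` —
    the input shape is then broader/narrower than any KWW curve (e.g. a
    strongly asymmetric HN input).
    """
    x, y = peak.x, peak.y
    keep = y > 0.01
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("too few points above 1% of the maximum")
    lx = np.log10(x)
    logy = np.log10(y)

    betas = np.round(np.arange(0.20, 1.0001, 0.01), 4)
    sses = np.array([_kww_sse_at_beta(b, lx, logy)[0] for b in betas])
    k = int(np.argmin(sses))
    # parabolic refinement on the grid minimum
    beta_best = betas[k]
    if 0 < k < betas.size - 1:
        d1 = (sses[k + 1] - sses[k - 1]) / 2.0
        d2 = sses[k + 1] - 2.0 * sses[k] + sses[k - 1]
        if d2 > 0:
            beta_best = float(np.clip(betas[k] - 0.01 * d1 / d2, betas[0], betas[-1]))
    sse, shift, amp = _kww_sse_at_beta(beta_best, lx, logy)
    rms = math.sqrt(sse / lx.size)
    # stderr from the SSE curvature over the beta grid
    if 0 < k < betas.size - 1:
        d2 = (sses[k + 1] - 2.0 * sses[k] + sses[k - 1]) / 0.01 ** 2
        s2 = sse / max(lx.size - 3, 1)
        berr = math.sqrt(2.0 * s2 / d2) if d2 > 0 else float("nan")
    else:
        berr = float("nan")
    return KWWFit(
        beta_kww=float(beta_best),
        tau_k=float(10.0 ** shift / (2.0 * np.pi)),
        amplitude=float(10.0 ** amp),
        resid_norm=rms,
        beta_stderr=berr,
        poor_fit=rms > poor_fit_rms,
    )


# ---------------------------------------------------------------------------
# Coupling-model test for a Johari-Goldstein secondary process
# ---------------------------------------------------------------------------

@dataclass
class CMResult:
    """Coupling-model primitive-relaxation prediction vs observed tau_beta."""

    n: float
    t_c: float
    tau0: float
    tau_beta_observed: float | None
    verdict: Literal["consistent", "inconsistent", "untested"]

    def __post_init__(self) -> None:
        if not (0.0 <= self.n < 1.0):
            raise ValueError("coupling parameter n must be in [0, 1)")


def cm_jg_test(
    tau_alpha: float,
    beta_kww: float,
    t_c: float = T_C_DEFAULT,
    tau_beta_observed: float | None = None,
    tol_decades: float = 1.0,
) -> CMResult:
    """Predict the primitive relaxation time tau0 = t_c^n tau_alpha^(1-n).

    n = 1 - beta_kww.  The secondary process is called ``consistent`` with a
    JG assignment when |log10 tau_beta_obs - log10 tau0| <= ``tol_decades``;
    with no observed tau_beta the verdict is ``untested``.
    """
    if tau_alpha <= 0:
        raise ValueError("tau_alpha must be > 0")
    n = 1.0 - beta_kww
    tau0 = t_c ** n * tau_alpha ** (1.0 - n)
    if tau_beta_observed is None:
        verdict = "untested"
    else:
        dev = abs(math.log10(tau_beta_observed) - math.log10(tau0))
        verdict = "consistent" if dev <= tol_decades else "inconsistent"
    return CMResult(n=n, t_c=t_c, tau0=tau0, tau_beta_observed=tau_beta_observed, verdict=verdict)
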