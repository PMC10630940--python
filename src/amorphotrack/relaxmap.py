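"""Relaxation maps: tau(T) assembly, VFT/Arrhenius fits, Tg, crossover.

Conventions: the glass transition is defined dielectrically as the
temperature where tau_alpha reaches ``TAU_REF_TG`` (100 s).  The VFT law is

    tau(T) = tau_vft * exp[D_T * T0 / (T - T0)]

fitted on log10 tau.  Sub-Tg secondary relaxations follow the Arrhenius law
``tau = tau_inf exp(Ea / R T)``.  A confinement crossover is a continuous
kink in log tau vs 1/T: VFT above ``T_cross``, an Arrhenius branch below,
accepted only when the two-regime fit beats a single VFT by an F-like ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from ._constants import R_GAS, TAU_REF_TG
from .fitting import HNFit, tau_max_from_hn

__all__ = [
    "TauMap",
    "VFTParams",
    "ArrheniusParams",
    "CrossoverResult",
    "build_tau_map",
    "fit_vft",
    "tg_from_vft",
    "fit_arrhenius",
    "detect_crossover",
    "vft_tau",
    "arrhenius_tau",
]

LN10 = math.log(10.0)


def vft_tau(T, tau_vft: float, d_t: float, t0: float):
    """tau(T) = tau_vft exp[D_T T0/(T - T0)]."""
    T = np.asarray(T, dtype=float)
    with np.errstate(over="ignore"):
        return tau_vft * np.exp(d_t * t0 / (T - t0))


def arrhenius_tau(T, tau_inf: float, ea_kj: float):
    """tau(T) = tau_inf exp(Ea/RT), Ea in kJ/mol."""
    T = np.asarray(T, dtype=float)
    return tau_inf * np.exp(ea_kj * 1e3 / (R_GAS * T))


@dataclass
class TauMap:
    """tau(T) (or tau(time) for annealing series) for one named process."""

    process: str
    index: np.ndarray          # K, or hours for isothermal annealing
    tau: np.ndarray            # s
    index_kind: Literal["temp_K", "time_h"] = "temp_K"
    source: str = ""

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.index.size != self.tau.size:
            raise ValueError("index/tau length mismatch")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if np.unique(self.index).size != self.index.size:
            raise ValueError("duplicate index values in tau map")

    def sorted(self) -> "TauMap":
        o = np.argsort(self.index)
        return TauMap(self.process, self.index[o], self.tau[o], self.index_kind, self.source)

    def __len__(self) -> int:
        return self.index.size


def build_tau_map(
    fits: Sequence[tuple],
    process: int | str = 0,
    index_kind: Literal["temp_K", "time_h"] = "temp_K",
    min_points: int = 5,
) -> TauMap:
    """Assemble a tau map from (T, HNFit) pairs via the loss-peak time.

    ``process`` selects the HN term by list position or by its name.
    """
    if len(fits) < min_points:
        raise ValueError(f"need >= {min_points} points to build a tau map, got {len(fits)}")
    idx, taus = [], []
    for T, fit in fits:
        if isinstance(process, str):
            cands = [p for p in fit.processes if p.name == process]
            if not cands:
                raise ValueError(f"no process named {process!r} in fit at {T}")
            proc = cands[0]
        else:
            proc = fit.processes[process]
        idx.append(float(T))
        taus.append(tau_max_from_hn(proc))
    name = process if isinstance(process, str) else f"process_{process}"
    return TauMap(name, np.array(idx), np.array(taus), index_kind=index_kind).sorted()


# ---------------------------------------------------------------------------
# VFT
# ---------------------------------------------------------------------------

@dataclass
class VFTParams:
    tau_vft: float
    d_t: float
    t0: float
    tg: float = float("nan")
    cov: np.ndarray | None = None
    stderr: dict = field(default_factory=dict)
    resid_rms: float = float("nan")
    vft_unnecessary: bool = False

    def __post_init__(self) -> None:
        if self.tau_vft <= 0 or self.d_t <= 0 or self.t0 <= 0:
            raise ValueError("tau_vft, D_T and T0 must be positive")

    def tau(self, T):
        return vft_tau(T, self.tau_vft, self.d_t, self.t0)


@dataclass
class ArrheniusParams:
    tau_inf: float
    ea_kj: float
    stderr_ea_kj: float = float("nan")
    resid_rms: float = float("nan")

    def __post_init__(self) -> None:
        if self.ea_kj <= 0:
            raise ValueError("Ea must be positive")

    def tau(self, T):
        return arrhenius_tau(T, self.tau_inf, self.ea_kj)


def fit_vft(tau_map: TauMap, min_decades: float = 3.0) -> VFTParams:
    """Nonlinear VFT fit on log10 tau(T).

    Requires >= 5 points spanning ``min_decades`` decades in tau.  When the
    data carry no super-Arrhenius curvature the result is flagged
    ``vft_unnecessary`` (a plain Arrhenius line fits as well).
    """
    m = tau_map.sorted()
    if len(m) < 5:
        raise ValueError("VFT fit needs >= 5 points")
    span = math.log10(m.tau.max() / m.tau.min())
    if span < min_decades:
        raise ValueError(f"tau span {span:.2f} decades < required {min_decades}")
    T, lt = m.index, np.log10(m.tau)

    def residual(theta):
        ltv, ld, t0 = theta
        return ltv + (10.0 ** ld) * t0 / (T - t0) / LN10 - lt

    tmin = T.min()
    best = None
    for t0_frac in (0.85, 0.7, 0.5):
        t0g = tmin * t0_frac
        # linearize: log tau = log tau_vft + D T0/(ln10 (T-T0))
        A = np.vstack([np.ones_like(T), 1.0 / (T - t0g)]).T
        c, *_ = np.linalg.lstsq(A, lt, rcond=None)
        dg = max(c[1] * LN10 / t0g, 1e-3)
        lb3 = np.array([-30.0, -3.0, 1.0])
        ub3 = np.array([10.0, 3.0, tmin - 1e-6])
        theta0 = np.clip([c[0], math.log10(dg), t0g], lb3, ub3)
        res = least_squares(
            residual, theta0,
            bounds=(lb3, ub3),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("VFT fit did not converge")
    ltv, ld, t0 = best.x
    rms = math.sqrt(2.0 * best.cost / len(m))
    dof = max(len(m) - 3, 1)
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * 2.0 * best.cost / dof
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {"log10_tau_vft": err[0], "log10_d_t": err[1], "t0": err[2]}
    except Exception:
        cov, stderr = None, {}
    params = VFTParams(
        tau_vft=10.0 ** ltv, d_t=10.0 ** ld, t0=t0, cov=cov, stderr=stderr, resid_rms=rms,
    )
    params.tg = tg_from_vft(params)
    # curvature check: does a straight Arrhenius line do as well?
    slope, icpt = np.polyfit(1.0 / T, lt * LN10, 1)
    arr_rms = math.sqrt(np.mean((icpt + slope / T - lt * LN10) ** 2)) / LN10
    params.vft_unnecessary = arr_rms <= max(2.0 * rms, 1e-10)
    return params


def tg_from_vft(params: VFTParams, tau_ref: float = TAU_REF_TG) -> float:
    """Solve tau(Tg) = tau_ref: Tg = T0 (1 + D_T / ln(tau_ref/tau_vft))."""
    if tau_ref <= params.tau_vft:
        raise ValueError("tau_ref must exceed the VFT prefactor")
    return params.t0 * (1.0 + params.d_t / math.log(tau_ref / params.tau_vft))


def fit_arrhenius(tau_map: TauMap, min_points: int = 4) -> ArrheniusParams:
    """ln tau vs 1/T regression; Ea = slope * R (reported in kJ/mol)."""
    m = tau_map.sorted()
    if len(m) < min_points:
        raise ValueError(f"Arrhenius fit needs >= {min_points} points")
    x = 1.0 / m.index
    y = np.log(m.tau)
    r = stats.linregress(x, y)
    if r.slope <= 0:
        raise ValueError("nonpositive Arrhenius slope (tau not increasing on cooling)")
    pred = r.intercept + r.slope * x
    return ArrheniusParams(
        tau_inf=math.exp(r.intercept),
        ea_kj=r.slope * R_GAS / 1e3,
        stderr_ea_kj=r.stderr * R_GAS / 1e3 if r.stderr is not None else float("nan"),
        resid_rms=float(np.sqrt(np.mean((pred - y) ** 2))) / LN10,
    )


# ---------------------------------------------------------------------------
# Crossover detection
# ---------------------------------------------------------------------------

@dataclass
class CrossoverResult:
    detected: bool
    t_cross: float = float("nan")
    high_t_law: VFTParams | None = None
    low_t_law: ArrheniusParams | None = None
    f_ratio: float = float("nan")
    single_vft: VFTParams | None = None

    def tau(self, T):
        """Piecewise tau(T) of the accepted two-regime law."""
        T = np.asarray(T, dtype=float)
        hi = self.high_t_law.tau(np.maximum(T, self.t_cross))
        anchor = float(self.high_t_law.tau(self.t_cross))
        lo = anchor * np.exp(
            self.low_t_law.ea_kj * 1e3 / R_GAS * (1.0 / T - 1.0 / self.t_cross)
        )
        return np.where(T >= self.t_cross, hi, lo)


def _t0_grid(tmin: float) -> np.ndarray:
    return np.linspace(0.3 * tmin, tmin - 2.0, 60)


def _batched_lin_sse(design: np.ndarray, lt: np.ndarray):
    """Solve min ||A_k c - lt|| for a stack of design matrices (k, n, p)."""
    At = np.swapaxes(design, 1, 2)
    gram = At @ design[:, :, :]
    rhs = At @ lt
    coef = np.linalg.solve(gram, rhs[..., None])[..., 0]
    resid = np.einsum("knp,kp->kn", design, coef) - lt
    sse = np.sum(resid * resid, axis=1)
    return coef, sse


def _single_vft_profile(T, lt):
    """Best VFT fit with T0 profiled on a grid (linear in the rest)."""
    t0s = _t0_grid(T.min())
    cq = 1.0 / ((T[None, :] - t0s[:, None]) * LN10)
    design = np.stack(
        [np.broadcast_to(np.ones_like(T), cq.shape), cq], axis=2
    )
    coef, sse = _batched_lin_sse(design, lt)
    k = int(np.argmin(sse))
    ltv, q = coef[k]
    return float(sse[k]), (float(ltv), float(q / t0s[k]), float(t0s[k]))


def _piecewise_fit(T, lt, t_cross):
    """Continuous VFT-above / Arrhenius-below fit at a fixed break.

    With T0 profiled on a grid the remaining parameters (log10 tau_vft,
    q = D_T*T0, Ea) enter linearly, so every T0 candidate is a 3x3 normal
    equation.  Returns (sse, (ltv, d, t0, ea)).
    """
    hi = T >= t_cross
    tmin_hi = T[hi].min()
    t0s = _t0_grid(tmin_hi)
    denom = np.where(hi[None, :], T[None, :] - t0s[:, None], t_cross - t0s[:, None])
    cq = 1.0 / (denom * LN10)
    ce = np.where(hi, 0.0, (1.0 / T - 1.0 / t_cross) * 1e3 / (R_GAS * LN10))
    design = np.stack(
        [
            np.broadcast_to(np.ones_like(T), cq.shape),
            cq,
            np.broadcast_to(ce, cq.shape),
        ],
        axis=2,
    )
    coef, sse = _batched_lin_sse(design, lt)
    k = int(np.argmin(sse))
    ltv, q, ea = coef[k]
    return float(sse[k]), (float(ltv), float(q / t0s[k]), float(t0s[k]), float(ea))


def detect_crossover(
    tau_map: TauMap,
    threshold: float = 4.0,
    min_side_points: tuple = (3, 5),
) -> CrossoverResult:
    """Search for a continuous kink in log tau vs 1/T.

    Candidate breaks run on a 0.5 K grid between the margins that leave
    ``min_side_points`` data points on each side (Arrhenius below, VFT
    above).  The kink is accepted when the F-like ratio
    ((SSE_single - SSE_kink)/2) / (SSE_kink/(n-5)) exceeds ``threshold``
    (default 4, two extra parameters); empirical false-positive rate on
    single-VFT null data at 0.05-decade noise is ~2-3%.
    """
    m = tau_map.sorted()
    n = len(m)
    if n < 10:
        raise ValueError("crossover detection needs >= 10 points")
    T, lt = m.index, np.log10(m.tau)
    sse0, (s_ltv, s_d, s_t0) = _single_vft_profile(T, lt)
    single = VFTParams(tau_vft=10.0 ** s_ltv, d_t=s_d, t0=s_t0) if s_d > 0 else None
    if single is not None:
        try:
            single.tg = tg_from_vft(single)
        except ValueError:
            pass

    lo_min, hi_min = min_side_points
    best = None
    best_tc = None
    # candidate breaks: 0.5 K grid between the allowed side margins
    t_lo = T[lo_min - 1] + 0.25
    t_hi = T[n - hi_min] - 0.25
    for t_cross in np.arange(t_lo, t_hi + 1e-9, 0.5):
        res = _piecewise_fit(T, lt, t_cross)
        if res is None:
            continue
        if best is None or res[0] < best[0]:
            best = res
            best_tc = t_cross
    if best is None:
        return CrossoverResult(detected=False, single_vft=single)
    sse1, (ltv, d, t0, ea) = best
    dof = max(n - 5, 1)
    f_ratio = ((sse0 - sse1) / 2.0) / max(sse1 / dof, 1e-300)
    detected = f_ratio > threshold and d > 0 and ea > 0
    if not detected:
        return CrossoverResult(detected=False, f_ratio=f_ratio, single_vft=single)
    hi_law = VFTParams(tau_vft=10.0 ** ltv, d_t=d, t0=t0)
    try:
        hi_law.tg = tg_from_vft(hi_law)
    except ValueError:
        pass
    anchor = float(hi_law.tau(best_tc))
    tau_inf = anchor * math.exp(-ea * 1e3 / (R_GAS * best_tc))
    lo_law = ArrheniusParams(tau_inf=tau_inf, ea_kj=ea)
    return CrossoverResult(
        detected=True,
        t_cross=float(best_tc),
        high_t_law=hi_law,
        low_t_law=lo_law,
        f_ratio=float(f_ratio),
        single_vft=single,
    )
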