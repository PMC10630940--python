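"""Dissolution profiles: release-model fitting, metrics, classification.

Candidate models (the observed shapes: steady prolonged release, logarithmic
rise to a stable maximum, supersaturation spike followed by precipitation to
a low plateau, and no release at all):

    first_order   C(t) = C_inf (1 - exp(-k t))
    log_rise      C(t) = a ln(1 + b t)
    rise_decay    C(t) = s (1 - exp(-k_r t)) (p + (1 - p) exp(-k_c t))
    constant      C(t) = c

Selection by small-sample-corrected AIC; a winning rise_decay with
peak/plateau ratio > 1.2 classifies as ``spring_and_crash``, a winning
monotone model as ``prolonged_release``, a winning constant as ``flat``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DissolutionProfile",
    "ReleaseFit",
    "ProfileMetrics",
    "read_profile",
    "write_profile",
    "fit_release",
    "summary_metrics",
    "compare_profiles",
]

MODELS = ("constant", "first_order", "log_rise", "rise_decay")


@dataclass
class DissolutionProfile:
    time: np.ndarray   # min
    conc: np.ndarray   # mg/mL
    medium: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.time.size < 4:
            raise ValueError("profile needs >= 4 sampling points")
        if self.time.size != self.conc.size:
            raise ValueError("time/conc length mismatch")
        if np.any(self.time < 0) or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be nonnegative and strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be nonnegative")


def write_profile(p: DissolutionProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_min,conc_mg_ml\n")
        for t, c in zip(p.time, p.conc):
            fh.write(f"{t:.12g},{c:.12g}\n")


def read_profile(path, medium: str = "", sample: str = "") -> DissolutionProfile:
    data = np.genfromtxt(path, delimiter=",", names=True)
    return DissolutionProfile(
        time=np.atleast_1d(data["time_min"]),
        conc=np.atleast_1d(data["conc_mg_ml"]),
        medium=medium,
        sample=sample,
    )


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def _constant(t, c):
    return np.full_like(t, c)


def _first_order(t, c_inf, k):
    return c_inf * (1.0 - np.exp(-k * t))


def _log_rise(t, a, b):
    return a * np.log1p(b * t)


def _rise_decay(t, s, k_r, k_c, p):
    return s * (1.0 - np.exp(-k_r * t)) * (p + (1.0 - p) * np.exp(-k_c * t))


_MODEL_FUNCS = {
    "constant": _constant,
    "first_order": _first_order,
    "log_rise": _log_rise,
    "rise_decay": _rise_decay,
}
_N_PARAMS = {"constant": 1, "first_order": 2, "log_rise": 2, "rise_decay": 4}


@dataclass
class ReleaseFit:
    model: str
    params: dict
    aicc: float
    sse: float
    label: str
    all_aicc: dict = field(default_factory=dict)


def _aicc(sse: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    sse = max(sse, 1e-300)
    aic = n * math.log(sse / n) + 2 * k
    denom = n - k - 1
    if denom < 1:
        # small-sample guard: keep the penalty finite but strongly
        # discouraging when the model nearly saturates the data
        denom = 0.5
    return aic + 2.0 * k * (k + 1) / denom


def _fit_model(model: str, t: np.ndarray, c: np.ndarray):
    func = _MODEL_FUNCS[model]
    cmax = max(c.max(), 1e-6)
    tspan = max(t[-1], 1.0)
    if model == "constant":
        theta = np.array([float(np.mean(c))])
        sse = float(np.sum((func(t, *theta) - c) ** 2))
        return theta, sse
    if model == "first_order":
        x0s = [[cmax, 2.0 / tspan], [cmax * 1.2, 0.2 / tspan]]
        lb, ub = [0.0, 1e-6], [10 * cmax + 1e-6, 100.0]
    elif model == "log_rise":
        x0s = [[cmax / 3.0, 0.2], [cmax, 0.02]]
        lb, ub = [1e-9, 1e-6], [100 * cmax, 1e3]
    else:  # rise_decay
        x0s = [
            [cmax * 1.5, 5.0 / tspan, 0.5 / tspan, 0.5],
            [cmax, 10.0 / tspan, 2.0 / tspan, 0.8],
            [cmax * 2.0, 20.0 / tspan, 0.1 / tspan, 0.3],
        ]
        lb, ub = [0.0, 1e-6, 1e-6, 0.0], [10 * cmax + 1e-6, 1e3, 1e3, 1.0]
    best = None
    for x0 in x0s:
        try:
            res = least_squares(
                lambda th: func(t, *th) - c, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"{model} fit failed")
    return best.x, float(2.0 * best.cost)


_PARAM_NAMES = {
    "constant": ["c_mg_ml"],
    "first_order": ["c_inf_mg_ml", "k_per_min"],
    "log_rise": ["a_mg_ml", "b_per_min"],
    "rise_decay": ["s_mg_ml", "k_rise_per_min", "k_crash_per_min", "plateau_frac"],
}


def fit_release(
    profile: DissolutionProfile,
    peak_plateau_ratio: float = 1.2,
    evidence_daicc: float = 8.0,
) -> ReleaseFit:
    """Fit all candidate models, select by AICc, classify the profile.

    ``evidence_daicc`` guards the label against overfitting: a non-constant
    winner (and a crash component) must beat the simpler alternative by this
    many AICc units, otherwise the simpler reading is kept.  True planted
    shapes carry margins an order of magnitude above this threshold.
    """
    t, c = profile.time, profile.conc
    n = t.size
    results = {}
    errors = {}
    for model in MODELS:
        try:
            theta, sse = _fit_model(model, t, c)
            results[model] = (theta, sse, _aicc(sse, n, _N_PARAMS[model]))
        except Exception as exc:  # pragma: no cover - defensive
            errors[model] = str(exc)
    if not results:
        raise RuntimeError(f"all release-model fits failed: {errors}")
    winner = min(results, key=lambda m: results[m][2])
    theta, sse, aicc = results[winner]
    params = dict(zip(_PARAM_NAMES[winner], [float(v) for v in theta]))

    # evidence guard: a non-constant winner must clearly beat the constant
    # model, otherwise the profile is indistinguishable from flat noise
    if winner != "constant" and "constant" in results:
        if results["constant"][2] - aicc < evidence_daicc:
            winner = "constant"
            theta, sse, aicc = results["constant"]
            params = dict(zip(_PARAM_NAMES["constant"], [float(v) for v in theta]))

    # likewise a crash component needs real evidence over the monotone models
    if winner == "rise_decay":
        mono = [m for m in ("first_order", "log_rise") if m in results]
        if mono:
            best_mono = min(mono, key=lambda m: results[m][2])
            if results[best_mono][2] - aicc < evidence_daicc:
                winner = best_mono
                theta, sse, aicc = results[winner]
                params = dict(zip(_PARAM_NAMES[winner], [float(v) for v in theta]))

    if winner == "constant":
        label = "flat"
    elif winner == "rise_decay":
        s, k_r, k_c, p = theta
        tt = np.linspace(0, max(t[-1] * 3, 1.0), 2000)
        peak = float(_rise_decay(tt, *theta).max())
        plateau = float(s * p)
        if plateau > 0 and peak / plateau > peak_plateau_ratio:
            label = "spring_and_crash"
        else:
            label = "prolonged_release"
    else:
        label = "prolonged_release"
    return ReleaseFit(
        model=winner,
        params=params,
        aicc=float(aicc),
        sse=float(sse),
        label=label,
        all_aicc={m: float(v[2]) for m, v in results.items()},
    )


# ---------------------------------------------------------------------------
# Metrics and ranking
# ---------------------------------------------------------------------------

@dataclass
class ProfileMetrics:
    c_max: float
    t_c_max: float
    auc: float
    final_over_max: float


def summary_metrics(profile: DissolutionProfile) -> ProfileMetrics:
    t, c = profile.time, profile.conc
    i = int(np.argmax(c))
    return ProfileMetrics(
        c_max=float(c[i]),
        t_c_max=float(t[i]),
        auc=float(np.trapezoid(c, t)),
        final_over_max=float(c[-1] / c[i]) if c[i] > 0 else float("nan"),
    )


def compare_profiles(profiles: Sequence[DissolutionProfile], rel_tol: float = 1e-9) -> dict:
    """Rank profiles by AUC (primary) and by final concentration.

    Profiles on mismatched time grids are interpolated to the common overlap
    with a warning.  Ties within ``rel_tol`` are reported.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to compare")
    grids = [p.time for p in profiles]
    common = grids[0]
    if not all(g.size == common.size and np.allclose(g, common) for g in grids):
        warnings.warn("mismatched time grids; interpolating to common overlap")
        lo = max(g[0] for g in grids)
        hi = min(g[-1] for g in grids)
        common = np.linspace(lo, hi, max(g.size for g in grids))
        profiles = [
            DissolutionProfile(
                time=common, conc=np.interp(common, p.time, p.conc),
                medium=p.medium, sample=p.sample,
            )
            for p in profiles
        ]
    aucs = [summary_metrics(p).auc for p in profiles]
    finals = [float(p.conc[-1]) for p in profiles]
    order_auc = sorted(range(len(profiles)), key=lambda i: -aucs[i])
    order_final = sorted(range(len(profiles)), key=lambda i: (-finals[i], -aucs[i]))
    ties = []
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            denom = max(abs(aucs[a]), abs(aucs[b]), 1e-300)
            if abs(aucs[a] - aucs[b]) / denom <= rel_tol:
                ties.append((profiles[a].sample or str(a), profiles[b].sample or str(b)))
    return {
        "ranking_by_auc": [profiles[i].sample or str(i) for i in order_auc],
        "ranking_by_final_conc": [profiles[i].sample or str(i) for i in order_final],
        "auc": {profiles[i].sample or str(i): aucs[i] for i in range(len(profiles))},
        "final_conc": {profiles[i].sample or str(i): finals[i] for i in range(len(profiles))},
        "ties": ties,
    }
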