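"""Nonisothermal DSC: thermogram I/O, event extraction, Kissinger analysis.

Event conventions: the glass transition temperature is the midpoint of the
heat-capacity increment (located at the extremum of the smoothed derivative
of the step); crystallization (Tc) and melting (Tm) temperatures are the
maxima of the exothermic and endothermic peaks.  Kissinger analysis regresses
ln(phi/Tc^2) on 1/Tc across heating rates; E_cr = -slope * R.  The heating
rate is converted to K/s internally — the unit choice shifts only the
intercept C_K, never the slope.

CSV dialect ``dsc-v1``: two comment-style metadata lines
(``# rate_K_min: <float>``, ``# exo_up: <true|false>``) followed by a header
``temp_K,heat_flow``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import binary_dilation, median_filter
from scipy.signal import find_peaks, savgol_filter

from ._constants import R_GAS

__all__ = [
    "DSCThermogram",
    "GlassStep",
    "PeakEvent",
    "ThermalEvents",
    "KissingerResult",
    "read_dsc",
    "write_dsc",
    "extract_events",
    "detect_double_events",
    "kissinger_fit",
    "kissinger_multi",
]


@dataclass
class DSCThermogram:
    """Heat-flow curve of a single heating segment at rate ``rate_K_min``."""

    T: np.ndarray
    heat_flow: np.ndarray
    rate_K_min: float
    exo_up: bool = True
    sample: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.T.size < 100:
            raise ValueError("thermogram needs >= 100 points")
        if self.T.size != self.heat_flow.size:
            raise ValueError("T/heat_flow length mismatch")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature must be strictly increasing (single heating segment)")
        if self.rate_K_min <= 0:
            raise ValueError("heating rate must be positive")

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.T)))


def write_dsc(tg: DSCThermogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate_K_min: {tg.rate_K_min:.9g}\n")
        fh.write(f"# exo_up: {'true' if tg.exo_up else 'false'}\n")
        fh.write("temp_K,heat_flow\n")
        for t, h in zip(tg.T, tg.heat_flow):
            fh.write(f"{t:.12g},{h:.12g}\n")


def read_dsc(path) -> DSCThermogram:
    rate = None
    exo_up = None
    rows_t, rows_h = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                key = key.strip()
                if key == "rate_K_min":
                    rate = float(val)
                elif key == "exo_up":
                    exo_up = val.strip().lower() == "true"
                continue
            if line.startswith("temp_K"):
                continue
            t, h = line.split(",")
            rows_t.append(float(t))
            rows_h.append(float(h))
    if rate is None:
        raise ValueError("missing rate_K_min metadata")
    return DSCThermogram(
        T=np.array(rows_t),
        heat_flow=np.array(rows_h),
        rate_K_min=rate,
        exo_up=True if exo_up is None else exo_up,
    )


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

@dataclass
class GlassStep:
    """A heat-capacity step: onset / midpoint / end and step height."""

    tg_mid: float
    onset: float
    end: float
    delta_cp: float


@dataclass
class PeakEvent:
    """An exo- or endothermic peak: extremum temperature and area."""

    t_peak: float
    area: float
    height: float
    kind: str  # "exo" | "endo"


@dataclass
class ThermalEvents:
    tg_list: list = field(default_factory=list)
    tc_list: list = field(default_factory=list)
    tm_list: list = field(default_factory=list)

    @property
    def tg_temps(self):
        return [g.tg_mid for g in self.tg_list]

    @property
    def tc_temps(self):
        return [p.t_peak for p in self.tc_list]

    @property
    def tm_temps(self):
        return [p.t_peak for p in self.tm_list]


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _local_line(T, y, lo, hi):
    """Slope/intercept of y over index window [lo, hi]; None if too short."""
    if hi - lo < 3:
        return None
    c = np.polyfit(T[lo:hi], y[lo:hi], 1)
    return c


def extract_events(
    tg: DSCThermogram,
    smooth_window_K: float = 1.0,
    step_smooth_window_K: float = 4.0,
    baseline_window_K: float = 40.0,
    prominence_mad: float = 5.0,
    step_prominence_mad: float = 6.0,
    min_peak_prominence_frac: float = 0.05,
    step_prominence_frac: float = 0.3,
    max_level_shift_frac: float = 0.5,
) -> ThermalEvents:
    """Extract Tg steps and exo/endo peaks from a heating thermogram.

    Sharp peaks are found on the signal minus a wide running-median baseline;
    the prominence threshold is the larger of ``prominence_mad`` times the
    noise MAD and ``min_peak_prominence_frac`` of the largest excursion.
    Candidates whose flanking baseline levels differ by more than
    ``max_level_shift_frac`` of their prominence are rejected — those are
    heat-capacity steps, not peaks.  Tg midpoints are extrema of the smoothed
    derivative outside peak regions; Delta-cp is the gap between local linear
    baselines extrapolated to the midpoint.
    """
    h = tg.heat_flow if tg.exo_up else -tg.heat_flow
    T = tg.T
    dT = tg.grid_step
    win = _odd(max(5, int(round(smooth_window_K / dT))))
    smooth = savgol_filter(h, win, 3)
    noise = float(np.median(np.abs(h - smooth))) * 1.4826

    bwin = _odd(max(15, int(round(baseline_window_K / dT))))
    base = median_filter(smooth, size=bwin, mode="nearest")
    resid = smooth - base
    span = float(np.max(np.abs(resid))) if np.any(resid) else 0.0
    prom = max(prominence_mad * noise, min_peak_prominence_frac * span, 1e-12)
    slope0 = float(np.median(np.gradient(smooth, T)))

    events = ThermalEvents()
    peak_mask = np.zeros(T.size, dtype=bool)
    for sign, kind in ((+1.0, "exo"), (-1.0, "endo")):
        # height filter too: a valley between two opposite-sign peaks can carry
        # large prominence while its apex barely leaves the baseline
        idx, props = find_peaks(sign * resid, prominence=prom, height=prom, width=5)
        for i, p in zip(idx, props["prominences"]):
            # flanks out to 2% of prominence
            lo = i
            while lo > 0 and sign * resid[lo] > 0.02 * p:
                lo -= 1
            hi = i
            while hi < T.size - 1 and sign * resid[hi] > 0.02 * p:
                hi += 1
            # step rejection: does the running-median baseline (peak-free,
            # edge-preserving) change level across the event?
            k = max(5, (hi - lo) // 2)
            left = base[max(lo - k, 0) : lo + 1]
            right = base[hi : hi + k + 1]
            if left.size and right.size:
                di = (hi + right.size / 2.0) - (lo - left.size / 2.0)
                shift = abs(
                    float(np.median(right)) - float(np.median(left)) - slope0 * dT * di
                )
                if shift > max_level_shift_frac * p:
                    continue
            area = float(np.trapezoid(resid[lo : hi + 1], T[lo : hi + 1]))
            ev = PeakEvent(t_peak=float(T[i]), area=area, height=float(resid[i]), kind=kind)
            (events.tc_list if kind == "exo" else events.tm_list).append(ev)
            pad = max(3, (hi - lo) // 3)
            peak_mask[max(lo - pad, 0) : min(hi + pad, T.size - 1) + 1] = True

    # --- glass transition steps: extrema of d(heat flow)/dT away from peaks.
    # A cp increase shows as an endothermic (downward, exo-up) step, i.e. a
    # negative bump in the derivative relative to the baseline slope.
    swin = _odd(max(win, int(round(step_smooth_window_K / dT))))
    ssmooth = savgol_filter(h, swin, 3)
    deriv = savgol_filter(h, swin, 3, deriv=1, delta=dT)
    dres = -(deriv - slope0)
    # widen the mask by the derivative smoothing half-width so peak flanks
    # cannot leak into the step channel
    if peak_mask.any():
        peak_mask = binary_dilation(peak_mask, iterations=swin // 2 + 3)
    dres[peak_mask] = 0.0
    edge = max(swin, 3)
    dres[:edge] = 0.0
    dres[-edge:] = 0.0
    dnoise = float(np.median(np.abs(deriv - median_filter(deriv, size=bwin, mode="nearest")))) * 1.4826
    dspan = float(np.max(dres)) if np.any(dres > 0) else 0.0
    dprom = max(step_prominence_mad * dnoise, step_prominence_frac * dspan, 1e-12)
    if dspan > 0:
        sidx, sprops = find_peaks(dres, prominence=dprom, width=2)
        gap = max(int(round(3.0 / dT)), 3)
        span = max(int(round(8.0 / dT)), 6)
        for i, wl, wr in zip(sidx, sprops["left_ips"], sprops["right_ips"]):
            half = max((wr - wl), 2) * dT
            # local baselines left/right of the step (fixed 3-8 K windows so
            # a neighbouring step cannot contaminate them), extrapolated to T[i]
            l_hi = max(i - gap, 0)
            l_lo = max(i - span, 0)
            r_lo = min(i + gap, T.size - 1)
            r_hi = min(i + span, T.size - 1)
            cl = _local_line(T, ssmooth, l_lo, l_hi)
            cr = _local_line(T, ssmooth, r_lo, r_hi)
            if cl is None or cr is None:
                dcp = float(np.trapezoid(dres[l_lo:r_hi], T[l_lo:r_hi]))
            else:
                dcp = float(np.polyval(cl, T[i]) - np.polyval(cr, T[i]))
            # physical consistency: the implied step height must clear the
            # signal noise, else the derivative bump was a noise excursion
            if dcp <= max(5.0 * noise, 1e-12):
                continue
            events.tg_list.append(
                GlassStep(
                    tg_mid=float(T[i]),
                    onset=float(T[i] - half),
                    end=float(T[i] + half),
                    delta_cp=dcp,
                )
            )
    events.tg_list.sort(key=lambda g: g.tg_mid)
    events.tc_list.sort(key=lambda p: p.t_peak)
    events.tm_list.sort(key=lambda p: p.t_peak)
    return events


@dataclass
class DoubleEventReport:
    """Per-rate resolved crystallization peak counts and the merge threshold."""

    counts: dict                      # rate -> number of exo peaks
    merge_threshold: float | None     # lowest rate at which peaks merge to one
    always_double: bool = False


def detect_double_events(events_by_rate: dict) -> DoubleEventReport:
    """Report how many crystallization peaks resolve at each heating rate.

    ``merge_threshold`` is the lowest rate showing a single peak above the
    highest rate still showing two.  If every rate shows two peaks the
    threshold is the maximum rate and ``always_double`` is set.
    """
    if len(events_by_rate) < 3:
        raise ValueError("need events from >= 3 heating rates")
    counts = {float(r): len(ev.tc_list) for r, ev in events_by_rate.items()}
    rates = sorted(counts)
    double = [r for r in rates if counts[r] >= 2]
    single = [r for r in rates if counts[r] <= 1]
    if not double:
        return DoubleEventReport(counts=counts, merge_threshold=None)
    if not single:
        return DoubleEventReport(counts=counts, merge_threshold=max(rates), always_double=True)
    merged_above = [r for r in single if r > max(double)]
    thr = min(merged_above) if merged_above else None
    return DoubleEventReport(counts=counts, merge_threshold=thr)


# ---------------------------------------------------------------------------
# Kissinger analysis
# ---------------------------------------------------------------------------

@dataclass
class KissingerResult:
    e_cr_kj: float
    c_k: float
    stderr_e_cr_kj: float
    stderr_c_k: float
    r_squared: float
    points: list

    def __post_init__(self) -> None:
        if self.e_cr_kj <= 0:
            raise ValueError("E_cr must be positive")


def kissinger_fit(points: Sequence[tuple], phi_unit: str = "K/min") -> KissingerResult:
    """OLS of ln(phi/Tc^2) on 1/Tc; E_cr = -slope*R [kJ/mol].

    ``points`` are (phi, Tc) pairs; phi is converted to K/s internally (the
    intercept C_K refers to phi in K/s).  The slope — hence E_cr — is
    invariant to the phi unit.
    """
    pts = [(float(p), float(t)) for p, t in points]
    if len(pts) < 3:
        raise ValueError("Kissinger regression needs >= 3 (rate, Tc) points")
    rates = [p for p, _ in pts]
    if len(set(rates)) != len(rates):
        raise ValueError("repeated heating rates in Kissinger points")
    conv = {"K/min": 1.0 / 60.0, "K/s": 1.0}
    if phi_unit not in conv:
        raise ValueError(f"unknown phi unit {phi_unit!r}")
    phi = np.array([p for p, _ in pts]) * conv[phi_unit]
    tc = np.array([t for _, t in pts])
    y = np.log(phi / tc ** 2)
    x = 1.0 / tc
    r = stats.linregress(x, y)
    return KissingerResult(
        e_cr_kj=-r.slope * R_GAS / 1e3,
        c_k=float(r.intercept),
        stderr_e_cr_kj=(r.stderr or float("nan")) * R_GAS / 1e3,
        stderr_c_k=float(r.intercept_stderr) if r.intercept_stderr is not None else float("nan"),
        r_squared=float(r.rvalue ** 2),
        points=pts,
    )


def kissinger_multi(groups: dict, phi_unit: str = "K/min") -> dict:
    """One Kissinger regression per labelled peak group (first/second/merged).

    Groups with fewer than 3 points are skipped with a warning.
    """
    out = {}
    for label, pts in groups.items():
        if len(pts) < 3:
            warnings.warn(f"Kissinger group {label!r} has {len(pts)} < 3 points; skipped")
            continue
        out[label] = kissinger_fit(pts, phi_unit=phi_unit)
    return out
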