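"""Data model and I/O for complex permittivity spectra.

A :class:`DielectricSpectrum` holds one temperature's (or one time slice's)
``eps*(omega) = eps' - i eps''`` sampled on a frequency grid.  Series of
spectra are indexed either by temperature (cooling/heating protocols) or by
elapsed time (isothermal annealing).  The module also implements the
parallel-capacitor composition/deconvolution used for drug-filled porous
matrices: admittances of the filler and the matrix add, so at fixed electrode
geometry the total permittivity is the area-fraction-weighted sum

    eps*_total = f * eps*_api + (1 - f) * eps*_matrix.

CSV dialect ``bds-v1``: header ``temp_K,freq_hz,eps_real,eps_imag`` (or
``time_h`` as first column), UTF-8, '.' decimal, values written with 9
significant digits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DielectricSpectrum",
    "SpectraSeries",
    "CompositeGeometry",
    "NormalizedPeak",
    "read_spectra",
    "write_spectra",
    "compose_composite",
    "deconvolve_composite",
    "normalize_peak",
    "resample_series",
]

MIN_POINTS = 8

Protocol = Literal["slow_cool", "slow_heat", "isothermal_time"]


@dataclass
class DielectricSpectrum:
    """Complex permittivity vs frequency at a single temperature/time.

    ``eps_imag`` values below zero (instrument noise on weak peaks) are kept
    as-is but counted in ``n_negative_loss`` so downstream fits see raw data.
    """

    T: float
    freq: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    sample: str = ""
    protocol: str = ""
    warnings_: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        n = self.freq.size
        if n < MIN_POINTS:
            raise ValueError(f"spectrum needs >= {MIN_POINTS} points, got {n}")
        if self.eps_real.size != n or self.eps_imag.size != n:
            raise ValueError("freq/eps_real/eps_imag length mismatch")
        if np.any(self.freq <= 0):
            bad = int(np.flatnonzero(self.freq <= 0)[0])
            raise ValueError(f"non-positive frequency at row {bad}")
        if np.any(np.diff(self.freq) <= 0):
            bad = int(np.flatnonzero(np.diff(self.freq) <= 0)[0]) + 1
            raise ValueError(f"frequency not strictly increasing at row {bad}")
        if np.any(self.eps_real <= 0):
            raise ValueError("eps_real must be positive everywhere")

    @property
    def n_negative_loss(self) -> int:
        return int(np.sum(self.eps_imag < 0))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency, omega = 2 pi f [rad/s]."""
        return 2.0 * np.pi * self.freq

    def complex_eps(self) -> np.ndarray:
        return self.eps_real - 1j * self.eps_imag


@dataclass
class SpectraSeries:
    """Ordered spectra indexed by temperature [K] or elapsed time [h]."""

    spectra: list
    protocol: Protocol = "slow_heat"
    index_kind: Literal["temp_K", "time_h"] = "temp_K"

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("empty series")
        idx = np.array([s.T for s in self.spectra], dtype=float)
        d = np.diff(idx)
        if idx.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("series index must be strictly monotone")

    @property
    def index(self) -> np.ndarray:
        return np.array([s.T for s in self.spectra], dtype=float)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def uniform_grid(self) -> bool:
        f0 = self.spectra[0].freq
        return all(
            s.freq.size == f0.size and np.allclose(s.freq, f0, rtol=1e-12)
            for s in self.spectra
        )


@dataclass
class CompositeGeometry:
    """Parallel-capacitor geometry of a filled porous matrix.

    ``fill_fraction`` is the area fraction of the drug phase seen by the
    field; when built from porosity and pore filling degree it equals their
    product.  ``matrix_eps`` is either a frequency-independent complex
    constant or a reference :class:`DielectricSpectrum` on the same grid.
    The fraction is always a user input, never inferred.
    """

    fill_fraction: float
    matrix_eps: Union[complex, DielectricSpectrum] = 1.0 + 0.0j
    porosity: float | None = None
    filling_degree: float | None = None

    @classmethod
    def from_porosity(
        cls,
        porosity: float,
        filling_degree: float,
        matrix_eps: Union[complex, DielectricSpectrum],
    ) -> "CompositeGeometry":
        return cls(
            fill_fraction=porosity * filling_degree,
            matrix_eps=matrix_eps,
            porosity=porosity,
            filling_degree=filling_degree,
        )

    def __post_init__(self) -> None:
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ValueError(f"fill_fraction must be in (0, 1], got {self.fill_fraction}")
        if isinstance(self.matrix_eps, DielectricSpectrum):
            pass
        else:
            self.matrix_eps = complex(self.matrix_eps)
            if self.matrix_eps.real <= 0:
                raise ValueError("matrix eps' must be positive")

    def matrix_on_grid(self, freq: np.ndarray) -> np.ndarray:
        if isinstance(self.matrix_eps, DielectricSpectrum):
            m = self.matrix_eps
            if m.freq.size != freq.size or not np.allclose(m.freq, freq, rtol=1e-9):
                raise ValueError("matrix reference spectrum grid does not match")
            return m.complex_eps()
        return np.full(freq.shape, self.matrix_eps, dtype=complex)


# ---------------------------------------------------------------------------
# I/O (dialect bds-v1)
# ---------------------------------------------------------------------------

def write_spectra(series: SpectraSeries, path) -> None:
    col0 = series.index_kind
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{col0},freq_hz,eps_real,eps_imag\n")
        for s in series.spectra:
            for f, er, ei in zip(s.freq, s.eps_real, s.eps_imag):
                fh.write(f"{s.T:.9g},{f:.12g},{er:.12g},{ei:.12g}\n")


def read_spectra(
    path,
    dialect: str = "bds-v1",
    protocol: Protocol = "slow_heat",
    resample: str | None = None,
    n_resample: int | None = None,
) -> SpectraSeries:
    """Read a ``bds-v1`` CSV into a :class:`SpectraSeries`.

    Spectra on differing grids are rejected unless ``resample='log-linear'``.
    """
    if dialect != "bds-v1":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[0] not in ("temp_K", "time_h"):
        raise ValueError("first column must be temp_K or time_h")
    for c in ("freq_hz", "eps_real", "eps_imag"):
        if c not in cols:
            raise ValueError(f"missing column {c!r}")
    index_kind = cols[0]
    spectra = []
    for key, grp in df.groupby(cols[0], sort=False):
        freq = grp["freq_hz"].to_numpy()
        if np.any(freq <= 0):
            row = int(grp.index[np.flatnonzero(freq <= 0)[0]]) + 2  # 1-based + header
            raise ValueError(f"non-positive frequency at file row {row}")
        if np.any(np.diff(freq) <= 0):
            row = int(grp.index[np.flatnonzero(np.diff(freq) <= 0)[0] + 1]) + 2
            raise ValueError(f"non-monotone frequency at file row {row}")
        spectra.append(
            DielectricSpectrum(
                T=float(key),
                freq=freq,
                eps_real=grp["eps_real"].to_numpy(),
                eps_imag=grp["eps_imag"].to_numpy(),
                protocol=protocol,
            )
        )
    series = SpectraSeries(spectra, protocol=protocol, index_kind=index_kind)
    if not series.uniform_grid():
        if resample is None:
            raise ValueError("mixed frequency grids; pass resample='log-linear'")
        series = resample_series(series, kind=resample, n=n_resample)
    return series


def resample_series(series: SpectraSeries, kind: str = "log-linear", n: int | None = None) -> SpectraSeries:
    """Interpolate every spectrum onto a shared log-spaced grid.

    Linear interpolation of eps' and eps'' in log10(f); the common grid spans
    the overlap of all member grids.
    """
    if kind != "log-linear":
        raise ValueError(f"unknown resample kind {kind!r}")
    lo = max(s.freq[0] for s in series.spectra)
    hi = min(s.freq[-1] for s in series.spectra)
    if hi <= lo:
        raise ValueError("spectra have no overlapping frequency range")
    if n is None:
        n = max(s.freq.size for s in series.spectra)
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    lg = np.log10(grid)
    out = []
    for s in series.spectra:
        lf = np.log10(s.freq)
        out.append(
            replace(
                s,
                freq=grid,
                eps_real=np.interp(lg, lf, s.eps_real),
                eps_imag=np.interp(lg, lf, s.eps_imag),
            )
        )
    return SpectraSeries(out, protocol=series.protocol, index_kind=series.index_kind)


# ---------------------------------------------------------------------------
# Composite mixing / deconvolution
# ---------------------------------------------------------------------------

def compose_composite(api: DielectricSpectrum, geom: CompositeGeometry) -> DielectricSpectrum:
    """Mix an API spectrum with the matrix: f*eps_api + (1-f)*eps_matrix."""
    f = geom.fill_fraction
    total = f * api.complex_eps() + (1.0 - f) * geom.matrix_on_grid(api.freq)
    return replace(
        api,
        eps_real=total.real.copy(),
        eps_imag=(-total.imag).copy(),
        sample=(api.sample + "+matrix") if api.sample else "composite",
    )


def deconvolve_composite(total: DielectricSpectrum, geom: CompositeGeometry) -> DielectricSpectrum:
    """Invert :func:`compose_composite`: eps_api = (eps_total - (1-f)*eps_m)/f.

    If the recovered eps' is non-positive anywhere the result is returned with
    a warning recorded in ``warnings_`` (implausible geometry), not silently.
    """
    f = geom.fill_fraction
    api = (total.complex_eps() - (1.0 - f) * geom.matrix_on_grid(total.freq)) / f
    warns = list(total.warnings_)
    er = api.real.copy()
    if np.any(er <= 0):
        msg = "deconvolution produced non-positive eps'; geometry implausible"
        warns.append(msg)
        warnings.warn(msg)
        er = np.clip(er, 1e-12, None)
    out = DielectricSpectrum(
        T=total.T,
        freq=total.freq,
        eps_real=er,
        eps_imag=(-api.imag).copy(),
        sample=total.sample,
        protocol=total.protocol,
        warnings_=warns,
    )
    return out


# ---------------------------------------------------------------------------
# Peak normalization (master curves)
# ---------------------------------------------------------------------------

@dataclass
class NormalizedPeak:
    """Loss peak rescaled to its maximum: y = eps''/eps''_max vs x = f/f_max."""

    x: np.ndarray
    y: np.ndarray
    f_max: float
    eps_max: float
    T: float = float("nan")


def normalize_peak(
    spectrum: DielectricSpectrum,
    window: tuple | None = None,
) -> NormalizedPeak:
    """Normalize a loss peak inside ``window`` (Hz interval) for superposition.

    The window must contain an interior maximum of eps''.
    """
    f = spectrum.freq
    y = spectrum.eps_imag
    if window is not None:
        lo, hi = window
        m = (f >= lo) & (f <= hi)
        if m.sum() < 3:
            raise ValueError("window contains too few points")
        f, y = f[m], y[m]
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        raise ValueError("no interior loss maximum in window")
    return NormalizedPeak(
        x=f / f[i], y=y / y[i], f_max=float(f[i]), eps_max=float(y[i]), T=spectrum.T
    )
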