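"""Shared data containers for digestion, scattering, spectral and surface data.

Unit conventions used across the package: time in minutes, hydrolysis in
percent of total starch, scattering vector ``q`` in Å⁻¹, real-space lengths
(lamellar thicknesses, roughness) in nm, masses in mg.  Conversions happen
inside operations, never at the I/O surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DigestionCurve",
    "GlucoseSeries",
    "ScatteringCurve",
    "CorrelationFunction",
    "Spectrum",
    "HeightMap",
]


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DigestionCurve:
    """Time-resolved percent of starch hydrolyzed.

    ``times`` are minutes since the start of digestion (strictly increasing,
    starting at 0); ``C`` is the percent of total starch hydrolyzed at each
    time point.
    """

    times: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        times = _as_1d(self.times, "times")
        C = _as_1d(self.C, "C")
        if times.size != C.size:
            raise ValueError("times and C must have equal length")
        if times.size and times[0] != 0:
            raise ValueError("times must start at 0 min")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if C.size and C[0] < 0:
            raise ValueError("C(0) must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "C", C)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class GlucoseSeries:
    """Glucose (mg) released at each sampling time.

    ``TS`` is total starch (mg); ``GF`` is free glucose present before
    digestion (mg, default 0 — rarely reported for pastes).
    """

    times: np.ndarray
    glucose: np.ndarray
    TS: float
    GF: float = 0.0

    def __post_init__(self) -> None:
        times = _as_1d(self.times, "times")
        glucose = _as_1d(self.glucose, "glucose")
        if times.size != glucose.size:
            raise ValueError("times and glucose must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(glucose < 0):
            raise ValueError("glucose must be non-negative")
        if self.TS <= 0:
            raise ValueError("TS (total starch, mg) must be positive")
        if self.GF < 0:
            raise ValueError("GF (free glucose, mg) must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)


@dataclass(frozen=True)
class ScatteringCurve:
    """Background-subtracted small-angle scattering curve I(q).

    ``q`` in Å⁻¹ (positive, strictly increasing; the instrument window for
    starch lamellae is typically 0.010–0.25 Å⁻¹), ``I`` in arbitrary units.
    """

    q: np.ndarray
    I: np.ndarray

    MIN_POINTS = 30

    def __post_init__(self) -> None:
        q = _as_1d(self.q, "q")
        I = _as_1d(self.I, "I")
        if q.size != I.size:
            raise ValueError("q and I must have equal length")
        if q.size < self.MIN_POINTS:
            raise ValueError(f"scattering curve needs >= {self.MIN_POINTS} points")
        if q[0] <= 0 or np.any(np.diff(q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)


@dataclass(frozen=True)
class CorrelationFunction:
    """Normalized 1-D correlation function L(r) on a uniform r grid (nm)."""

    r: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        r = _as_1d(self.r, "r")
        L = _as_1d(self.L, "L")
        if r.size != L.size:
            raise ValueError("r and L must have equal length")
        if r[0] != 0:
            raise ValueError("r grid must start at 0")
        dr = np.diff(r)
        if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-8):
            raise ValueError("r grid must be uniform and increasing")
        if abs(L[0] - 1.0) > 1e-6:
            raise ValueError("L(0) must equal 1 (normalization)")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "L", L)


@dataclass(frozen=True)
class Spectrum:
    """Generic 1-D spectrum: FTIR absorbance vs wavenumber (cm⁻¹) or XRD
    intensity vs 2θ (degrees)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = _as_1d(self.x, "x")
        y = _as_1d(self.y, "y")
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        d = np.diff(x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("x must be strictly monotone")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def covers(self, lo: float, hi: float) -> bool:
        return self.x.min() <= lo and self.x.max() >= hi


@dataclass(frozen=True)
class HeightMap:
    """Square 2-D height field (nm) with lateral sampling ``pixel_size``
    (nm/pixel), e.g. an AFM scan of a starch granule surface."""

    heights: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("heights must be a square 2-D grid")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights contain non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "heights", h)

    @property
    def scan_size(self) -> float:
        """Edge length of the scanned area in nm."""
        return self.heights.shape[0] * self.pixel_size
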