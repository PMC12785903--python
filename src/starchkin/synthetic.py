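"""Synthetic data generators with known ground truth.

Every analysis stage in this package has a matching forward model here, so
the whole pipeline can be exercised and validated without laboratory data:

* multi-phase first-order hydrolysis curves (continuous across phase
  boundaries) with optional Gaussian read noise, sampled on the standard
  digestion time grid;
* ideal lamellar (two-phase layer stack) scattering profiles with Gaussian
  layer-thickness jitter, together with a brute-force real-space
  autocorrelation that serves as the independent oracle for the
  reciprocal-space correlation-function pipeline;
* Gaussian-peak spectra on linear baselines (FTIR/XRD stand-ins);
* correlated random height fields with an exactly prescribed RMS roughness,
  plus fractional-Brownian surfaces of known fractal dimension.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import (
    CorrelationFunction,
    DigestionCurve,
    GlucoseSeries,
    HeightMap,
    ScatteringCurve,
    Spectrum,
)
from .fractions import GLUCOSE_TO_STARCH

__all__ = [
    "PhaseSpec",
    "StackSpec",
    "HeightMapSpec",
    "STANDARD_TIME_GRID",
    "UNIFORM_5MIN_GRID",
    "gen_digestion_curve",
    "curve_to_glucose",
    "default_reference_curve",
    "gen_lamellar_scattering",
    "gen_spectrum",
    "gen_height_map",
    "gen_fbm_surface",
]

#: standard in vitro digestion sampling protocol (minutes)
STANDARD_TIME_GRID = np.array([0, 5, 10, 20, 30, 40, 50, 60, 90, 120, 180, 360, 540], dtype=float)
#: uniform 5-min grid over the same 0–540 min span (used for recovery tests:
#: uniform spacing makes the discrete LOS slope equal −k exactly)
UNIFORM_5MIN_GRID = np.arange(0.0, 541.0, 5.0)


@dataclass(frozen=True)
class PhaseSpec:
    """One first-order digestion phase: rate k (min⁻¹), equilibrium extent
    C_inf (% of starch) and the time t_end (min) at which the phase ends."""

    k: float
    C_inf: float
    t_end: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (0 < self.C_inf <= 100):
            raise ValueError("C_inf must lie in (0, 100]")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


def _validate_phases(phases: Sequence[PhaseSpec]) -> None:
    if not phases:
        raise ValueError("phase list must not be empty")
    for a, b in zip(phases[:-1], phases[1:]):
        if b.t_end <= a.t_end:
            raise ValueError("phase t_end values must be strictly increasing")
        if b.k >= a.k:
            raise ValueError("phase rate constants must be strictly decreasing")
        if b.C_inf < a.C_inf:
            raise ValueError("phase C_inf values must be non-decreasing")


def gen_digestion_curve(
    phases: Sequence[PhaseSpec],
    times: Sequence[float] | np.ndarray = STANDARD_TIME_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DigestionCurve:
    """Sample a continuous multi-phase first-order hydrolysis curve.

    Within phase i the curve relaxes toward that phase's equilibrium from
    the level reached at the previous boundary,

        C(t) = C(t_{i−1}) + (C_inf_i − C(t_{i−1}))·(1 − e^(−k_i·(t − t_{i−1}))),

    with t_0 = 0 and C(0) = 0, so the noise-free curve is continuous and
    non-decreasing.  Gaussian noise of sd ``noise_sd`` (percent units,
    emulating GOPOD read scatter) is added per point and the result clipped
    to [0, 100].
    """
    _validate_phases(phases)
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must start at 0 and be strictly increasing")
    if t[-1] > phases[-1].t_end:
        raise ValueError("last sampling time exceeds the last phase's t_end")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    C = np.empty_like(t)
    t_start, c_start = 0.0, 0.0  # continuity anchor: each phase starts where the last ended
    for phase in phases:
        mask = (t >= t_start) & (t <= phase.t_end)
        C[mask] = c_start + (phase.C_inf - c_start) * (1.0 - np.exp(-phase.k * (t[mask] - t_start)))
        c_start = c_start + (phase.C_inf - c_start) * (1.0 - np.exp(-phase.k * (phase.t_end - t_start)))
        t_start = phase.t_end
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        C = np.clip(C + rng.normal(0.0, noise_sd, size=C.shape), 0.0, 100.0)
        C[0] = 0.0 if t[0] == 0 else C[0]
    return DigestionCurve(times=t, C=C)


def curve_to_glucose(curve: DigestionCurve, TS: float = 200.0, GF: float = 0.0) -> GlucoseSeries:
    """Invert the hydrolysis-percent definition to mg glucose released.

    glucose(t) = C(t)·TS/(0.9·100) + GF, the inverse of
    :func:`starchkin.fractions.glucose_to_curve` (round trip exact to
    floating-point rounding, ~1 ulp).
    """
    if TS <= 0:
        raise ValueError("TS must be positive")
    if GF < 0:
        raise ValueError("GF must be non-negative")
    if np.any(curve.C < 0):
        raise ValueError("curve has negative hydrolysis values")
    glucose = curve.C * TS / (GLUCOSE_TO_STARCH * 100.0) + GF
    return GlucoseSeries(times=curve.times, glucose=glucose, TS=TS, GF=GF)


def default_reference_curve(times: np.ndarray | None = None) -> DigestionCurve:
    """Synthetic white-bread reference curve for HI/EGI computation.

    Single-phase first-order with C_inf = 100 % and k = 0.09 min⁻¹ — a
    documented synthetic stand-in for a rapidly digested reference food,
    not a measured white-bread dataset.
    """
    t = STANDARD_TIME_GRID if times is None else np.asarray(times, dtype=float)
    ref_phase = PhaseSpec(k=0.09, C_inf=100.0, t_end=float(t[-1]))
    return gen_digestion_curve([ref_phase], times=t, noise_sd=0.0)


# --------------------------------------------------------------------------
# lamellar stacks

@dataclass(frozen=True)
class StackSpec:
    """Ideal lamellar two-phase stack: alternating crystalline/amorphous
    layers of mean thickness d_c_mean/d_a_mean (nm) with Gaussian jitter
    sigma_c/sigma_a, plus an optional power-law (mass-fractal) background
    bg_amplitude·q^alpha_bg on the emitted intensity."""

    d_c_mean: float
    d_a_mean: float
    sigma_c: float = 0.0
    sigma_a: float = 0.0
    n_repeats: int = 30
    alpha_bg: float = -2.0
    bg_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.d_c_mean <= 0 or self.d_a_mean <= 0:
            raise ValueError("layer mean thicknesses must be positive")
        if self.sigma_c < 0 or self.sigma_a < 0:
            raise ValueError("thickness standard deviations must be non-negative")
        if self.n_repeats < 20:
            raise ValueError("need at least 20 lamellar repeats")
        if self.bg_amplitude < 0:
            raise ValueError("bg_amplitude must be non-negative")

    @property
    def long_period(self) -> float:
        """Ground-truth lamellar repeat d = d_c + d_a (nm)."""
        return self.d_c_mean + self.d_a_mean


def _sample_thickness(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    # jitter truncated at ±0.2·mean so thicknesses stay positive
    if sigma == 0:
        return np.full(n, mean)
    jitter = np.clip(rng.normal(0.0, sigma, size=n), -0.2 * mean, 0.2 * mean)
    return mean + jitter


def gen_lamellar_scattering(
    spec: StackSpec,
    q_grid: np.ndarray,
    n_realizations: int = 20,
    seed: int = 0,
    dz: float = 0.05,
) -> tuple[ScatteringCurve, CorrelationFunction]:
    """Forward-model lamellar scattering and its real-space oracle.

    Builds ``n_realizations`` random 1-D two-phase density profiles
    (crystalline density 1, amorphous 0, thickness jitter per
    :class:`StackSpec`) on a fine grid of step ``dz`` nm and returns

    * the ensemble-averaged autocorrelation of the mean-subtracted profile,
      normalized to 1 at r = 0 — the brute-force correlation-function
      oracle, independent of any reciprocal-space computation; and
    * the orientationally weighted intensity I(q) = I₁D(q)/q² from the
      squared Fourier magnitude of the same profiles (ensemble-averaged),
      plus the ``bg_amplitude·q^alpha_bg`` background.

    ``q_grid`` is in Å⁻¹; real-space lengths are nm.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0 or q[0] <= 0 or np.any(np.diff(q) <= 0):
        raise ValueError("q_grid must be positive and strictly increasing")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    d_nm = spec.long_period
    if q[-1] < 4.0 * np.pi / (d_nm * 10.0):
        raise ValueError(
            "q range too narrow to resolve the long period "
            f"(need q_max >= {4.0 * np.pi / (d_nm * 10.0):.3f} Å⁻¹)"
        )

    rng = np.random.default_rng(seed)
    total_len = spec.n_repeats * d_nm
    n_z = int(np.ceil(total_len / dz))
    z_A = (np.arange(n_z) * dz) * 10.0  # grid positions in Å for the DFT

    acf_sum = np.zeros(n_z)
    i1d_sum = np.zeros(q.size)
    phase_mat = np.exp(1j * np.outer(q, z_A))  # (n_q, n_z)

    for _ in range(n_realizations):
        dc = _sample_thickness(rng, spec.d_c_mean, spec.sigma_c, spec.n_repeats)
        da = _sample_thickness(rng, spec.d_a_mean, spec.sigma_a, spec.n_repeats)
        profile = np.zeros(n_z)
        pos = 0.0
        for thick_c, thick_a in zip(dc, da):
            i0, i1 = int(round(pos / dz)), int(round((pos + thick_c) / dz))
            profile[i0:min(i1, n_z)] = 1.0
            pos += thick_c + thick_a
        rho = profile - profile.mean()
        # brute-force autocorrelation of the finite (zero-padded) profile —
        # exactly what the squared Fourier magnitude encodes
        acf_sum += np.correlate(rho, rho, mode="full")[n_z - 1:]
        # squared Fourier magnitude on the requested q grid (z in Å)
        amp = phase_mat @ rho
        i1d_sum += np.abs(amp) ** 2

    L = acf_sum / acf_sum[0]
    r = np.arange(n_z) * dz  # nm

    # keep the oracle on a useful window (a few long periods)
    r_keep = r <= min(4.0 * d_nm, r[-1])
    cf = CorrelationFunction(r=r[r_keep], L=L[r_keep])

    i1d = i1d_sum / n_realizations
    intensity = i1d / q**2 + spec.bg_amplitude * q**spec.alpha_bg
    return ScatteringCurve(q=q, I=intensity), cf


# --------------------------------------------------------------------------
# spectra

def gen_spectrum(
    peaks: Sequence[tuple[float, float, float]],
    baseline: tuple[float, float] = (0.0, 0.0),
    x_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Sum of Gaussian peaks (center, height, width-sigma) on a linear
    baseline ``slope·x + intercept`` with seeded Gaussian noise."""
    if x_grid is None or len(x_grid) == 0:
        raise ValueError("x_grid must be a non-empty monotone grid")
    x = np.asarray(x_grid, dtype=float)
    slope, intercept = baseline
    y = slope * x + intercept
    for center, height, width in peaks:
        if width <= 0:
            raise ValueError("peak widths must be positive")
        y = y + height * np.exp(-0.5 * ((x - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Spectrum(x=x, y=y)


# --------------------------------------------------------------------------
# height fields

@dataclass(frozen=True)
class HeightMapSpec:
    """Correlated random surface: ``n_pixels`` square grid, lateral sampling
    ``pixel_size`` (nm/pixel), RMS roughness rescaled exactly to
    ``target_rq`` (nm), lateral correlation length ``corr_length`` (nm)."""

    n_pixels: int = 256
    pixel_size: float = 7.8125  # 2 µm scan / 256 px
    target_rq: float = 8.0
    corr_length: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels < 16:
            raise ValueError("n_pixels must be >= 16")
        if self.target_rq < 0:
            raise ValueError("target_rq must be non-negative")
        if self.corr_length <= 0 or self.pixel_size <= 0:
            raise ValueError("corr_length and pixel_size must be positive")


def gen_height_map(spec: HeightMapSpec) -> HeightMap:
    """Gaussian white noise low-pass filtered at ``corr_length``,
    mean-subtracted, then rescaled so the sample RMS roughness equals
    ``target_rq`` exactly (to machine precision)."""
    rng = np.random.default_rng(spec.seed)
    field = rng.standard_normal((spec.n_pixels, spec.n_pixels))
    sigma_px = spec.corr_length / spec.pixel_size
    field = gaussian_filter(field, sigma=sigma_px, mode="wrap")
    field -= field.mean()
    rms = np.sqrt(np.mean(field**2))
    if spec.target_rq == 0 or rms == 0:
        field = np.zeros_like(field)
    else:
        field *= spec.target_rq / rms
    return HeightMap(heights=field, pixel_size=spec.pixel_size)


def gen_fbm_surface(n_pixels: int = 256, hurst: float = 0.5, seed: int = 0) -> HeightMap:
    """Fractional-Brownian surface by spectral synthesis.

    Isotropic power spectrum S(f) ∝ f^−(2H+2) gives a self-affine surface
    of Hurst exponent H and fractal dimension D = 3 − H.
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(n_pixels)
    fy = np.fft.fftfreq(n_pixels)
    f = np.sqrt(fx[:, None] ** 2 + fy[None, :] ** 2)
    f[0, 0] = np.inf  # kill the DC mode
    amplitude = f ** (-(hurst + 1.0))
    noise = rng.standard_normal((n_pixels, n_pixels)) + 1j * rng.standard_normal((n_pixels, n_pixels))
    surface = np.real(np.fft.ifft2(amplitude * noise))
    surface -= surface.mean()
    surface /= np.sqrt(np.mean(surface**2))
    return HeightMap(heights=surface, pixel_size=1.0)
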