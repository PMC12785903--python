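"""Digestible-fraction arithmetic and the self-assembly index.

Implements the Englyst-style classification of starch into rapidly digestible
(RDS, glucose released by 20 min), slowly digestible (SDS, released between
20 and 120 min) and resistant starch (RS, the remainder), the GOPOD
absorbance → percent-hydrolyzed conversion, and the iodine-absorbance
self-assembly index used to quantify complexation of starch chains.

Glucose→starch conversion uses the anhydroglucose factor 162/180 = 0.9 as a
multiplier on released glucose (the Englyst convention): starch hydrolyzed
(mg) = 0.9 × glucose (mg).  An alternative formulation that instead divides
by 0.9 circulates in the literature; it is available behind the
``as_printed`` flag of :func:`percent_hydrolyzed` but is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import DigestionCurve, GlucoseSeries

__all__ = [
    "GOPODReading",
    "FractionResult",
    "SelfAssemblyIndex",
    "GLUCOSE_TO_STARCH",
    "self_assembly_index",
    "percent_hydrolyzed",
    "glucose_to_curve",
    "rds_sds_rs",
]

#: anhydroglucose correction: 162 g starch residue per 180 g free glucose
GLUCOSE_TO_STARCH = 162.0 / 180.0  # = 0.9


@dataclass(frozen=True)
class GOPODReading:
    """One GOPOD (glucose oxidase–peroxidase, 510 nm) colorimetric reading.

    ``abs_sample`` and ``abs_standard`` are the blank-corrected absorbances
    ΔA of the hydrolysate aliquot and of the glucose standard;
    ``standard_mass`` is the glucose mass (mg) the standard cuvette
    represents; ``dilution_factor`` accounts for the aliquot dilution
    (25 for a 0.5 mL aliquot in the assay used here); ``starch_mass`` is the
    digested starch mass in mg.
    """

    abs_sample: float
    abs_standard: float
    dilution_factor: float = 25.0
    starch_mass: float = 200.0
    standard_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.abs_standard <= 0:
            raise ValueError("abs_standard must be positive")
        if self.abs_sample < 0:
            raise ValueError("abs_sample must be non-negative")
        if self.starch_mass <= 0:
            raise ValueError("starch_mass must be positive")
        if self.dilution_factor <= 0 or self.standard_mass <= 0:
            raise ValueError("dilution_factor and standard_mass must be positive")

    @property
    def glucose_mg(self) -> float:
        """Glucose mass (mg) represented by the reading."""
        return (self.abs_sample / self.abs_standard) * self.dilution_factor * self.standard_mass


@dataclass(frozen=True)
class FractionResult:
    """RDS/SDS/RS as percent of total starch; sums to 100 when GF = 0."""

    RDS: float
    SDS: float
    RS: float


@dataclass(frozen=True)
class SelfAssemblyIndex:
    """Percent reduction of starch–iodine absorbance upon complexation."""

    value: float
    abs_native: float
    abs_complex: float


def self_assembly_index(abs_native: float, abs_complex: float) -> SelfAssemblyIndex:
    """Self-assembly index SI = 100·(A_native − A_complex)/A_native.

    SI is the fractional loss of iodine-binding absorbance when starch
    chains are sequestered into complexes; 0 means no complexation, 100
    means complete loss of iodine binding.  Negative values (complex darker
    than the native paste) are physically odd but returned with a warning.
    """
    if abs_native <= 0:
        raise ValueError("abs_native must be positive")
    if abs_complex < 0:
        raise ValueError("abs_complex must be non-negative")
    value = 100.0 * (abs_native - abs_complex) / abs_native
    if value < 0:
        warnings.warn(
            "self-assembly index is negative: complex absorbs more than native starch",
            stacklevel=2,
        )
    return SelfAssemblyIndex(value=value, abs_native=abs_native, abs_complex=abs_complex)


def percent_hydrolyzed(reading: GOPODReading, as_printed: bool = False) -> float:
    """Percent of starch hydrolyzed from a GOPOD reading.

    Default (Englyst convention)::

        C = glucose_mg · 0.9 / starch_mass · 100

    With ``as_printed=True`` the anhydroglucose factor divides instead of
    multiplies (C = glucose_mg / 0.9 / starch_mass · 100), matching a
    formulation sometimes seen in print.  Values above 100% are possible
    with inconsistent inputs and trigger a warning.
    """
    glucose = reading.glucose_mg
    if as_printed:
        c = glucose / GLUCOSE_TO_STARCH / reading.starch_mass * 100.0
    else:
        c = glucose * GLUCOSE_TO_STARCH / reading.starch_mass * 100.0
    if c > 100.0:
        warnings.warn(f"percent hydrolyzed {c:.2f}% exceeds 100%", stacklevel=2)
    return c


def glucose_to_curve(series: GlucoseSeries) -> DigestionCurve:
    """Convert a glucose release series to percent starch hydrolyzed.

    Exact inverse of :func:`starchkin.synthetic.curve_to_glucose`:
    C(t) = (glucose(t) − GF) · 0.9 / TS · 100.
    """
    net = series.glucose - series.GF
    if np.any(net < -1e-12):
        raise ValueError("glucose readings below the free-glucose level GF")
    C = np.clip(net, 0.0, None) * GLUCOSE_TO_STARCH / series.TS * 100.0
    return DigestionCurve(times=series.times, C=C)


def _reading_at(series: GlucoseSeries, minute: float, tol: float = 1.0) -> float:
    idx = np.argmin(np.abs(series.times - minute))
    if abs(series.times[idx] - minute) > tol:
        raise ValueError(f"no glucose reading within ±{tol:g} min of {minute:g} min")
    return float(series.glucose[idx])


def rds_sds_rs(series: GlucoseSeries) -> FractionResult:
    """Classify starch into RDS/SDS/RS from 20- and 120-min glucose readings.

    RDS = (G20 − GF)·0.9/TS·100, SDS = (G120 − G20)·0.9/TS·100 and
    RS = 100 − RDS − SDS.  Readings within ±1 min of the nominal 20/120 min
    sampling times are accepted.
    """
    g20 = _reading_at(series, 20.0)
    g120 = _reading_at(series, 120.0)
    if g120 < g20:
        raise ValueError("G120 < G20: glucose release cannot decrease")
    rds = (g20 - series.GF) * GLUCOSE_TO_STARCH / series.TS * 100.0
    sds = (g120 - g20) * GLUCOSE_TO_STARCH / series.TS * 100.0
    rs = 100.0 - rds - sds
    return FractionResult(RDS=rds, SDS=sds, RS=rs)
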