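"""Readers, writers and run configuration.

Unit contract at the I/O surface: time in minutes, q in Å⁻¹, lengths in nm.
Readers validate aggressively and fail with line-numbered messages rather
than silently coercing.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np

from .datatypes import DigestionCurve, GlucoseSeries, ScatteringCurve, Spectrum

__all__ = [
    "RunConfig",
    "ReportBundle",
    "read_timeseries",
    "read_xy",
    "write_report",
]

Q_WINDOW = (0.010, 0.25)  # Å⁻¹, typical lamellar SAXS window

_ALLOWED_LOG_LEVELS = ("debug", "info", "warning")


@dataclass(frozen=True)
class RunConfig:
    """Flat key-value run configuration; unknown keys are rejected."""

    params: dict[str, Any]
    seed: int = 0
    output_dir: str = "."
    log_level: str = "info"

    KNOWN_KEYS = frozenset({
        "kind", "input", "reference", "max_phases", "auc_source", "gf", "ts",
        "standard_abs", "dilution", "starch_mg", "rmax_nm", "assign_thinner",
        "fractal_q", "pixel_size_nm", "levels", "mode", "spec", "out",
    })

    def __post_init__(self) -> None:
        if self.log_level not in _ALLOWED_LOG_LEVELS:
            raise ValueError(f"log_level must be one of {_ALLOWED_LOG_LEVELS}")
        unknown = set(self.params) - self.KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")


@dataclass
class ReportBundle:
    """Machine-readable results plus provenance for one analysis run."""

    results: dict[str, Any]
    summary: str = ""
    seed: int | None = None
    input_hashes: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def hash_file(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _parse_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    return rows[0], rows[1:]


def read_timeseries(path: str | Path) -> DigestionCurve | GlucoseSeries:
    """Read a digestion CSV/TSV and dispatch on its columns.

    ``time_min`` + ``C_percent`` → DigestionCurve;
    ``time_min`` + ``glucose_mg`` (optional ``ts_mg``, ``gf_mg``) →
    GlucoseSeries (TS defaults to 200 mg).
    """
    header, rows = _parse_rows(path)
    header = [h.strip() for h in header]
    if "time_min" not in header:
        raise ValueError(f"{path}: missing required column 'time_min'")
    kind = "C_percent" if "C_percent" in header else "glucose_mg" if "glucose_mg" in header else None
    if kind is None:
        raise ValueError(f"{path}: need a 'C_percent' or 'glucose_mg' column")
    idx_t = header.index("time_min")
    idx_v = header.index(kind)

    times, values = [], []
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            t = float(row[idx_t])
            v = float(row[idx_v])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric or missing cell") from exc
        if t in times:
            raise ValueError(f"{path}: line {lineno}: duplicate time {t:g} min")
        times.append(t)
        values.append(v)

    order = np.argsort(times)
    t_arr = np.asarray(times, dtype=float)[order]
    v_arr = np.asarray(values, dtype=float)[order]
    if kind == "C_percent":
        return DigestionCurve(times=t_arr, C=v_arr)
    ts = _optional_column(header, rows, "ts_mg", default=200.0)
    gf = _optional_column(header, rows, "gf_mg", default=0.0)
    return GlucoseSeries(times=t_arr, glucose=v_arr, TS=ts, GF=gf)


def _optional_column(header: list[str], rows: list[list[str]], name: str, default: float) -> float:
    if name not in header:
        return default
    idx = header.index(name)
    for row in rows:
        if row and row[idx].strip():
            return float(row[idx])
    return default


def read_xy(path: str | Path, kind: str = "saxs") -> ScatteringCurve | Spectrum:
    """Read a two-column text file (whitespace or comma separated, ``#``
    comments) as a ScatteringCurve (kind='saxs') or Spectrum ('ftir'/'xrd').

    SAXS q values outside the usual lamellar window (0.010–0.25 Å⁻¹) only
    warn — wider windows are legitimate for synthetic or merged data.
    """
    if kind not in ("saxs", "ftir", "xrd"):
        raise ValueError("kind must be 'saxs', 'ftir' or 'xrd'")
    xs, ys = [], []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: need two numeric columns")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    if not xs:
        raise ValueError(f"{path}: no data rows")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if kind == "saxs":
        if x[0] < Q_WINDOW[0] or x[-1] > Q_WINDOW[1]:
            warnings.warn(
                f"q range [{x[0]:g}, {x[-1]:g}] extends beyond the usual "
                f"lamellar window {Q_WINDOW}", stacklevel=2,
            )
        return ScatteringCurve(q=x, I=y)
    return Spectrum(x=x, y=y)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    """Write the machine-readable report (JSON, full precision) and a
    sibling ``.txt`` summary with 2-decimal display rounding.

    The JSON is deterministic for identical inputs: timestamps live only in
    the text summary.
    """
    path = Path(path)
    doc = {
        "results": _to_jsonable(bundle.results),
        "manifest": {
            "seed": bundle.seed,
            "input_hashes": bundle.input_hashes,
            "package": "starchkin 0.1.0",
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    lines = [f"starchkin report — {datetime.now(timezone.utc).isoformat(timespec='seconds')}"]
    if bundle.summary:
        lines.append(bundle.summary)
    for key, value in bundle.results.items():
        if isinstance(value, (int, float, np.floating, np.integer)):
            lines.append(f"  {key}: {float(value):.2f}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
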