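"""Atmospheric Δ¹⁴C reference curve.

Above-ground nuclear weapons testing nearly doubled the ¹⁴C content of
atmospheric CO₂ between 1955 and 1963 (the "bomb pulse"); after the 1963
test-ban treaty the excess decayed back towards baseline as ¹⁴C equilibrated
into the oceans and biosphere.  Because DNA synthesized at mitosis
incorporates carbon at the contemporaneous atmospheric concentration, the
Δ¹⁴C of genomic DNA acts as a date mark for the birth of a cell population,
read off against this curve.

The module represents the Northern-Hemisphere curve as ordered
(decimal year, Δ¹⁴C ‰) knots with linear interpolation between them.  Δ¹⁴C
values are taken as already decay-corrected relative to the universal
standard, so no further decay correction is applied anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtmosphericCurve",
    "CurveDomainError",
    "default_curve",
    "load_curve",
    "evaluate",
]

# Packaged approximation to published Northern-Hemisphere compilations
# (Levin/Hua-style records).  Fixed design parameter: pinning the knots makes
# every downstream inversion deterministic.  Swappable via load_curve().
_DEFAULT_KNOTS: tuple[tuple[float, float], ...] = (
    (1890.0, -20.0),
    (1900.0, -18.0),
    (1910.0, -16.0),
    (1920.0, -14.0),
    (1930.0, -12.0),
    (1940.0, -9.0),
    (1945.0, -6.0),
    (1950.0, -3.0),
    (1954.0, 0.0),
    (1955.0, 5.0),
    (1957.0, 60.0),
    (1959.0, 220.0),
    (1961.0, 220.0),
    (1962.0, 370.0),
    (1963.0, 700.0),
    (1964.0, 970.0),
    (1965.0, 780.0),
    (1967.0, 620.0),
    (1970.0, 525.0),
    (1975.0, 350.0),
    (1980.0, 250.0),
    (1985.0, 180.0),
    (1990.0, 140.0),
    (1995.0, 110.0),
    (2000.0, 90.0),
    (2005.0, 65.0),
    (2010.0, 40.0),
    (2016.0, 20.0),
)

CSV_HEADER = ("year", "delta14c_permil")


class CurveDomainError(ValueError):
    """A year outside the curve's knot span was requested."""


@dataclass(frozen=True)
class AtmosphericCurve:
    """Piecewise-linear atmospheric Δ¹⁴C curve.

    Parameters
    ----------
    years : ndarray
        Strictly increasing decimal calendar years of the knots.
    deltas : ndarray
        Δ¹⁴C at each knot, in ‰ relative to the universal standard
        (decay-corrected).
    label : str
        Free-text provenance of the knot table.
    """

    years: np.ndarray
    deltas: np.ndarray
    label: str = field(default="unlabelled")

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        deltas = np.asarray(self.deltas, dtype=float)
        if years.ndim != 1 or years.shape != deltas.shape:
            raise ValueError("years and deltas must be matching 1-D arrays")
        if years.size < 2:
            raise ValueError("a curve needs at least 2 knots")
        if not np.all(np.diff(years) > 0):
            raise ValueError("knot years must be strictly increasing")
        if not (np.all(np.isfinite(years)) and np.all(np.isfinite(deltas))):
            raise ValueError("knots must be finite")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "deltas", deltas)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.years[0]), float(self.years[-1])

    @property
    def peak_year(self) -> float:
        """Year of the global Δ¹⁴C maximum (first knot attaining it)."""
        return float(self.years[int(np.argmax(self.deltas))])

    @property
    def peak_delta(self) -> float:
        return float(np.max(self.deltas))

    def __call__(self, year):
        return evaluate(self, year)

    def to_csv(self, path: str | Path) -> None:
        """Write the knot table as ``year,delta14c_permil`` CSV."""
        frame = pd.DataFrame({CSV_HEADER[0]: self.years, CSV_HEADER[1]: self.deltas})
        frame.to_csv(path, index=False)


def default_curve() -> AtmosphericCurve:
    """Return the packaged Northern-Hemisphere bomb-pulse curve."""
    knots = np.array(_DEFAULT_KNOTS, dtype=float)
    return AtmosphericCurve(knots[:, 0], knots[:, 1], label="packaged NH bomb-pulse approximation")


def load_curve(path: str | Path, label: str | None = None) -> AtmosphericCurve:
    """Load a curve from a ``year,delta14c_permil`` CSV.

    Rows are sorted by year; duplicate years are rejected because they make
    the interpolant ill-defined.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse curve file {path}: {exc}") from exc
    missing = [c for c in CSV_HEADER if c not in frame.columns]
    if missing:
        raise ValueError(f"curve file {path} lacks column(s) {missing}; expected header {','.join(CSV_HEADER)}")
    if len(frame) < 2:
        raise ValueError(f"curve file {path} needs at least 2 knot rows")
    for col in CSV_HEADER:
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"curve file {path}: non-numeric {col!r} at line {int(bad[0]) + 2}")
    frame = frame.astype(float).sort_values(CSV_HEADER[0], kind="mergesort")
    years = frame[CSV_HEADER[0]].to_numpy()
    if np.any(np.diff(years) == 0):
        dup = years[:-1][np.diff(years) == 0][0]
        raise ValueError(f"curve file {path}: duplicate knot year {dup:g}")
    return AtmosphericCurve(years, frame[CSV_HEADER[1]].to_numpy(), label=label or str(path))


def evaluate(curve: AtmosphericCurve, year) -> float | np.ndarray:
    """Linearly interpolate the curve at ``year`` (scalar or array).

    Raises
    ------
    CurveDomainError
        If any requested year lies outside the knot span; the curve is a
        measured record and is never extrapolated.
    """
    y = np.asarray(year, dtype=float)
    lo, hi = curve.domain
    if np.any(y < lo) or np.any(y > hi):
        raise CurveDomainError(f"year {np.min(y):g}..{np.max(y):g} outside curve domain [{lo:g}, {hi:g}]")
    out = np.interp(y, curve.years, curve.deltas)
    return float(out) if np.isscalar(year) or y.ndim == 0 else out
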