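"""Retrospective ¹⁴C birth-dating of bulk-DNA cell populations.

A bulk AMS (accelerator mass spectrometry) measurement gives one Δ¹⁴C value
per DNA sample, with a 1σ measurement error.  Inverting that value against
the atmospheric bomb-pulse curve yields candidate calendar years at which
the population's genomic DNA was, on average, synthesized.  Two
complications are handled here:

* **Tumor purity.**  The tissue contains a fraction ``1 - purity`` of
  non-tumor cells whose DNA contributes to the bulk signal.  Under a
  two-component linear mixing model the tumor-compartment Δ¹⁴C is recovered
  as ``(measured - (1 - purity) * contaminant) / purity``.
* **Worst-case contamination.**  The contaminant's own Δ¹⁴C is unknown; its
  two extremes are cells as old as the individual (Δ¹⁴C at the birth year)
  and cells made just before surgery (Δ¹⁴C at the collection year).  The
  worst-case interval enumerates every extreme combination of measurement
  error, purity margin and contaminant scenario.

Candidate years are always restricted to ``[birth_year, collection_year]``:
no cell of the individual can predate them or postdate sample collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .curve import AtmosphericCurve, CurveDomainError, evaluate

__all__ = [
    "Delta14CMeasurement",
    "SampleRecord",
    "BirthDateEstimate",
    "DatingConfig",
    "invert",
    "correct_for_purity",
    "measurement_interval",
    "worst_case_interval",
    "date_sample",
    "average_cell_age",
    "methylation_carbon_shift",
]

_MERGE_TOL = 1e-9  # candidates closer than this are one crossing


@dataclass(frozen=True)
class Delta14CMeasurement:
    """One AMS Δ¹⁴C measurement of a DNA sample."""

    sample_id: str
    delta: float  # ‰
    one_sigma: float  # AMS standard error, ‰

    def __post_init__(self) -> None:
        if self.one_sigma < 0:
            raise ValueError(f"{self.sample_id}: one_sigma must be >= 0, got {self.one_sigma}")


@dataclass(frozen=True)
class SampleRecord:
    """Per-individual metadata for one dated tissue sample.

    Dates are decimal calendar years; dates known only to the year should be
    mapped to mid-year (``year + 0.5``) by the caller or via
    :func:`midyear`.  ``purity`` is the fraction of cells of interest
    (tumor cells for tumor tissue), with a symmetric ``purity_margin``
    covering intra-tumor heterogeneity of the pathology estimate.
    """

    sample_id: str
    birth_year: float
    collection_year: float
    purity: float = 1.0
    purity_margin: float = 0.05
    tissue_class: Literal["tumor", "control"] = "tumor"
    location: str = ""

    def __post_init__(self) -> None:
        if not self.birth_year < self.collection_year:
            raise ValueError(
                f"{self.sample_id}: birth_year {self.birth_year} must precede "
                f"collection_year {self.collection_year}"
            )
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"{self.sample_id}: purity must be in [0, 1], got {self.purity}")
        if self.purity_margin < 0:
            raise ValueError(f"{self.sample_id}: purity_margin must be >= 0")
        if self.tissue_class not in ("tumor", "control"):
            raise ValueError(f"{self.sample_id}: tissue_class must be 'tumor' or 'control'")

    @property
    def window(self) -> tuple[float, float]:
        """Admissible DNA-synthesis window: [birth, collection]."""
        return self.birth_year, self.collection_year

    def purity_extremes(self) -> tuple[float, float, float]:
        """(low, central, high) purity after clipping the margin into [0, 1]."""
        lo = max(self.purity - self.purity_margin, 0.0)
        hi = min(self.purity + self.purity_margin, 1.0)
        return lo, self.purity, hi


@dataclass(frozen=True)
class BirthDateEstimate:
    """Dating result for one sample."""

    sample_id: str
    candidate_years: tuple[float, ...]
    point_year: float | None
    ci_measurement: tuple[float, float]
    ci_worst_case: tuple[float, float]
    ambiguous: bool
    clipped: bool

    def __post_init__(self) -> None:
        lo_m, hi_m = self.ci_measurement
        lo_w, hi_w = self.ci_worst_case
        if not (lo_w <= lo_m + _MERGE_TOL and hi_m <= hi_w + _MERGE_TOL):
            raise ValueError(
                f"{self.sample_id}: measurement interval {self.ci_measurement} not "
                f"contained in worst-case interval {self.ci_worst_case}"
            )


@dataclass(frozen=True)
class DatingConfig:
    """Policy knobs for :func:`date_sample`.

    n_sigma
        Measurement-error multiplier for both interval types (1 = 1σ
        shading).
    ambiguity_policy
        ``report-all`` leaves ``point_year`` unset when the inversion has
        two or more crossings; ``latest``/``earliest`` pick one.
    """

    n_sigma: float = 1.0
    ambiguity_policy: Literal["report-all", "latest", "earliest"] = "report-all"

    def __post_init__(self) -> None:
        if self.n_sigma < 0:
            raise ValueError("n_sigma must be >= 0")
        if self.ambiguity_policy not in ("report-all", "latest", "earliest"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity_policy!r}")


def midyear(year: float) -> float:
    """Map a calendar year known only to the year to its midpoint."""
    return float(year) + 0.5


def invert(curve: AtmosphericCurve, delta: float, window: tuple[float, float]) -> list[float]:
    """All years in ``window`` where the piecewise-linear curve equals ``delta``.

    Returns crossings in ascending order; an empty list if the value is never
    attained in the window.  A crossing that falls exactly on a knot is
    reported once; a flat segment sitting exactly at ``delta`` contributes
    its two endpoints (the attainment set's extremes).
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"window must satisfy lo < hi, got [{lo}, {hi}]")
    dom_lo, dom_hi = curve.domain
    if lo < dom_lo or hi > dom_hi:
        raise CurveDomainError(f"window [{lo}, {hi}] outside curve domain [{dom_lo}, {dom_hi}]")

    # knot years inside the window, bracketed by the (interpolated) endpoints
    inner = curve.years[(curve.years > lo) & (curve.years < hi)]
    years = np.concatenate(([lo], inner, [hi]))
    values = np.interp(years, curve.years, curve.deltas)

    crossings: list[float] = []
    for (y0, d0), (y1, d1) in zip(zip(years, values), zip(years[1:], values[1:])):
        if d0 == d1:
            if d0 == delta:
                crossings.extend((y0, y1))
            continue
        if min(d0, d1) <= delta <= max(d0, d1):
            crossings.append(y0 + (delta - d0) * (y1 - y0) / (d1 - d0))
    crossings.sort()
    merged: list[float] = []
    for y in crossings:
        if not merged or y - merged[-1] > _MERGE_TOL:
            merged.append(float(y))
    return merged


def correct_for_purity(measured: float, purity: float, contaminant_delta: float) -> float:
    """Tumor-compartment Δ¹⁴C under two-component linear mixing.

    ``measured = purity * tumor + (1 - purity) * contaminant`` solved for the
    tumor term.  Undefined at purity 0 (the bulk signal then carries no
    tumor information).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    return (measured - (1.0 - purity) * contaminant_delta) / purity


def _nearest_year_in_value(
    curve: AtmosphericCurve, delta: float, window: tuple[float, float]
) -> float:
    """Year in the window whose curve value is closest to an unattainable delta.

    An unattainable delta lies outside the curve's range over the window, so
    the closest-in-value year is the arg-max (delta above the range) or
    arg-min (below) of the curve there — the window endpoint itself whenever
    the curve is monotone on the window.  Ties resolve to the earliest year.
    """
    lo, hi = window
    inner = curve.years[(curve.years > lo) & (curve.years < hi)]
    years = np.concatenate(([lo], inner, [hi]))
    values = np.interp(years, curve.years, curve.deltas)
    return float(years[int(np.argmin(np.abs(values - delta)))])


def _invert_or_clip(
    curve: AtmosphericCurve, delta: float, window: tuple[float, float]
) -> tuple[list[float], bool]:
    cands = invert(curve, delta, window)
    if cands:
        return cands, False
    return [_nearest_year_in_value(curve, delta, window)], True


def _band_hull(
    curve: AtmosphericCurve,
    d_lo: float,
    d_hi: float,
    window: tuple[float, float],
) -> tuple[tuple[float, float], bool]:
    """Hull of the level set {y in window : d_lo <= curve(y) <= d_hi}.

    The extrema of the level set sit either at crossings of the band
    boundaries or at a window endpoint whose curve value lies inside the
    band; both are enumerated exactly.  An empty level set (the whole band
    unattainable in the window) snaps to the endpoint closest in curve
    value and is flagged as clipped, so cohort runs complete.
    """
    years: list[float] = []
    clipped = False
    for boundary in {d_lo, d_hi}:
        years.extend(invert(curve, boundary, window))
    for endpoint in window:
        if d_lo <= evaluate(curve, endpoint) <= d_hi:
            years.append(float(endpoint))
    if not years:
        years = [_nearest_year_in_value(curve, 0.5 * (d_lo + d_hi), window)]
        clipped = True
    return (min(years), max(years)), clipped


def measurement_interval(
    curve: AtmosphericCurve,
    m: Delta14CMeasurement,
    rec: SampleRecord,
    n_sigma: float = 1.0,
) -> tuple[tuple[float, float], bool]:
    """Dating interval from AMS measurement error alone.

    The measurement is expected to be already purity-corrected (or the
    sample pure).  The interval is the hull of every year in
    ``[birth_year, collection_year]`` whose curve value is consistent with
    the measurement at ``n_sigma``, i.e. lies within
    ``[m.delta - nσ, m.delta + nσ]``.  Its endpoints fall on inversions of
    the band boundaries, except where the admissible window truncates the
    consistent set, in which case the window endpoint itself bounds the
    interval.  A band unattainable anywhere in the window snaps to the
    window endpoint closest in curve value and flags the result as clipped.

    Returns ``((lo, hi), clipped)``.
    """
    half = n_sigma * m.one_sigma
    return _band_hull(curve, m.delta - half, m.delta + half, rec.window)


def worst_case_interval(
    curve: AtmosphericCurve,
    m: Delta14CMeasurement,
    rec: SampleRecord,
    n_sigma: float = 1.0,
    trace: list | None = None,
) -> tuple[tuple[float, float], bool]:
    """Dating interval under worst-case contamination scenarios.

    Enumerates the extreme-combination grid: measured delta at ``-nσ, 0,
    +nσ`` × purity at ``{p - margin, p, p + margin}`` (clipped to [0, 1]) ×
    contaminant Δ¹⁴C at the two extremes — cells as old as the individual
    (curve value at the birth year) and contemporary cells (curve value at
    the collection year).  Each combination is purity-corrected; because the
    correction is monotone in each coordinate, the grid's extreme corrected
    values bound the full Δ¹⁴C band consistent with *some* admissible
    scenario, and the interval is the hull of every year in the window whose
    curve value falls inside that band.  This level-set construction keeps
    the worst-case interval a superset of the measurement interval and
    monotone in the purity margin even when the admissible window truncates
    individual crossings.

    ``trace``, if given, collects ``(delta, purity, contaminant, corrected,
    candidates)`` tuples for every grid combination (used by the CLI's
    debug logging).  Returns ``((lo, hi), clipped)``.
    """
    if rec.purity <= 0:
        raise ValueError(f"{rec.sample_id}: worst-case interval needs purity > 0")
    window = rec.window
    contaminants = (evaluate(curve, rec.birth_year), evaluate(curve, rec.collection_year))
    purities = [p for p in rec.purity_extremes() if p > 0]
    corrected_values: list[float] = []
    for ds in (-1.0, 0.0, 1.0):
        delta = m.delta + ds * n_sigma * m.one_sigma
        for purity in purities:
            for cont in contaminants:
                corrected = correct_for_purity(delta, purity, cont)
                corrected_values.append(corrected)
                if trace is not None:
                    trace.append(
                        (delta, purity, cont, corrected, tuple(invert(curve, corrected, window)))
                    )
    return _band_hull(curve, min(corrected_values), max(corrected_values), window)


def central_contaminant(curve: AtmosphericCurve, rec: SampleRecord) -> float:
    """Central contamination scenario: mean of the two extreme contaminant
    Δ¹⁴C values (as-old-as-individual and contemporary)."""
    return 0.5 * (evaluate(curve, rec.birth_year) + evaluate(curve, rec.collection_year))


def date_sample(
    rec: SampleRecord,
    m: Delta14CMeasurement,
    curve: AtmosphericCurve,
    config: DatingConfig = DatingConfig(),
) -> BirthDateEstimate:
    """Full dating pipeline for one sample.

    Purity-corrects the measurement under the central contaminant scenario,
    inverts over ``[birth_year, collection_year]``, builds the
    measurement-error and worst-case intervals, and applies the ambiguity
    policy to select a point estimate.  The measurement interval is computed
    on the corrected delta with the AMS σ scaled by ``1/purity`` — the exact
    propagation of a symmetric measurement error through the linear mixing
    correction.
    """
    if rec.sample_id != m.sample_id:
        raise ValueError(f"record {rec.sample_id!r} and measurement {m.sample_id!r} do not match")

    delta_c = correct_for_purity(m.delta, rec.purity, central_contaminant(curve, rec))
    corrected = Delta14CMeasurement(m.sample_id, delta_c, m.one_sigma / rec.purity)

    candidates, clipped_point = _invert_or_clip(curve, delta_c, rec.window)
    ci_meas, clipped_m = measurement_interval(curve, corrected, rec, config.n_sigma)
    # nesting ci_measurement ⊆ ci_worst_case holds structurally: the
    # central-scenario band is inside the worst-case band, and level-set
    # hulls are monotone in the band
    ci_worst, clipped_w = worst_case_interval(curve, m, rec, config.n_sigma)

    ambiguous = len(candidates) >= 2
    if clipped_point:
        point: float | None = candidates[0]
    elif ambiguous:
        if config.ambiguity_policy == "latest":
            point = max(candidates)
        elif config.ambiguity_policy == "earliest":
            point = min(candidates)
        else:
            point = None
    else:
        point = candidates[0]

    return BirthDateEstimate(
        sample_id=rec.sample_id,
        candidate_years=tuple(candidates),
        point_year=point,
        ci_measurement=ci_meas,
        ci_worst_case=ci_worst,
        ambiguous=ambiguous,
        clipped=clipped_point or clipped_m or clipped_w,
    )


def average_cell_age(est: BirthDateEstimate, rec: SampleRecord) -> float:
    """Average age, in years at collection, of the dated cell population."""
    if est.point_year is None:
        raise ValueError(
            f"{est.sample_id}: ambiguous dating ({len(est.candidate_years)} candidates) "
            "has no point estimate; choose an ambiguity policy or report candidates"
        )
    return rec.collection_year - est.point_year


def methylation_carbon_shift(
    genome_size_bp: float = 3.1e9,
    cpg_count: float = 2.8e7,
    methylated_fraction: float = 0.75,
    carbons_per_bp: float = 19.75,
) -> float:
    """Fraction of genomic carbon contributed by 5-methylcytosine methyl groups.

    Each symmetrically methylated CpG adds two carbon atoms (one per strand)
    on top of ``carbons_per_bp`` backbone-plus-base carbons per base pair.
    With human-genome defaults the fraction is well below 0.1%, which is why
    carbon exchange through methylation turnover is negligible for dating.
    """
    if min(genome_size_bp, cpg_count, carbons_per_bp) <= 0:
        raise ValueError("genome_size_bp, cpg_count and carbons_per_bp must be positive")
    if not 0.0 <= methylated_fraction <= 1.0:
        raise ValueError("methylated_fraction must be in [0, 1]")
    return (2.0 * cpg_count * methylated_fraction) / (genome_size_bp * carbons_per_bp)
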