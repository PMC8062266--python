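"""Model / Results layer.

Two estimator-style entry points tie the package together, in the spirit of
statsmodels: a model object is constructed from data, ``fit()`` runs the
estimation, and the returned Results object carries estimates,
uncertainties, diagnostics and a ``summary()`` table.

* :class:`BirthDatingModel` — cohort of (sample record, Δ¹⁴C measurement)
  pairs dated against an atmospheric curve.
* :class:`MethylationClusterModel` — a beta-value matrix filtered,
  subsetted to the most variable CpGs, clustered (1 − Pearson / ward.D),
  with bootstrap stability and an age-composition Fisher test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import (
    ClusterResult,
    MethylationMatrix,
    bootstrap_stability,
    composition_test,
    cut,
    filter_probes,
    median_group_value,
    pearson_distance,
    top_variable,
    ward_cluster,
)
from .curve import AtmosphericCurve, default_curve
from .dating import (
    BirthDateEstimate,
    DatingConfig,
    Delta14CMeasurement,
    SampleRecord,
    average_cell_age,
    date_sample,
)

__all__ = [
    "BirthDatingModel",
    "BirthDatingResults",
    "MethylationClusterModel",
    "MethylationClusterResults",
]

COHORT_CSV_COLUMNS = (
    "sample_id",
    "birth_year",
    "collection_year",
    "purity",
    "purity_margin",
    "tissue_class",
    "location",
    "delta14c_permil",
    "one_sigma_permil",
)


class BirthDatingModel:
    """Retrospective ¹⁴C birth-dating of a cohort.

    Parameters
    ----------
    records, measurements
        Paired per-sample metadata and AMS measurements (same order, same
        sample_ids).
    curve
        Atmospheric reference curve; the packaged curve by default.
    config
        Interval/ambiguity policy (σ multiplier, point-estimate policy).
    """

    def __init__(
        self,
        records: Sequence[SampleRecord],
        measurements: Sequence[Delta14CMeasurement],
        curve: AtmosphericCurve | None = None,
        config: DatingConfig = DatingConfig(),
    ) -> None:
        if len(records) != len(measurements):
            raise ValueError("records and measurements must pair up 1:1")
        if len(records) == 0:
            raise ValueError("no samples")
        for rec, m in zip(records, measurements):
            if rec.sample_id != m.sample_id:
                raise ValueError(f"sample order mismatch: {rec.sample_id!r} vs {m.sample_id!r}")
        self.records = list(records)
        self.measurements = list(measurements)
        self.curve = curve if curve is not None else default_curve()
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        curve: AtmosphericCurve | None = None,
        config: DatingConfig = DatingConfig(),
        purity_percent: bool = False,
    ) -> "BirthDatingModel":
        """Build from a cohort table with the standard columns
        (``sample_id, birth_year, collection_year, purity, purity_margin,
        tissue_class, location, delta14c_permil, one_sigma_permil``).

        ``purity_percent=True`` accepts purity and margin on the 0–100
        scale, as pathology reports state them.
        """
        missing = [c for c in COHORT_CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort table lacks column(s) {missing}")
        if len(frame) == 0:
            raise ValueError("no samples")
        scale = 0.01 if purity_percent else 1.0
        records, measurements = [], []
        for _, row in frame.iterrows():
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    birth_year=float(row["birth_year"]),
                    collection_year=float(row["collection_year"]),
                    purity=float(row["purity"]) * scale,
                    purity_margin=float(row["purity_margin"]) * scale,
                    tissue_class=str(row["tissue_class"]),
                    location="" if pd.isna(row["location"]) else str(row["location"]),
                )
            )
            measurements.append(
                Delta14CMeasurement(
                    sample_id=str(row["sample_id"]),
                    delta=float(row["delta14c_permil"]),
                    one_sigma=float(row["one_sigma_permil"]),
                )
            )
        return cls(records, measurements, curve=curve, config=config)

    def fit(self) -> "BirthDatingResults":
        estimates = [
            date_sample(rec, m, self.curve, self.config)
            for rec, m in zip(self.records, self.measurements)
        ]
        return BirthDatingResults(self, estimates)


@dataclass
class BirthDatingResults:
    """Per-sample birth-date estimates with both interval types."""

    model: BirthDatingModel
    estimates: list[BirthDateEstimate]

    @property
    def frame(self) -> pd.DataFrame:
        """One row per sample: candidates, point estimate, intervals, flags,
        and average cell age at collection (NaN when ambiguous)."""
        rows = []
        for rec, est in zip(self.model.records, self.estimates):
            age = (
                average_cell_age(est, rec) if est.point_year is not None else float("nan")
            )
            rows.append(
                {
                    "sample_id": est.sample_id,
                    "tissue_class": rec.tissue_class,
                    "location": rec.location,
                    "birth_year": rec.birth_year,
                    "collection_year": rec.collection_year,
                    "n_candidates": len(est.candidate_years),
                    "candidate_years": ";".join(f"{y:.3f}" for y in est.candidate_years),
                    "point_year": est.point_year if est.point_year is not None else float("nan"),
                    "ci_meas_lo": est.ci_measurement[0],
                    "ci_meas_hi": est.ci_measurement[1],
                    "ci_worst_lo": est.ci_worst_case[0],
                    "ci_worst_hi": est.ci_worst_case[1],
                    "ambiguous": est.ambiguous,
                    "clipped": est.clipped,
                    "average_cell_age": age,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def cohort_summary(self) -> pd.DataFrame:
        """Cohort medians of average cell age and interval widths, by
        tissue class and location."""
        f = self.frame.copy()
        f["ci_meas_width"] = f["ci_meas_hi"] - f["ci_meas_lo"]
        f["ci_worst_width"] = f["ci_worst_hi"] - f["ci_worst_lo"]
        grouped = f.groupby(["tissue_class", "location"], dropna=False)
        out = grouped.agg(
            n=("point_year", "size"),
            median_cell_age=("average_cell_age", "median"),
            median_ci_meas_width=("ci_meas_width", "median"),
            median_ci_worst_width=("ci_worst_width", "median"),
            n_ambiguous=("ambiguous", "sum"),
            n_clipped=("clipped", "sum"),
        )
        return out

    def summary(self) -> str:
        f = self.frame
        n_amb = int(f["ambiguous"].sum())
        n_clip = int(f["clipped"].sum())
        lines = [
            "Retrospective 14C birth-dating results",
            "=" * 54,
            f"samples: {len(f)}   ambiguous: {n_amb}   clipped: {n_clip}",
            f"curve: {self.model.curve.label}",
            f"n_sigma: {self.model.config.n_sigma}   "
            f"ambiguity policy: {self.model.config.ambiguity_policy}",
            "",
            f[
                [
                    "point_year",
                    "ci_meas_lo",
                    "ci_meas_hi",
                    "ci_worst_lo",
                    "ci_worst_hi",
                    "average_cell_age",
                ]
            ].to_string(float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)


class MethylationClusterModel:
    """Location-stratified methylome clustering.

    Parameters
    ----------
    matrix
        Beta-value matrix with probe and sample annotations.
    location
        Optional stratum; when given, only samples with that ``location``
        annotation are analysed.
    fraction
        Most-variable-CpG fraction retained for clustering (default 1%).
    k
        Number of clusters at the dendrogram cut (default 2).
    adult_cutoff
        Age (years) at or above which a patient counts as adult in the
        composition test.
    """

    def __init__(
        self,
        matrix: MethylationMatrix,
        location: str | None = None,
        fraction: float = 0.01,
        k: int = 2,
        adult_cutoff: float = 18.0,
    ) -> None:
        if location is not None:
            matrix = matrix.stratum(location)
        if matrix.n_samples < 3:
            raise ValueError(f"need at least 3 samples to cluster, got {matrix.n_samples}")
        self.matrix = matrix
        self.location = location
        self.fraction = fraction
        self.k = k
        self.adult_cutoff = adult_cutoff

    def fit(self, bootstrap: int = 0, seed: int = 0) -> "MethylationClusterResults":
        """Run filter → top-variable → distance → ward.D → cut, plus
        ``bootstrap`` stability replicates when requested."""
        filtered = filter_probes(self.matrix)
        selected = top_variable(filtered, self.fraction)
        tree = ward_cluster(pearson_distance(selected))
        assignments = cut(tree, self.k, selected.values.index)
        bp = None
        skipped = 0
        if bootstrap > 0:
            bp, skipped = bootstrap_stability(
                filtered, self.k, bootstrap, seed, fraction=self.fraction
            )
        composition = None
        fisher_p = None
        if self.k == 2 and "age_years" in self.matrix.sample_annotations.columns:
            adult = (
                self.matrix.sample_annotations["age_years"] >= self.adult_cutoff
            ).map({True: "adult", False: "pediatric"})
            if adult.nunique() == 2:
                composition, fisher_p = composition_test(assignments, adult)
        return MethylationClusterResults(
            model=self,
            result=ClusterResult(
                merge_tree=tree,
                assignments=assignments,
                bp_values=bp,
                composition=composition,
                fisher_p=fisher_p,
            ),
            n_probes_after_filter=filtered.n_probes,
            n_probes_clustered=selected.n_probes,
            bootstrap_replicates=bootstrap,
            bootstrap_skipped=skipped,
        )


@dataclass
class MethylationClusterResults:
    model: MethylationClusterModel
    result: ClusterResult
    n_probes_after_filter: int
    n_probes_clustered: int
    bootstrap_replicates: int
    bootstrap_skipped: int

    @property
    def assignments(self) -> pd.Series:
        return self.result.assignments

    @property
    def bp_values(self) -> pd.Series | None:
        return self.result.bp_values

    @property
    def fisher_p(self) -> float | None:
        return self.result.fisher_p

    def median_age(self) -> pd.Series:
        """Per-cluster median patient age, in years."""
        return median_group_value(
            self.assignments, self.model.matrix.sample_annotations["age_years"]
        )

    def summary(self) -> str:
        sizes = self.assignments.value_counts().sort_index()
        lines = [
            "Methylome clustering results",
            "=" * 54,
            f"stratum: {self.model.location or 'all samples'}   "
            f"samples: {len(self.assignments)}   k: {self.model.k}",
            f"probes: {self.model.matrix.n_probes} -> {self.n_probes_after_filter} after "
            f"filtering -> {self.n_probes_clustered} most variable "
            f"({self.model.fraction:.1%})",
            "cluster sizes: " + ", ".join(f"c{lab}: {n}" for lab, n in sizes.items()),
        ]
        if "age_years" in self.model.matrix.sample_annotations.columns:
            med = self.median_age()
            lines.append(
                "median age by cluster: "
                + ", ".join(f"c{lab}: {v:.1f} y" for lab, v in med.items())
            )
        if self.bp_values is not None:
            lines.append(
                f"bootstrap probability (B={self.bootstrap_replicates}, "
                f"skipped {self.bootstrap_skipped}): "
                + ", ".join(f"c{lab}: {v:.2f}" for lab, v in self.bp_values.items())
            )
        if self.result.composition is not None:
            lines += [
                "",
                "cluster x age-group composition:",
                self.result.composition.to_string(),
                f"Fisher exact p (two-sided): {self.fisher_p:.3g}",
            ]
        return "\n".join(lines)
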