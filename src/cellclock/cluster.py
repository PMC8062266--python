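"""Location-stratified methylome clustering.

The clustering stage mirrors a standard array-methylation workflow for
brain-tumor cohorts profiled on the Illumina 450k and EPIC platforms:

1. drop probes overlapping SNPs, probes absent from either platform, and
   probes off the autosomes;
2. keep the most variable fraction of CpGs (by per-probe standard deviation
   of beta values);
3. hierarchically cluster samples with 1 − Pearson correlation as the
   distance and the **ward.D** agglomeration convention (Ward's
   Lance–Williams update applied to the distances as given, *not* squared —
   the convention of R's ``hclust(method = "ward.D")``, distinct from
   ward.D2);
4. assess cluster stability by bootstrap resampling of probes (plain
   bootstrap probability: the frequency with which a reference cluster's
   exact membership reappears among replicate clusters);
5. test cluster composition against a binary sample grouping (e.g. adult
   vs pediatric patients) with a two-sided Fisher exact test computed by
   hypergeometric enumeration.

Beta values (methylated fraction in [0, 1]) are clustered directly, without
an M-value logit transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree
from scipy.stats import hypergeom

__all__ = [
    "MethylationMatrix",
    "ClusterResult",
    "filter_probes",
    "top_variable",
    "pearson_distance",
    "ward_cluster",
    "cut",
    "bootstrap_stability",
    "composition_test",
    "median_group_value",
]

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

PROBE_ANNOTATION_COLUMNS = ("chrom", "snp_overlap", "on_450k", "on_850k")
SAMPLE_ANNOTATION_COLUMNS = ("age_years", "location", "diagnosis")


@dataclass(frozen=True)
class MethylationMatrix:
    """Beta-value matrix (rows = samples, columns = CpG probes) with probe
    and sample annotations.

    Missing beta values are NaN, never silent zeros.  Annotation indexes
    must match the matrix dimensions exactly.
    """

    values: pd.DataFrame
    probe_annotations: pd.DataFrame
    sample_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        finite = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(finite, initial=0.0) < 0.0 or np.nanmax(finite, initial=1.0) > 1.0:
                raise ValueError("beta values must lie in [0, 1] (missing = NaN)")
        if not self.probe_annotations.index.equals(v.columns):
            raise ValueError("probe_annotations index must equal the matrix columns")
        if not self.sample_annotations.index.equals(v.index):
            raise ValueError("sample_annotations index must equal the matrix rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def select_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(
            self.values.loc[:, list(probe_ids)],
            self.probe_annotations.loc[list(probe_ids)],
            self.sample_annotations,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(
            self.values.loc[list(sample_ids)],
            self.probe_annotations,
            self.sample_annotations.loc[list(sample_ids)],
        )

    def stratum(self, location: str) -> "MethylationMatrix":
        """Samples whose ``location`` annotation equals the given stratum.

        Strata are analysed independently: an infratentorial run never reads
        supratentorial samples, and vice versa.
        """
        mask = self.sample_annotations["location"] == location
        if not mask.any():
            raise ValueError(f"no samples with location {location!r}")
        return self.select_samples(self.sample_annotations.index[mask])


@dataclass(frozen=True)
class ClusterResult:
    """Output of the clustering pipeline for one stratum."""

    merge_tree: np.ndarray  # (n-1, 4) linkage: left, right, height, size
    assignments: pd.Series  # sample -> cluster label (0-based, by first appearance)
    bp_values: pd.Series | None = None  # cluster label -> bootstrap probability
    composition: pd.DataFrame | None = None  # cluster x group contingency
    fisher_p: float | None = None


def filter_probes(m: MethylationMatrix) -> MethylationMatrix:
    """Standard probe filter: SNP-overlapping, platform-restricted and
    non-autosomal probes are dropped; surviving probe order is preserved."""
    ann = m.probe_annotations
    missing = [c for c in PROBE_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"probe annotations lack column(s) {missing}")
    keep = (
        ~ann["snp_overlap"].astype(bool)
        & ann["on_450k"].astype(bool)
        & ann["on_850k"].astype(bool)
        & ann["chrom"].astype(str).isin(_AUTOSOMES)
    )
    return m.select_probes(ann.index[keep])


def _rank_probes(values: np.ndarray, probe_ids: Sequence, k: int) -> np.ndarray:
    """Indices of the k probes with largest sample SD (ddof=1), ties broken
    by ascending probe identifier.  Probes with any missing value are
    excluded before ranking."""
    complete = ~np.isnan(values).any(axis=0)
    sd = np.full(values.shape[1], -np.inf)
    sd[complete] = np.std(values[:, complete], axis=0, ddof=1)
    order = sorted(np.flatnonzero(complete), key=lambda j: (-sd[j], str(probe_ids[j])))
    if len(order) < k:
        raise ValueError(f"only {len(order)} rankable probes for a top-{k} selection")
    return np.array(order[:k], dtype=int)


def top_variable(m: MethylationMatrix, fraction: float = 0.01) -> MethylationMatrix:
    """Keep the ``ceil(fraction * n_probes)`` most variable probes.

    Variability is the per-probe standard deviation of beta values across
    samples.  Probes containing any missing value are excluded before
    ranking; ``n_probes`` counts the rankable probes.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    values = m.values.to_numpy(dtype=float)
    n_rankable = int((~np.isnan(values).any(axis=0)).sum())
    if n_rankable == 0:
        raise ValueError("no probes without missing values to rank")
    k = max(int(math.ceil(fraction * n_rankable)), 1)
    idx = _rank_probes(values, m.values.columns, k)
    # preserve matrix column order among the selected probes
    idx = np.sort(idx)
    return m.select_probes(m.values.columns[idx])


def pearson_distance(m: MethylationMatrix | pd.DataFrame) -> pd.DataFrame:
    """Sample × sample distance ``d(i, j) = 1 - r(i, j)`` over the current
    probe set.  Identical profiles are at distance 0, perfectly
    anticorrelated ones at 2."""
    values = m.values if isinstance(m, MethylationMatrix) else m
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 probes to correlate samples")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"zero-variance sample {values.index[flat[0]]!r}: correlation undefined")
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 2.0)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def _ward_d_linkage(d: np.ndarray) -> np.ndarray:
    """ward.D agglomeration on a distance matrix.

    Lance–Williams update with Ward coefficients applied to the distances
    AS GIVEN (R hclust ward.D; contrast ward.D2, which squares first):

        d(k, i∪j) = [(n_i + n_k) d(k,i) + (n_j + n_k) d(k,j) - n_k d(i,j)]
                    / (n_i + n_j + n_k)

    Ties at the current minimum are broken by the lexicographically smallest
    (cluster id, cluster id) pair, ids assigned scipy-style (originals
    0..n-1, merges n, n+1, ...).
    """
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    dist = d.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    ids = list(range(n))  # scipy-style cluster id of each active row
    sizes = [1] * n
    active = list(range(n))  # active row indices into dist
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        # minimum with deterministic tie-break on cluster ids
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                ri, rj = active[ai], active[aj]
                dij = dist[ri, rj]
                pair = (min(ids[ri], ids[rj]), max(ids[ri], ids[rj]))
                if best is None or dij < best[0] - 1e-15 or (abs(dij - best[0]) <= 1e-15 and pair < best[1]):
                    best = (dij, pair, ri, rj)
        dij, (id_lo, id_hi), ri, rj = best
        ni, nj = sizes[ri], sizes[rj]
        Z[step] = (id_lo, id_hi, dij, ni + nj)
        # Lance-Williams update into row ri, retire row rj
        for rk in active:
            if rk in (ri, rj):
                continue
            nk = sizes[rk]
            new = ((ni + nk) * dist[rk, ri] + (nj + nk) * dist[rk, rj] - nk * dij) / (
                ni + nj + nk
            )
            dist[rk, ri] = dist[ri, rk] = new
        sizes[ri] = ni + nj
        ids[ri] = n + step
        active.remove(rj)
    return Z


def ward_cluster(d: pd.DataFrame | np.ndarray) -> np.ndarray:
    """ward.D merge tree of a sample × sample distance table.

    Returns an (n−1) × 4 linkage array ``(left, right, height, size)`` in
    the scipy convention; merge heights are non-decreasing (Ward's criterion
    is reducible, so no inversions occur).
    """
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance table must be square")
    return _ward_d_linkage(arr)


def cut(tree: np.ndarray, k: int, sample_ids: Sequence | None = None) -> pd.Series:
    """Cut the merge tree into ``k`` clusters.

    Labels are 0-based integers ordered by first-sample appearance (the
    first sample is always in cluster 0).
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = cut_tree(tree, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        labels[i] = relabel[lab]
    index = list(sample_ids) if sample_ids is not None else list(range(n))
    return pd.Series(labels, index=index, name="cluster")


def run_pipeline(m: MethylationMatrix, fraction: float, k: int) -> tuple[np.ndarray, pd.Series]:
    """top_variable → pearson_distance → ward_cluster → cut."""
    selected = top_variable(m, fraction)
    tree = ward_cluster(pearson_distance(selected))
    return tree, cut(tree, k, m.values.index)


def bootstrap_stability(
    m: MethylationMatrix,
    k: int,
    B: int,
    seed: int,
    fraction: float = 0.01,
    jaccard: float | None = None,
) -> tuple[pd.Series, int]:
    """Plain bootstrap probability of each reference cluster.

    Probes are resampled with replacement ``B`` times; each replicate
    re-runs the variable-probe selection, distance and ward.D cut.  A
    reference cluster counts as recovered in a replicate when some replicate
    cluster has *identical* sample membership (or, with the exploratory
    ``jaccard`` relaxation, Jaccard overlap at least that threshold).
    Degenerate replicates (a zero-variance sample after resampling) are
    skipped and tallied.

    Returns ``(bp_values indexed by reference cluster label, n_skipped)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if jaccard is not None and not 0.0 < jaccard <= 1.0:
        raise ValueError("jaccard threshold must be in (0, 1]")
    _, reference = run_pipeline(m, fraction, k)
    ref_sets = {
        label: frozenset(reference.index[reference == label]) for label in sorted(reference.unique())
    }
    values = m.values.to_numpy(dtype=float)
    probe_ids = list(m.values.columns)
    rng = np.random.default_rng(seed)
    hits = {label: 0 for label in ref_sets}
    skipped = 0
    n_probes = values.shape[1]
    k_top = max(int(math.ceil(fraction * n_probes)), 1)
    for _ in range(B):
        draw = rng.integers(0, n_probes, size=n_probes)
        x = values[:, draw]
        # rank by SD with ties broken by (probe id, resampled position)
        sd = np.std(x, axis=0, ddof=1)
        order = sorted(range(n_probes), key=lambda j: (-sd[j], str(probe_ids[draw[j]]), j))
        xs = x[:, order[:k_top]]
        if np.any(xs.std(axis=1) == 0):
            skipped += 1
            continue
        d = 1.0 - np.corrcoef(xs)
        np.fill_diagonal(d, 0.0)
        labels = cut(_ward_d_linkage(d), k, m.values.index)
        rep_sets = {frozenset(labels.index[labels == lab]) for lab in labels.unique()}
        for label, members in ref_sets.items():
            if jaccard is None:
                recovered = members in rep_sets
            else:
                recovered = any(
                    len(members & rep) / len(members | rep) >= jaccard for rep in rep_sets
                )
            if recovered:
                hits[label] += 1
    n_eff = B - skipped
    if n_eff == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    bp = pd.Series({label: hits[label] / n_eff for label in ref_sets}, name="bp")
    return bp, skipped


def composition_test(
    assignments: pd.Series, binary_group: pd.Series
) -> tuple[pd.DataFrame, float]:
    """2 × 2 cluster-composition test.

    Builds the cluster × group contingency table and computes the two-sided
    Fisher exact p by hypergeometric enumeration: with margins fixed, the
    p-value is the total probability of every table at least as extreme as
    (probability no larger than) the observed one.

    Only 2 clusters × 2 groups are supported; for more clusters, run
    pairwise tests.
    """
    binary_group = binary_group.loc[assignments.index]
    table = pd.crosstab(assignments, binary_group)
    if table.shape != (2, 2):
        raise ValueError(
            f"composition_test needs exactly 2 clusters x 2 groups, got table shape "
            f"{table.shape}; run pairwise tests for larger problems"
        )
    return table, fisher_exact_2x2(table.to_numpy())


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table, by enumeration.

    With row margins (r1, r2) and column margin c1 fixed, the count ``a`` in
    the top-left cell is hypergeometric; the two-sided p sums P(a') over all
    admissible a' whose table probability does not exceed the observed
    table's (with a small relative tolerance against floating-point ties).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def median_group_value(assignments: pd.Series, values: pd.Series) -> pd.Series:
    """Per-cluster median of a per-sample numeric annotation (e.g. age).

    Even-sized clusters use the mean of the central pair.
    """
    values = values.loc[assignments.index]
    if values.isna().any():
        missing = values.index[values.isna()][0]
        raise ValueError(f"value missing for sample {missing!r}")
    out = values.groupby(assignments).median()
    if (assignments.value_counts() == 0).any():  # pragma: no cover - groupby drops empties
        raise ValueError("empty cluster has no median")
    out.name = values.name or "median"
    return out
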