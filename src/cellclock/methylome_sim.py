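"""Synthetic methylome generator with planted cluster structure.

Emulates the statistical structure the clustering stage assumes: beta
values drawn from beta distributions parameterized by (mean μ, concentration
κ) with shapes ``(μκ, (1 − μ)κ)``; a planted two-group structure in which an
``informative_fraction`` of probes shifts its mean by ``± effect_delta / 2``
between groups; an age covariate correlated with group membership
("adult-like" vs "pediatric-like"); and annotation flags (SNP overlap, sex
chromosome, single-platform) assigned to disjoint probe sets so filtering
arithmetic is exact.

It does not attempt probe-type chemistry biases, batch effects, or genome-
wide correlation structure — passing tests on these matrices show the
pipeline's statistical behaviour, not array-specific artefact handling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import MethylationMatrix

__all__ = ["MethylomeSimConfig", "generate", "null_matrix", "write_tsv_trio", "load_tsv_trio"]


@dataclass(frozen=True)
class MethylomeSimConfig:
    """Configuration of one synthetic methylome.

    n_samples_per_group
        (adult-like, pediatric-like) sample counts.
    effect_delta
        Between-group shift of the mean beta at informative probes; the two
        groups sit at ``μ ± effect_delta / 2``.
    concentration
        Beta-distribution precision κ; larger = tighter around the mean.
    snp_fraction / sexchrom_fraction / single_platform_fraction
        Rates of the three filtering flags, assigned to disjoint probe sets.
    age_model
        Per-group (lo, hi) uniform age ranges, in years.
    """

    n_samples_per_group: tuple[int, int] = (20, 20)
    n_probes: int = 2000
    informative_fraction: float = 0.05
    effect_delta: float = 0.2
    concentration: float = 30.0
    snp_fraction: float = 0.05
    sexchrom_fraction: float = 0.03
    single_platform_fraction: float = 0.05
    age_model: tuple[tuple[float, float], tuple[float, float]] = ((18.0, 60.0), (1.0, 17.0))
    location: str = "supratentorial"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples_per_group) < 1:
            raise ValueError("n_samples_per_group entries must be >= 1")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not 0.0 < self.informative_fraction < 1.0:
            raise ValueError("informative_fraction must be in (0, 1)")
        if not 0.0 <= self.effect_delta <= 0.5:
            raise ValueError("effect_delta must be in [0, 0.5]")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        flags = self.snp_fraction + self.sexchrom_fraction + self.single_platform_fraction
        for name in ("snp_fraction", "sexchrom_fraction", "single_platform_fraction"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if flags >= 1.0:
            raise ValueError("flag fractions must sum to < 1")

    @property
    def flag_counts(self) -> tuple[int, int, int]:
        """(n_snp, n_sexchrom, n_single_platform) — exact disjoint counts."""
        return (
            int(round(self.snp_fraction * self.n_probes)),
            int(round(self.sexchrom_fraction * self.n_probes)),
            int(round(self.single_platform_fraction * self.n_probes)),
        )


def generate(config: MethylomeSimConfig) -> tuple[MethylationMatrix, dict]:
    """Draw a synthetic methylome; returns ``(matrix, truth)``.

    ``truth`` records the group label of every sample, the identities of the
    informative probes and the baseline probe means, so every downstream
    recovery test has exact bookkeeping.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_a, n_p = config.n_samples_per_group
    n = n_a + n_p
    probes = [f"cg{i:07d}" for i in range(config.n_probes)]
    samples = [f"S{i:03d}" for i in range(n)]
    groups = np.array(["adult-like"] * n_a + ["pediatric-like"] * n_p)

    n_snp, n_sex, n_single = config.flag_counts
    snp = np.zeros(config.n_probes, bool)
    sex = np.zeros(config.n_probes, bool)
    single = np.zeros(config.n_probes, bool)
    snp[:n_snp] = True
    sex[n_snp : n_snp + n_sex] = True
    single[n_snp + n_sex : n_snp + n_sex + n_single] = True
    clean = ~(snp | sex | single)

    half = config.effect_delta / 2.0
    # keep shifted means inside (0, 1) with headroom for the beta draw
    mu_lo, mu_hi = 0.1 + half, 0.9 - half
    baseline = rng.uniform(mu_lo, mu_hi, size=config.n_probes)

    # informative probes live among the clean (filter-surviving) probes so
    # the planted structure survives filter_probes
    n_inf = max(int(round(config.informative_fraction * config.n_probes)), 1)
    clean_idx = np.flatnonzero(clean)
    if config.effect_delta > 0:
        if n_inf > clean_idx.size:
            raise ValueError("informative_fraction exceeds the clean-probe budget")
        informative = rng.choice(clean_idx, size=n_inf, replace=False)
    else:
        informative = np.array([], dtype=int)

    mu = np.tile(baseline, (n, 1))
    is_adult_like = groups == "adult-like"
    # direction of the shift varies per probe (hyper- and hypomethylation both
    # occur); a same-signed shift everywhere would be a constant profile
    # offset, invisible to the 1 - Pearson distance downstream
    sign = rng.choice([-1.0, 1.0], size=informative.size)
    mu[np.ix_(is_adult_like, informative)] += sign * half
    mu[np.ix_(~is_adult_like, informative)] -= sign * half

    kappa = config.concentration
    values = rng.beta(mu * kappa, (1.0 - mu) * kappa)

    chrom = rng.integers(1, 23, size=config.n_probes).astype(str)
    chrom[sex] = "X"
    probe_ann = pd.DataFrame(
        {
            "chrom": chrom,
            "snp_overlap": snp,
            "on_450k": True,
            "on_850k": ~single,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    (a_lo, a_hi), (p_lo, p_hi) = config.age_model
    ages = np.where(
        is_adult_like, rng.uniform(a_lo, a_hi, size=n), rng.uniform(p_lo, p_hi, size=n)
    )
    sample_ann = pd.DataFrame(
        {
            "age_years": ages,
            "location": config.location,
            "diagnosis": "PA",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    matrix = MethylationMatrix(
        pd.DataFrame(values, index=sample_ann.index, columns=probe_ann.index),
        probe_ann,
        sample_ann,
    )
    truth = {
        "groups": dict(zip(samples, groups)),
        "informative_probes": sorted(np.array(probes)[informative].tolist()),
        "baseline_means": dict(zip(probes, baseline.tolist())),
        "flag_counts": {"snp": n_snp, "sexchrom": n_sex, "single_platform": n_single},
        "effect_delta": config.effect_delta,
        "seed": config.seed,
    }
    return matrix, truth


def null_matrix(n_samples: int, n_probes: int, seed: int) -> MethylationMatrix:
    """Structureless matrix: no planted effect, no annotation flags."""
    if n_samples < 2 or n_probes < 2:
        raise ValueError("need at least 2 samples and 2 probes")
    n_a = n_samples // 2
    config = MethylomeSimConfig(
        n_samples_per_group=(n_a, n_samples - n_a),
        n_probes=n_probes,
        effect_delta=0.0,
        snp_fraction=0.0,
        sexchrom_fraction=0.0,
        single_platform_fraction=0.0,
        seed=seed,
    )
    matrix, _ = generate(config)
    return matrix


def write_tsv_trio(matrix: MethylationMatrix, outdir: str | Path, truth: dict | None = None) -> None:
    """Write ``betas.tsv``, ``probes.tsv``, ``samples.tsv`` (and optionally
    ``truth.json``) in the formats the clustering CLI consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(outdir / "betas.tsv", sep="\t", index_label="sample_id")
    matrix.probe_annotations.to_csv(outdir / "probes.tsv", sep="\t")
    matrix.sample_annotations.to_csv(outdir / "samples.tsv", sep="\t")
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def load_tsv_trio(indir: str | Path) -> MethylationMatrix:
    """Load the TSV trio written by :func:`write_tsv_trio`."""
    indir = Path(indir)
    values = pd.read_csv(indir / "betas.tsv", sep="\t", index_col="sample_id")
    probes = pd.read_csv(indir / "probes.tsv", sep="\t", index_col="probe_id")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample_id")
    return MethylationMatrix(values, probes.loc[values.columns], samples.loc[values.index])
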