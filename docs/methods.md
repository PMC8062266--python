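# Methods

## The atmospheric reference curve

The dating reference is a piecewise-linear Northern-Hemisphere Δ¹⁴C curve
carried as a fixed knot table (28 knots, 1890–2016).  The knots are an
explicit approximation to published Northern-Hemisphere compilations: a
slightly negative pre-1955 baseline (−20 to 0 ‰), the bomb-test rise from
1955 to a single peak of 970 ‰ at 1964.0, and the subsequent decay to
20 ‰ by 2016.  Pinning the knots makes every downstream inversion
deterministic; any other compilation can be substituted via
`load_curve()` (CSV with header `year,delta14c_permil`).  Linear
interpolation between knots is used deliberately: it preserves
monotonicity within segments, so inversion reduces to per-segment linear
solves, and it never manufactures spurious extrema the way a spline can.
Δ¹⁴C values are treated as already decay-corrected against the universal
standard; no further decay correction is applied.  The curve is never
extrapolated — evaluation outside the knot span is a domain error.

Time is decimal calendar years throughout.  Dates known only to the year
(as in clinical metadata) map to mid-year, `year + 0.5`.

## Inversion, mixing correction, and intervals

`invert(curve, delta, window)` returns every crossing of the curve with a
horizontal line in the admissible window `[birth_year, collection_year]` —
no cell can predate the individual or postdate collection.  A value lying
on a flat curve segment contributes the segment's two endpoints (the
extremes of the attainment set).  Values above ~220 ‰ typically cross the
curve twice (once on the rise, once on the decay) when the window includes
the pre-peak years; this is a genuine physical ambiguity, not a numerical
artifact, and the default policy (`report-all`) refuses to pick a point
estimate in that case.  `latest` / `earliest` policies are available when
outside evidence (e.g. symptom history) justifies a choice.

The bulk measurement mixes tumor and non-tumor DNA.  With purity *p* and
contaminant Δ¹⁴C *c*, the tumor compartment is
`(m − (1 − p)·c) / p`; the correction is undefined at *p* = 0, where the
bulk signal carries no tumor information.  For the point estimate the
contaminant is set to the mean of the two extreme scenarios (cells as old
as the individual, i.e. the curve at the birth year, and contemporary
cells, i.e. the curve at the collection year): unbiased between the
extremes, which themselves enter only the worst-case interval.

### Level-set construction of the intervals

Both intervals are computed as hulls of curve *level sets* rather than as
hulls of finitely many inverted deltas:

* the **measurement interval** is the hull of every year in the window
  whose curve value lies within `±n_sigma·σ` of the purity-corrected
  measurement (σ is scaled by `1/p`, the exact propagation of a symmetric
  error through the linear mixing correction);
* the **worst-case interval** enumerates the extreme-combination grid
  (measured delta at −nσ/0/+nσ × purity at `p − margin`, `p`,
  `p + margin`, clipped to [0, 1] × the two contaminant extremes),
  purity-corrects each combination, and takes the hull of the years whose
  curve value lies inside the band spanned by the extreme corrected
  values.  Because the correction is monotone in each coordinate, the grid
  corners bound that band exactly.

The level-set formulation matters at window boundaries: a naive hull over
the finitely many inverted corner deltas can *lose* a crossing that slides
out of the admissible window for a corner value while remaining in-window
for intermediate values, which breaks both the nesting of the measurement
interval inside the worst-case interval and the monotone widening of the
worst-case interval with the purity margin.  With level-set hulls both
properties are theorems: bands are nested, so their level sets and hulls
are nested.  The extrema of a level set sit either on inversions of the
band boundaries or on a window endpoint whose value lies inside the band,
and both sets are enumerated exactly.

A band unattainable anywhere in the window (e.g. a measured value above
everything the curve reaches between birth and collection) snaps to the
in-window year whose curve value is closest — the arg-max/arg-min of the
curve over the window, which is the window endpoint itself whenever the
curve is monotone there — and flags the estimate `clipped`, so cohort
runs complete instead of erroring.

Defaults: `n_sigma = 1` (interval shading at 1σ), `purity_margin = 0.05`
(a symmetric 5-percentage-point allowance for intra-tumor heterogeneity of
the pathology purity estimate); both configurable.  A 1σ band is a ~68%
statement; coverage claims at the 95% level require `n_sigma = 2`, and the
simulator-based coverage test is run at 2σ accordingly.

Methylation adds carbon to DNA (one methyl carbon per 5-methylcytosine),
which could in principle perturb the date mark.
`methylation_carbon_shift()` quantifies the effect: with ~2.8 × 10⁷ CpGs at
75% methylation against ~19.75 carbons per base pair of a 3.1-Gb genome,
methyl groups contribute < 0.1% of genomic carbon — negligible at AMS
precision even if every methyl group were contemporary.

## Genome birth-date simulator

A bulk measurement reflects the distribution of genome synthesis dates,
not a single date.  The simulator provides three distribution families:

* **point** — all genomes synthesized at one date (post-mitotic tissue,
  e.g. cerebellar neurons);
* **growth** — a founder cell at `t0` grows exponentially with per-year
  division rate `rate` and death rate `death_rate < rate`; genomes
  synthesized near *t* carry weight
  `rate · e^{(rate−death)(t−t0)} · e^{−death·(collection−t)}` plus the
  founder's surviving point mass at `t0`, normalized on a regular grid
  (default spacing 0.05 yr, well below dating precision).  The
  exponential-with-turnover family is the simulator's own testing choice,
  not a biological claim about any tumor entity;
* **uniform** — a maximally agnostic contaminant over `[birth,
  collection]`.

Weights are computed in log space so large `rate × timespan` products do
not overflow.  `expected_delta` integrates the curve over the
distribution — exactly what bulk AMS measures.

`synthesize_cohort` mixes the tumor-compartment expectation with a
contaminant scenario (`old` = curve at birth, `contemporary` = curve at
collection, `mixed` = uniform contaminant — real non-tumor fractions are
mixtures of cell types with variable turnover) at weight `1 − purity`,
adds Gaussian noise (default σ = 5 ‰, a typical modern AMS error
magnitude; the noise is approximately symmetric at these values), and
emits dating-ready records plus a ground-truth table.  Seeds are
mandatory; there is no implicit global randomness, and a (config, seed)
pair reproduces a cohort byte-for-byte.

What the simulator does **not** emulate: subclonal structure, spatially
heterogeneous growth, strand-level semiconservative bookkeeping, or
non-Gaussian AMS error tails.  Passing recovery tests therefore
demonstrates correctness of the inversion machinery under the stated
mixing and noise model, not robustness to every biology.

## Methylome clustering

The pipeline mirrors the standard two-platform (450k + EPIC) array
workflow:

1. **Probe filter** — drop SNP-overlapping probes, probes absent from
   either platform, and probes off autosomes 1–22; survivor order is
   preserved.
2. **Variable-probe selection** — keep the `ceil(fraction · n)` probes
   with the largest across-sample standard deviation (default fraction
   1%).  Probes with any missing beta value are dropped before ranking
   (the simplest defensible rule); ties break by probe identifier so runs
   are deterministic.
3. **Distance** — `1 − Pearson r` between samples over the selected
   probes.  Beta values are clustered directly (no M-value logit
   transform).  Zero-variance samples are a hard error naming the sample.
4. **ward.D agglomeration** — Ward's Lance–Williams coefficients applied
   to the dissimilarities *as given* (the R `hclust` ward.D convention;
   ward.D2 squares first, which changes merge order on non-Euclidean
   inputs such as correlation distances).  Ties at the current minimum
   break by the lexicographically smallest cluster-id pair.  Ward's
   criterion is reducible, so merge heights are non-decreasing and
   dendrogram cuts are well defined.  The implementation is validated
   against R `hclust(method = "ward.D")` on a frozen fixture (heights to
   1e−12) and against hand-computed Lance–Williams updates.
5. **Bootstrap probability** — probes resampled with replacement B times;
   each replicate re-runs selection → distance → ward.D → cut; a
   reference cluster scores a hit when a replicate cluster has *identical*
   membership.  This is plain BP (recovery frequency), not
   multiscale-corrected AU.  Degenerate replicates (a zero-variance sample
   after resampling) are skipped and tallied.
6. **Composition test** — 2 × 2 cluster × group contingency with a
   two-sided Fisher exact p computed by hypergeometric enumeration (sum of
   all table probabilities not exceeding the observed table's, with a
   1e−7 relative tolerance against floating-point ties — strictly smaller
   than the minimal spacing between distinct hypergeometric probabilities
   at the table sizes in scope).  Larger tables are rejected with a
   pointer to pairwise testing.  The adult/pediatric dichotomy defaults to
   age ≥ 18 years, configurable.

Strata (supratentorial vs infratentorial) are analysed independently:
`MethylationMatrix.stratum()` subsets samples before anything else runs,
so one stratum's analysis never reads the other's data.

`k` defaults to 2 clusters, always overridable.

## Synthetic methylome

Beta values are drawn from Beta(μκ, (1 − μ)κ) with per-probe baseline
means μ ~ U(0.1 + δ/2, 0.9 − δ/2) and concentration κ = 30, which matches
the spread of array beta values without modelling bimodality explicitly.
A fraction of probes (default 5%) is informative: their means shift by
±δ/2 between the two planted groups, with the *direction* drawn per probe
— differential methylation is both hyper- and hypo-directed, and a
same-signed shift everywhere would be a constant profile offset invisible
to correlation distance.  Informative probes are planted among
filter-surviving probes so the filter cannot delete the structure being
tested.  Annotation flags (SNP, sex-chromosome, single-platform; defaults
5%/3%/5%) go to disjoint probe sets, making filter arithmetic exact.
Ages are planted per group (adult-like ~ U(18, 60), pediatric-like ~
U(1, 17)) so the composition test has known truth.  The generator does
not simulate probe-type chemistry, batch effects, or genome-wide
correlation structure.

## Problem sizes and numerical choices

Default study conditions: planted methylomes of 20 + 20 samples × 2000
probes at δ = 0.2 with 5% informative probes; bootstrap stability at
B = 100; the dating-precision figure uses 500 replicates with true years
uniform in [1965, 1995], σ = 5 ‰, purity 1, inverted over the post-peak
window (birth 1964, collection 2016) where the curve is strictly
decreasing and the inversion unique; the type-I-error calibration uses
500 null matrices of 20 samples × 200 probes.  Inversion candidates
closer than 1e−9 yr merge into one crossing; distribution grids use
0.05-yr spacing.

## Known limitations

* The packaged curve is an approximation; absolute dates shift by up to a
  couple of years against other compilations (swap in a measured
  compilation via `load_curve` for production dating).
* Point estimates under ambiguity are policy, not inference; a full
  Bayesian posterior over the curve is out of scope.
* The worst-case interval treats purity and contaminant scenarios as
  set-valued (min/max), not probabilistic: it is a bounding box, and its
  coverage is therefore conservative in the contaminated directions and
  limited by `n_sigma` in the noise direction.
* Bootstrap probability with exact-membership matching is strict for
  large cohorts; a Jaccard-relaxed matching exists behind a flag for
  exploration but is off by default.
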