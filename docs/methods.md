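# Methods note

This note records the statistical model, its assumptions, the default
parameters and the numerical choices behind `acetylpipe`, plus what the
synthetic benchmark can and cannot demonstrate.

## 1. Data model

A feature table holds linear-scale reporter intensities for features (acetyl
sites or protein groups) across a `(plex, channel)` column grid; a masked cell
(NaN) means *not observed* and is never imputed. The plex design maps each
`(plex, channel)` to a condition and replicate, with exactly one pooled
reference (REF) channel per plex and the baseline condition (`wildtype`)
present in every plex. The default design is three plexes (one biological
replicate each) of 16 channels: wildtype, MS-275 at 6 h and 24 h,
catalytically-inactive (CI) HDAC1/2/3/8 mutants in both wildtype and knockout
backgrounds, the straight HDAC1/2/3/8 knockouts, and REF on channel 133C.

## 2. Pipeline stages

### 2.1 Reporter-ion impurity correction

Each label's signal leaks into ladder neighbours at lot-sheet percentages
(offsets −2, −1, +1, +2). Column *j* of the impurity matrix `A` distributes
label *j*'s true signal; the diagonal is one minus the label's total stated
leakage, and leakage pointing outside the ladder is discarded (column sums
≤ 1, with a warning). Per (feature, plex) the observed vector `o = A·t` is
solved exactly (`numpy.linalg.solve`, vectorized over features); any solution
with a negative component — physically impossible intensity — is replaced by
non-negative least squares (`scipy.optimize.nnls`), clamping the offending
channels to zero. Vectors with any masked channel pass through uncorrected
(the partial system is underdetermined) and are counted. Matrices with
condition number above 1e8 or any diagonal ≤ 0.5 are rejected.

### 2.2 Within-plex median normalization

Channel *c* of a plex is scaled by `2^(grand − median_c)`, where `median_c` is
its log2 median over unmasked features and `grand` is the median of the
channel medians. This removes per-channel loading while leaving the plex's
overall scale intact, and it is idempotent.

*Bias under heavy regulation:* median normalization assumes most features are
unregulated in every channel. When a large fraction of sites in one condition
is truly up, that channel's median rises and normalization subtracts part of
the real effect from every site. At the generator's default (~8% of sites
regulated per affected condition) the induced bias is small; in a stress
configuration with ~27% regulated sites we measured a log2 fold-change bias of
about −0.65. This is a property of the method itself, shared with any
global-scaling normalization, not an implementation artifact — effect-size
accuracy is therefore benchmarked at the differential-testing level where the
normalization assumption holds.

### 2.3 Between-plex IRS normalization

For each feature, the REF intensities across plexes are aligned to their
geometric mean; the per-(feature, plex) factor `geomean/ref` rescales every
channel of that plex. A purely multiplicative plex batch effect is removed
exactly. Features whose REF is masked in a plex have that plex masked (no
imputation); features with REF masked everywhere are dropped, and both events
are counted in the normalization report.

### 2.4 Site-to-protein normalization

`log2(site) − log2(protein)` cell-wise via the site's protein group, so a site
is only "up" if it moves relative to its protein. Sites whose protein was not
quantified are routed to a separate unnormalized output.

### 2.5 Empirical-Bayes moderated testing

Per feature, a one-way layout over all conditions pools the residual variance
`s²` with `d = N − G` degrees of freedom. The variances are assumed to follow
a scaled inverse-chi-square prior with hyperparameters `(d0, s0²)`, estimated
by moment matching on `log s²`: the theoretical mean and variance of
`log χ²_d/d` involve digamma/trigamma functions, and `d0` is obtained by
inverting the trigamma function with a Newton iteration (`trigamma_inverse`).
The posterior variance `s̃² = (d0·s0² + d·s²)/(d0 + d)` gives the moderated
t-statistic with `d0 + d` degrees of freedom. Degenerate regimes are explicit:
fewer than two informative features → no moderation (`d0 = 0`, ordinary t);
under-dispersed observed variances → complete shrinkage (`d0 = ∞`). Setting
`prior_df=0` reproduces the ordinary pooled-variance t exactly, which is used
as an oracle in the tests.

Contrasts are each condition versus wildtype. A feature–contrast pair is
tested only if both arms have at least `min_replicates` (default 3) unmasked
observations; otherwise it is reported `untested`, never silently dropped.
Benjamini–Hochberg adjustment (`statsmodels`, verified against a brute-force
step-up in the tests) runs per contrast family. The regulated call is
inclusive: `|log2fc| ≥ log2(1.5)` and `padj ≤ 0.05`.

*Sensitivity at the threshold:* for effects planted exactly at the 1.5-fold
boundary, an unbiased estimator lands below the inclusive threshold with
probability ≈ 0.5 (at CV 10%, n = 3/arm the estimate is ≈ N(log2 1.5, 0.118)),
so no correct implementation can achieve high sensitivity of the *joint* rule
there; the significance component alone is well powered (> 0.97). The test
suite therefore checks unbiasedness (±0.1) at the boundary and ≥ 0.9
sensitivity of the full rule at 2-fold effects, the lower edge of the clearly
regulated regime.

### 2.6 Substrate classification

From the per-contrast calls: a *hyperacetylated protein* owns ≥ 1 up-called
site in a condition; a *confident substrate* of an isoform is up in its CI
mutant in both genetic backgrounds (optionally also in the knockout); the
*overlap fraction* is the percentage of a reference up-set covered by the
union of target up-sets, at site or protein level; the *preferential class*
partitions features into HDAC1/2, HDAC3, HDAC1/2/3 or none from the genotype
conditions only (inhibitor conditions contribute to overlaps, never to
classification).

### 2.7 PRM arm

Three transitions per peptide/charge are summed, then summed across charge
states, into a total peak area. Unmodified (never-acetylated) peptides define
per-sample loading factors by median-of-ratios: each normalizer peptide's
across-sample **median** total is its pseudo-reference, and the sample factor
is the median over peptides of reference/total. The median pseudo-reference
(rather than a geometric mean) makes the hand-computable fixtures exact —
identical samples get factor 1.0 and a uniformly doubled sample gets exactly
0.5 — while keeping the estimator robust to aberrant peptides and equalizing
normalizer levels under multiplicative loading. Modified-peptide totals are
scaled, expressed as fold change over the mock-group mean, and compared
across time-point groups with a classical one-way ANOVA (`scipy`; for two
groups F = t² exactly). Every group needs ≥ 2 replicates.

## 3. Synthetic generator

Generative model (log2 space): protein abundance ~ N(20, 1.5²); site signal =
protein + site offset N(−2, 1²) + planted acetylation effect + per-(feature,
plex) batch effect N(0, 0.5²) + per-(plex, channel) loading N(0, 0.2²) +
measurement noise with sd = CV/ln 2 (first-order lognormal). REF is the
in-silico pool (log-space mean) of the plex's condition channels, matching its
physical construction. Intensities are linearized, mixed through the impurity
matrix, and thinned by logistic intensity-dependent dropout
(P(missing) = sigmoid(−(log2 x − 12)/1)).

Planted truth: HDAC1/2 substrates are up in the four HDAC1/2 CI conditions;
HDAC3 substrates in both HDAC3 CI clones and (for an exact-count 80% protein
subset) the HDAC3 knockout; shared substrates in all seven. MS-275 responses
mirror the genetic classes with exact-count protein coverages (82% of HDAC1/2
and shared, 32% of HDAC3 substrates at 6 h; 100% at 24 h). Coverage subsets
are drawn as exact counts, not Bernoulli, so noise-free recovery of set sizes
is exact. Independently, 50 proteins receive a pure protein-abundance change
(2-fold) to exercise site-to-protein normalization.

**Problem sizes are this package's own choice**: the default desk scale
(1,000 proteins, ~3,000 sites, 3 plexes) keeps the full test suite in seconds;
`SimConfig.paper_scale()` approximates the full-study scale for stress runs.

What the synthetic benchmark shows: exact inversion of every distortion it
plants (impurity mixing, loading, batch effects, protein confounding), correct
null calibration, hyperparameter recovery, and exact recovery of planted set
sizes and classes in the noise-free limit. What it does not show: anything
about identification (search engines, FDR at the PSM level), co-eluting
interference/ratio compression beyond the linear impurity model,
peptide-to-site aggregation ambiguity, or biological variance structure beyond
independent lognormal noise.

*Class recovery and dropout:* the completeness rule requires all three
replicates in both arms, on both the site and its protein. With
intensity-dependent dropout on, a site missing one wildtype replicate loses
all its contrasts and cannot be classified — a designed property of the
completeness rule, not an error. End-to-end class-recovery benchmarks
therefore disable dropout (`missing_scale=0`) to measure the classifier
itself; with default dropout the measured class accuracy stays above 0.9.

## 4. Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| fold-change threshold | 1.5 (inclusive) | the study's regulated-site rule |
| alpha (padj) | 0.05 (inclusive) | the study's regulated-site rule |
| min_replicates | 3 | "quantified in all three replicates" completeness rule |
| impurity offsets | −1: 1%, +1: 3%, +2: 0.1% | typical reagent-certificate magnitudes |
| condition-number limit | 1e8 | reject near-singular impurity matrices before solving |
| CV | 0.10 | typical TMT reporter-level measurement noise |
| plex batch sd | 0.5 (log2) | strong enough that IRS is load-bearing |
| channel loading sd | 0.2 (log2) | moderate pipetting-scale variation |
| dropout midpoint / scale | log2 x = 12 / 1 | low-abundance features lost preferentially |
| substrate counts | 40 / 25 / 15 (HDAC1/2, HDAC3, shared) | set sizes comparable to the study's substrate lists |
| effect range | 4- to 90-fold | clearly regulated regime observed for substrates |
| PRM groups | mock, 2 h, 6 h, 24 h × 4 | the validation arm's time course |

## 5. Numerical choices

- Batch linear solves (`numpy.linalg.solve`) with per-row NNLS fallback only
  where a negative component appears.
- `d0` estimation via trigamma Newton inversion with a guarded starting point;
  moment matching on log s² is insensitive to a few extreme variances.
- TSV output quantizes numbers to 6 significant digits (`%.6g`) so
  write→read→write round trips are byte-identical; result files are sorted by
  (feature, contrast) with a stable mergesort, making output independent of
  input row order.
- All randomness flows through `numpy.random.default_rng(seed)`; derived seeds
  come from `SeedSequence` and stay below 2³¹.
- Standard statistical primitives are delegated to established libraries
  (`statsmodels` for BH, `scipy` for ANOVA/NNLS/distributions); the moderated
  variance machinery is implemented here and cross-checked against independent
  brute-force oracles in the tests.

## 6. Limitations

- Median normalization biases effect sizes when a large fraction of features
  is regulated in a condition (§2.2).
- The impurity model is linear and within-ladder; co-isolation interference is
  out of scope.
- The moderated model assumes exchangeable variances across features within
  one prior; no intensity-dependent variance trend is fitted.
- PRM fold changes assume normalizer peptides are truly unregulated.
- The generator's missingness mechanism is univariate-logistic in intensity;
  real missingness also depends on precursor selection stochasticity.
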