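# Methods

## Setting

The package analyses K paired cohorts, one per cancer type.  Each
cohort is a genes × samples table of nonnegative FPKM-like expression
values split into a normal arm and a cancer arm by a sample map, and
admitted only when both arms have at least 10 samples (configurable).
Analyses are restricted to a user-supplied gene panel — the motivating
application is a 127-gene glucose-metabolism panel — by exact,
case-sensitive symbol match; panel symbols absent from a cohort are
reported, never imputed, and propagate through the screens as missing
per-cohort records.

## Differential expression

**Normalization.**  Both arms of a cohort are normalized jointly: every
sample column is scaled to the median column sum of the combined
matrix (for an even number of columns, the median is the mean of the
two middle sums).  Joint rather than per-arm scaling is essential —
scaling each arm to its own median would absorb part of the very
between-arm differences being estimated.

**Effect size.**  `log2FC = log2((mean_cancer + c)/(mean_normal + c))`
on normalized values, positive = up in cancer.  The pseudocount
`c = 1e-3` (configurable) only matters near zero means; it bounds the
attainable |log2FC| at roughly `log2(mean/c)` and keeps the statistic
defined for silent genes.

**Significance.**  A per-gene two-group likelihood-ratio test on
rounded normalized values: H₀ one shared Poisson mean, H₁ one mean per
arm, statistic `Λ = 2(ℓ₁ − ℓ₀)` referred to χ²(1).  The factorial
terms of the Poisson log-likelihood cancel in the ratio, so the
implementation evaluates only `Σx·log μ̂ − n·μ̂` terms; a brute-force
evaluation with the full `logpmf` is kept as a test oracle.  Two
all-zero groups are a flagged degenerate case (Λ = 0, p = 1).  The
Poisson model treats normalized expression as counts; bulk RNA-seq is
overdispersed relative to Poisson, so raw p-values are anti-
conservative for near-null genes and the fold-change cut-off is the
effective false-positive control in the differential screen.  This is
the standard behavior of Poisson-likelihood DE tests and is why the
screen always applies both criteria together.  Benjamini–Hochberg
adjustment within cohort is available behind a flag, off by default
(the screen's convention is raw p < 0.05 per cohort).

**Cross-cohort screens.**  The *trend* screen calls a gene consistent
when all available log2FC values are strictly positive or strictly
negative (zero counts as neither — a flat gene is never declared
consistent).  The *differential* screen passes a gene per cohort iff
available ∧ |log2FC| ≥ 1 ∧ p < 0.05, and (by default) requires a pass
in every cohort where the gene is available.  When records carry no
p-value — screening a published fold-change grid — the p criterion is
treated as satisfied and the run report says so explicitly.  Note the
differential screen does not itself require sign consistency: with the
cut-offs at zero it degenerates to "available everywhere", and callers
combine it with the trend screen when direction matters.

## Correlation decoupling

Pearson correlation matrices are computed per cohort and arm on
`log2(x+1)`-transformed expression (FPKM is heavy-tailed; the
transform is a config knob and `none` reproduces correlation on raw
values).  Genes with zero variance yield undefined entries, tracked in
an explicit mask rather than as numeric sentinels.

Each defined pair is classified by `(r_normal, r_cancer)`:

1. the starting sign needs `|r_normal| > sign_tau` (else *undefined*);
2. `|r_normal − r_cancer| < delta_min` is *null_change*;
3. otherwise, a positive start maps to more-positive
   (`r_cancer > r_normal`), sign-crossing (`r_cancer < −sign_tau`) or
   less-positive; negative starts mirror exactly.

Boundary conventions are half-open and fixed: `r_cancer` landing
exactly on the far dead-zone edge is "less", not sign-crossing.  The
defaults `sign_tau = delta_min = 0.1` are deliberately small and
symmetric; no field-standard values exist for "strong" or "weaker"
correlation, so both are explicit configuration echoed into every run
report.  The classifier is exactly antisymmetric: negating both r
values mirrors positive-start categories onto negative-start ones.

A pair is a consistency hit when every cohort in which it is defined
assigns the same one of the six real categories; with `require_all`
(default) the pair must be defined in every cohort.  Hits shrink
monotonically as `delta_min` grows or as cohorts are added.  They are
*not* guaranteed monotone in `sign_tau`: raising the dead zone can
reclassify a sign-crossing cohort as "less" and thereby harmonize a
previously mixed pair, so `sign_tau` sweeps should be read as different
conventions, not nested filters.  The number of cohorts is the real
multiplicity control: with 12 cohorts chance agreement is negligible,
while the 3-cohort smoke preset readily produces chance hits (visible
in its own example output).

An optional two-sample Fisher z-test
(`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, two-sided normal
p) is provided as a significance filter on correlation changes; it is
not applied inside the categorical screen by default.

## PPI neighborhood

BioGRID tab-format files are parsed on the official-symbol columns;
rows with empty/placeholder symbols are skipped and counted, evidence
lines collapse to one undirected edge per pair, self-interactions are
dropped, and both removals are reported.  No filtering by experimental
system or organism happens by default (flags exist).  The
direct-interaction subnetwork of a seed set keeps exactly the
seed-incident edges; seed–seed edges count once.  Interaction counts
from a given BioGRID release are properties of that release and are
reported as computed, not compared against pinned historical values.

## Synthetic cohorts

The generator emulates the structure the screens are built to detect,
not RNA-seq noise in full.  Expression is `exp(z)` with latent Gaussian
`z`: per-gene baselines spread uniformly over `base_log_mean ± 1`
(defaults give means of roughly e² – e⁴ ≈ 7–55 expression units) and
within-group standard deviation `base_log_sd = 0.5` on the natural-log
scale, i.e. a biological CV of ≈ 53 %, a typical within-group spread
for bulk tissue cohorts.  Differential genes shift the cancer-arm
latent mean by `log2fc · ln 2`, making the population log2FC of means
exactly the planted value.  Decoupling pairs draw their latent noise
from a bivariate Gaussian with the target correlation per arm
(Gaussian copula), so realized log-scale Pearson r concentrates on the
target; decoupling is a correlation change only — no outliers or
mixture samples.  Backgrounds are independent.  Not emulated: library-
size variation, overdispersion beyond lognormal, dropout, batch
effects, or the true gene–gene covariance of real tissue — so passing
recovery tests demonstrates the screens' statistical machinery, not
performance on real TCGA data.

One global seed expands into `SeedSequence(seed, spawn_key=(1, cohort,
arm))` substreams (gene baselines use `spawn_key=(0,)`), so adding a
cohort never perturbs earlier cohorts and runs are bit-reproducible.

Two presets exist.  `paper_shaped_spec()` reproduces the pan-cancer
study shape: 12 cohorts with the real TCGA sample counts (normal arms
from 11 to 113), 127 genes, two consistent differential genes (log2FC
−3 and +2, echoing the magnitudes of the study's two headline genes)
and five decoupling pairs, three positive-weakening and two
negative-weakening.  Planted correlations go from ±0.9 (strong) to
±0.2 (weak): with the smallest normal arm at n = 11 the sampling sd of
r̂ around 0.9 is ≈ 0.13 (Fisher scale 1/√8), so a 0.9 → 0.2 transition
stays identifiable in every cohort while, e.g., 0.8 → 0.3 would not be
reliably ordered at that n.  `small_spec()` is a 3-cohort, 40-gene
miniature with 30/60 samples per arm, sized so its planted effects are
estimable — it exists for fast smoke runs, and its 3-cohort consistency
screen is expected to admit chance pairs.

## Determinism and numerics

Screens are deterministic; all randomness lives in the generator and
is seed-controlled.  Correlation matrices are symmetrized
(`(R + Rᵀ)/2`), clipped to [−1, 1], and carry exact 1.0 diagonals;
classifier inputs outside [−1, 1] or NaN are errors, not categories.
Ties in screen orderings are broken by gene symbol under a stable
sort, so output files are byte-identical across reruns.  Problem sizes
in the test suite (10 seeds of the 12-cohort spec; 2000-replicate null
calibrations; 41 × 41 classifier grids) were chosen to give the
recovery and calibration assertions low flake probability while
keeping the full suite under a minute.

## Known limitations

- The Poisson LRT is a simple likelihood model for normalized
  expression, not a dispersion-aware count model (no MA-plot/MARS
  variants, no negative-binomial mode); its raw p-values should not be
  interpreted alone near the null.
- Whether correlations should be computed on raw or log-transformed
  FPKM is a convention, not a derivable fact; both are supported and
  the choice is logged.
- Gene identity is exact symbol match; alias resolution and
  cross-release symbol drift are out of scope.
- The consistency screen has no permutation-based null; the
  cross-cohort agreement requirement is the only multiplicity control.
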