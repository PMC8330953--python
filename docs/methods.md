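# Methods

This note documents the models behind each `pitfoam` module, the defaults
and why they were chosen, what the synthetic cohort generator does and
does not emulate, and the numerical conventions.

## Study system and data model

Deep-pit swine manure storages are sampled monthly across many farms. Each
sample carries a surface texture label (no-foam, crust, foam), amplicon
OTU tables for bacteria (16S rRNA) and methanogens (*mcrA*), and diet /
manure-chemistry covariates including the methane production rate (MPR,
L CH₄ · L manure⁻¹ · day⁻¹; foaming is associated with MPR ≥ 0.1). The
analyses treat the OTU tables as the unit of community data and never
rarefy: raw counts feed the QC filters, per-sample relative abundances
feed everything downstream.

## QC (`amplicon_qc`)

OTUs with fewer than 5 reads across all samples are removed first, then
samples failing depth/coverage thresholds (16S: 10 000 reads and Good's
coverage ≥ 0.97; *mcrA*: 4 000 and ≥ 0.99). Good's coverage is
`1 − F₁/N`: the estimated probability that one more read would belong to
an already-seen OTU. Coverage is computed on the table as passed to
`filter_samples` — i.e. after the OTU filter in the default pipeline
order; callers wanting pre-filter coverage simply call `sample_coverage`
before filtering. Both filters report every removal with its reason, and
aggregation to a taxonomic rank conserves per-sample totals exactly,
pooling OTUs unclassified at that rank into "unclassified &lt;parent&gt;"
groups.

## Community comparison (`ecology_stats`)

*Bray-Curtis* is computed as `1 − 2Σmin(xᵢ,xⱼ)/(Σxᵢ+Σxⱼ)`, algebraically
identical to `Σ|xᵢ−xⱼ|/Σ(xᵢ+xⱼ)`.

*PERMANOVA* uses the one-factor partition of squared dissimilarities
(`SS_total = Σ_{i<j} d²ᵢⱼ/N`; within-group sums divided by group size) and
a pseudo-F with (a−1, N−a) degrees of freedom. p-values carry the +1
permutation correction and so never reach 0. Because repeated samples of
one farm are not exchangeable across farms, farm blocking is implemented
as **restricted permutation**: texture labels are shuffled only within
each farm. When texture is constant within farms this scheme returns
p = 1 — by design, since such data contain no within-block evidence. The
farm factor itself is tested with free permutations. An exact mode
enumerates all distinct label arrangements for small n.

*NMDS* minimizes Kruskal stress-1 `√(Σ(d−d̂)²/Σd²)` where `d` are
configuration distances and `d̂` isotonic (primary-tie) disparities,
alternating PAVA isotonic regression with the Guttman transform (SMACOF).
An iteration that would increase stress is discarded and the run stops,
so the recorded stress sequence is non-increasing. Restart 0 starts from
classical metric scaling, further restarts from random configurations;
the best restart wins. Stress around 0.3 at k = 2 is expected for
high-dimensional compositional data and is reported, not hidden.

*Environmental surfaces* regress a covariate (e.g. MPR) on the full
quadratic polynomial in the ordination coordinates by least squares. This
is a deliberately simple, deterministic stand-in for spline/GAM contour
fitters; its R² plays the same role but is not numerically comparable to
values produced by other smoothers. Constant covariates define R² = 0.

## Ordered-trend Bayes factors (`trend_bayes`)

`bf_anova` is a JZS one-way ANOVA Bayes factor: the alternative places the
group effects, standardized by σ and expressed in an orthonormal
sum-to-zero (Helmert) basis, under a N(0, g·σ²) prior with
g ~ InverseGamma(1/2, r²/2) — jointly a Cauchy prior with scale
r = `prior_scale` (default 0.5, "medium") — and (μ, σ²) under the Jeffreys
prior. For fixed g the marginal likelihood ratio is available in closed
form; g is integrated out by Simpson quadrature on a fixed log-scale grid
(4001 points over ±35 log units), so the BF is deterministic. For two
balanced groups this model is exactly the JZS two-sample Bayes factor
with Cauchy scale √2·r; the tests verify this against an independent
noncentral-t double-integration oracle. Bayes factors reported by other
software on other data are not reproduction targets.

`posterior_trend_probability` simulates group means from the conjugate
posterior of the separate-means common-variance model (Jeffreys prior:
σ² ~ InvGamma((n−a)/2, SSE/2), μ_g ~ N(ȳ_g, σ²/n_g)) and reports the
fraction of draws satisfying the strict observed ordering; ties count as
failures, and the complementary `p_not_trend` is what the trend table
prints. With identical groups every one of the 3! orderings receives
probability 1/6. Analyses are complete-case per variable and unblocked
(no farm random effect) — the trend table records this caveat.

## Dependence screen (`correlation_screen`)

Spearman's ρ uses mid-ranks and the t-approximation for p (scipy).
Hoeffding's D is computed from mid-ranks R, S and the concordance counts
`Q_i = Σ_{j≠i} u(xᵢ−xⱼ)u(yᵢ−yⱼ)` with `u(0) = ½` (half-credit for ties),
combined as `D = 30(A − 2(n−2)B + (n−2)(n−3)C)/(n…(n−4))`; the ×30
scaling puts the maximum at 1. Its p-value comes from a seeded
permutation test with the +1 correction — exact in distribution at desk
scale and free of asymptotic tables. BH adjustment runs separately within
each (texture group × test family); classification is monotonic when
adjusted Spearman p < α, non-monotonic when only the adjusted Hoeffding
p < α, else none. Because |ρ| and D are not on one scale, "strongest"
rankings interleave the two classes by within-class rank rather than by
raw magnitude.

A caution learned from the calibration tests: for a noiseless quadratic
y = x² with randomly drawn x, Spearman's ρ has inflated sampling variance
and its t-approximation flags ~14% of replicates at n = 200, which the
classification rule then calls monotonic. With a sign-symmetric design
the rate drops to nominal. This is a property of the rule itself, not of
the implementation.

## Stability (`stability_bootstrap`)

Dissimilarity–time pairs are restricted to samples of the same texture
from the **same farm** (zero-lag pairs excluded): between-farm
dissimilarity is dominated by the farm effect and would swamp the
temporal signal. Lag is calendar months. Pooled pairs from all farms are
fit by nonlinear least squares to `y = a·exp(b·x)`, initialized from the
log-linear fit of log(y + 10⁻⁶). The bootstrap resamples *samples* (each
keeping its farm identity) with replacement, rebuilds pairs and refits;
replicates with fewer than 3 distinct lags or failed convergence are
redrawn, and more than 20% failures aborts the fit for that group (the
pipeline then skips the group with a warning). The overlap coefficient
integrates min(f̂_a, f̂_b) of Gaussian KDEs (Silverman bandwidth) on a
512-point grid spanning both samples ±4 bandwidths, by the trapezoid
rule. Pairwise OVL for all three textures and the pooled comparison
(no-foam vs crust+foam) are both reported.

## Core communities (`core_community`)

Core membership means presence (count > 0) in at least a prevalence
fraction (default 1.0 — every sample) of a texture's samples, computed on
the post-QC table, per OTU with aggregation afterwards. The Venn
partition reports all exclusive regions; counts sum to the union size.
Differential abundance runs `bf_anova` per rank-aggregated taxon on
relative abundances, with decisive-evidence thresholds of 100 at genus
and 20 at species rank, percentile-bootstrap 95% CIs on per-texture
means, and a "most abundant in" label from the largest group mean.

## Synthetic cohorts (`synthetic_cohort`)

Defaults describe a 46-farm, 13-month study (598 scheduled samples, 5%
missingness ≈ 568 collected). Per farm, texture follows a first-order
Markov chain with persistent states (self-transitions 0.80 / 0.84 / 0.90
for no-foam / crust / foam; stationary shares ≈ 0.24 / 0.29 / 0.47) from
an initial distribution (0.55, 0.08, 0.37) that yields declining no-foam
and rising crust proportions over the study.

Community composition is logistic-normal: softmax of
`base + farm + texture + drift + noise` on the log scale, with base
log-abundances N(0, 1.5), farm effects N(0, 1.2) for 16S and N(0, 2.4)
for *mcrA*, texture signatures N(0, 0.35)/N(0, 0.7), per-sample noise
N(0, 0.5)/N(0, 0.3), and drift a Gaussian random walk whose monthly step
depends on the current texture (no-foam 0.20 > crust 0.10 > foam 0.06):
non-foaming communities are the least stable. These scales were fixed
once so the variance hierarchy matches a farm-blocked field study —
farm ≫ texture, *mcrA* more farm-blocked and more texture-structured than
16S — and so within-farm variation is drift-dominated, which is what
makes the time-decay analysis meaningful.

Counts are multinomial at negative-binomial depths (means 30 000 / 12 000
reads, shape 5), so roughly 5–10% of samples fail depth QC. Two extra
compositional strata make the QC filters non-trivial: a *rare tail*
(1 200 / 240 OTUs at log-abundance ≈ −4) that produces per-sample
singletons and Good's coverage visibly below 1, and *spurious* OTUs
(400 / 80 at ≈ −8.5) whose cohort-wide totals fall under the rare-OTU
filter. Column sums equal the drawn depths exactly.

Diet and chemistry covariates are Gaussian per texture with means
implementing the orderings a foaming study reports (DDGS, NDF, MPR
highest under foam; SBM highest under no-foam; crude protein/fiber, ADF,
temperature and depth highest under crust; SCFA 12.4 / 10.0 / 7.3 and
acetic acid 7.5 / 5.8 / 4.0 mg/g for no-foam / crust / foam; LCFA
strongly enriched in crust at 30 vs 2.0 / 1.4 mg/g; pH 8.2 everywhere)
and coefficients of variation of 0.25 (pH 0.03, MPR 0.35, LCFA 0.40).
Planted correlations are induced on standardized scores per texture —
default: a single monotonic LCFA–SCFA coupling of 0.8 in foam samples
only. Quadratic-shape plants use (z² − 1)/√2, which is uncorrelated with
z but strongly dependent.

**What the generator does not emulate:** sequencing-read-level artifacts
(chimeras, PCR bias), phylogenetic correlation among OTUs, farm-level
diet confounding (covariates are sampled per sample, not per feed mill),
seasonal cycles, or compositional interaction between planted covariate
correlations and community structure. Passing recovery tests therefore
demonstrates that the inference chain detects the planted statistical
structure at realistic sample sizes and noise levels — not that real
manure data satisfy the generative assumptions.

## Problem sizes and determinism

Test-suite simulations use reduced sizes chosen for desk-scale runs:
8-farm cohorts for pipeline smoke tests, 20-farm cohorts for drift
recovery, 99–199 permutations/bootstraps where distributional medians are
the target (medians of a bootstrap distribution stabilize far below 999
replicates), and the full 46 × 13 default cohort for end-to-end recovery
(20 seeds for trend/correlation recovery, 10 for slope ordering). The
acceptance script runs the complete default pipeline with 999
permutations and 999 bootstrap replicates. Every stochastic routine takes
an explicit seed; sub-streams derive from a single `SeedSequence`, so
identical configuration and seed reproduce outputs bit for bit (the run
manifest records SHA-256 of every artifact).

## Known limitations

* PERMANOVA is one-factor with blocks-as-strata; no multi-factor or
  interaction partitions.
* The Hoeffding permutation p-value costs O(n² · n_perm); for very large
  groups reduce `n_perm` or subsample.
* The quadratic environmental surface cannot represent multi-modal
  response shapes a GAM would capture.
* Bayes factors assume normal within-group errors; heavy-tailed
  covariates (LCFA under crust) are tested on the raw scale, not
  log-transformed, matching the trend-table convention.
* The exponential stability fit treats pooled pairs as independent,
  ignoring the dependence among pairs sharing a sample; the bootstrap
  over samples (not pairs) is what restores honest uncertainty.
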