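# pitfoam

Statistical analysis of deep-pit swine manure microbiomes for studies of
manure **foaming** — the hazardous accumulation of methane-trapping foam in
underground manure storage pits. Longitudinal surveys of such pits produce
bacterial 16S rRNA and methanogen *mcrA* OTU count tables plus per-sample
metadata (farm, month, surface texture ∈ {no-foam, crust, foam}, diet and
manure-chemistry variables, methane production rate). `pitfoam` implements
the full inference chain such a study needs, as a tested, reusable library
with a thin CLI, and ships a synthetic cohort generator with known ground
truth so every stage can be validated end to end.

## What it computes

* **QC** (`amplicon_qc`) — remove OTUs with total count < 5; remove samples
  below read-depth/Good's-coverage thresholds (16S: 10 000 reads / 0.97;
  *mcrA*: 4 000 / 0.99); per-sample relative abundance; rank aggregation.
  Good's coverage is `1 − F₁/N` (singleton OTUs over total reads).
* **Community comparison** (`ecology_stats`) — Bray-Curtis dissimilarity
  `d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ)`; one-factor PERMANOVA on squared
  dissimilarities with **restricted permutations within farms** (farms as
  blocks, guarding against pseudoreplication); NMDS minimizing Kruskal
  stress-1 by SMACOF + isotonic regression; quadratic surface fits of
  environmental variables (e.g. methane production rate, MPR) onto the
  ordination.
* **Ordered trends** (`trend_bayes`) — for each diet/manure variable, a
  JZS one-way ANOVA Bayes factor `BF₁₀` (Cauchy prior, scale 0.5, on
  standardized group effects; evaluated by deterministic quadrature) plus
  the posterior probability that the observed ordering of texture means
  (e.g. *foam > crust > no-foam*) fails, from conjugate posterior
  simulation.
* **Dependence screen** (`correlation_screen`) — Spearman's ρ and
  Hoeffding's D per texture group with Benjamini-Hochberg FDR control;
  relationships classified *monotonic* (Spearman significant),
  *non-monotonic* (only Hoeffding significant) or *none*.
* **Stability** (`stability_bootstrap`) — within-farm Bray-Curtis
  dissimilarity vs time lag fit to `y = a·exp(b·x)`; the slope `b`
  (per month) measures community drift. Bootstrap (999×) slope
  distributions per texture are compared with the overlap coefficient
  (OVL) of their kernel density estimates.
* **Core communities** (`core_community`) — taxa present in all (or a
  prevalence fraction of) samples per texture; Venn partition of shared
  and unique members; differential relative abundance by Bayes factor
  (thresholds 100 at genus, 20 at species) with bootstrap 95% CIs.
* **Synthetic cohorts** (`synthetic_cohort`) — logistic-normal
  compositions with farm, texture and random-walk drift effects, Markov
  texture trajectories, negative-binomial sequencing depths, planted
  ordered diet means and a planted foam-only LCFA–SCFA correlation.

## Worked example

```python
import numpy as np
from pitfoam import (CohortConfig, generate_cohort, filter_rare_otus,
                     filter_samples, relative_abundance, bray_curtis,
                     permanova, bootstrap_slopes, overlap_coefficient)

table_16s, table_mcra, metadata, truth = generate_cohort(CohortConfig(seed=1))
table, _ = filter_rare_otus(table_16s)            # drop OTUs with total < 5
table, _ = filter_samples(table, 10_000, 0.97)    # 16S sample QC
meta = metadata.loc[table.sample_ids]
rel = relative_abundance(table)

dm = bray_curtis(rel)
farm = permanova(dm, meta["farm"], n_perm=99, seed=0)
texture = permanova(dm, meta["texture"], strata=meta["farm"], seed=0)
print(f"farm R2={farm.R2:.3f}  texture R2={texture.R2:.3f} p={texture.p_value}")

slopes = {t: bootstrap_slopes(rel, meta, t, n_boot=999, seed=0)
          for t in ("no-foam", "foam")}
ovl = overlap_coefficient(slopes["no-foam"].bootstrap_slopes,
                          slopes["foam"].bootstrap_slopes)
print(f"b(no-foam)={slopes['no-foam'].b_hat:.4f} "
      f"b(foam)={slopes['foam'].b_hat:.4f}  OVL={ovl:.4f}")
```

prints (seed 1):

```
farm R2=0.781  texture R2=0.047 p=0.001
b(no-foam)=0.0201 b(foam)=0.0027  OVL=0.0076
```

Farm identity dominates community variance (R² = 0.78) while texture still
differs significantly under farm-restricted permutations (p = 0.001); the
non-foaming communities drift ~7× faster per month than foaming ones, and
their bootstrap slope distributions barely overlap (OVL < 0.01) — foaming
communities are the more stable ones.

The same chain runs from the shell:

```sh
pitfoam all --seed 1 --outdir run/       # synthetic cohort, every stage
pitfoam ecology --config my_study.yaml   # real tables, one stage
```

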