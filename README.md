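# methtraj

Longitudinal DNA-methylation trajectory analysis for Infinium-style
beta-value data: per-individual slope estimation, blood cell-composition
correction, rapid-gain CpG detection, CpG-density and genomic annotation,
slope-QTL mapping, and density-variance analyses — with a synthetic
cohort generator that provides ground truth for every stage.

## The scientific problem

DNA methylation at individual CpGs changes with age, and those changes
underpin epigenetic clocks and epigenetic drift. Given repeated blood
methylation measurements per person (here: a cohort design of 600
individuals measured at mean ages 69.6, 72.6, 76.3 and 79.3 years),
`methtraj` asks, CpG by CpG: how fast is methylation changing, is the
change real, is it driven by shifting blood cell proportions, does local
DNA sequence — both CpG density and nearby polymorphisms — influence the
rate, and how variable is the rate between people?

The core model fits each CpG *j* and individual *i* separately,

beta_ij = gamma_ij + alpha_ij · age_i,

takes mu_j = mean_i(alpha_ij) as the per-CpG rate of change (beta/year),
and tests it against zero (one-sample t, Bonferroni). A random-intercept
linear mixed model (beta_ij = alpha_j age_i + gamma_i + eps_ij) is fitted
per CpG by a fast profiled REML as the pooled cross-check. Slope-QTLs are
SNPs whose minor-allele dosage predicts alpha_ij (slope ~ G per cis pair
within 1 Mb, BH-corrected, variance-QTL artefacts filtered, linked SNPs
resolved by conditional analysis, hits validated by a pooled
methylation ~ age × genotype interaction model).

The library is organised as scikit-learn-style estimators
(`IndividualTrajectoryFitter`, `MixedTrajectoryFitter`,
`CellCompositionResidualizer`, `ReferenceDeconvolver`,
`RapidGainDetector`, `SlopeQTLMapper`) over plain functions, plus a
`methtraj` CLI for shell use.

## Worked example

```python
import numpy as np
from methtraj import (
    CohortDesign, IndividualTrajectoryFitter, MixedTrajectoryFitter,
    SlopeQTLMapper, simulate_cohort, simulate_truth,
)
from methtraj.trajectory import compare_slope_estimators

rng = np.random.default_rng(1)
truth = simulate_truth(n_cpgs=500, n_snps=800, n_qtls=40,
                       qtl_effect_range=(0.004, 0.01), seed=rng)
cohort = simulate_cohort(CohortDesign(), truth, seed=rng)

fit = IndividualTrajectoryFitter(age_ref=70.0).fit(cohort.betas)
print(fit.summary_["significant"].sum(), "significant CpGs")

mixed = MixedTrajectoryFitter().fit(cohort.betas)
print(compare_slope_estimators(fit.summary_, mixed.fits_))

mapper = SlopeQTLMapper().fit(fit.trajectories_, cohort.genotypes,
                              truth.cpgs[["chrom", "pos"]])
print(len(mapper.qtls_), "significant pairs,",
      int(mapper.independent_["lead"].sum()), "lead SNPs")
```

Output:

```
442 significant CpGs
{'pearson_r': 0.9998825966704924, 'p': 0.0, 'n_cpgs': 500}
42 significant pairs, 41 lead SNPs
```

442 of 500 CpGs have a mean slope distinguishable from zero at
Bonferroni-corrected p < 0.01 under the default simulation (most CpGs are
given small nonzero true slopes). The per-individual mean slopes and the
mixed-model fixed slopes agree at Pearson r = 0.9999 — the two estimators
are interchangeable on this design. The QTL scan declares 42 significant
SNP–CpG pairs, covering all 40 designated causal pairs; conditional
analysis resolves them to 41 independent lead associations (one CpG picks
up a second, chance-associated SNP).

The full pipeline can also be driven from a YAML config:

```sh
methtraj run --config run.yaml     # simulate → fit → rapidgain → annotate → qtl → variance
methtraj fit --betas B.tsv --samples S.csv --min-points 3 --out out/
```

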