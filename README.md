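# mmtraj — longitudinal multimorbidity-pattern trajectories

`mmtraj` is a tested, reusable pipeline for studying how multimorbidity
patterns (MP) evolve in elderly primary-care populations and how they relate
to organ function. It targets epidemiologists and biostatisticians working
with long-format electronic-health-record extracts — one row per patient per
year, carrying chronic-disease indicators, annual drug-package counts per
ATC level-4 code, a small lab panel (serum creatinine, ALP, ALT, GGT) and
vital status. Because such registries cannot be redistributed, the package
ships a synthetic-cohort generator with the same statistical structure, so
every stage is testable end to end without any data access.

## What it computes

**Phenotypes.** Multimorbidity is the presence of ≥2 chronic diseases out of
60 chronic-disease groups; a drug is in *chronic use* in a year when ≥3
packages were dispensed; polypharmacy is concurrent chronic use of ≥5 drugs.
Kidney function uses the IDMS-calibrated 4-variable MDRD equation,

    eGFR = 175 · creatinine^(−1.154) · age^(−0.203) · (0.742 if female),

flagged abnormal when any post-baseline eGFR < 60 ml/min/1.73 m². Liver
function is abnormal when any post-baseline panel has ALP > 2×129 IU/L,
ALT > 5×41 IU/L (men) / 5×33 IU/L (women), or GGT > 61 IU/L.

**Trajectory clustering.** Mixed phenotype data (binary disease flags + sex
as qualitative, age as quantitative) are reduced by PCAmix — a generalized
SVD blending PCA for quantitative and multiple correspondence analysis for
qualitative variables — fitted at baseline and projected onto later waves.
Patient trajectories in factor-score space follow a hidden Markov model with
K living pattern states and two *observed* absorbing states (death,
drop-out). Living states emit diagonal-covariance Gaussians; parameters are
estimated by Baum–Welch from fuzzy c-means initialisations over seeded
restarts, the number of states is selected by BIC (or held-out likelihood),
and each patient's best trajectory is decoded by the Viterbi algorithm
alongside fuzzy posterior memberships.

**Pattern profiles.** Each cluster × year is characterised by disease
prevalence and mean drug packages, with

    O/E ratio  = statistic in cluster / statistic in overall population
    exclusivity = cluster's share of all cases (or of all packages)

An item belongs to a pattern when O/E ≥ 2; drugs carry a secondary flag when
exclusivity strictly exceeds the cluster's population share. Size-weighted
mean O/E is identically 1 and exclusivities partition to 1, which the tests
enforce on every profile table.

**Association.** One analysis row per patient — baseline decoded cluster,
post-baseline kidney/liver abnormality, age, sex, deprivation quintile
(MEDEA, ~7% missing), baseline total packages. The deprivation quintile is
multiply imputed (m = 7) with a proportional-odds model inside a
chained-equations sweep; per-imputation logistic regressions (reference =
largest cluster) are pooled with Rubin's rules, T = W̄ + (1 + 1/m)B, and
95% CIs reported on the odds-ratio scale.

## Worked example

```python
from mmtraj import pipeline

cfg = pipeline.PipelineConfig(scenario="paperlike", n_patients=5000,
                              seed=1, d=10, restarts=3,
                              outdir="run_paperlike")
arts = pipeline.run_all(cfg)
print(arts["descriptives"].head(4))
print(arts["effects"]["kidney"])
```

The `paperlike` scenario draws 5000 patients aged 65–99 over 5 annual waves
from 10 latent clusters (plus absorbing death/drop-out), with six signature
diseases per cluster, cluster-specific drug-package means, and one cluster
each with shifted creatinine ("renal") and liver-enzyme ("hepatic")
distributions. The run above prints baseline descriptives per decoded
cluster:

| cluster |    n | share_pct | female_pct | multimorbid_pct | polypharmacy_pct | age_median_iqr   |
|--------:|-----:|----------:|-----------:|----------------:|-----------------:|:-----------------|
|       9 | 1933 |     38.7  |      57.4  |            99.5 |             56.4 | 74.1 [70.0;79.2] |
|       7 |  922 |     18.4  |      58.7  |            99.8 |             57.6 | 73.9 [70.1;79.0] |
|       3 |  634 |     12.7  |      57.4  |            99.8 |             56.6 | 74.2 [70.3;78.8] |
|       4 |  454 |      9.1  |      55.7  |           100.0 |             57.5 | 73.4 [70.2;78.4] |

and the pooled kidney odds ratios (reference = largest cluster), where the
decoded cluster absorbing the planted renal population stands out:

| term      |   OR | ci_low | ci_high |
|:----------|-----:|-------:|--------:|
| cluster_3 | 4.59 |   3.70 |    5.69 |
| cluster_0 | 0.83 |   0.55 |    1.24 |
| cluster_7 | 0.84 |   0.69 |    1.03 |
| …         |      |        |         |

`run_paperlike/` then holds every stage artifact (cohort, phenotypes, factor
scores, HMM JSON, trajectories, profiles, OR tables), a Markdown report with
per-cluster profile sections, and a manifest with the seed and config hash.
The same stages are available from the shell:

```bash
mmtraj simulate --scenario paperlike --n 5000 --seed 42 --out cohort.csv
mmtraj phenotype --in cohort.csv --out pheno.csv
mmtraj run-all --scenario tiny --seed 0 --outdir run_tiny
```

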