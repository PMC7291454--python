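# Methods

This note documents the models, conventions and numerical choices behind
`mmtraj`, and what its simulation-based tests do and do not establish.

## Synthetic cohort generator

The generator emulates a closed elderly primary-care cohort: no new entries,
attrition only by death or transfer out ("drop-out"), both recorded as
distinct absorbing states. Each patient carries a latent cluster label that
evolves as a first-order Markov chain over K living states plus the two
absorbing states; the baseline label is drawn from a configured initial
distribution over living states only, so nobody can be dead at baseline.
One row is emitted per patient per wave up to and including the event wave;
the event row carries demographics and carried-forward disease flags but no
drug or lab draws.

Conditional on the cluster at a wave:

* **Disease flags** are Bernoulli with cluster-specific prevalence, then made
  persistent by a running maximum — the disease groups modelled are chronic,
  so a flag never reverts. This persistence rule is a simulator convention;
  it is what makes multimorbidity accumulate over follow-up.
* **Drug packages** are negative binomial (gamma–Poisson) with
  cluster-specific mean and dispersion 1.0 by default. Overdispersion is
  deliberate: Poisson counts would make downstream recovery tests
  unrealistically easy.
* **Labs** (creatinine mg/dL; ALP/ALT/GGT IU/L) are log-normal per cluster.
* **Visits** are Poisson with a cluster-specific mean.

Demographics: age at baseline is 65 + 34·Beta(1.5, 3.5) (mean ≈ 75 years,
right-tailed, fixed over follow-up); sex is Bernoulli with P(female)=0.578;
the deprivation quintile (MEDEA: rural plus five urban quintiles) is drawn
once per patient from fixed margins and set missing completely at random
with probability 0.07 — the missingness rate a deprivation index typically
shows in these registries and the rate the imputation stage is designed
around.

The `paperlike` scenario uses K=10 clusters with baseline shares from 42%
down to 1.7%, 60 disease groups (six signature diseases per cluster with
prevalence 0.65 against a 0.04 background, so every planted signature has
O/E ≥ 2 by construction even in the largest cluster), 40 ATC level-4 drug
codes (ten population-wide staples with mean 2 packages; three signature
drugs per cluster with mean 5 against a 0.2 background), per-cluster death
hazards between 0.015 and 0.08 per wave and a uniform 0.015 drop-out hazard
with self-stay 0.86, and two planted organ-effect clusters: a *renal*
cluster with median creatinine 1.25 versus 0.75 elsewhere and a *hepatic*
cluster with shifted GGT/ALP/ALT medians. `tiny` (K=3, 6 diseases, 4 drugs,
n=200) is for fast smoke tests; `null` removes all cluster structure.

What the generator does **not** emulate: real disease co-occurrence beyond
block structure, age- or sex-dependent prevalences and hazards, informative
(non-MCAR) deprivation missingness, measurement error in labs, or seasonal
dispensing. Passing recovery tests therefore show the pipeline is correct
and well-calibrated under its own assumptions, not that a real registry
would yield clusters of this clarity.

## Phenotyping

All thresholds are strict or inclusive exactly as defined: multimorbidity
≥2 diseases; chronic drug use ≥3 packages/year per drug; polypharmacy ≥5
chronic drugs; abnormal kidney function when any post-baseline eGFR is
strictly < 60 ml/min/1.73 m²; abnormal liver function when any post-baseline
panel is strictly above ALP 258, ALT 205 (men)/165 (women) or GGT 61 IU/L.
"Post-baseline" means waves 1 and later; baseline labs never trigger the
patient-level flags. Sex is time-invariant, so the sex-specific ALT limit
uses baseline sex. The MDRD ethnicity coefficient (1.212) is not applied —
the target cohorts do not record ethnicity — but is exported as a constant
for callers who need it. A patient lost before wave 1 has no post-baseline
series; the flags default to 0 with a logged warning.

## PCAmix

Quantitative columns are standardized with population SD; each qualitative
variable is indicator-coded, centred by category frequency p_s and weighted
by 1/√p_s. The SVD of the combined matrix divided by √n yields eigenvalues
summing to p_quant + (Σ categories − p_qual). With only quantitative input
the scores coincide with PCA of the standardized matrix; with only
qualitative input the eigenvalues equal p_qual times the correspondence-
analysis principal inertias of the indicator matrix — the scaling consistent
with the total-inertia convention above. Component signs are fixed by making
the largest-magnitude loading positive, so repeated runs are reproducible.

The model is fitted on the **baseline wave only** and later waves are
projected onto the baseline axes. Fitting per wave would give each wave its
own coordinate system and break the HMM's common emission space. The default
clustering input is disease flags + age + sex; drug counts can be added with
a switch (`cluster_features="diseases+drugs"`). The retained dimension d
defaults to the smallest d with cumulative inertia ≥ 80%; the paperlike
pipeline runs use d=10, which captures the ten planted cluster contrasts.
A category unseen at fit time projects with zero weight and a logged
warning.

## Hidden Markov model

States: K living clusters plus observed death and drop-out. "Observed"
means their emission likelihood is a point mass on the recorded event and
their transition rows are frozen to the identity — occupancy of these
states is recorded in the data, not inferred, and no emission parameters
are estimated for them. Living states emit Gaussians with diagonal
covariance on the d factor scores; diagonal keeps the parameter count
identifiable with only five waves (a full-covariance switch is a natural
extension but is not implemented).

Estimation is Baum–Welch in log space. Initial responsibilities come from
fuzzy c-means (fuzzifier m=2) on baseline scores; initial transition rows
use self-stay 0.7 of the non-event mass and empirical event hazards.
Numerical conventions: covariance floor 1e-6 (applied with a warning),
relative log-likelihood convergence tolerance 1e-6, max 500 iterations,
10 restarts by default with ties broken toward the lowest restart seed.
The log-likelihood trace is monotone up to 1e-9 relative tolerance and the
tests assert this on every fitted instance. Degenerate inputs: a state
receiving no posterior mass keeps its previous parameters; an all-−inf
forward column raises with the patient index.

Model selection fits each candidate K from seeded restarts and scores by
BIC with parameter count (K−1) + K(K+1) + 2Kd over the total number of
patient-rows; a held-out criterion (mean per-row log-likelihood on a seeded
20% patient split) is available. Viterbi decoding provides the hard cluster
assignment used for profiling; the posterior (gamma) memberships are kept
alongside for fuzzy-weighted analyses.

Test problem sizes were chosen to keep each simulation study informative at
desk scale: transition recovery uses 3 well-separated states, n=2000, T=5,
10 restarts, 20 replicate cohorts; selection uses candidates {2,3,4,5} with
3 restarts; the end-to-end direction study uses 20 paperlike replicates of
n=5000 with 2 restarts and max 150 EM iterations, which already achieves
~85% baseline label accuracy.

## Profiles

The overall ("expected") population at a wave is the alive, decoded
patients at that wave — the death and drop-out clusters are excluded from
both numerator and denominator (switchable with `include_absorbed=True`;
whether deceased patients belong in the denominator within a calendar year
is genuinely ambiguous, and this choice is the conservative one). Drug
means are over **all** cluster members including non-users. Hard Viterbi
assignments are used; membership is O/E ≥ 2 (inclusive), and the secondary
drug flag requires exclusivity strictly greater than the cluster's
population share. Items with zero overall count are emitted as missing with
a warning. Two invariants hold by construction and are enforced by tests on
every profile table: the cluster-size-weighted mean O/E equals 1 (±1e-9)
and exclusivities sum to 1 across clusters.

## Association

One row per patient; baseline cluster from the Viterbi state at wave 0.
The reference category defaults to the largest baseline cluster — the
analogue of a dominant non-specific pattern — because decoded labels carry
no intrinsic order. Baseline clusters with fewer than 30 members are
excluded with a warning: a near-empty pattern cannot support a stable
cluster-level OR and only induces separation in the logit.

Imputation: the deprivation quintile is the only incomplete variable, so
the chained-equations sweep is idempotent — the conditional model (a
proportional-odds ordinal logit of MEDEA on age, sex, both outcomes,
baseline total packages and cluster dummies, fit on observed rows with
standardized predictors) is estimated once and m=7 completed datasets are
drawn from its fitted category probabilities, fully seeded. If the ordinal
fit fails, predictive-mean matching on the integer coding is the fallback.

Analysis model: maximum-likelihood logit of each outcome on cluster dummies
+ age + sex + MEDEA (quintile dummies by default; ordinal coding available)
+ baseline total packages. Zero-variance covariates are dropped with a
warning. Newton failures are retried with BFGS; if the optimizer stops with
an essentially zero score (quasi-separation, boundary estimate) the fit is
accepted with a warning, while genuine non-convergence raises. Pooling
follows Rubin's rules with Barnard–Rubin degrees of freedom at a
configurable complete-data df (default infinite, appropriate for the
large-sample logit; this reduces to the classic Rubin df and makes the
zero-between-variance case collapse exactly to the single-fit normal CI).
α = 0.05 two-sided, no multiple-testing correction — per-cluster CIs are
reported as-is.

## Known limitations

* The emission family (diagonal Gaussian) and the baseline-anchored factor
  space are modelling choices the data cannot fully validate at T=5.
* Viterbi hard assignments understate membership uncertainty; the gamma
  columns should be consulted when clusters overlap.
* The association stage estimates adjusted ORs, not causal effects, and
  ignores the competing risk of death — attrition enters only through the
  absorbing states of the trajectory model.
* With a single incomplete covariate, multiple imputation mainly propagates
  category uncertainty; it cannot correct non-MCAR missingness.
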