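# Methods

This note documents the statistical models implemented in `longevipept`,
the design choices made where the design was genuinely open, what the
synthetic cohort generator does and does not emulate, and the numerical
details that matter for reproducing its behaviour.

## 1. Study design being modelled

The pipeline targets a nested case–control longevity design: a cohort of
older men (baseline ages 73–84, six clinical sites) followed ~12 years,
with the binary outcome `alive90th` — reaching the 90th percentile of
expected age for one's birth cohort — and baseline serum proteomics
(label-free LC-IMS-MS; log10 peptide abundances with peptide→protein
mapping, pooled-QC technical replicates, and abundance-dependent
missingness). Covariates are baseline age, the population (life-table)
cumulative hazard at that age (to absorb birth-cohort differences in
hazard at the same age), clinical site, and a per-cell indicator for
upstream-imputed abundances. Survival follow-up (time, vital status) and
four health indices (self-rated health, SF-12 physical component, Healthy
Aging Index, Fried frailty) complete the phenotype table.

## 2. Synthetic cohort generator

Every downstream stage is exercised against simulated cohorts with known
truth. The generating model:

* **Latent factor.** Each participant carries `f ~ N(0,1)`, interpreted as
  a systemic-inflammation axis. It drives the longevity label
  (`logit P(alive90th) = a0 + a1 f`, `a1 = -0.5`), the mortality hazard
  (exponential survival with log-hazard Gompertz in age plus
  `survival_link = 0.35` per unit `f`, censored at 15 years), and the four
  health indices (Gaussian-copula components with Pearson loadings chosen
  so the latent↔index Spearman correlations hit the configured targets,
  defaults 0.15–0.23 in magnitude).
* **Proteins.** 224 proteins: 25 signal proteins in 5 correlation blocks
  (sizes 8/6/5/4/2) plus 199 null proteins in 7 blocks. Marginal
  biological SD is 0.13 log10 (~35% CV, typical for serum proteins);
  within-block correlation targets 0.6 (observed cluster correlations in
  such panels span ~0.33–0.89); signal proteins additionally load on `f`
  with a 25% variance share, which produces the coherent high/low
  abundance stripes seen in cohort heatmaps and couples the proteome to
  survival and health. Signal proteins also carry a small age trend
  (+0.004 log10/yr).
* **Planted effects.** The default 25 signal effects are the published
  tier-1 fold changes (−1.101 … −1.217, i.e. log10 magnitudes
  0.0418–0.0853) with the published per-protein peptide counts (3–58).
  Because the label is driven by `f` and signal proteins load on `f`, the
  direct label coefficient is adjusted by the *realized* label-group
  difference in `f`, making the total planted group difference exact in
  each simulated cohort (not merely in expectation). Without this, all 25
  signal proteins share a single `λ·(f̄₁−f̄₀)` sampling error that swings
  whole-cohort selection sensitivity.
* **Peptides.** Peptide abundance = protein abundance + a peptide
  intercept (protein base level N(0, 0.5) plus Uniform(−1.5, 1.5), giving
  a realistic multi-log dynamic range) + biological peptide noise
  (SD 0.15) + technical noise (CV 20% on the natural scale). Peptides of a
  protein also differ in their *group effects*: a centred (sum-to-zero
  within protein) heterogeneity term with SD 0.05 log10 models
  digestion/ionisation differences between peptides of one protein. This
  value is what the published per-protein posterior summaries imply for
  the between-peptide spread (e.g. a 7-peptide protein with effect 0.0457
  and sign-error probability 0.0078 implies posterior SD ≈ 0.019, hence
  τ ≈ 0.05); with no heterogeneity at all, the heterogeneity prior
  dominates the posterior for few-peptide proteins, which matches neither
  real data nor the published summaries. Centring preserves exact
  protein-level truth.
* **QC pools.** 102 replicate rows per peptide carrying the peptide
  intercept plus technical noise only.
* **Missingness.** Cell (i, j) is retained with probability
  `Φ(a + b_w (y_ij − mean_j) + b_b (mean_j − grand mean) + c q_i)` with
  defaults a = 1.2, within-peptide slope b_w = 0.6 (MNAR: a peptide's low
  values drop out preferentially), between-peptide slope b_b = 0.25
  (low-abundance peptides are missing more often: peptide-specific
  detection limits), and a per-participant sample-quality factor
  `q_i ~ N(0,1)` scaled by c = 0.8 (injection/column variability). The
  overall missing fraction is ~18%; the study's actual missingness rate is
  not published and is a free parameter. QC rows are never masked, and a
  peptide never loses its last observation.
* **Determinism.** All stages draw from named sub-streams of one seed;
  identical configurations are byte-identical.

**What the generator does not emulate:** raw spectra, retention/drift-time
structure, depletion chemistry, shared/degenerate peptides mapping to
multiple proteins, batch drift over run order, non-Gaussian abundance
tails, and competing causes of death. Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed generating
model, not robustness to these real-data features.

## 3. Peptide-level association model and selection correction

Per peptide, OLS of observed log10 abundance on intercept, `alive90th`,
age, cumulative hazard, site indicators and the imputed-cell indicator;
`antilog10(β₁)` is the fold difference. Peptides need ≥20 observed values
and both label groups; rank-deficient designs drop aliased columns; a
constant peptide returns β₁ = 0, SE = 0, non-converged.

**Heckman two-step.** Detection of a peptide value depends on the value
itself, biasing naive fits. Step 1 is a probit of the detection indicator
on the outcome covariates plus one exclusion variable; step 2 adds the
inverse Mills ratio λ(η̂) to the outcome regression, with the standard
two-step covariance (Greene's formulation, selection-probit uncertainty
propagated; ρ̂² clamped to [0, 1]). Peptides ≥99% observed are returned
uncorrected; probit failures fall back to the uncorrected fit flagged
non-converged.

*Choice of exclusion variable.* The default instrument is the
participant's **detection propensity**: the probit of their observed
fraction over peptides of *other* proteins. It captures sample-level
detection quality (which shifts every peptide's selection probability) and
is exogenous to the target peptide's outcome error. The often-suggested
alternative — the participant's mean abundance over the same protein's
other peptides — is retained as `instrument="protein_block_mean"`, but it
is essentially the protein-level component of the outcome error
(correlation ≈ 0.6 in this generating model), and simulation shows
two-step corrections built on it *inflate* error several-fold rather than
reduce it; it is not recommended.

*Normalization interaction.* Median per-sample offsets absorb
(signal fraction) × (effect size) of any genuine one-directional group
difference — with ~10% of peptides lower in the long-lived group, each
long-lived sample's median offset shifts by ≈ −0.006, attenuating every
β₁ by the same amount. Since sample handling and run order cannot depend
on future longevity, the pipeline equalises the label-group means of the
estimated offsets before subtracting them.

## 4. Peptide→protein meta-analysis

Model: `y_i ~ N(θ_i, s_i²)` with `s_i` the peptide SE treated as known,
`θ_i ~ N(μ, τ²)`, `μ ~ N(0, 1)` (log10 scale), and an IG(1/100, 1/100)
prior on the between-peptide heterogeneity. Gibbs sampling with burn-in
2500 and `round(10000 × max(1, log10 k))` samples; convergence is checked
by a Geweke z-score on the μ chain (|z| < 2, batch-means variances) plus
an effective-sample-size floor of 1000, with chain doubling up to 3 times
on failure. The meta-p is `min(P(μ>0), P(μ<0))` with exact zeros split.
Credible bounds are central 2.5/97.5% quantiles.

*Scale of the heterogeneity prior.* The IG(1/100, 1/100) prior is placed
on the between-peptide **SD** τ by default (`MetaPriors.var_prior_on`).
Placed literally on the variance τ², the prior's density vanishes below
τ² ≈ 0.002 and decays only as τ²^(−1.01) above, so for proteins with 3–4
peptides the posterior for μ inherits a heavy scale mixture regardless of
how concordant the peptides are: 2-D quadrature shows the sign-error
probability is then bounded near ~0.15 for a 3-peptide protein with
effect −0.08 — a regime in which published small-peptide-count selections
at meta-p 0.05–0.10 could not occur. On the SD scale the same shape/scale
constants let the heterogeneity posterior track the observed spread and
vanish when peptides agree, reproducing the reported behaviour. The τ
update is a Metropolis random-walk step on log τ inside the Gibbs sweep
(step 0.6, jointly with conjugate θ and μ updates); the conjugate
variance-scale version remains available.

A batched engine runs all proteins' chains simultaneously on padded
arrays; replicate-grade chains (burn-in 500, 2000 samples, no extension)
are used inside the jackknife, where only replicate medians are consumed —
on identical data they reproduce full-length summaries to within ~0.001.

## 5. Stability selection

200 (configurable) delete-half jackknife replicates: each drops a
uniformly random half of participants, stratified by label, drawn without
replacement within replicate (replicates independent; a with-replacement
variant is a flag). Each replicate re-runs the peptide fits and
meta-analysis; per protein the replicate **median** meta-effect and meta-p
("bootstrap" summaries) and the 2.5–97.5% replicate band are recorded;
a protein is *stable* when its full-cohort estimate lies inside the band.
Tier 1: bootstrap meta-p < 0.1 and |bootstrap effect| ≥ 0.041. Tier 2:
|fold| > 1.05, meta-p < 0.2, and rank ≤ ⌈n/3⌉ under the empirical-Bayes
ranking (posterior expected rank of |μ| across proteins, ties broken by
meta-p then id), excluding tier-1 members.

## 6. Protein abundance, clustering, scores

**Crossed random effects.** Per protein, `y = β₀ + a_participant +
c_peptide + ε` on observed cells. Variance components come from a
method-of-moments decomposition (peptide means → participant means of
peptide-centred values → residuals); the participant block of Henderson's
mixed-model equations is diagonal, so BLUPs are solved exactly by a Schur
complement onto the (small) peptide block. A participant's protein level
is β₀ + their BLUP; participants with no observed peptide receive β₀. A
boundary participant-variance estimate falls back to participant means of
peptide-centred values with a warning. The intercept/peptide-mean split is
not identifiable, so estimates are defined up to a common constant — which
every consumer (standardization, Cox, clustering) is invariant to.

**Clustering.** Protein columns are standardized; Gower dissimilarity
between protein profiles treats each participant as a continuous variable
(mean range-normalised absolute difference — equal to Manhattan distance
on range-scaled columns divided by the variable count); Ward linkage
(squared-update convention, a pragmatic heuristic on non-Euclidean
distances); Duda–Hart stopping scanning k upward, accepting a split while
its Je(2)/Je(1) ratio falls below the critical value. Because protein
clustering has few points (proteins) in many dimensions (participants),
the classical critical value is replaced by a Monte-Carlo null: the best
Ward bisection of iid Gaussian clouds of the same size and dimension,
with critical = null mean − 3.2 × null SD. Ties resolve toward fewer
clusters; constant columns are dropped with a warning.

**Scores.** z-score per protein, sum over the protein set, z-score of the
sum; cluster subscores are means of member z-scores. Health associations
are Spearman correlations with p-values; constant indices are reported
missing.

## 7. Classification

Backward elimination on the between-group Mahalanobis distance (pooled
within-group covariance, ridge fallback for singularity): repeatedly drop
the protein whose removal least reduces the separation while staying
within 2% (configurable) of the full-set separation, with a hard cap
(default 14) for the 2^k model enumeration. All nonempty subsets of the
reduced set are fitted by maximum-likelihood logistic regression
(age-adjusted, features standardized on training data), weighted by
`exp(−ΔBIC/2)` under a uniform model prior (failed/separated fits get
weight zero), and averaged. AUC uses the midrank Mann–Whitney estimator
with a DeLong variance band; cross-validated AUC pools out-of-fold
predictions over stratified folds (default 5). In-sample AUC is reported
to mirror common practice; the cross-validated value is the honest one.

## 8. Survival and death proximity

**Hazard ratios.** Cox partial likelihood (lifelines) of standardized
protein abundance with a 3-knot restricted cubic spline in baseline age;
reported as HR per 1 SD with Wald 95% CI. Requires ≥20 deaths and
non-degenerate abundance. The spline-in-age Cox reading of
"semiparametric time-to-event model using cubic splines" is the default;
fits are run at tight convergence tolerances so they agree with a
textbook Newton partial-likelihood implementation to ≤1e-6.

**Tertile curves.** Top/bottom abundance tertile indicators (middle as
reference) interacted with the centred age-spline basis; HR(age) with
delta-method bands on an age grid; grid points in age bins where a
tertile is empty are reported missing.

**Death proximity.** Staged structural model: (1) a one-factor
maximum-likelihood measurement model (sklearn FactorAnalysis; sign
aligned to positive mean loading; Heywood cases clamped with a warning;
single-protein sets reduce to the standardized protein); (2) 2SLS of the
factor score on baseline age and time to death, instrumenting time to
death with SF-12 PCS and the population cumulative hazard (first-stage F
< 10 flags weak instruments); (3) model-predicted scores at the mean age
smoothed along time to death by Epanechnikov-kernel local-linear
regression (bandwidth: Silverman-type rule widened ×3 for regression use;
infinite bandwidth reduces exactly to the OLS line), with the slope
reported as the mean of the local derivatives. Censored participants are
excluded by default (the axis is time to actual death); an option enters
them at the follow-up horizon. Staged estimation (factor, then 2SLS) is
used instead of joint ML for transparency and testability.

## 9. Problem sizes used by the benchmark suite

The benchmark experiments run at the study's own scale: 1196 participants,
224 proteins, ~3700 peptides, with a 50-replicate delete-half jackknife
(the 200-replicate default is a configuration flag; replicate medians
stabilise well before 50). The Heckman head-to-head uses 100 replicate
cohorts of 1200 participants with a 12-peptide target protein under
strong within-peptide MNAR (probit slope 3/log10, ~35% missing, quality
SD 1.2, peptide noise 0.35, protein SD 0.03 — chosen so selection bias
dominates sampling noise and the estimator contrast is identifiable);
hazard recovery uses 50 cohorts of 2473; death proximity uses 1200
decedents. These sizes are the package's benchmark conditions and are
reproduced verbatim by `scripts/acceptance.py`.

## 10. Known limitations

* The Heckman correction assumes a probit selection mechanism and a valid
  exclusion variable; with selection driven purely by the peptide's own
  value and no sample-quality variation, no observable instrument exists
  and the correction cannot help.
* The meta-analysis treats peptide estimates of one protein as
  conditionally independent given θ; in truth they share the protein-level
  sampling error, so full-cohort posterior spreads understate
  cohort-to-cohort variability — which is exactly why selection is based
  on the delete-half jackknife summaries.
* Planted effects equal to the published fold changes place several true
  effects exactly at the |fold| ≥ 1.1 selection boundary; those proteins
  are irreducibly borderline (≈50% selection probability each), so tier-1
  sensitivity against planted truth plateaus around 80–90% at this cohort
  size no matter the estimator.
* Ward on Gower distances and the Monte-Carlo Duda–Hart rule are
  pragmatic heuristics; cluster counts on weakly structured data should
  not be over-interpreted.
* The 2SLS death-proximity model identifies a *linear* proximity effect;
  the kernel smooth visualises, but does not test, non-linearity.
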