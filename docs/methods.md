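# Methods

This note documents the models, conventions, and design choices behind
`htnprs`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
details that affect reproducibility.

## Summary-statistics harmonization

Input records carry chromosome, 1-based position, effect/other allele,
effect size (mmHg per allele for SBP/DBP, log-OR for HTN), standard error,
p-value, and optionally effect-allele frequency and sample size. Quality
control keeps variants whose minor allele frequency is ≥ 0.01 (default) in
**both** the discovery GWAS and the target cohort; a record without a
discovery frequency passes the discovery-side filter with a log entry.
Allele harmonization tries, in order: exact match; swapped alleles (negate
β, mirror frequency); strand complement; complement-plus-swap. Palindromic
A/T and C/G variants are dropped outright — frequency-based strand
disambiguation is deliberately avoided so harmonization is deterministic —
and duplicate variant keys keep the smallest-p record. Harmonization is
idempotent, and a per-category count report is produced.

## Clump-and-threshold scores

Clumping is greedy: repeatedly take the smallest-p unclaimed variant as an
index and remove all unclaimed same-chromosome variants within the window
whose dosage r² with the index exceeds the cutoff. Conventions chosen here:

* p ties break by (chromosome, position), so results are
  platform-independent;
* the window is index-to-candidate distance in kb, inclusive;
* the removal condition is strictly r² > r²_max;
* r² is the squared Pearson correlation of dosages over pairwise-complete
  samples (the PLINK convention); a monomorphic variant has r² ≡ 0;
* the LD reference panel is the full combined cohort.

Clumping is performed once per (r², window) pair on all harmonized variants
and p-thresholds are applied to the clumped set afterwards — the PRSice
convention — so the 108-cell default grid costs nine clumping passes. An
equivalent family-shared scorer (`score_grid`) exploits the nestedness of
the per-threshold weight sets; it is verified against the direct scorer.

Scoring sums weight × dosage with missing dosages imputed as 2 × the
cohort effect-allele frequency (the standard scoring convention; the choice
matters little at the simulated missingness of zero). Scores are
standardized with a *pre-computed* mean and SD — by convention the full
combined cohort — so per-SD effect sizes are comparable across analysis
subsets and groups; per-group SDs are available as a secondary scaling, and
the per-SD log-OR under the two scalings differs exactly by the SD ratio.

## Tuning-parameter selection

The CV criterion splits the training samples into K = 5 equal-sized folds
with kinship components assigned whole (largest first, each to the
currently smallest fold; ties in component size follow a seeded shuffle, so
the split is reproducible and no related pair spans folds). Per candidate,
the hypertension association model is fitted in each fold with the same
covariates as the main model (degenerate factor levels are dropped per
fold with a log entry); the criterion is sd/mean of the K log-ORs with the
n−1 sd. A candidate whose mean fold effect is ≤ 0 or whose fold fit fails
is disqualified (CV = +∞): a score anti-associated with its own trait is
never the intended selection. Exact ties break by smaller p-threshold, then
smaller r², larger window, fewer SNPs. The PVAL criterion minimizes the
full-sample Wald p with the same tie chain; the genome-wide-significant
score uses fixed parameters (5·10⁻⁸, r² 0.1, 1000 kb) and no selection.

**Known limitation — selection noise at small training sizes.** With K = 5
the sd in the CV numerator is a 4-df estimate whose relative sampling error
is ≈ 48%. At ~2,000 training samples (fold n ≈ 400) the per-fold log-OR
standard error (~0.11) dominates fold-to-fold dispersion, so CV differences
between similar candidates sit inside the estimator's own noise, and the
argmin over 108 correlated candidates scatters several grid steps around
the mean-CV optimum — occasionally escaping into heavily diluted
high-threshold candidates whose five fold estimates happen to be
hyper-uniform. The replicate-average CV curve is minimized at the same
p-threshold that maximizes held-out AUC (verified in simulation), but
single-replicate agreement within one grid step occurs in roughly half of
replicates at this size, not the large majority; training cohorts an order
of magnitude larger (as in the intended application) shrink the per-fold
standard error accordingly. The selection-recovery experiment reports this
agreement fraction honestly rather than at a size where it is trivial.

## PRSsum

The combined hypertension score is the unweighted sum of the three
full-cohort-standardized trait scores, re-standardized with its own
full-cohort constants. Summation is order-invariant; mismatched sample sets
are an error. No adaptive weighting is implemented.

## Blood-pressure phenotyping

Per-visit categories with explicit precedence HYPERTENSION > ELEVATED >
NORMAL: hypertension if SBP ≥ 130 mmHg, or DBP ≥ 80 mmHg, or self-reported
physician diagnosis, or antihypertensive treatment; otherwise elevated if
120 ≤ SBP ≤ 129; otherwise normal. The boundary values SBP = 120 and
DBP = 80 are genuinely ambiguous in the prose definitions of the ACC/AHA
2017 staging; the precedence rule resolves them as DBP = 80 → hypertension
and SBP = 120 (DBP < 80, untreated) → elevated, and an exhaustive sweep of
the integer lattice pins the truth table in the tests.

Two-visit longitudinal categories: hypertension at both exams; worsened
(category rank increased); improved (rank decreased **and** untreated at
both exams — treated individuals are never "improved"); never hypertensive
(unchanged non-hypertensive rank). A treated or diagnosed first visit
followed by an untreated non-hypertensive second visit has a rank decrease
but is barred from "improved"; forcing it into any other category would
misstate it, so such records are flagged UNCLASSIFIED and excluded from
tabulations. The four categories plus UNCLASSIFIED partition all pairs.

Incident cohorts condition on the baseline category (normal or elevated),
define the outcome as follow-up hypertension, and carry time-between-exams
as a covariate.

## Association models

The primary fit is maximum-likelihood logistic regression (statsmodels GLM)
of hypertension on the standardized PRS plus sex, age, age², BMI, current
smoking, study site, background label, and ancestry PCs; inference on the
PRS coefficient is a Wald test. Missing covariates are handled by listwise
deletion with counts logged; constant design columns (degenerate factor
levels) are dropped with a log entry; separation raises an explicit error
suggesting penalization.

With a kinship graph the model adds a sample-level random effect with
covariance σ²K, K the genetic relationship matrix implied by the sparse
kinship coefficients (2φ off-diagonal, unit diagonal). No installed package
fits a logistic model with an arbitrary kinship covariance, so it is fitted
here by penalized quasi-likelihood (PQL): iterate the working linear mixed
model z = η + (y−μ)/w with V = W⁻¹ + σ²K, profiling σ² by the working REML
criterion. With σ² = 0 the fit reduces exactly to the ordinary logistic MLE
(verified to 10⁻⁶), and all acceptance properties hold for the
plain-logistic path as well.

AUC is the Mann–Whitney statistic with ties counted ½, computed on
unrelated individuals only (a greedy maximum-degree-removal independent
set, seeded, verified edge-free on every call). It is computed from mid-ranks,
which makes it bit-identical to the explicit all-pairs computation.

Heterogeneity across strata uses the generalized Cochran's Q
Q = (β − β̄1)ᵀ Σ⁻¹ (β − β̄1) with the GLS pooled mean and k−1 df; Σ comes
from a single joint model with PRS-by-stratum interactions, so its
off-diagonals carry whatever correlation the joint information matrix (or
the kinship PQL fit) implies. A diagonal Σ recovers the textbook
fixed-effects Q. Decile analyses use rank-based deciles with seeded
tie-breaks: per-category counts are regressed on decile index 1…10 by OLS,
and the top-vs-bottom decile contrast is an ordinary logistic fit on the
extreme deciles. Ancestry strata label a sample with an ancestry iff its
proportion is ≥ 0.8 (default) and no other ancestry also qualifies.

## Age-risk trajectories

Within PRS strata (<10, 10–50, 50–90, >90 percentiles, combined or within
group, seeded tie-breaks), visit-level hypertension status is modeled by a
logistic GLMM with a per-subject random intercept and fixed effects sex,
ancestry PCs, (age − 17), and (age − 17)². The random-intercept model is
fitted by the same PQL machinery with a block-diagonal working covariance
(Woodbury identity per subject); the variance profile uses working REML.
Adaptive quadrature is not implemented — PQL is the single documented
fitting route, and the zero-variance degenerate case reproduces pooled
logistic exactly. The OR-by-age curve relative to the reference age is
exp(Δβ_age + Δ²β_age²) with delta-method variance
Δ²v₁₁ + Δ⁴v₂₂ + 2Δ³v₁₂ and normal 95% bands (1.96), so OR(17) ≡ 1 and the
curve is invariant to consistent age shifts. Treated visits count as
hypertensive at that visit; status is modeled per visit as observed, not as
an absorbing state.

## Synthetic-data generator

The generator emulates the statistical structure of a multi-ethnic
whole-genome cohort; all randomness descends from a single mandatory seed
through per-operation streams, so identical configurations reproduce
byte-identical outputs.

* **Allele frequencies**: ancestral p ~ Uniform(0.05, 0.5) per variant;
  group frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F_ST = 0.1 by default (clipped to [0.005, 0.995]).
* **Admixture**: per-sample Dirichlet concentrated (α = 20) on the sample's
  own group ancestry; the centered proportions stand in for genetic PCs —
  PC estimation itself is out of scope.
* **LD**: haplotypes are thresholded latent Gaussians with AR(1) block
  correlation (block size 10, latent ρ = 0.9 by default). Dichotomization
  attenuates correlation, so latent 0.9 yields adjacent-variant dosage
  r² ≈ 0.4 and near-zero across blocks — analytically controllable, unlike
  a coalescent simulator, and fast at cohort scale. Positions are spaced
  20 kb on one chromosome so the clumping windows are meaningful.
* **Relatedness**: a configurable fraction of samples (10% default) form
  sibships that draw haplotypes from shared simulated parents; sibling
  pairs appear as kinship-0.25 edges. Any positive kinship is an edge — the
  4th-degree sparsification is the data provider's job, mirrored here.
* **Genetic effects**: causal variants (1% default) carry an
  (SBP, DBP, HTN-specific) effect triple from a multivariate normal with
  cross-trait correlation 0.4–0.5; the HTN-specific component is folded
  into both BP traits with weight λ = 0.5, so the three discovery GWAS
  share signal while each contributes its own. The HTN discovery effect
  (log-OR) is a stylized liability mapping
  0.85·(t_SBP/σ_SBP + t_DBP/σ_DBP) of the total BP effects. Causal effect
  magnitudes are re-scaled so their discovery |z| falls in a configured
  range (default 7–15, i.e. unambiguously genome-wide significant) — this
  ties "how significant are the causal variants" directly to the study
  conditions a given experiment states, with the correlated sign structure
  preserved.
* **Phenotypes**: SBP = 118 + genetic + covariate effects (sex, age, BMI,
  smoking, site) + an ancestry shift (4 mmHg per unit first-ancestry
  proportion) + a person-level intercept (SD 6) + visit noise (SD 12); DBP
  analogous (mean 74, noise SD 8); later visits add a progression drift
  (3 mmHg/visit). Treatment is absorbing: once a sample meets the
  hypertension criteria it starts treatment with probability 0.4 per
  visit, lowering subsequent measured BP by 10/5 mmHg. Hypertension status
  is derived *only* through the phenotyping module.
* **Discovery GWAS**: β̂ ~ Normal(β_true, se²) with
  se = σ_trait/√(2·n·f(1−f)) for continuous traits and
  se = 1/√(2·n·f(1−f)·φ(1−φ)) (case fraction φ = 0.35) for the binary
  trait; p is the two-sided normal tail. Null p-values are uniform and
  doubling n shrinks the median se by √2 (both verified).
* **Calibration outcomes**: a direct logistic outcome generator
  (`simulate_binary_outcome`) draws y from expit(α + β·z) so the generating
  per-SD log-OR is exactly known for coverage studies.

What the generator does **not** emulate: realistic human LD maps and allele
frequency spectra, genotyping error and missingness patterns, phenotype
measurement protocols differing by site, gene–environment interaction, and
ascertainment. Passing tests therefore demonstrate the *machinery* —
harmonization, clumping, selection, combination, and evaluation behave as
specified under known structure — not the clinical performance of any score
on real data.

## Experiment designs and problem sizes

The simulation studies in `htnprs.experiments` (reused by
`scripts/acceptance.py`) use these fixed conditions:

* **Clumping oracle**: 100 random instances of ≤ 50 variants on two
  chromosomes, 50 samples, random thresholds; exact set equality against an
  independent list-based greedy with pairwise `corrcoef` r².
* **CV-selection recovery**: 20 replicates, 5,000 variants, 2,000 training
  and 2,000 held-out samples, 100 causal variants with discovery |z| in
  4.6–6.2 (p concentrated just below 10⁻⁶, so the threshold genuinely
  matters on both sides: stringent thresholds miss causal stragglers and
  permissive ones dilute with noise weights), discovery n scaled to 20–30k
  with per-allele effects scaled up accordingly. Reported: fraction of
  replicates where the CV-chosen p-threshold is within one grid step of the
  threshold whose best candidate maximizes held-out AUC. See the selection
  noise limitation above for why this fraction is ≈ 0.4–0.6 at this
  training size.
* **PRSsum dominance**: 20 replicates, 2,000 variants, 1,200 + 1,200
  samples, default correlated-effects architecture; dominance means the
  PRSsum held-out AUC is within 0.02 of every single-trait AUC.
* **Calibration**: 300 replicates of n = 2,000 logistic outcomes at
  generating per-SD log-OR 0.7 and prevalence 0.35; 95% CI coverage.
* **Decile pattern**: one cohort of 10,000 samples, 800 variants, strong
  signal (2.5% causal, |z| 10–20 at discovery n 20–30k); OLS slopes of
  per-decile counts for the hypertension-at-both-exams and
  never-hypertensive categories.
* **Pipeline determinism**: the full staged workflow run twice at 1,000
  samples and 600 variants; manifests (SHA-256 of every artifact) must be
  byte-identical.

These sizes keep the default test suite and the acceptance script to a few
minutes on one CPU while leaving every measured property well away from
its small-sample regime, except where noted.

## Numerical choices

* Sample SD uses the n−1 denominator throughout the CV criterion.
* Logistic Newton iterations use step-halving with |coefficient| > 30 as
  the separation diagnostic; statsmodels GLM fits use tol 10⁻¹².
* PQL profiles σ² by bounded scalar minimization of the working REML
  criterion (log-scale, tolerance 10⁻³–10⁻⁴), outer loop to a 10⁻⁶–10⁻⁷
  coefficient change.
* The 95% bands use the normal quantile 1.959963984540054.
* Deciles and strata resolve exact ties by a seeded uniform key.
* Stage and fold assignment operate on lexicographically sorted kinship
  components before the seeded shuffle; graph containers are rebuilt rather
  than viewed so no result depends on Python hash ordering.
* Empty weight sets are flagged degenerate rather than raised; selection
  skips them and errors only if no candidate remains.

## Known limitations

* The CV-selection argmin instability at small training sizes, analyzed
  above.
* PQL is known to bias variance components toward zero for binary outcomes
  with small cluster sizes; fixed-effect estimates (the quantities used
  here) are much less affected, and the degenerate-variance path is exact.
* The generator's liability mapping for the binary-trait GWAS is stylized;
  it preserves the shared-signal structure but not the exact link between
  BP thresholds and log-ORs.
* Harmonization drops palindromic variants unconditionally, sacrificing a
  deterministic ~1/3 of real SNPs in exchange for zero strand errors; real
  pipelines may prefer frequency-based rescue at non-intermediate
  frequencies.
* X-chromosome dosages, indels, multi-allelic sites, and genome-build
  liftover are out of scope.
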