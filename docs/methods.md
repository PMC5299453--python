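# Methods

This note documents the models, conventions and design choices behind
`rxdyn`, in the order the pipeline runs them.

## The synthetic-EMR generative model

No public EMR with linked patient/provider identifiers exists at desk
scale, so the package's study conditions are defined by a generator whose
defaults are the conditions the analysis is built around, and whose ground
truth is emitted as a sidecar (`truth.json`) that the analysis stages never
read.

**Providers.** Each of `n_providers` (default 504) draws a latent
trazodone preference from Beta(2, 2), except an
`exclusive_trazodone_fraction` (default 10%) set exactly to 1. Exclusive
prescribers write trazodone deterministically — index, follow-up and
history scripts alike — so the observed all-time preference distribution
reproduces the characteristic point mass at *p* = 1. Each provider also
receives a Poisson(`history_rx_per_provider_mean`, default 100) historical
prescription record of Bernoulli(preference) trazodone/zolpidem draws,
dated in the first two study years, strictly before any index encounter.

**Notes.** Text is bag-of-words from a blocked topic model: the vocabulary
(default 500 terms) is partitioned into `n_topics_true` = 5 disjoint
blocks; topic k has support only on block k, with within-block weights
drawn once from Dirichlet(0.5). Topic 0 is the depression topic; its block
begins with real depression vocabulary (depression, mood, psychiatric,
suicidal, ...) and the other blocks are themed analogously (diabetes,
cardiac, musculoskeletal, respiratory). Each index patient draws a
document-topic vector θ ~ Dirichlet(0.5·1₅) shared by their 1–3 window
notes (Poisson length, default mean 100 words). Disjoint support makes
planted-topic recovery and separability exactly measurable; it is the one
deliberate idealisation relative to real clinical language, where topics
share vocabulary (see Limitations).

**Outcome.** The index prescription is trazodone with probability
expit(β₀ + β_pref·preference + β_depr·θ_depression); defaults β₀ = −0.3,
β_pref = log 3.13, β_depr = log 1.38 give roughly a 57%/38%
trazodone/zolpidem split once ~5% of patients are routed to the minor
hypnotics (eszopiclone, zolpidem ER). About 43% of insomnia indications
arrive as ICD-9 codes and the rest as a sleep expression embedded verbatim
in a lookback-window note, exercising both phenotyping paths.

**Decoys.** A configurable fraction of patients (default 5% each) violates
exactly one inclusion criterion: an old sleep script before the indicated
index (prior medication), no indication at all, or no follow-up script.
The prior script's drug follows the prescriber's preference so exclusive
prescribers stay exclusive.

Everything is reproducible from the single config seed.

## Phenotyping conventions

The index date t0 is the **earliest sleep prescription that has an
indication in its 12-month lookback**; exclusion reasons are then
well-defined per patient: `no_indication` (no prescription qualifies),
`prior_sleep_medication` (a sleep script predates t0), `no_followup`
(nothing in the following year). Window conventions: indication window
half-open [t0−365d, t0) — an indication dated exactly at t0 does not
certify the prescription it accompanies; follow-up window half-open
(t0, t0+365d]; note window closed [t0−7d, t0+7d]. Expression matching is
case-insensitive raw substring matching after whitespace normalisation; no
stemming or negation handling, because the criteria are literal phrases.
Multiple notes in the window are concatenated newline-separated, in
(date, note id) order. If several index-date scripts tie, the
lexicographically first drug name is taken and the record flagged. The
"sleep medication" list is configurable, defaulting to {trazodone,
zolpidem, zolpidem ER, eszopiclone}.

## Provider preference

p_i = t_i/(t_i + z_i) over a provider's entire trazodone/zolpidem record
(all patients, not just cohort members); "zolpidem ER" is a distinct
product and never counted as zolpidem. The time-specific variant counts
only scripts dated **strictly before** the encounter, making the modeling
feature leakage-free by construction (property-tested by perturbing
future-dated scripts). Zero-history encounters are undefined; the default
policy imputes the uninformative midpoint 0.5 and flags the row, a
drop-the-encounter policy is available. No shrinkage or decay weighting is
applied — the statistic is the raw ratio. The all-time distribution is
used for the preference histogram, the time-specific one for modeling.

## Topic model

LDA is fit by collapsed Gibbs sampling: topic proportions and topic-word
distributions are integrated out and each token's topic is resampled from

p(z_i = k | z₋ᵢ, w) ∝ (n_dk + α)(n_kw + η)/(n_k + Vη),

counts excluding token i. Defaults: α = 50/K, η = 0.01, 2000 sweeps with
500 burn-in; φ and θ are posterior means of their smoothed count estimates
over post-burn-in sweeps. One uniform variate per token per sweep is
pre-drawn from a seeded generator, and the numba-compiled kernel and the
pure-Python instrumented sweep consume the identical stream, so both
produce bit-identical trajectories; the instrumented path records every
conditional distribution, which the tests check token-by-token against a
from-scratch brute-force evaluation. Note that smaller α (≈0.5, matching
the generator) is preferable when θ is used as a regression feature; 50/K
over-smooths small documents toward uniform and attenuates topic signal.

Preprocessing: lowercase, punctuation stripped, tokens ≥ 2 characters, a
small stopword list; vocabulary ordered by first appearance; documents
emptied by preprocessing are excluded and logged. Held-out θ is inferred
by fold-in Gibbs with φ fixed; documents with no in-vocabulary tokens get
the uniform distribution and a flag.

Topic indices carry no meaning, so comparisons to planted truth (and
across runs) first align topics by minimum-total-variation optimal
assignment (`scipy.optimize.linear_sum_assignment`); an optimal matching
was preferred to a greedy one since it is just as deterministic and never
mis-pairs nearly-tied topics. Relevance ranking uses
λ·log φ_tw + (1−λ)·log(φ_tw/p_w) with p_w the empirical corpus term
probability and λ = 0.6 by default.

## Decision model

Design matrix: intercept, time-specific provider preference, and the first
K−1 of the K topic proportions. Because the K proportions sum to 1, the
last topic is dropped as the reference level; its effect is absorbed into
the intercept, and the choice of reference moves individual topic
coefficients but — as the tests verify to 1e-8 — no fitted probability,
deviance or CV AUC. One practical consequence: when the *planted* topic of
interest happens to be matched to the dropped column, its effect surfaces
as uniformly negative odds ratios on the remaining topics; reports should
be read with the reference level in mind.

Fitting is Newton/IRLS maximum likelihood (statsmodels `Logit`, gradient
tolerance 1e-8). Perfect separation is detected (non-convergence or
|coefficient| > 30) and raised with guidance rather than silently
reported; rank-deficient designs are rejected with the collinear columns
named. Inference is Wald: z = coef/SE, OR = exp(coef), significance
threshold 0.05 with no multiplicity correction across topic coefficients —
the topic p-values are deliberately reported raw.

Cross-validation: seeded unstratified shuffle into 10 folds (a stratified
option exists), model refit per training fold, AUC on held-out predictions
by the Mann–Whitney rank statistic (ties get half credit; the tests verify
equality with exhaustive concordant-pair counting and with trapezoidal ROC
integration). Sensitivity/specificity use a 0.5 probability threshold by
default — with an imbalanced outcome this sits off the ROC knee, which is
visible in the demo output; a Youden-optimal threshold is a config option.
Folds whose test split contains one outcome class yield an undefined AUC
and are excluded from the summary with a warning. Topics are fit once on
the full cohort corpus before CV (topics-then-regression); fold-wise topic
refitting would be the stricter protocol but is not the default. The
chosen K maximises mean CV AUC and the final coefficient table comes from
a refit on the full cohort.

## Parameter-recovery testing protocol

Recovery and calibration tests fit the logistic model on the generator's
*true* covariates (latent provider preference, planted depression-topic
proportion) with `exclusive_trazodone_fraction = 0`, so the fitted model
is exactly well-specified and 95% Wald-interval coverage of the planted
log-odds is a valid oracle. Fitting on estimated covariates instead would
attenuate coefficients (errors-in-variables) and test measurement error,
not the estimator. The full estimated-covariate chain is exercised
separately: the grid sweep finds the planted depression topic significant
when its effect is strong, and the preference-ablation contrast shows the
CV AUC collapse when the preference column is removed.

## Problem sizes and determinism

The demo configuration (`configs/demo.yaml`) analyses a 2000-patient
cohort with 250 providers and runs the LDA grid at 400 sweeps / 100
burn-in; it completes in a few minutes on one CPU and is the basis of the
acceptance script. Sub-studies use 500 documents × 150 tokens for topic
recovery, 50 replicates at n = 5000 for interval coverage (30 in the
acceptance script), and 200 replicates at n = 1000 for null calibration.
A pipeline rerun with the same config is byte-identical in every CSV/JSON
data output; `manifest.json` is the single exception since it records
wall-clock timestamps alongside the config, per-stage seeds and output
digests.

## Known limitations

- Notes are bags of planted-topic tokens; no grammar, negation, or shared
  vocabulary between topics. Passing tests show the pipeline recovers what
  the generative model plants — they say nothing about LDA's adequacy on
  real clinical narrative, where topics overlap and expression matching
  ("denies poor sleep") produces false indications by design.
- The outcome model is the same logistic form the analysis fits; recovery
  results certify the estimation chain, not robustness to model
  misspecification (except the deliberate exclusive-prescriber point
  mass, whose inflation of the observed preference OR is visible in the
  demo output).
- The preference statistic is unsmoothed; providers with tiny histories
  produce noisy p_i, and the midpoint imputation for zero-history
  providers is a convention, not an estimate.
- Continued-use follow-up prescriptions are generated unconditionally, so
  adherence/discontinuation dynamics are absent.
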