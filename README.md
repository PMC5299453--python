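# rxdyn

Physician–patient prescribing dynamics for first sleep-medication
prescriptions: a tested, reusable pipeline for asking *who determines which
sleep medication a patient gets — the patient's clinical state, or the
prescribing physician's habit?*

Insomnia is commonly treated either with the non-benzodiazepine hypnotic
**zolpidem** or, off-label, with the antidepressant **trazodone**. `rxdyn`
reconstructs the full analysis chain needed to decompose that decision from
EMR data, and ships a synthetic-EMR generator with *planted* effect sizes so
every stage can be validated by parameter recovery rather than by access to
proprietary hospital records:

1. **Cohort phenotyping** — extract the START cohort (first-ever sleep
   prescription) by combining codified indications (ICD-9 insomnia codes
   307.41, 307.42, 327.00–327.09, 780.52) with narrative ones (literal
   sleep-disorder expressions such as "sleeps poorly" in note text), with
   no prior sleep medication and evidence of continued use within 12
   months.
2. **Provider preference** — for provider *i* with *t<sub>i</sub>*
   trazodone and *z<sub>i</sub>* zolpidem prescriptions,

   *p<sub>i</sub>* = *t<sub>i</sub>* / (*t<sub>i</sub>* + *z<sub>i</sub>*),

   computed **time-specifically**: only prescriptions strictly before the
   index encounter count, so the feature is leakage-free by construction.
3. **Topic features** — latent Dirichlet allocation over the clinical
   notes in the ±7-day window around the index encounter, fit by a
   collapsed Gibbs sampler; topic terms ranked by relevance
   (λ·log φ<sub>tw</sub> + (1−λ)·log(φ<sub>tw</sub>/p<sub>w</sub>), λ = 0.6).
4. **Decision model** — logistic regression of trazodone-vs-zolpidem on
   provider preference and K−1 topic proportions (the K-th topic is the
   reference level), with odds ratios, Wald p-values, and 10-fold
   cross-validated AUC/sensitivity/specificity over the grid
   K ∈ {0, 5, 10, 15, 20}.

The package is aimed at quantitative clinical researchers and
methods-minded data scientists who want a workbench for provider-preference
analyses: every quantity the pipeline estimates is something the bundled
generator can plant, so the whole chain is testable end to end.

## Worked example

`examples/05_decision_model.py` generates a 1000-patient synthetic EMR,
phenotypes the cohort, computes time-specific preferences, and sweeps the
topic grid:

```text
cross-validated metrics by number of topics:
 k   auc  auc_sd  sensitivity  sensitivity_sd  specificity  specificity_sd
 0 0.600   0.054        0.947           0.029        0.068           0.027
 5 0.606   0.065        0.925           0.031        0.118           0.057
10 0.601   0.063        0.903           0.044        0.128           0.048

chosen K = 5

final model (refit on the full cohort):
           variable    coef     se  odds_ratio  p_value
              const -0.8070 0.3826      0.4462   0.0349
provider_preference  1.6003 0.2874      4.9543   0.0000
            topic_1 -0.0820 0.5324      0.9213   0.8776
            topic_2  0.7155 0.5385      2.0452   0.1839
            topic_3  1.0366 0.5499      2.8195   0.0594
            topic_4  1.0244 0.5432      2.7853   0.0593
```

Reading this: the provider-preference odds ratio ≈ 5.0 means each unit of
historical trazodone preference multiplies the odds of a trazodone first
prescription about five-fold — provider habit dominates the decision (the
planted per-unit OR is 3.13; the observed one is amplified by the planted
point mass of exclusive trazodone prescribers). No topic reaches the 0.05
level at this sample size, and the AUC gain from adding topics over the
preference-only model (K = 0) is correspondingly small. The other examples
(`examples/01…06`) walk through each stage individually and print what
every number means.

There is also a thin CLI:

```bash
rxdyn run --config configs/demo.yaml --out runs/demo
rxdyn report --in runs/demo
```

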