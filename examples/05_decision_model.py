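"""Fit the trazodone-vs-zolpidem decision model and sweep the topic grid.

Design: intercept + time-specific provider preference + K-1 topic
proportions (the last topic is the reference level). For each K in
{0, 5, 10, 15, 20} the model is cross-validated 10-fold; the best K is
refit on the full cohort for odds ratios and Wald p-values.
"""

from rxdyn import (GeneratorConfig, build_corpus, encounter_preferences,
                   extract_cohort, filter_to_binary_outcome,
                   generate_snapshot, sweep_topic_grid)

snap = generate_snapshot(GeneratorConfig(n_patients=1000, n_providers=120,
                                         seed=7, doc_length_mean=80.0))
cohort = filter_to_binary_outcome(extract_cohort(snap).records)
prefs = encounter_preferences(snap.prescriptions, cohort)
corpus = build_corpus([r.window_text for r in cohort],
                      doc_ids=[r.patient_id for r in cohort])

report = sweep_topic_grid(cohort, prefs["p_i"].to_numpy(), corpus,
                          k_grid=(0, 5, 10), n_folds=10, seed=2,
                          lda_iterations=300, lda_burnin=100)

print("cross-validated metrics by number of topics:")
print(report.metrics.round(3).to_string(index=False))
print(f"\nchosen K = {report.chosen_k}")
print("\nfinal model (refit on the full cohort):")
print(report.coefficients.round(4).to_string(index=False))
# provider_preference should carry a large odds ratio (the planted per-unit
# OR is 3.13; the observed one is amplified by exclusive prescribers). The
# K = 0 row shows how much the preference variable achieves alone.
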