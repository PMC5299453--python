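import numpy as np
import pandas as pd
import pytest

from rxdyn import (auc_rank, build_design_matrix, crossvalidate,
                   fit_logistic, generate_snapshot, sweep_topic_grid)
from rxdyn.decision_model import (DesignMatrix, SeparationError,
                                  SingularDesignError,
                                  sensitivity_specificity)
from rxdyn.phenotyping import CohortRecord
from rxdyn.synthetic_emr import GeneratorConfig


def _cohort(drugs):
    return [CohortRecord(patient_id=f"p{i}", provider_id="P",
                         t0=pd.Timestamp("2008-01-01"), outcome_drug=d,
                         indication_source="code", window_text="",
                         age_at_t0=50.0, sex="F")
            for i, d in enumerate(drugs)]


def _design_from_arrays(X_dict, y):
    X = pd.DataFrame({"const": np.ones(len(y)), **X_dict})
    return DesignMatrix(X, np.asarray(y), 0, None)


class TestDesignMatrix:
    def _inputs(self, n=10, k=5, seed=0):
        rng = np.random.default_rng(seed)
        cohort = _cohort(["trazodone" if i % 2 else "zolpidem"
                          for i in range(n)])
        pref = rng.random(n)
        theta = rng.dirichlet(np.ones(k), size=n)
        return cohort, pref, theta

    def test_k0_is_preference_only(self):
        cohort, pref, _ = self._inputs()
        d = build_design_matrix(cohort, pref, None, 0)
        assert list(d.X.columns) == ["const", "provider_preference"]

    def test_k5_has_four_topic_columns(self):
        cohort, pref, theta = self._inputs()
        d = build_design_matrix(cohort, pref, theta, 5)
        assert list(d.X.columns) == ["const", "provider_preference",
                                     "topic_1", "topic_2", "topic_3",
                                     "topic_4"]
        np.testing.assert_allclose(
            d.X[["topic_1", "topic_2", "topic_3", "topic_4"]].to_numpy(),
            theta[:, :4])

    def test_uniform_theta_row_passes_through(self):
        cohort, pref, theta = self._inputs()
        theta[0] = 0.2
        d = build_design_matrix(cohort, pref, theta, 5)
        assert (d.X.iloc[0][["topic_1", "topic_2", "topic_3", "topic_4"]]
                == 0.2).all()

    def test_misaligned_rows_and_nan_preference_rejected(self):
        cohort, pref, theta = self._inputs()
        with pytest.raises(ValueError):
            build_design_matrix(cohort, pref[:-1], theta, 5)
        pref[0] = np.nan
        with pytest.raises(ValueError, match="policy"):
            build_design_matrix(cohort, pref, theta, 5)


class TestLogisticFit:
    def test_two_by_two_table_recovers_cross_product_ratio(self):
        # cells (a,b,c,d) = (30,10,10,30): OR = 30*30/(10*10) = 9
        x = np.array([1] * 40 + [0] * 40)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        fit = fit_logistic(_design_from_arrays({"x": x}, y))
        or_x = fit.table.set_index("variable").loc["x", "odds_ratio"]
        assert or_x == pytest.approx(9.0, abs=1e-6)

    def test_null_predictors_give_unit_odds_ratios(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        fit = fit_logistic(_design_from_arrays({"x": x}, y))
        row = fit.table.set_index("variable").loc["x"]
        assert row["odds_ratio"] == pytest.approx(1.0, abs=0.2)
        assert row["p_value"] > 0.001

    def test_oracle_against_statsmodels_free_formula(self):
        """Wald z p-value equals 2*Phi(-|coef/se|) from the fit's own
        coefficient and standard error."""
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
        fit = fit_logistic(_design_from_arrays({"x": x}, y))
        row = fit.table.set_index("variable").loc["x"]
        expected = 2 * norm.sf(abs(row["coef"] / row["se"]))
        assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_perfect_separation_flagged(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(SeparationError):
            fit_logistic(_design_from_arrays({"x": x}, x.astype(int)))

    def test_singular_design_names_collinear_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        with pytest.raises(SingularDesignError, match="x2"):
            fit_logistic(_design_from_arrays({"x1": x, "x2": 2 * x}, y))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(_design_from_arrays({"x": np.arange(5.0)},
                                             np.ones(5, dtype=int)))


class TestAuc:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(y, y.astype(float)) == 1.0
        sens, spec = sensitivity_specificity(y, y.astype(float))
        assert sens == 1.0 and spec == 1.0

    def test_rank_auc_equals_exhaustive_pair_counting(self):
        """On 1000 random small prediction sets (with ties), the rank AUC
        equals concordant-pair counting with half credit for ties."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            pairs = conc = 0.0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    pairs += 1
                    conc += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0)
            assert auc_rank(y, s) == pytest.approx(conc / pairs, abs=1e-10)

    def test_matches_trapezoidal_roc_integration(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        assert auc_rank(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-10)


class TestCrossValidation:
    def _null_design(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return _design_from_arrays({"x": rng.normal(size=n)},
                                   rng.integers(0, 2, n))

    def test_null_predictor_auc_near_half(self):
        cv = crossvalidate(self._null_design(n=2000), seed=1)
        assert cv.auc_mean == pytest.approx(0.5, abs=0.05)

    def test_fold_count_and_determinism(self):
        d = self._null_design()
        a = crossvalidate(d, n_folds=10, seed=5)
        b = crossvalidate(d, n_folds=10, seed=5)
        assert len(a.fold_metrics) == 10
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(self._null_design(n=6), n_folds=10)

    def test_single_class_fold_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 3 + [0] * 57)
        d = _design_from_arrays({"x": rng.normal(size=60)}, y)
        with pytest.warns(UserWarning, match="single outcome class"):
            cv = crossvalidate(d, n_folds=10, seed=0)
        assert cv.n_folds_used < 10
        assert np.isfinite(cv.auc_mean)


class TestReferenceLevel:
    def test_dropped_topic_choice_does_not_move_fitted_probabilities(self):
        rng = np.random.default_rng(4)
        n, k = 300, 5
        cohort = _cohort(["trazodone" if u < 0.5 else "zolpidem"
                          for u in rng.random(n)])
        pref = rng.random(n)
        theta = rng.dirichlet(np.ones(k), size=n)
        base = fit_logistic(build_design_matrix(cohort, pref, theta, k))
        for dropped in range(k - 1):
            alt = fit_logistic(build_design_matrix(cohort, pref, theta, k,
                                                   drop_topic=dropped))
            assert np.abs(alt.fitted_probs - base.fitted_probs).max() < 1e-8
            assert abs(alt.llf - base.llf) < 1e-8


class TestParameterRecovery:
    def test_beta_pref_bias_shrinks_with_n(self):
        """Fitted provider-preference log-odds approaches the planted value
        as the cohort grows (well-specified covariates from truth)."""
        import math

        rms = {}
        for n in (500, 2000, 8000):
            errs = []
            for rep in range(5):
                cfg = GeneratorConfig(
                    n_patients=n, n_providers=max(30, n // 20),
                    seed=1000 * rep + n,
                    exclusive_trazodone_fraction=0.0, other_drug_fraction=0.0,
                    doc_length_mean=12.0, notes_per_patient=(1, 1),
                    history_rx_per_provider_mean=20.0,
                    decoy_fraction_prior_rx=0.0,
                    decoy_fraction_no_indication=0.0,
                    decoy_fraction_no_followup=0.0)
                snap = generate_snapshot(cfg)
                pi = snap.truth.patient_index
                y = (pi["drug"] == "trazodone").to_numpy().astype(int)
                fit = fit_logistic(_design_from_arrays(
                    {"provider_preference": pi["preference_true"].to_numpy(),
                     "depression": pi["depression_proportion"].to_numpy()}, y))
                coef = fit.table.set_index("variable").loc[
                    "provider_preference", "coef"]
                errs.append(coef - math.log(3.13))
            rms[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rms[8000] < rms[500]
        assert rms[8000] < 0.2


class TestTopicGridSweep:
    def _pipeline_inputs(self, beta_depr, seed=0, n=1000):
        from rxdyn import (build_corpus, encounter_preferences,
                           extract_cohort, filter_to_binary_outcome)

        cfg = GeneratorConfig(
            n_patients=n, n_providers=80, seed=seed, beta_pref=2.5,
            beta_depr=beta_depr, doc_length_mean=80.0,
            history_rx_per_provider_mean=60.0)
        snap = generate_snapshot(cfg)
        cohort = filter_to_binary_outcome(extract_cohort(snap).records)
        prefs = encounter_preferences(snap.prescriptions, cohort)
        corpus = build_corpus([r.window_text for r in cohort],
                              doc_ids=[r.patient_id for r in cohort])
        return snap, cohort, prefs["p_i"].to_numpy(), corpus

    def test_planted_depression_topic_found_significant(self):
        snap, cohort, pref, corpus = self._pipeline_inputs(beta_depr=2.5,
                                                           seed=10)
        report = sweep_topic_grid(cohort, pref, corpus, k_grid=(0, 5),
                                  seed=3, lda_iterations=300, lda_burnin=100)
        assert report.chosen_k == 5
        # locate the fitted topic matching the planted depression topic and
        # refit with a different reference level so its coefficient is
        # identified (reference choice does not move fitted probabilities)
        from rxdyn import match_topics

        fit = report.topic_fits[5]
        col = {t: j for j, t in enumerate(fit.vocabulary)}
        phi_est = np.zeros((5, len(snap.truth.vocabulary)))
        for j, term in enumerate(snap.truth.vocabulary):
            if term in col:
                phi_est[:, j] = fit.phi[:, col[term]]
        mapping, _ = match_topics(phi_est, snap.truth.topic_word_true)
        depr = mapping[0]
        design = build_design_matrix(cohort, pref, fit.theta, 5,
                                     drop_topic=(depr + 1) % 5)
        coefs = fit_logistic(design).table.set_index("variable")
        depr_col = f"topic_{depr + 1}"
        assert coefs.loc[depr_col, "p_value"] < 0.05
        assert coefs.loc[depr_col, "odds_ratio"] > 1.0

    def test_no_topic_signal_prefers_preference_only_model(self):
        _, cohort, pref, corpus = self._pipeline_inputs(beta_depr=0.0, seed=11)
        report = sweep_topic_grid(cohort, pref, corpus, k_grid=(0, 5),
                                  seed=4, lda_iterations=200, lda_burnin=80)
        m = report.metrics.set_index("k")
        assert m.loc[0, "auc"] >= m.loc[5, "auc"] - m["auc_sd"].max()
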