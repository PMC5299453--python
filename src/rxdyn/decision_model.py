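"""Logistic decision model: which sleep medication does a patient receive?

The design is intercept + time-specific provider preference + the first
K-1 of the K LDA topic proportions; because the K proportions sum to 1 the
last topic is dropped (reference level) and its effect is absorbed into the
intercept. Fitting is maximum likelihood (Newton/IRLS, gradient tolerance
1e-8) via statsmodels, with Wald z p-values and odds ratios exp(coef).

Discrimination is estimated by seeded 10-fold cross-validation; AUC uses
the Mann-Whitney rank formulation (ties contribute 1/2), sensitivity and
specificity use a configurable probability threshold (default 0.5). The
topic count K is swept over {0, 5, 10, 15, 20} and the model with the best
mean CV AUC is selected and refit on the full cohort for the coefficient
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

DEFAULT_K_GRID = (0, 5, 10, 15, 20)
SIGNIFICANCE_LEVEL = 0.05


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges; coefficients are unreliable."""


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""


@dataclass
class DesignMatrix:
    X: pd.DataFrame = field(repr=False)  # includes "const" column
    y: np.ndarray = field(repr=False)    # 1 = trazodone, 0 = zolpidem
    k: int
    dropped_topic: int | None

    @property
    def n(self) -> int:
        return len(self.y)


def build_design_matrix(cohort, preference, theta=None, k: int = 0,
                        drop_topic: int | None = None) -> DesignMatrix:
    """Assemble the regression design for a binary-outcome cohort.

    ``preference`` is aligned with ``cohort`` (undefined values must already
    be resolved by the preference policy). ``theta`` is the (n, K) topic
    proportion matrix when k > 0; ``drop_topic`` picks the reference topic
    (default: the last, topic K-1).
    """
    from .phenotyping import outcome_vector

    records = list(cohort)
    y = outcome_vector(records)
    pref = np.asarray(preference, dtype=float)
    if pref.shape[0] != len(records):
        raise ValueError(
            f"preference rows ({pref.shape[0]}) != cohort rows ({len(records)})")
    if np.isnan(pref).any():
        raise ValueError("preference contains undefined values; apply a policy")
    cols = {"const": np.ones(len(records)), "provider_preference": pref}
    dropped = None
    if k > 0:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(records), k):
            raise ValueError(f"theta shape {theta.shape} != ({len(records)}, {k})")
        dropped = k - 1 if drop_topic is None else int(drop_topic)
        if not 0 <= dropped < k:
            raise ValueError("drop_topic out of range")
        for t in range(k):
            if t != dropped:
                cols[f"topic_{t + 1}"] = theta[:, t]
    return DesignMatrix(pd.DataFrame(cols), y, k, dropped)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns whose removal restores full rank
        bad = [c for i, c in enumerate(X.columns)
               if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank]
        raise SingularDesignError(f"collinear columns: {bad}")


@dataclass
class LogisticFit:
    table: pd.DataFrame = field(repr=False)  # variable, coef, se, OR, p
    params: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    fitted_probs: np.ndarray = field(repr=False)
    llf: float
    columns: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(X[self.columns].to_numpy(dtype=float) @ self.params)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.cov))
        zq = norm.ppf(0.5 + level / 2)
        return pd.DataFrame({
            "variable": self.columns,
            "lower": self.params - zq * se,
            "upper": self.params + zq * se,
        })


def fit_logistic(design: DesignMatrix, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""
    if len(np.unique(design.y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    _check_rank(design.X)
    model = sm.Logit(design.y, design.X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", tol=tol, maxiter=100, disp=0)
    except Exception as exc:  # statsmodels signals separation variously
        raise SeparationError(
            "logistic MLE failed to converge; check for perfect separation "
            "or quasi-separation in the design"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(
            "logistic MLE failed to converge; check for perfect separation "
            "or quasi-separation in the design")
    if np.max(np.abs(res.params)) > 30:
        raise SeparationError(
            "diverging coefficients (|beta| > 30) indicate perfect "
            "separation; consider pooling or removing the offending predictor")
    table = pd.DataFrame({
        "variable": list(design.X.columns),
        "coef": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "odds_ratio": np.exp(res.params.to_numpy()),
        "p_value": res.pvalues.to_numpy(),
    })
    return LogisticFit(
        table=table, params=res.params.to_numpy(),
        cov=res.cov_params().to_numpy(), fitted_probs=res.predict(),
        llf=float(res.llf), columns=list(design.X.columns))


def auc_rank(y, scores) -> float:
    """AUC by the Mann-Whitney rank statistic (average ranks for ties)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def sensitivity_specificity(y, scores, threshold: float = 0.5):
    y = np.asarray(y)
    pred = np.asarray(scores) >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


@dataclass
class CvResult:
    fold_metrics: pd.DataFrame = field(repr=False)  # fold, n_test, auc, sens, spec
    auc_mean: float
    auc_sd: float
    sens_mean: float
    sens_sd: float
    spec_mean: float
    spec_sd: float
    n_folds_used: int


def crossvalidate(design: DesignMatrix, n_folds: int = 10, seed: int = 0,
                  threshold: float = 0.5, stratified: bool = False) -> CvResult:
    """Seeded k-fold CV of the logistic model on held-out predictions.

    Folds come from an unstratified shuffle by default. A fold whose test
    split has a single outcome class yields an undefined AUC and is
    excluded from the summary with a warning.
    """
    n = design.n
    if n < n_folds:
        raise ValueError(f"cohort size {n} < n_folds {n_folds}")
    rng = np.random.default_rng(seed)
    if stratified:
        idx_pos = rng.permutation(np.flatnonzero(design.y == 1))
        idx_neg = rng.permutation(np.flatnonzero(design.y == 0))
        folds = [np.concatenate([idx_pos[f::n_folds], idx_neg[f::n_folds]])
                 for f in range(n_folds)]
    else:
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)

    rows = []
    for f, test_idx in enumerate(folds):
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train = DesignMatrix(design.X[~mask], design.y[~mask],
                             design.k, design.dropped_topic)
        fit = fit_logistic(train)
        p_test = fit.predict(design.X[mask])
        y_test = design.y[mask]
        if len(np.unique(y_test)) < 2:
            warnings.warn(f"fold {f}: single outcome class, AUC undefined")
            rows.append((f, int(mask.sum()), np.nan, np.nan, np.nan))
            continue
        auc = auc_rank(y_test, p_test)
        sens, spec = sensitivity_specificity(y_test, p_test, threshold)
        rows.append((f, int(mask.sum()), auc, sens, spec))
    fm = pd.DataFrame(rows, columns=["fold", "n_test", "auc", "sensitivity",
                                     "specificity"])
    ok = fm.dropna(subset=["auc"])
    return CvResult(
        fold_metrics=fm,
        auc_mean=float(ok["auc"].mean()), auc_sd=float(ok["auc"].std(ddof=1)),
        sens_mean=float(ok["sensitivity"].mean()),
        sens_sd=float(ok["sensitivity"].std(ddof=1)),
        spec_mean=float(ok["specificity"].mean()),
        spec_sd=float(ok["specificity"].std(ddof=1)),
        n_folds_used=len(ok),
    )


@dataclass
class ModelReport:
    metrics: pd.DataFrame = field(repr=False)  # one row per K (Table-1 shape)
    chosen_k: int
    coefficients: pd.DataFrame = field(repr=False)  # final model (Table-2 shape)
    final_fit: LogisticFit = field(repr=False)
    topic_fits: dict = field(repr=False, default_factory=dict)
    manifest: dict = field(default_factory=dict)


def sweep_topic_grid(cohort, preference, corpus, k_grid=DEFAULT_K_GRID,
                     n_folds: int = 10, seed: int = 0, threshold: float = 0.5,
                     lda_iterations: int = 2000, lda_burnin: int = 500,
                     lda_eta: float = 0.01, include_preference: bool = True) -> ModelReport:
    """Fit LDA + logistic model for each K and select the best by CV AUC.

    Topics are fit once on the full cohort corpus before cross-validation
    (topics-then-regression, the default protocol); the chosen model is
    refit on the full cohort for the coefficient table.
    """
    from .topic_model import fit_lda

    rows, topic_fits, designs = [], {}, {}
    for k in k_grid:
        if k > 0:
            fit = fit_lda(corpus, k, eta=lda_eta, n_iterations=lda_iterations,
                          n_burnin=lda_burnin, seed=seed + 1000 + k)
            topic_fits[k] = fit
            theta = fit.theta
        else:
            theta = None
        design = build_design_matrix(cohort, preference, theta, k)
        if not include_preference:
            design = DesignMatrix(design.X.drop(columns="provider_preference"),
                                  design.y, design.k, design.dropped_topic)
        designs[k] = design
        cv = crossvalidate(design, n_folds=n_folds, seed=seed + 2000,
                           threshold=threshold)
        rows.append((k, cv.auc_mean, cv.auc_sd, cv.sens_mean, cv.sens_sd,
                     cv.spec_mean, cv.spec_sd))
    metrics = pd.DataFrame(rows, columns=["k", "auc", "auc_sd", "sensitivity",
                                          "sensitivity_sd", "specificity",
                                          "specificity_sd"])
    chosen_k = int(metrics.loc[metrics["auc"].idxmax(), "k"])
    final_fit = fit_logistic(designs[chosen_k])
    return ModelReport(
        metrics=metrics, chosen_k=chosen_k,
        coefficients=final_fit.table.copy(), final_fit=final_fit,
        topic_fits=topic_fits,
        manifest={
            "k_grid": list(k_grid), "n_folds": n_folds, "seed": seed,
            "threshold": threshold, "lda_iterations": lda_iterations,
            "lda_burnin": lda_burnin, "lda_eta": lda_eta,
            "include_preference": include_preference,
            "final_model": "refit on full cohort at chosen K",
        },
    )
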