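"""Implicit calibration: label prediction from features plus surrogates.

In predictive mode the radiome is not explicitly corrected; instead the
classifier receives the qualified surrogates as additional covariates,

    b_hat_i = f(r_i., s_i(qualified)),

so the model can calibrate internally while optimising discrimination.
Baselines cover the feature-only GLM/RF, the naive (all-surrogate) GLM
after mRMR+AIC selection, the naive RF, and a RAVEL-like variant feeding
the leading surrogate principal components to the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .calibration import mrmr_rank
from .qualification import QualifiedSurrogateSets
from .tables import CohortLabels, RadiomeMatrix, SurrogateMatrix

__all__ = [
    "PredictiveModel",
    "PredictionMetrics",
    "fit_predictive",
    "predict_proba",
    "auc",
]

VARIANTS = (
    "technome_glm",
    "glm_features_only",
    "rf_features_only",
    "naive_glm",
    "naive_rf",
    "ravel_like_pred",
)


@dataclass
class PredictiveModel:
    variant: str
    feature_names: list[str]
    surrogate_names: list[str]  # all surrogate columns expected at apply time
    used_surrogates: np.ndarray  # indices into surrogate columns
    mean: np.ndarray
    scale: np.ndarray
    clf: object = field(repr=False, default=None)
    components: np.ndarray = None  # ravel_like_pred: PCA directions over surrogates
    surrogate_stats: tuple = None  # ravel_like_pred: (mean, sd) used before projection

    def design(self, radiome: RadiomeMatrix, surrogates: SurrogateMatrix) -> np.ndarray:
        if list(radiome.feature_names) != list(self.feature_names):
            raise ValueError("feature columns do not match the fitted model")
        if list(surrogates.surrogate_names) != list(self.surrogate_names):
            raise ValueError("surrogate columns do not match the fitted model")
        if self.variant == "ravel_like_pred":
            mu, sd = self.surrogate_stats
            z = (surrogates.values - mu) / sd
            return np.column_stack([radiome.values, z @ self.components])
        if self.variant in ("naive_rf", "technome_glm", "naive_glm"):
            cols = surrogates.values[:, self.used_surrogates]
            return np.column_stack([radiome.values, cols])
        return radiome.values


@dataclass
class PredictionMetrics:
    auc: float
    n_test: int
    per_fold: list[float] = field(default_factory=list)


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Unpenalised logistic fit; small-ridge fallback on (quasi-)separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200, tol=1e-8)
        clf.fit(X, y)
        if clf.n_iter_[0] >= 200:
            warnings.warn("logistic fit did not converge (likely separation); ridge fallback")
            clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=300, tol=1e-8)
            clf.fit(X, y)
    return clf


def _standardiser(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return mu, np.where(sd > 0, sd, 1.0)


def _stepwise_aic_logistic(X: np.ndarray, y: np.ndarray, candidates: list[int], base: np.ndarray) -> list[int]:
    """Forward-stepwise AIC over logistic models with fixed base covariates."""

    def aic(cols: list[int]) -> float:
        design = np.column_stack([base, X[:, cols]]) if cols else base
        clf = _fit_logistic(design, y)
        p = np.clip(clf.predict_proba(design)[:, 1], 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return 2 * (design.shape[1] + 1) - 2 * ll

    chosen: list[int] = []
    best = aic(chosen)
    improved = True
    while improved and len(chosen) < len(candidates):
        improved = False
        best_c, best_a = None, best
        for c in candidates:
            if c in chosen:
                continue
            a = aic(chosen + [c])
            if a < best_a - 1e-9:
                best_c, best_a = c, a
        if best_c is not None:
            chosen.append(best_c)
            best = best_a
            improved = True
    return chosen


def fit_predictive(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    labels: CohortLabels,
    sets: QualifiedSurrogateSets = None,
    variant: str = "technome_glm",
    seed: int = 0,
    k_max: int = 10,
    var_explained: float = 0.95,
    n_estimators: int = 500,
) -> PredictiveModel:
    """Fit a label classifier on training rows for the requested variant.

    ``technome_glm`` augments the features with the union of the per-feature
    qualified surrogate sets; with all-empty sets it reduces exactly to the
    feature-only GLM.  GLM variants z-score their design on training rows.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    y = np.asarray(labels.b)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    feats = radiome.values
    used = np.array([], dtype=int)
    components = None
    stats = None

    if variant == "technome_glm":
        if sets is None:
            raise ValueError("technome_glm requires qualified surrogate sets")
        used = sets.union
    elif variant == "naive_rf":
        used = np.arange(surrogates.n_surrogates)
    elif variant == "naive_glm":
        mu_f, sd_f = _standardiser(feats)
        base = np.column_stack([np.ones(len(y)), (feats - mu_f) / sd_f])
        mu_s, sd_s = _standardiser(surrogates.values)
        z = (surrogates.values - mu_s) / sd_s
        ranked = mrmr_rank(z, y.astype(float), k_max, names=surrogates.surrogate_names)
        used = np.asarray(sorted(_stepwise_aic_logistic(z, y, ranked, base)), dtype=int)
    elif variant == "ravel_like_pred":
        mu_s, sd_s = _standardiser(surrogates.values)
        z = (surrogates.values - mu_s) / sd_s
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        var = s**2
        total = var.sum()
        ncomp = 0
        if total > 0:
            frac = np.cumsum(var) / total
            ncomp = int(np.searchsorted(frac, var_explained - 1e-12) + 1)
            ncomp = min(ncomp, int((var > total * 1e-12).sum()))
        components = vt[:ncomp].T
        stats = (mu_s, sd_s)

    model = PredictiveModel(
        variant,
        list(radiome.feature_names),
        list(surrogates.surrogate_names),
        used,
        mean=None,
        scale=None,
        components=components,
        surrogate_stats=stats,
    )
    X = model.design(radiome, surrogates)
    if variant in ("rf_features_only", "naive_rf"):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        clf.fit(X, y)
        model.mean = np.zeros(X.shape[1])
        model.scale = np.ones(X.shape[1])
    else:
        model.mean, model.scale = _standardiser(X)
        clf = _fit_logistic((X - model.mean) / model.scale, y)
    model.clf = clf
    return model


def predict_proba(model: PredictiveModel, radiome: RadiomeMatrix, surrogates: SurrogateMatrix) -> np.ndarray:
    """Per-row class-1 probability using training standardisation."""
    X = model.design(radiome, surrogates)
    X = (X - model.mean) / model.scale
    return model.clf.predict_proba(X)[:, 1]


def auc(scores, labels) -> float:
    """Mann-Whitney rank AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(scores)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))
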