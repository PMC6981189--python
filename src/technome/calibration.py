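"""Explicit feature calibration (stabilisation mode) and its baselines.

All variants share one contract: a model ``g_j`` is fitted per feature on
training rows, and calibration subtracts the fitted technical contribution,

    r*_ij = r_ij - g_j(s_i.),

where surrogate deviations are always taken against the *training* means
stored inside the model, so the calibration transfers to unseen rows.

Variants
--------
``technome``   per-feature OLS on the qualified surrogate set
``naive_glm``  per-feature OLS on all surrogates after mRMR ranking and
               best-subset selection by AIC
``naive_rf``   per-feature random-forest regression on all surrogates
``ravel_like`` SVD of the column-standardised surrogate matrix; each
               feature is regressed on the leading components (plus the
               label term to protect biological signal) and only the
               component part is subtracted
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.ensemble import RandomForestRegressor

from .qualification import QualifiedSurrogateSets
from .tables import CohortLabels, RadiomeMatrix, SurrogateMatrix

__all__ = [
    "StabilisationModel",
    "fit_technome_stabilisation",
    "apply_calibration",
    "fit_ravel_like",
    "fit_naive_glm",
    "fit_naive_rf",
    "stabilisation_performance",
    "mrmr_rank",
    "best_subset_aic",
]


@dataclass
class FeatureFit:
    surrogate_idx: np.ndarray
    intercept: float
    coef: np.ndarray
    r2: float = np.nan
    coef_se: np.ndarray = None


@dataclass
class RavelParts:
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # right-singular vectors, columns = retained components
    n_components: int
    var_explained: float
    intercepts: np.ndarray  # per feature
    coefs: np.ndarray  # (n_features, n_components)
    label_coefs: np.ndarray = None


@dataclass
class StabilisationModel:
    variant: str
    feature_names: list[str]
    surrogate_names: list[str]
    surrogate_means: np.ndarray
    fits: list[FeatureFit] = None
    ravel: RavelParts = None
    forests: list = field(default=None, repr=False)

    def g(self, surrogate_values: np.ndarray) -> np.ndarray:
        """Fitted technical contribution per (row, feature)."""
        n = surrogate_values.shape[0]
        m = len(self.feature_names)
        if self.variant == "ravel_like":
            rv = self.ravel
            sd = np.where(rv.scale > 0, rv.scale, 1.0)
            scores = ((surrogate_values - rv.mean) / sd) @ rv.components
            return rv.intercepts[None, :] + scores @ rv.coefs.T
        delta = surrogate_values - self.surrogate_means
        out = np.zeros((n, m))
        if self.variant == "naive_rf":
            for j, forest in enumerate(self.forests):
                out[:, j] = forest.predict(delta)
            return out
        for j, fit in enumerate(self.fits):
            out[:, j] = fit.intercept + delta[:, fit.surrogate_idx] @ fit.coef
        return out

    @property
    def is_identity(self) -> bool:
        return (
            self.variant in ("technome", "naive_glm")
            and all(len(f.surrogate_idx) == 0 and f.intercept == 0.0 for f in self.fits)
        )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, float, np.ndarray, np.ndarray]:
    """Intercept OLS with pivoted-QR drop of collinear columns.

    Returns (intercept, coef over kept columns, R^2, kept column indices,
    coefficient standard errors).
    """
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    keep = np.arange(p)
    if p:
        _, r, piv = sla.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > max(n, p + 1) * np.finfo(float).eps * diag.max()).sum())
        if rank < p + 1:
            kept_cols = sorted(piv[:rank])
            if 0 not in kept_cols:  # never drop the intercept
                kept_cols = [0] + kept_cols[: rank - 1]
            keep = np.array([c - 1 for c in kept_cols if c > 0], dtype=int)
            warnings.warn("rank-deficient calibration design; dropped collinear surrogate columns")
            design = np.column_stack([np.ones(n), X[:, keep]])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
    dof = max(n - design.shape[1], 1)
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    return float(beta[0]), beta[1:], float(r2), keep, se[1:]


def fit_technome_stabilisation(
    radiome: RadiomeMatrix, surrogates: SurrogateMatrix, sets: QualifiedSurrogateSets
) -> StabilisationModel:
    """Per-feature OLS of r_j on the qualified surrogate deviations.

    Features with an empty qualified set get the identity calibration
    (g_j = 0), i.e. they are left untouched.
    """
    means = surrogates.values.mean(axis=0)
    delta = surrogates.values - means
    fits = []
    for j in range(radiome.n_features):
        idx = np.asarray(sets.sets[j], dtype=int)
        if len(idx) == 0:
            fits.append(FeatureFit(idx, 0.0, np.zeros(0), r2=0.0))
            continue
        if len(idx) >= radiome.n_patients - 1:
            raise ValueError(
                f"feature {radiome.feature_names[j]!r}: {len(idx)} qualified surrogates "
                f"for {radiome.n_patients} training rows (rank guard)"
            )
        b0, coef, r2, keep, se = _ols(radiome.values[:, j], delta[:, idx])
        fits.append(FeatureFit(idx[keep], b0, coef, r2=r2, coef_se=se))
    return StabilisationModel(
        "technome", list(radiome.feature_names), list(surrogates.surrogate_names), means, fits=fits
    )


def apply_calibration(
    model: StabilisationModel, radiome: RadiomeMatrix, surrogates: SurrogateMatrix
) -> RadiomeMatrix:
    """r* = r - g(surrogates); works on unseen rows with training means."""
    if list(surrogates.surrogate_names) != list(model.surrogate_names):
        raise ValueError("surrogate columns do not match the fitted model")
    if list(radiome.feature_names) != list(model.feature_names):
        raise ValueError("feature columns do not match the fitted model")
    calibrated = radiome.values - model.g(surrogates.values)
    return RadiomeMatrix(calibrated, list(radiome.patient_ids), list(radiome.feature_names))


def fit_ravel_like(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    labels: CohortLabels = None,
    var_explained: float = 0.95,
    protect_label: bool = True,
) -> StabilisationModel:
    """SVD-based calibration on the leading surrogate components.

    Surrogate columns are standardised on training rows, the smallest
    number N of right-singular components explaining at least
    ``var_explained`` of the training variance is retained, and each
    feature is fitted on those component scores.  When labels are given and
    ``protect_label`` is set, the label enters the fit as a covariate but
    its contribution is *not* subtracted, so biological signal survives the
    calibration.
    """
    n = radiome.n_patients
    if n < 3:
        raise ValueError("need at least 3 training rows")
    mean = surrogates.values.mean(axis=0)
    scale = surrogates.values.std(axis=0)
    sd = np.where(scale > 0, scale, 1.0)
    z = (surrogates.values - mean) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        ncomp = 0
    else:
        frac = np.cumsum(var) / total
        ncomp = int(np.searchsorted(frac, var_explained - 1e-12) + 1)
        ncomp = min(ncomp, int((var > total * 1e-12).sum()))
    components = vt[:ncomp].T
    scores = z @ components
    intercepts = np.zeros(radiome.n_features)
    coefs = np.zeros((radiome.n_features, ncomp))
    label_coefs = np.zeros(radiome.n_features)
    use_label = protect_label and labels is not None
    for j in range(radiome.n_features):
        X = scores if not use_label else np.column_stack([scores, np.asarray(labels.b, float)])
        b0, coef, _, keep, _ = _ols(radiome.values[:, j], X)
        full = np.zeros(X.shape[1])
        full[keep] = coef
        intercepts[j] = b0
        coefs[j] = full[:ncomp]
        if use_label:
            label_coefs[j] = full[ncomp]
    ravel = RavelParts(
        mean, scale, components, ncomp, float(var[:ncomp].sum() / total) if total else 1.0,
        intercepts, coefs, label_coefs if use_label else None,
    )
    return StabilisationModel(
        "ravel_like", list(radiome.feature_names), list(surrogates.surrogate_names), mean, ravel=ravel
    )


def mrmr_rank(X: np.ndarray, target: np.ndarray, k: int, names: list[str] = None) -> list[int]:
    """Correlation-based mRMR (MID variant): relevance minus mean redundancy.

    Deterministic tie-break by column name (or index).  Returns the first
    ``k`` column indices in selection order.
    """
    n, p = X.shape
    names = names if names is not None else [str(i) for i in range(p)]
    sd = X.std(axis=0)
    tz = (target - target.mean()) / (target.std() or 1.0)
    ok = sd > 0
    rel = np.abs(((X - X.mean(axis=0)) / np.where(ok, sd, 1.0)).T @ tz / n)
    rel[~ok] = 0.0
    corr_x = np.abs(np.corrcoef(X, rowvar=False)) if p > 1 else np.ones((1, 1))
    corr_x = np.nan_to_num(corr_x, nan=0.0)
    picked: list[int] = []
    remaining = list(range(p))
    while remaining and len(picked) < k:
        if picked:
            red = corr_x[np.ix_(remaining, picked)].mean(axis=1)
        else:
            red = np.zeros(len(remaining))
        score = rel[remaining] - red
        order = sorted(range(len(remaining)), key=lambda i: (-score[i], names[remaining[i]]))
        choice = remaining[order[0]]
        picked.append(choice)
        remaining.remove(choice)
    return picked


def _aic_ols(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    k = design.shape[1] + 1  # + error variance
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def best_subset_aic(y: np.ndarray, X: np.ndarray, candidates: list[int]) -> list[int]:
    """AIC-best subset of the candidate columns.

    Exhaustive when there are at most 10 candidates, forward stepwise
    otherwise.  The empty (intercept-only) model competes too.
    """
    if len(candidates) <= 10:
        best, best_aic = [], _aic_ols(y, X[:, []])
        for r in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                a = _aic_ols(y, X[:, list(combo)])
                if a < best_aic - 1e-12:
                    best, best_aic = list(combo), a
        return best
    chosen: list[int] = []
    best_aic = _aic_ols(y, X[:, []])
    improved = True
    while improved:
        improved = False
        for c in candidates:
            if c in chosen:
                continue
            a = _aic_ols(y, X[:, chosen + [c]])
            if a < best_aic - 1e-12:
                best_aic, chosen = a, chosen + [c]
                improved = True
    return chosen


def fit_naive_glm(
    radiome: RadiomeMatrix, surrogates: SurrogateMatrix, k_max: int = 10
) -> StabilisationModel:
    """Unqualified linear baseline: mRMR-ranked, AIC-regularised OLS per feature."""
    means = surrogates.values.mean(axis=0)
    delta = surrogates.values - means
    fits = []
    for j in range(radiome.n_features):
        y = radiome.values[:, j]
        ranked = mrmr_rank(delta, y, k_max, names=surrogates.surrogate_names)
        subset = best_subset_aic(y, delta, ranked)
        idx = np.asarray(sorted(subset), dtype=int)
        if len(idx) == 0:
            fits.append(FeatureFit(idx, float(y.mean()), np.zeros(0), r2=0.0))
            continue
        b0, coef, r2, keep, se = _ols(y, delta[:, idx])
        fits.append(FeatureFit(idx[keep], b0, coef, r2=r2, coef_se=se))
    return StabilisationModel(
        "naive_glm", list(radiome.feature_names), list(surrogates.surrogate_names), means, fits=fits
    )


def fit_naive_rf(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    seed: int = 0,
    n_estimators: int = 500,
) -> StabilisationModel:
    """Unqualified non-linear baseline: random-forest regression per feature.

    The forest predicts the feature deviation from its training mean out of
    the surrogate deviations; calibration subtracts that prediction.
    """
    means = surrogates.values.mean(axis=0)
    delta = surrogates.values - means
    forests = []
    for j in range(radiome.n_features):
        y = radiome.values[:, j] - radiome.values[:, j].mean()
        rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed + j, n_jobs=1)
        rf.fit(delta, y)
        forests.append(rf)
    return StabilisationModel(
        "naive_rf", list(radiome.feature_names), list(surrogates.surrogate_names), means, forests=forests
    )


def stabilisation_performance(before: RadiomeMatrix, after: RadiomeMatrix) -> float:
    """Mean per-feature variance reduction 1 - var(r*)/var(r) on test rows.

    Negative when calibration adds variance.  Features with zero
    pre-calibration variance are skipped with a warning.
    """
    if before.values.shape != after.values.shape:
        raise ValueError("matrices must have matching shapes")
    var_before = before.values.var(axis=0, ddof=1)
    var_after = after.values.var(axis=0, ddof=1)
    ok = var_before > 0
    if not ok.all():
        warnings.warn("skipping zero-variance features in stabilisation performance")
    if not ok.any():
        raise ValueError("no feature with positive pre-calibration variance")
    perf = 1.0 - var_after[ok] / var_before[ok]
    return float(perf.mean())
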