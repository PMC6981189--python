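"""Technome construction: loss assembly and Bayesian optimisation of theta.

The criterion weights theta are tuned by minimising

    L(theta) = L_train(S_q(theta)) + L_calib(theta),

where ``L_train`` is the task loss of the model built on the qualified
sets implied by theta (negative mean R^2 of the per-feature calibration
fits in stabilisation mode, negative AUC of the surrogate-augmented GLM in
predictive mode) and ``L_calib = -alpha / sum(theta)`` pulls the weights
down so that only highly qualified surrogates clear the selection
threshold.  Because the qualified sets are a piecewise-constant function
of theta, the loss is a step function; the Gaussian-process surrogate
treats it as a noisy continuous one, and a pure random-search fallback is
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from . import prediction
from .calibration import fit_technome_stabilisation
from .qualification import (
    CRITERIA,
    DEFAULT_BOUNDS,
    QualificationTensor,
    QualifiedSurrogateSets,
    combine_q,
    compute_tensor,
    select_qualified,
)
from .tables import CohortLabels, RadiomeMatrix, SeriesTable, SurrogateMatrix, split_train_test

__all__ = [
    "LossConfig",
    "OptimizationResult",
    "TechnomeModel",
    "l_train_stabilisation",
    "l_train_predictive",
    "l_calib",
    "bayes_optimize",
    "random_search",
    "make_objective",
    "construct_technome",
]


@dataclass
class LossConfig:
    """Configuration of the technome construction loop.

    alpha scales the calibration loss; ``active`` selects which criteria
    enter both the combined score and the weight sum (a phantom run, for
    instance, uses the in-vivo criterion alone).  ``calib_form`` chooses
    between the reciprocal form ``-alpha/sum(theta)`` (default, rewards
    small weights and hence high qualification) and the literal linear
    form ``-alpha*sum(theta)`` that rewards large weights instead.
    """

    mode: str = "predictive"
    alpha: float = 0.2
    active: tuple[str, ...] = CRITERIA
    bounds: dict = field(default_factory=dict)
    inner: str = "in_sample"  # or "cv10_inner"
    q_min: float = 1.0
    calib_form: str = "reciprocal"  # or "linear"
    bo_init: int = 8
    bo_iter: int = 500
    kappa: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("stabilisation", "predictive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not self.active:
            raise ValueError("at least one active criterion required")
        for c in self.active:
            if c not in CRITERIA:
                raise ValueError(f"unknown criterion {c!r}")
            self.bounds.setdefault(c, DEFAULT_BOUNDS)

    def bounds_list(self) -> list[tuple[float, float]]:
        return [self.bounds[c] for c in self.active]

    def theta_dict(self, vec) -> dict[str, float]:
        return {c: float(v) for c, v in zip(self.active, vec)}


@dataclass
class OptimizationResult:
    best_theta: dict
    best_loss: float
    l_train: float
    l_calib: float
    trace: list  # [(theta dict, loss), ...]
    seed: int

    def trace_thetas(self) -> np.ndarray:
        return np.array([[t[c] for c in t] for t, _ in self.trace])

    def trace_losses(self) -> np.ndarray:
        return np.array([loss for _, loss in self.trace])


@dataclass
class TechnomeModel:
    """Fitted calibration artifact: qualified sets, weights, final model."""

    mode: str
    theta: dict
    tensor: QualificationTensor
    sets: QualifiedSurrogateSets
    model: object  # StabilisationModel or PredictiveModel
    config: LossConfig


def l_train_stabilisation(
    radiome: RadiomeMatrix, surrogates: SurrogateMatrix, sets: QualifiedSurrogateSets
) -> float:
    """Negative mean explained variance of the per-feature calibration fits."""
    model = fit_technome_stabilisation(radiome, surrogates, sets)
    r2 = np.array([f.r2 for f in model.fits])
    return float(-r2.mean())


def l_train_predictive(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    labels: CohortLabels,
    sets: QualifiedSurrogateSets,
    inner: str = "in_sample",
    seed: int = 0,
) -> float:
    """Negative AUC of the surrogate-augmented GLM on the training data.

    ``in_sample`` scores the fitted classifier on its own training rows;
    ``cv10_inner`` scores it by an inner group-aware 10-fold CV, which
    resists the optimism of in-sample AUC when many surrogates enter.
    """
    if inner == "in_sample":
        model = prediction.fit_predictive(radiome, surrogates, labels, sets, "technome_glm")
        scores = prediction.predict_proba(model, radiome, surrogates)
        return float(-prediction.auc(scores, labels.b))
    if inner != "cv10_inner":
        raise ValueError(f"unknown inner evaluation {inner!r}")
    splits = split_train_test(
        radiome.n_patients, "cv10", group_ids=labels.group_ids, seed=seed, labels=labels.b
    )
    scores = np.empty(radiome.n_patients)
    for train, test in splits:
        model = prediction.fit_predictive(
            radiome.subset_rows(train), surrogates.subset_rows(train),
            labels.subset_rows(train), sets, "technome_glm",
        )
        scores[test] = prediction.predict_proba(
            model, radiome.subset_rows(test), surrogates.subset_rows(test)
        )
    return float(-prediction.auc(scores, labels.b))


def l_calib(theta, alpha: float, form: str = "reciprocal", min_total: float = 1e-6) -> float:
    """Calibration loss over the active weights.

    Reciprocal form ``-alpha/sum(theta)`` (the default) penalises large
    weights: lowering the weights while keeping surrogates selected forces
    higher qualification.  The literal linear form ``-alpha*sum(theta)``
    is kept selectable because a single-criterion phantom run can be
    phrased either way.
    """
    if hasattr(theta, "theta"):
        theta = theta.theta
    total = float(sum(theta.values())) if isinstance(theta, dict) else float(np.sum(theta))
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return 0.0
    if form == "linear":
        return -alpha * total
    if total < min_total:
        raise ValueError("sum of active weights below the singularity guard")
    return -alpha / total


def _calib_term(theta: dict, config: LossConfig) -> float:
    """Calibration loss as used in the construction objective.

    The reciprocal form is clamped at ``sum(theta) = q_min``: criterion
    scores are bounded by 1, so no surrogate can clear the selection
    threshold once the weights sum below ``q_min`` — the whole sub-``q_min``
    region is identical to the overconstrained boundary, and evaluating the
    reciprocal inside it would only reward approaching its singularity.
    """
    total = float(sum(theta.values()))
    if config.calib_form == "reciprocal":
        total = max(total, config.q_min)
    return l_calib({"_total": total}, config.alpha, form=config.calib_form)


def _as_array(x, d):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (d,):
        raise ValueError("point dimension mismatch")
    return x


def random_search(objective, bounds, n: int, seed: int = 0):
    """Uniform random search over the box; returns (best_x, best_f, trace)."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    trace = []
    for _ in range(n):
        x = rng.uniform(lo, hi)
        f = objective(x)
        trace.append((x, float(f)))
    finite = [(x, f) for x, f in trace if np.isfinite(f)]
    best_x, best_f = min(finite, key=lambda t: t[1])
    return best_x, best_f, trace


def bayes_optimize(
    objective,
    bounds,
    seed: int = 0,
    init_points: int = 8,
    n_iter: int = 500,
    kappa: float = 5.0,
    method: str = "gp",
    n_candidates: int = 256,
):
    """Gaussian-process Bayesian minimisation with a UCB-type acquisition.

    ``init_points`` uniform evaluations seed the GP; each of the ``n_iter``
    iterations refits the GP on all evaluations (inputs scaled to the unit
    box, Matern-5/2 kernel with a white-noise term for the piecewise-flat
    objective) and evaluates the candidate minimising the lower confidence
    bound ``mu - kappa*sigma`` over a seeded candidate cloud.  Deterministic
    given ``seed``.  Non-finite objective values are recorded but excluded
    from the GP with a penalty.  ``method="random"`` falls back to pure
    random search with the same total budget.

    Returns (best_x, best_f, trace) with the argmin over all evaluations.
    """
    d = len(bounds)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    span = hi - lo
    if not np.isfinite(span).all() or (span <= 0).any():
        raise ValueError("bounds must be finite with positive extent")
    if method == "random":
        return random_search(objective, bounds, init_points + n_iter, seed)

    rng = np.random.default_rng(seed)
    X: list[np.ndarray] = []
    y: list[float] = []
    trace = []

    def evaluate(x):
        f = float(objective(x))
        trace.append((x.copy(), f))
        if np.isfinite(f):
            X.append((x - lo) / span)
            y.append(f)
        else:
            warnings.warn("non-finite objective value skipped in GP")
        return f

    for _ in range(init_points):
        evaluate(rng.uniform(lo, hi))
    if not y:
        raise ValueError("objective returned no finite value on the initial design")

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-3, (1e-8, 1e1))
    for _ in range(n_iter):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, alpha=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(X), np.asarray(y))
        cand = rng.uniform(0.0, 1.0, size=(n_candidates, d))
        # local candidates around the incumbent sharpen exploitation
        inc = X[int(np.argmin(y))]
        local = np.clip(inc + rng.normal(scale=0.05, size=(n_candidates // 4, d)), 0, 1)
        cand = np.vstack([cand, local])
        mu, sigma = gp.predict(cand, return_std=True)
        lcb = mu - kappa * sigma
        evaluate(lo + cand[int(np.argmin(lcb))] * span)

    finite = [(x, f) for x, f in trace if np.isfinite(f)]
    best_x, best_f = min(finite, key=lambda t: t[1])
    return best_x, best_f, trace


def make_objective(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    labels: CohortLabels = None,
    perturbation: SeriesTable = None,
    phantom: SeriesTable = None,
    config: LossConfig = None,
    seed: int = 0,
    tensor: QualificationTensor = None,
):
    """Build the construction objective theta -> L_train + L_calib.

    The qualification tensor is computed once and closed over; because the
    qualified sets are piecewise constant in theta, the training loss is
    cached per distinct selection signature, making repeated evaluation
    (optimisation traces, random-search baselines) cheap and exactly
    reproducible.  Returns (objective over weight vectors, tensor).
    """
    config = config or LossConfig()
    if tensor is None:
        tensor = compute_tensor(
            radiome, surrogates, labels=labels, perturbation=perturbation,
            phantom=phantom, active=config.active,
        )

    cache: dict[tuple, float] = {}

    def train_loss(sets: QualifiedSurrogateSets) -> float:
        sig = sets.signature()
        if sig not in cache:
            if config.mode == "stabilisation":
                cache[sig] = l_train_stabilisation(radiome, surrogates, sets)
            else:
                cache[sig] = l_train_predictive(
                    radiome, surrogates, labels, sets, inner=config.inner, seed=seed
                )
        return cache[sig]

    def objective(vec) -> float:
        theta = config.theta_dict(vec)
        sets = select_qualified(combine_q(tensor, theta), config.q_min, valid=tensor.valid)
        try:
            return train_loss(sets) + _calib_term(theta, config)
        except ValueError:
            return np.nan

    return objective, tensor


def construct_technome(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    labels: CohortLabels = None,
    perturbation: SeriesTable = None,
    phantom: SeriesTable = None,
    config: LossConfig = None,
    seed: int = 0,
    tensor: QualificationTensor = None,
) -> tuple[TechnomeModel, OptimizationResult]:
    """Full construction loop on training data.

    The qualification tensor is computed once; the objective maps theta to
    qualified sets, evaluates the mode's training loss (cached per distinct
    selection, since many theta values induce the same sets) plus the
    calibration loss, and Bayesian optimisation picks the weights.  The
    final model is refitted at the best theta on all training rows.
    """
    config = config or LossConfig()
    objective, tensor = make_objective(
        radiome, surrogates, labels=labels, perturbation=perturbation,
        phantom=phantom, config=config, seed=seed, tensor=tensor,
    )
    best_x, best_f, trace = bayes_optimize(
        objective,
        config.bounds_list(),
        seed=seed,
        init_points=config.bo_init,
        n_iter=config.bo_iter,
        kappa=config.kappa,
    )
    best_theta = config.theta_dict(best_x)
    sets = select_qualified(combine_q(tensor, best_theta), config.q_min, valid=tensor.valid)
    lc = _calib_term(best_theta, config)
    lt = best_f - lc
    if config.mode == "stabilisation":
        final = fit_technome_stabilisation(radiome, surrogates, sets)
    else:
        final = prediction.fit_predictive(radiome, surrogates, labels, sets, "technome_glm")
    result = OptimizationResult(
        best_theta, float(best_f), float(lt), float(lc),
        [(config.theta_dict(x), f) for x, f in trace], seed,
    )
    model = TechnomeModel(config.mode, best_theta, tensor, sets, final, config)
    return model, result
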