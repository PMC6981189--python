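"""Outer evaluation harness: CV/SSD experiments, weight sweeps, discovery.

Everything here is leakage-safe by construction: qualification tensors,
surrogate means, standardisation, subset selection and the weights theta
are computed strictly on the training side of each split; held-out rows
only ever enter through ``apply``/``predict`` calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, prediction
from .optimization import LossConfig, construct_technome, TechnomeModel
from .qualification import QualifiedSurrogateSets, combine_q, compute_tensor, select_qualified
from .tables import Cohort, SeriesTable, split_train_test

__all__ = [
    "ExperimentResult",
    "SweepResult",
    "DiscoveryReport",
    "run_experiment",
    "run_baseline_suite",
    "weight_sweep",
    "discovery_report",
]


@dataclass
class ExperimentResult:
    scheme: str
    mode: str
    method: str
    fold_metrics: list
    fold_details: list = field(default_factory=list)  # per fold: dict with theta, set sizes
    fold_indices: list = field(default_factory=list)
    n_skipped: int = 0
    seed: int = 0

    @property
    def mean_metric(self) -> float:
        return float(np.mean(self.fold_metrics))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "mode": self.mode,
            "method": self.method,
            "fold_metrics": [float(m) for m in self.fold_metrics],
            "mean_metric": self.mean_metric,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
        }


def _series_pair(series) -> tuple[SeriesTable | None, SeriesTable | None]:
    if series is None:
        return None, None
    if isinstance(series, SeriesTable):
        return (series, None) if series.kind == "perturbation" else (None, series)
    return series.get("perturbation"), series.get("phantom")


def _evaluate_stabilisation(model, train: Cohort, test: Cohort) -> float:
    calibrated = calibration.apply_calibration(model, test.radiome, test.surrogates)
    return calibration.stabilisation_performance(test.radiome, calibrated)


def run_experiment(
    cohort: Cohort,
    series=None,
    config: LossConfig = None,
    scheme: str = "cv10",
    seed: int = 0,
) -> ExperimentResult:
    """Construct the technome per fold and score it on held-out rows.

    Stabilisation mode reports the mean variance reduction on test rows;
    predictive mode reports the test AUC.  Folds whose training side has a
    single class are skipped with a warning (predictive mode only).
    """
    config = config or LossConfig()
    perturbation, phantom = _series_pair(series)
    splits = split_train_test(
        cohort.n, scheme, group_ids=cohort.labels.group_ids, seed=seed, labels=cohort.labels.b
    )
    metrics, details, indices = [], [], []
    skipped = 0
    for train_idx, test_idx in splits:
        train = cohort.subset(train_idx)
        test = cohort.subset(test_idx)
        if config.mode == "predictive" and np.unique(train.labels.b).size < 2:
            warnings.warn("skipping fold with single-class training data")
            skipped += 1
            continue
        pert = perturbation.subset_rows(train_idx) if perturbation is not None else None
        model, result = construct_technome(
            train.radiome, train.surrogates, train.labels,
            perturbation=pert, phantom=phantom, config=config, seed=seed,
        )
        if config.mode == "stabilisation":
            metrics.append(_evaluate_stabilisation(model.model, train, test))
        else:
            scores = prediction.predict_proba(model.model, test.radiome, test.surrogates)
            metrics.append(prediction.auc(scores, test.labels.b))
        details.append(
            {
                "theta": model.theta,
                "set_sizes": [len(s) for s in model.sets.sets],
                "loss": result.best_loss,
            }
        )
        indices.append((train_idx, test_idx))
    return ExperimentResult(scheme, config.mode, "technome", metrics, details, indices, skipped, seed)


def run_baseline_suite(
    cohort: Cohort,
    series=None,
    scheme: str = "cv10",
    seed: int = 0,
    config: LossConfig = None,
    n_estimators: int = 500,
    methods: tuple = None,
) -> dict:
    """Head-to-head comparison of all methods under identical folds.

    Stabilisation: technome, RAVEL-like, naive GLM, naive RF.
    Predictive: those four (as classifier variants) plus the feature-only
    GLM and RF.  Every method sees exactly the same train/test indices.
    """
    config = config or LossConfig()
    perturbation, phantom = _series_pair(series)
    splits = split_train_test(
        cohort.n, scheme, group_ids=cohort.labels.group_ids, seed=seed, labels=cohort.labels.b
    )
    if methods is None:
        methods = (
            ("technome", "ravel_like", "naive_glm", "naive_rf")
            if config.mode == "stabilisation"
            else ("technome", "ravel_like_pred", "naive_glm", "naive_rf",
                  "glm_features_only", "rf_features_only")
        )
    results = {
        m: ExperimentResult(scheme, config.mode, m, [], [], [], 0, seed) for m in methods
    }
    for train_idx, test_idx in splits:
        train = cohort.subset(train_idx)
        test = cohort.subset(test_idx)
        if config.mode == "predictive" and np.unique(train.labels.b).size < 2:
            for res in results.values():
                res.n_skipped += 1
            continue
        pert = perturbation.subset_rows(train_idx) if perturbation is not None else None
        for name in methods:
            res = results[name]
            if config.mode == "stabilisation":
                if name == "technome":
                    model, _ = construct_technome(
                        train.radiome, train.surrogates, train.labels,
                        perturbation=pert, phantom=phantom, config=config, seed=seed,
                    )
                    fitted = model.model
                elif name == "ravel_like":
                    fitted = calibration.fit_ravel_like(train.radiome, train.surrogates, train.labels)
                elif name == "naive_glm":
                    fitted = calibration.fit_naive_glm(train.radiome, train.surrogates)
                elif name == "naive_rf":
                    fitted = calibration.fit_naive_rf(
                        train.radiome, train.surrogates, seed=seed, n_estimators=n_estimators
                    )
                else:
                    raise ValueError(f"unknown stabilisation method {name!r}")
                res.fold_metrics.append(_evaluate_stabilisation(fitted, train, test))
            else:
                if name == "technome":
                    model, _ = construct_technome(
                        train.radiome, train.surrogates, train.labels,
                        perturbation=pert, phantom=phantom, config=config, seed=seed,
                    )
                    fitted = model.model
                else:
                    fitted = prediction.fit_predictive(
                        train.radiome, train.surrogates, train.labels,
                        variant=name, seed=seed, n_estimators=n_estimators,
                    )
                scores = prediction.predict_proba(fitted, test.radiome, test.surrogates)
                res.fold_metrics.append(prediction.auc(scores, test.labels.b))
            res.fold_indices.append((train_idx, test_idx))
    return results


@dataclass
class SweepResult:
    samples: pd.DataFrame  # theta columns + metric, n_selected, mean_q, tag
    mode: str
    seed: int

    def region_max(self, tag: str) -> float:
        sub = self.samples[self.samples["tag"] == tag]
        return float(sub["metric"].max()) if len(sub) else float("nan")


def weight_sweep(
    cohort: Cohort,
    series=None,
    config: LossConfig = None,
    n_samples: int = 200,
    seed: int = 0,
    mode: str = "vary_theta",
    uc_fraction: float = 0.9,
    include_corners: bool = True,
) -> SweepResult:
    """Map the weight space without loss optimisation.

    One shared SSD-style train/test split per seed; for each sampled theta
    (uniform in the bounds, plus the two bound corners so the boundary
    regimes are always represented) the qualified sets are formed, the
    mode's model is fitted on training rows and scored on test rows.
    Samples are tagged OC (all sets empty: no calibration), UC (at least
    ``uc_fraction`` of surrogates selected for some feature) or
    intermediate.  ``mode="vary_qmin"`` instead holds theta at unity and
    sweeps the selection threshold.
    """
    config = config or LossConfig()
    perturbation, phantom = _series_pair(series)
    rng = np.random.default_rng(seed)
    (train_idx, test_idx), = split_train_test(
        cohort.n, "ssd", group_ids=cohort.labels.group_ids, seed=seed, labels=cohort.labels.b
    )
    train = cohort.subset(train_idx)
    test = cohort.subset(test_idx)
    pert = perturbation.subset_rows(train_idx) if perturbation is not None else None
    tensor = compute_tensor(
        train.radiome, train.surrogates, labels=train.labels,
        perturbation=pert, phantom=phantom, active=config.active,
    )
    bounds = config.bounds_list()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    if mode == "vary_theta":
        thetas = rng.uniform(lo, hi, size=(n_samples, len(bounds)))
        if include_corners:
            thetas = np.vstack([thetas, lo, hi])
        qmins = np.full(len(thetas), config.q_min)
    elif mode == "vary_qmin":
        ones = np.ones(len(bounds))
        Q1 = combine_q(tensor, config.theta_dict(ones))
        qmins = np.linspace(0.0, float(Q1.max()) * 1.05, n_samples)
        thetas = np.tile(ones, (n_samples, 1))
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")

    n_sur = train.surrogates.n_surrogates
    cache: dict[tuple, float] = {}
    rows = []
    for theta_vec, qmin in zip(thetas, qmins):
        theta = config.theta_dict(theta_vec)
        Q = combine_q(tensor, theta)
        sets = select_qualified(Q, qmin, valid=tensor.valid)
        sig = sets.signature()
        if sig not in cache:
            if config.mode == "stabilisation":
                fitted = calibration.fit_technome_stabilisation(train.radiome, train.surrogates, sets)
                metric = _evaluate_stabilisation(fitted, train, test)
            else:
                fitted = prediction.fit_predictive(
                    train.radiome, train.surrogates, train.labels, sets, "technome_glm"
                )
                scores = prediction.predict_proba(fitted, test.radiome, test.surrogates)
                metric = prediction.auc(scores, test.labels.b)
            cache[sig] = metric
        metric = cache[sig]
        selected = sets.union
        if sets.all_empty:
            tag = "OC"
        elif max(len(s) for s in sets.sets) >= uc_fraction * n_sur:
            tag = "UC"
        else:
            tag = "intermediate"
        mean_q = float(np.mean([Q[j, s].mean() for j, s in enumerate(sets.sets) if len(s)])) if not sets.all_empty else float("nan")
        row = {f"theta_{c}": theta[c] for c in theta}
        row.update(q_min=qmin, metric=metric, n_selected=len(selected), mean_q=mean_q, tag=tag)
        rows.append(row)
    return SweepResult(pd.DataFrame(rows), config.mode, seed)


@dataclass
class DiscoveryReport:
    """Per-feature readout of qualified surrogates grouped by control region.

    Control regions are ordered by the share of the feature's variance a
    refit on that CR's qualified surrogates alone explains; features whose
    qualified set is empty are reported as robust (left uncalibrated).
    """

    per_feature: dict  # feature -> list of dicts (cr, surrogates, r2_share)
    robust_features: list

    def to_markdown(self) -> str:
        lines = ["| Feature | CR | Qualified surrogates | Explained variance |",
                 "|---|---|---|---|"]
        for feat, entries in self.per_feature.items():
            for e in entries:
                lines.append(
                    f"| {feat} | {e['cr']} | {', '.join(e['surrogates'])} | {e['r2']:.3f} |"
                )
        for feat in self.robust_features:
            lines.append(f"| {feat} | - | robust to technical variation, omitted | - |")
        return "\n".join(lines)


def discovery_report(model: TechnomeModel, cohort: Cohort) -> DiscoveryReport:
    """Read the fitted technome out as a table of calibrating CRs."""
    sur = cohort.surrogates
    per_feature = {}
    robust = []
    for j, feat in enumerate(cohort.radiome.feature_names):
        idx = model.sets.sets[j]
        if len(idx) == 0:
            robust.append(feat)
            continue
        by_cr: dict[str, list[int]] = {}
        for l in idx:
            by_cr.setdefault(sur.cr_of[sur.surrogate_names[l]], []).append(int(l))
        entries = []
        for cr, cols in by_cr.items():
            single = QualifiedSurrogateSets([np.asarray(cols, dtype=int)], model.sets.q_min, None)
            one = calibration.fit_technome_stabilisation(_single_feature(cohort.radiome, j), sur, single)
            entries.append(
                {
                    "cr": cr,
                    "surrogates": [sur.surrogate_names[c] for c in cols],
                    "r2": one.fits[0].r2,
                }
            )
        entries.sort(key=lambda e: -e["r2"])
        per_feature[feat] = entries
    return DiscoveryReport(per_feature, robust)


def _single_feature(radiome, j):
    from .tables import RadiomeMatrix

    return RadiomeMatrix(
        radiome.values[:, [j]], list(radiome.patient_ids), [radiome.feature_names[j]]
    )
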