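"""Surrogate qualification: the four per-(feature, surrogate) criteria.

A control-region surrogate is admitted into a calibration only if it is
*qualified* for the feature it is meant to calibrate.  Four criteria are
scored in ``[0, 1]`` per (feature j, surrogate l) pair:

* ``invivo``   — |Pearson correlation| between feature and surrogate across
  training patients; rewards surrogates that co-vary with the feature in
  the cohort itself.
* ``insilico`` — whether that in-vivo association is re-identified when
  synthetic noise (Gaussian/Rayleigh/Poisson/Gamma, monotone levels) is
  superimposed: the level-response curves of feature and surrogate must
  correlate with the same sign as in vivo.
* ``invitro``  — |Pearson correlation| across phantom acquisitions, where
  all variation is technical by construction.
* ``orthog``   — one minus the |point-biserial correlation| between the
  surrogate and the biological label; a valid covariate must not interact
  with the biology being predicted.

The combined score ``Q_jl = sum_c theta_c * q_jl^c`` is thresholded at
``q_min`` (strict inequality, default 1.0) to yield per-feature qualified
surrogate sets.  The weights ``theta`` are tuned upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import CohortLabels, RadiomeMatrix, SeriesTable, SurrogateMatrix

__all__ = [
    "CRITERIA",
    "QualificationTensor",
    "QualificationWeights",
    "QualifiedSurrogateSets",
    "q_invivo",
    "invivo_sign",
    "q_insilico",
    "q_invitro",
    "q_orthog",
    "combine_q",
    "select_qualified",
    "compute_tensor",
]

CRITERIA = ("invivo", "insilico", "invitro", "orthog")

DEFAULT_BOUNDS = (0.01, 10.0)


def _standardise_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns (population sd); returns (z, nonconstant mask)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(x, dtype=float)
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return z, ok


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of a and columns of b.

    Zero-variance columns yield 0 by convention (no association defined).
    """
    za, oka = _standardise_columns(a)
    zb, okb = _standardise_columns(b)
    r = za.T @ zb / a.shape[0]
    r[~oka, :] = 0.0
    r[:, ~okb] = 0.0
    return np.clip(r, -1.0, 1.0)


def q_invivo(radiome: RadiomeMatrix, surrogates: SurrogateMatrix) -> np.ndarray:
    """|corr(feature, surrogate)| over (training) patients; shape (m, s)."""
    if radiome.n_patients < 3:
        raise ValueError("in-vivo qualification needs at least 3 patients")
    return np.abs(_cross_correlation(radiome.values, surrogates.values))


def invivo_sign(radiome: RadiomeMatrix, surrogates: SurrogateMatrix) -> np.ndarray:
    """Sign matrix of the in-vivo feature-surrogate correlations."""
    return np.sign(_cross_correlation(radiome.values, surrogates.values))


def _level_responses(series: SeriesTable, family: str, rows=None):
    base = series.baseline()
    recs = series.family_levels(family)
    if len(recs) < 2:
        raise ValueError(f"family {family!r} has fewer than 2 noise levels")
    sel = slice(None) if rows is None else np.asarray(rows)
    rb = base.radiome.values[sel].mean(axis=0)
    sb = base.surrogates.values[sel].mean(axis=0)
    dr = np.stack([r.radiome.values[sel].mean(axis=0) - rb for r in recs])
    ds = np.stack([r.surrogates.values[sel].mean(axis=0) - sb for r in recs])
    return dr, ds


def q_insilico(perturbation: SeriesTable, invivo_sign: np.ndarray, rows=None) -> np.ndarray:
    """Sign-gated mean |correlation| of level-response curves across families.

    For each noise family the cohort-mean deviation from the unperturbed
    baseline is computed per level; the correlation over levels between the
    feature response and the surrogate response only counts when its sign
    matches the in-vivo association (an association that flips under pure
    noise manipulation cannot be the technical one observed in vivo).
    """
    if perturbation.kind != "perturbation":
        raise ValueError("expected a perturbation series")
    families = perturbation.families
    if not families:
        raise ValueError("perturbation series contains no noise families")
    score = np.zeros_like(invivo_sign, dtype=float)
    for fam in families:
        dr, ds = _level_responses(perturbation, fam, rows)
        rho = _cross_correlation(dr, ds)
        score += np.abs(rho) * (np.sign(rho) == invivo_sign)
    return score / len(families)


def q_invitro(phantom: SeriesTable) -> np.ndarray:
    """|corr(feature, surrogate)| across phantom protocol acquisitions."""
    if phantom.kind != "phantom":
        raise ValueError("expected a phantom series")
    if len(phantom.records) < 3:
        raise ValueError("phantom qualification needs at least 3 protocol conditions")
    r = np.vstack([rec.radiome.values for rec in phantom.records])
    s = np.vstack([rec.surrogates.values for rec in phantom.records])
    return np.abs(_cross_correlation(r, s))


def q_orthog(surrogates: SurrogateMatrix, labels: CohortLabels, n_features: int = 1) -> np.ndarray:
    """1 - |point-biserial corr(surrogate, label)|, tiled over features.

    Identical for every feature; materialised per feature so all criteria
    share one tensor shape.  Constant surrogates score 1 (no association by
    convention; degenerate columns are excluded by the upstream pre-filter).
    """
    b = np.asarray(labels.b, dtype=float)
    if np.unique(b).size < 2:
        raise ValueError("orthogonality qualification needs both classes")
    pb = _cross_correlation(surrogates.values, b[:, None])[:, 0]
    return np.tile(1.0 - np.abs(pb), (n_features, 1))


@dataclass
class QualificationTensor:
    """Per-criterion score matrices, each (n_features x n_surrogates)."""

    scores: dict[str, np.ndarray]
    feature_names: list[str]
    surrogate_names: list[str]
    valid: np.ndarray = None  # surrogate columns that passed the degeneracy pre-filter

    def __post_init__(self) -> None:
        for name, mat in self.scores.items():
            if name not in CRITERIA:
                raise ValueError(f"unknown criterion {name!r}")
            if not np.isfinite(mat).all() or (mat < 0).any() or (mat > 1).any():
                raise ValueError(f"criterion {name!r} scores must be finite in [0, 1]")
        if self.valid is None:
            self.valid = np.ones(len(self.surrogate_names), dtype=bool)

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(c for c in CRITERIA if c in self.scores)

    def get(self, criterion: str) -> np.ndarray:
        return self.scores[criterion]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for crit, mat in self.scores.items():
            for j, feat in enumerate(self.feature_names):
                for l, sur in enumerate(self.surrogate_names):
                    rows.append((feat, sur, crit, mat[j, l]))
        return pd.DataFrame(rows, columns=["feature", "surrogate", "criterion", "score"])


@dataclass
class QualificationWeights:
    """Non-negative criterion weights theta with box bounds."""

    theta: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.theta.items():
            if name not in CRITERIA:
                raise ValueError(f"unknown criterion {name!r}")
            if value < 0:
                raise ValueError(f"weight for {name!r} must be non-negative")
        for name in self.theta:
            self.bounds.setdefault(name, DEFAULT_BOUNDS)

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(c for c in CRITERIA if c in self.theta)

    @property
    def total(self) -> float:
        return float(sum(self.theta.values()))


def combine_q(tensor: QualificationTensor, theta: Mapping[str, float] | QualificationWeights) -> np.ndarray:
    """Weighted sum Q = sum_c theta_c q^c over the active criteria."""
    if isinstance(theta, QualificationWeights):
        theta = theta.theta
    q = None
    for name, weight in theta.items():
        if weight < 0:
            raise ValueError("negative qualification weight")
        term = weight * tensor.get(name)
        q = term if q is None else q + term
    if q is None:
        raise ValueError("at least one active criterion required")
    return q


@dataclass
class QualifiedSurrogateSets:
    """Per-feature sets of surrogate indices with Q > q_min (strict)."""

    sets: list[np.ndarray]
    q_min: float
    Q: np.ndarray

    @property
    def union(self) -> np.ndarray:
        if not self.sets:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([s for s in self.sets] + [np.array([], dtype=int)]))

    @property
    def all_empty(self) -> bool:
        return all(len(s) == 0 for s in self.sets)

    def signature(self) -> tuple:
        """Hashable identity of the selection (for loss caching)."""
        return tuple(tuple(int(i) for i in s) for s in self.sets)


def select_qualified(Q: np.ndarray, q_min: float = 1.0, valid: np.ndarray = None) -> QualifiedSurrogateSets:
    """Strict thresholding of the combined score, per feature.

    Degenerate (zero-variance) surrogate columns are excluded regardless of
    their score via the ``valid`` mask.
    """
    if not np.isfinite(Q).all():
        raise ValueError("qualification scores must be finite")
    mask = Q > q_min
    if valid is not None:
        mask = mask & valid[None, :]
    sets = [np.nonzero(mask[j])[0] for j in range(Q.shape[0])]
    return QualifiedSurrogateSets(sets, q_min, Q)


def compute_tensor(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    labels: CohortLabels = None,
    perturbation: SeriesTable = None,
    phantom: SeriesTable = None,
    active: tuple[str, ...] = CRITERIA,
    train_rows=None,
) -> QualificationTensor:
    """Assemble the qualification tensor for the requested criteria.

    ``train_rows`` restricts cohort-derived criteria (invivo, insilico
    responses, orthog) to the training side of a split; the phantom series
    carries no patient information and is used as-is.  Degenerate surrogate
    columns score 0 on every criterion and are flagged invalid.
    """
    if train_rows is not None:
        radiome = radiome.subset_rows(train_rows)
        surrogates = surrogates.subset_rows(train_rows)
        if labels is not None:
            labels = labels.subset_rows(train_rows)
    m = radiome.n_features
    scores: dict[str, np.ndarray] = {}
    sign = None
    if "invivo" in active or "insilico" in active:
        sign = invivo_sign(radiome, surrogates)
    if "invivo" in active:
        scores["invivo"] = q_invivo(radiome, surrogates)
    if "insilico" in active:
        if perturbation is None:
            raise ValueError("insilico criterion requires a perturbation series")
        scores["insilico"] = q_insilico(perturbation, sign, rows=train_rows)
    if "invitro" in active:
        if phantom is None:
            raise ValueError("invitro criterion requires a phantom series")
        scores["invitro"] = q_invitro(phantom)
    if "orthog" in active:
        if labels is None:
            raise ValueError("orthog criterion requires labels")
        scores["orthog"] = q_orthog(surrogates, labels, n_features=m)

    valid = surrogates.values.std(axis=0) > 0
    for name in scores:
        scores[name][:, ~valid] = 0.0
    return QualificationTensor(scores, list(radiome.feature_names), list(surrogates.surrogate_names), valid)
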