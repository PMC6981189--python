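"""Ground-truth synthetic data: confounded cohorts, noise series, phantoms.

The generator emulates the statistical situation internal calibration is
built for: a per-patient latent technical factor ``t`` (think patient
cross-section driving the CT noise level) imprints on the target-ROI
features *and* on control-region surrogates, while a binary biological
label ``b`` drives the features directly and may be correlated with ``t``
(confounding).  Per row,

    t_i = rho * (2 b_i - 1) + sqrt(1 - rho^2) * N(0, 1)
    r_ij = beta_j * b_i + gamma_j * t_i + N(0, sigma_rj^2)

and the surrogate columns come in four roles:

* ``clean``   — t plus small noise: the genuine technical fingerprint
* ``noisy``   — t plus substantial noise: genuine but degraded
* ``bioleak`` — label plus noise: a decoy that leaks biology and must be
  rejected by the orthogonality criterion
* ``noise``   — pure standard-normal decoys

Because the generative model is jointly Gaussian given ``b`` with a common
class covariance, the optimal (Bayes) AUC of any column subset is known in
closed form, which anchors the validation of the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.stats import norm, skew

from .tables import Cohort, CohortLabels, RadiomeMatrix, SeriesRecord, SeriesTable, SurrogateMatrix

__all__ = [
    "SurrogateGroup",
    "SyntheticCohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_perturbation_series",
    "generate_phantom_series",
    "copd_like",
    "linear_confounding",
    "ImageFixtureSpec",
    "generate_image_fixture",
    "perturb_volume",
    "extract_fixture_features",
]

NOISE_FAMILIES = ("gamma", "gaussian", "poisson", "rayleigh")

# family-specific response slopes of noise-sensitive quantities
FAMILY_SLOPES = {"gaussian": 1.0, "rayleigh": 0.8, "poisson": 0.6, "gamma": 0.7}


@dataclass
class SurrogateGroup:
    """Surrogate layout of one control region."""

    cr: str
    n_clean: int = 0
    n_noisy: int = 0
    n_bioleak: int = 0
    n_noise: int = 0


def _default_groups() -> list[SurrogateGroup]:
    # 7 CRs x 12 surrogates; the genuine technical fingerprints sit in the
    # regions a chest/abdomen protocol would read them from
    return [
        SurrogateGroup("trachea", 1, 1, 1, 9),
        SurrogateGroup("air", 1, 1, 1, 9),
        SurrogateGroup("adipose", 1, 1, 1, 9),
        SurrogateGroup("heart", 1, 1, 1, 9),
        SurrogateGroup("liver", 0, 1, 2, 9),
        SurrogateGroup("spleen", 0, 1, 1, 10),
        SurrogateGroup("aorta", 0, 1, 1, 10),
    ]


@dataclass
class SyntheticCohortSpec:
    """Generative parameters with retrievable ground truth."""

    n_patients: int = 500
    beta_b: tuple = (0.9, 0.7)  # label loading per feature
    gamma: tuple = (3.0, 2.6)  # technical-factor loading per feature
    sigma_feature: tuple = (0.7, 0.7)
    label_p: float = 0.5
    confounding: float = 0.3  # corr(t, label), in [-1, 1]
    clean_sd: float = 0.05
    noisy_sd: float = 0.5
    bioleak_b: float = 0.4
    bioleak_t: float = 0.0
    bioleak_sd: float = 1.0
    groups: list = field(default_factory=_default_groups)
    lesions_per_patient: int = 1
    feature_names: tuple = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.confounding <= 1.0):
            raise ValueError("confounding strength must lie in [-1, 1]")
        m = len(self.beta_b)
        if len(self.gamma) != m or len(self.sigma_feature) != m:
            raise ValueError("beta_b, gamma and sigma_feature must have equal length")
        for name, val in asdict(self).items():
            if isinstance(val, (int, float)) and not np.isfinite(val):
                raise ValueError(f"non-finite spec field {name!r}")
        if self.feature_names is None:
            self.feature_names = tuple(f"LAA{910 + 40 * j}" for j in range(m))

    @property
    def n_features(self) -> int:
        return len(self.beta_b)


@dataclass
class GroundTruth:
    """What the generator knows: roles and loadings per surrogate column."""

    spec: SyntheticCohortSpec
    roles: list[str]  # per surrogate: clean | noisy | bioleak | noise
    t_loading: np.ndarray
    b_loading: np.ndarray
    noise_sd: np.ndarray
    t: np.ndarray = field(repr=False, default=None)

    def role_indices(self, *roles: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r in roles], dtype=int)

    def bayes_auc(self, which: str = "features+technical") -> float:
        """Closed-form optimal AUC of a column subset of the Gaussian model.

        Conditional on the label the design is Gaussian with common
        covariance ``v a a' + diag(noise^2)`` (v = 1 - rho^2) and mean gap
        ``delta = b_loading + 2 rho a``; the optimal linear score then has
        AUC = Phi(sqrt(delta' Sigma^-1 delta / 2)).
        """
        spec = self.spec
        a = list(spec.gamma)
        bload = list(spec.beta_b)
        noise = list(spec.sigma_feature)
        if which in ("features+technical", "all"):
            idx = self.role_indices("clean", "noisy")
            if which == "all":
                idx = np.arange(len(self.roles))
            a += list(self.t_loading[idx])
            bload += list(self.b_loading[idx])
            noise += list(self.noise_sd[idx])
        elif which != "features":
            raise ValueError(f"unknown subset {which!r}")
        a = np.asarray(a, float)
        bload = np.asarray(bload, float)
        noise = np.asarray(noise, float)
        rho = spec.confounding
        v = 1.0 - rho**2
        delta = bload + 2 * rho * a
        sigma = v * np.outer(a, a) + np.diag(noise**2)
        m2 = float(delta @ np.linalg.solve(sigma, delta))
        return float(norm.cdf(np.sqrt(m2 / 2)))

    def to_json(self, path) -> None:
        payload = {
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(self.spec).items()},
            "roles": self.roles,
            "t_loading": self.t_loading.tolist(),
            "b_loading": self.b_loading.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "bayes_auc_features": self.bayes_auc("features"),
            "bayes_auc_features_technical": self.bayes_auc("features+technical"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _surrogate_layout(spec: SyntheticCohortSpec):
    names, crs, roles, t_load, b_load, noise_sd = [], [], [], [], [], []
    for grp in spec.groups:
        k = 0
        for role, count in (("clean", grp.n_clean), ("noisy", grp.n_noisy),
                            ("bioleak", grp.n_bioleak), ("noise", grp.n_noise)):
            for _ in range(count):
                names.append(f"{grp.cr}_s{k:02d}_{role}")
                crs.append(grp.cr)
                roles.append(role)
                if role == "clean":
                    t_load.append(1.0); b_load.append(0.0); noise_sd.append(spec.clean_sd)
                elif role == "noisy":
                    t_load.append(1.0); b_load.append(0.0); noise_sd.append(spec.noisy_sd)
                elif role == "bioleak":
                    t_load.append(spec.bioleak_t); b_load.append(spec.bioleak_b); noise_sd.append(spec.bioleak_sd)
                else:
                    t_load.append(0.0); b_load.append(0.0); noise_sd.append(1.0)
                k += 1
    return names, crs, roles, np.asarray(t_load), np.asarray(b_load), np.asarray(noise_sd)


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[RadiomeMatrix, SurrogateMatrix, CohortLabels, GroundTruth]:
    """Draw one cohort; bit-identical given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    n_pat = spec.n_patients
    lp = spec.lesions_per_patient
    n = n_pat * lp
    rho = spec.confounding

    b_pat = rng.binomial(1, spec.label_p, n_pat)
    t_pat = rho * (2 * b_pat - 1) + np.sqrt(1 - rho**2) * rng.normal(size=n_pat)
    b = np.repeat(b_pat, lp)
    t = np.repeat(t_pat, lp)

    beta = np.asarray(spec.beta_b, float)
    gamma = np.asarray(spec.gamma, float)
    sig = np.asarray(spec.sigma_feature, float)
    r = b[:, None] * beta[None, :] + t[:, None] * gamma[None, :] + rng.normal(size=(n, spec.n_features)) * sig[None, :]

    names, crs, roles, t_load, b_load, noise_sd = _surrogate_layout(spec)
    s = (
        t[:, None] * t_load[None, :]
        + b[:, None] * b_load[None, :]
        + rng.normal(size=(n, len(names))) * noise_sd[None, :]
    )

    if lp == 1:
        ids = [f"p{i:04d}" for i in range(n_pat)]
        group_ids = ids
    else:
        ids = [f"p{i:04d}_l{j}" for i in range(n_pat) for j in range(lp)]
        group_ids = [f"p{i:04d}" for i in range(n_pat) for _ in range(lp)]

    radiome = RadiomeMatrix(r, ids, list(spec.feature_names))
    surrogates = SurrogateMatrix(s, ids, names, dict(zip(names, crs)))
    labels = CohortLabels(b, ids, group_ids)
    truth = GroundTruth(spec, roles, t_load, b_load, noise_sd, t=t)
    return radiome, surrogates, labels, truth


def _response_profile(truth: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Noise sensitivity per feature / surrogate column.

    Genuine technical columns co-respond with the features; decoys are
    unresponsive by construction (their association with the radiome, if
    any, is biological and noise superimposition leaves them flat).
    """
    feat = np.ones(truth.spec.n_features)
    sur = np.zeros(len(truth.roles))
    for i, role in enumerate(truth.roles):
        if role == "clean":
            sur[i] = 1.0
        elif role == "noisy":
            sur[i] = 0.8
    return feat, sur


def generate_perturbation_series(
    radiome: RadiomeMatrix,
    surrogates: SurrogateMatrix,
    truth: GroundTruth,
    families: tuple = NOISE_FAMILIES,
    n_levels: int = 5,
    response_scale: float = 1.0,
    jitter_sd: float = 0.02,
    seed: int = 0,
) -> SeriesTable:
    """In-silico noise superimposition series at feature level.

    Each family shifts the cohort mean of every responsive column linearly
    in the (monotone) noise magnitude, with a family-specific slope and a
    small per-level jitter so the level-response curves are realistically
    imperfect; unresponsive columns stay at baseline exactly.  Level 0 is
    the unperturbed baseline.
    """
    for fam in families:
        if fam not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {fam!r}")
    rng = np.random.default_rng(seed)
    feat_resp, sur_resp = _response_profile(truth)
    records = [SeriesRecord("baseline", radiome, surrogates, None, 0)]
    for fam in families:
        slope = FAMILY_SLOPES[fam]
        for level in range(1, n_levels + 1):
            mag = level / n_levels * response_scale
            shift_r = slope * mag * feat_resp + rng.normal(scale=jitter_sd * slope, size=feat_resp.size) * (feat_resp > 0)
            shift_s = slope * mag * sur_resp + rng.normal(scale=jitter_sd * slope, size=sur_resp.size) * (sur_resp > 0)
            rec = SeriesRecord(
                f"{fam}:{level}",
                RadiomeMatrix(radiome.values + shift_r[None, :], list(radiome.patient_ids), list(radiome.feature_names)),
                SurrogateMatrix(surrogates.values + shift_s[None, :], list(surrogates.patient_ids), list(surrogates.surrogate_names), dict(surrogates.cr_of)),
                fam,
                level,
            )
            records.append(rec)
    return SeriesTable("perturbation", records)


def generate_phantom_series(
    truth: GroundTruth,
    n_protocols: int = 16,
    protocol_sd: float = 1.0,
    meas_sd: float = 0.05,
    seed: int = 0,
) -> SeriesTable:
    """Protocol-varied scans of a fixed object, at feature level.

    A latent protocol severity drives features and genuine technical
    surrogates with their technical loadings; there is no biological
    variation, so decoy surrogates reduce to measurement noise.
    """
    if n_protocols < 3:
        raise ValueError("need at least 3 protocol conditions")
    rng = np.random.default_rng(seed)
    spec = truth.spec
    gamma = np.asarray(spec.gamma, float)
    names, crs, _, t_load, _, _ = _surrogate_layout(spec)
    cr_of = dict(zip(names, crs))
    out = []
    for k in range(n_protocols):
        cond = f"protocol_{k:03d}"
        p = rng.normal(scale=protocol_sd)
        r = gamma * p + rng.normal(scale=meas_sd, size=spec.n_features)
        s = t_load * p + rng.normal(scale=meas_sd, size=len(names))
        out.append(
            SeriesRecord(
                cond,
                RadiomeMatrix(r[None, :], [cond], list(spec.feature_names)),
                SurrogateMatrix(s[None, :], [cond], list(names), cr_of),
                None,
                None,
            )
        )
    return SeriesTable("phantom", out)


def copd_like(seed: int = 0, n_patients: int = 500) -> SyntheticCohortSpec:
    """Headline confounded-classification scenario.

    Two emphysema-like attenuation features carrying a moderate label
    effect on top of a strong technical factor; the label is mildly
    confounded with the technical factor (corpulent patients are both
    noisier and sicker); 7 control regions with 12 surrogates each, of
    which four are genuine clean fingerprints.
    """
    return SyntheticCohortSpec(n_patients=n_patients, seed=seed)


def linear_confounding(seed: int = 0, n_patients: int = 200) -> SyntheticCohortSpec:
    """Stabilisation scenario: pure linear technical confounding.

    No label effect on the features (beta = 0), technical loading
    gamma = 2, tight feature noise (sd 0.1) and a near-noiseless clean
    surrogate (sd 0.05): the regression on the clean surrogate should
    recover gamma and remove almost all inter-patient variance.
    """
    return SyntheticCohortSpec(
        n_patients=n_patients,
        beta_b=(0.0, 0.0),
        gamma=(2.0, 2.0),
        sigma_feature=(0.1, 0.1),
        confounding=0.0,
        clean_sd=0.05,
        groups=[
            SurrogateGroup("air", n_clean=1, n_noise=3),
            SurrogateGroup("adipose", n_noisy=1, n_noise=3),
        ],
        feature_names=("tex_var", "tex_energy"),
        seed=seed,
    )


def make_cohort(spec: SyntheticCohortSpec) -> tuple[Cohort, GroundTruth]:
    radiome, surrogates, labels, truth = generate_cohort(spec)
    return Cohort(radiome, surrogates, labels), truth


# ---------------------------------------------------------------------------
# tiny 3-D image fixtures


@dataclass
class ImageFixtureSpec:
    """A miniature CT-like volume with ROI and control-region compartments."""

    shape: tuple = (32, 32, 16)
    roi_intensity: float = 60.0  # HU-like soft tissue lesion
    air_intensity: float = -1000.0
    adipose_intensity: float = -90.0
    trachea_intensity: float = -990.0
    body_intensity: float = 40.0
    smoothing: float = 0.0  # reconstruction-kernel-like blur (voxel units)
    noise_family: str = "gaussian"
    noise_magnitude: float = 0.0
    cupping: float = 0.0  # radial low-frequency artifact amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_magnitude < 0 or self.smoothing < 0 or self.cupping < 0:
            raise ValueError("degradation magnitudes must be non-negative")


def generate_image_fixture(spec: ImageFixtureSpec) -> tuple[np.ndarray, dict]:
    """Build the volume and disjoint compartment masks (ROI + 3 CRs)."""
    nx, ny, nz = spec.shape
    vol = np.full(spec.shape, spec.body_intensity, dtype=float)
    x, y, z = np.mgrid[0:nx, 0:ny, 0:nz]

    roi = ((x - nx * 0.55) ** 2 + (y - ny * 0.55) ** 2 + ((z - nz * 0.5) * 2) ** 2) <= (nx * 0.15) ** 2
    air = (x < nx // 6) & (y < ny // 6)
    adipose = (x >= nx - nx // 5) & (y < ny // 5)
    trachea = ((x - nx * 0.25) ** 2 + (y - ny * 0.75) ** 2) <= (nx * 0.08) ** 2

    masks = {"roi": roi, "air": air & ~roi, "adipose": adipose & ~roi, "trachea": trachea & ~(roi | air | adipose)}
    vol[masks["roi"]] = spec.roi_intensity
    vol[masks["air"]] = spec.air_intensity
    vol[masks["adipose"]] = spec.adipose_intensity
    vol[masks["trachea"]] = spec.trachea_intensity

    rng = np.random.default_rng(spec.seed)
    if spec.cupping > 0:
        r2 = ((x - nx / 2) / nx) ** 2 + ((y - ny / 2) / ny) ** 2
        vol = vol + spec.cupping * r2 * 4
    if spec.smoothing > 0:
        vol = ndimage.gaussian_filter(vol, spec.smoothing)
    if spec.noise_magnitude > 0:
        vol = perturb_volume(vol, spec.noise_family, spec.noise_magnitude, rng)
    return vol, masks


def perturb_volume(volume: np.ndarray, family: str, magnitude: float, rng) -> np.ndarray:
    """Superimpose centred noise of the requested family."""
    if magnitude == 0:
        return volume.copy()
    size = volume.shape
    if family == "gaussian":
        noise = rng.normal(scale=magnitude, size=size)
    elif family == "rayleigh":
        noise = rng.rayleigh(scale=magnitude, size=size)
        noise -= magnitude * np.sqrt(np.pi / 2)
    elif family == "poisson":
        lam = max(magnitude, 1e-9)
        noise = (rng.poisson(lam, size=size) - lam) * np.sqrt(magnitude / lam)
    elif family == "gamma":
        shape_k = 2.0
        noise = rng.gamma(shape_k, magnitude / shape_k, size=size) - magnitude
    else:
        raise ValueError(f"unknown noise family {family!r}")
    return volume + noise


def _entropy_uniformity(values: np.ndarray, bins: int = 32) -> tuple[float, float]:
    hist, _ = np.histogram(values, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return entropy, uniformity


def _glcm_contrast(values_3d: np.ndarray, mask: np.ndarray, levels: int = 32) -> float:
    """Unit-offset co-occurrence contrast along the first axis, within mask."""
    v = values_3d[mask]
    lo, hi = v.min(), v.max()
    if hi == lo:
        return 0.0
    q = np.clip(((values_3d - lo) / (hi - lo) * (levels - 1)).astype(int), 0, levels - 1)
    a = mask[:-1] & mask[1:]
    if not a.any():
        return 0.0
    i = q[:-1][a].astype(float)
    j = q[1:][a].astype(float)
    return float(np.mean((i - j) ** 2))


def extract_fixture_features(volume: np.ndarray, masks: dict) -> dict:
    """Compact per-compartment feature bank (10 deterministic features)."""
    out = {}
    grad = np.linalg.norm(np.stack(np.gradient(volume)), axis=0)
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"empty mask for compartment {name!r}")
        v = volume[mask]
        entropy, uniformity = _entropy_uniformity(v)
        out[name] = {
            "mean": float(v.mean()),
            "sd": float(v.std()),
            "skewness": float(skew(v)) if v.std() > 0 else 0.0,
            "entropy": entropy,
            "uniformity": uniformity,
            "p10": float(np.percentile(v, 10)),
            "p90": float(np.percentile(v, 90)),
            "gradient_mean": float(grad[mask].mean()),
            "glcm_contrast": _glcm_contrast(volume, mask),
        }
    return out
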