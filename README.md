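# technome

Predictive internal calibration of quantitative imaging features through
qualified control-region surrogates.

## The problem

Radiomic features extracted from CT images drift with technical
conditions. Part of that drift is *reducible* — scan and reconstruction
parameters can be standardised away — but part is not: a corpulent
patient attenuates more photons than a slim one, so noise and artifact
levels differ between patients even under a fixed protocol. Features that
quantify texture are highly sensitive to exactly this kind of variation,
and a classifier trained on them can end up reading patient geometry
instead of biology.

The idea implemented here is *internal* calibration: regions with little
biological inter-patient variation — air outside the body, the trachea
lumen, subcutaneous adipose tissue, liver, spleen, heart, aorta — are
treated as **control regions** (CRs) whose features ("surrogates"
`s_il`) fingerprint the technical state of each scan. Features of the
target ROI (`r_ij`, the "radiome") can then be stabilised against, or
jointly modelled with, these surrogates.

Not every CR feature is a valid technical surrogate, so candidates are
scored by four **qualification criteria** in `[0, 1]` per (feature `j`,
surrogate `l`):

| criterion | measures |
|---|---|
| `q^inVivo` | \|corr(r_j, s_l)\| across training patients |
| `q^inSilico` | whether that association reappears under superimposed synthetic noise (Gaussian/Rayleigh/Poisson/Gamma, 5 monotone levels), with matching sign |
| `q^inVitro` | \|corr(r_j, s_l)\| across protocol-varied phantom scans (pure technical variation) |
| `q^orthog` | 1 − \|point-biserial corr(s_l, label)\| — a valid covariate must not carry the biology |

A weighted score `Q_jl(Θ) = Σ_c θ_c q_jl^c` is thresholded at
`Q_min = 1` (strict) to form per-feature qualified sets `S^q_j`. The
weights Θ are tuned by Gaussian-process Bayesian optimisation (UCB
acquisition) of

```
L(Θ) = L_train(S^q(Θ)) − α / Σ θ
```

where `L_train` is −mean R² of the per-feature calibration fits
(*stabilisation* mode) or −AUC of the surrogate-augmented logistic
regression (*predictive* mode), and the reciprocal term pushes the
weights down so that only highly qualified surrogates clear the
threshold. The fitted artifact — qualified sets, weights, and either
per-feature regressions `g_j` or the augmented classifier `f(r, s)` — is
the **technome**.

Baselines for head-to-head comparison: a RAVEL-like calibration
(principal components of all surrogates, with label protection in the
fit), a naive GLM on mRMR-ranked and AIC-selected surrogates, a naive
random forest, and feature-only GLM/RF. Validation runs group-aware
10-fold CV (9:1) or a small-sample-detectability split (SSD, 1:4 train
to test).

No clinical data ships with the package. The `synthetic` module
generates cohorts with a known generative model — label `b`, latent
technical factor `t` with `corr(t, b) = ρ` (confounding), features
`r_j = β_j b + γ_j t + ε`, and surrogate columns in four roles (clean
technical, noisy technical, biology-leaking decoy, pure noise) — plus
noise-superimposition series, phantom protocol series, and optional tiny
3-D image fixtures. Because the model is Gaussian given `b`, the optimal
AUC of any column subset is available in closed form and anchors every
downstream check.

## Worked example

```python
import technome as tn

spec = tn.synthetic.copd_like(seed=0)            # n=500, 2 features, 84 surrogates
cohort, truth = tn.synthetic.make_cohort(spec)
pert = tn.synthetic.generate_perturbation_series(
    cohort.radiome, cohort.surrogates, truth, seed=1)
phantom = tn.synthetic.generate_phantom_series(truth, seed=2)

cfg = tn.LossConfig(mode="predictive", alpha=0.2,
                    inner="cv10_inner", bo_init=8, bo_iter=50)
model, result = tn.construct_technome(
    cohort.radiome, cohort.surrogates, cohort.labels,
    perturbation=pert, phantom=phantom, config=cfg, seed=0)

print({k: round(v, 2) for k, v in model.theta.items()})
print("selected:", [model.tensor.surrogate_names[l] for l in model.sets.union][:3], "...")

test, _ = tn.synthetic.make_cohort(tn.synthetic.copd_like(seed=1000))
scores = tn.predict_proba(model.model, test.radiome, test.surrogates)
print("held-out AUC:", round(tn.auc(scores, test.labels.b), 3))
print("feature-only Bayes AUC:", round(truth.bayes_auc("features"), 3))
print("features+technical Bayes AUC:", round(truth.bayes_auc("features+technical"), 3))
```

Output:

```
{'invivo': 0.01, 'insilico': 1.38, 'invitro': 0.01, 'orthog': 0.01}
selected: ['trachea_s00_clean', 'trachea_s01_noisy', 'air_s00_clean'] ...
held-out AUC: 0.889
feature-only Bayes AUC: 0.742
features+technical Bayes AUC: 0.89
```

The optimiser puts its weight on the in-silico criterion, which on this
cohort isolates exactly the genuine technical surrogates; the resulting
classifier reaches 0.889 held-out AUC — essentially the 0.890 ceiling of
the generative model, and ~0.15 above what the features alone support
(0.742) under this confounding.

A command-line interface wraps the same pipeline
(`technome simulate | qualify | construct | calibrate | predict |
validate | sweep | discover`); every run writes a `manifest.json` so it
can be reproduced bit-identically.

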