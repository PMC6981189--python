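# Methods

## Model

Rows are patients (or lesions, grouped by patient). The generative
situation the method addresses: a binary biological label `b_i` and a
latent per-patient technical factor `t_i` (noise/artifact level driven by
patient geometry) both imprint on target-ROI features,

    r_ij = beta_j b_i + gamma_j t_i + eps_ij ,

while control-region (CR) surrogates `s_il` carry `t_i` (genuine
technical surrogates), `b_i` (invalid, biology-leaking candidates), or
nothing. Confounding means `corr(t, b) = rho != 0`: the technical factor
then mimics biological signal in-sample and corrupts generalisation.

Calibration takes two forms. **Stabilisation** (explicit): per feature,
an OLS fit of `r_j` on the centred qualified surrogates, subtracted from
the feature (`r* = r - (b0 + sum_l beta_l (s_l - mean_train(s_l)))`);
surrogate means are frozen at training time, so the correction transfers
to unseen rows. **Predictive** (implicit): an unpenalised logistic
regression on z-scored features plus the union of the qualified
surrogate sets; the classifier learns the calibration internally while
optimising discrimination.

## Qualification criteria

Scores per (feature j, surrogate l), all in [0, 1]:

* **inVivo** — |Pearson r| between feature and surrogate over training
  patients. Pearson is the default because the calibration model is
  linear; Spearman would protect against monotone nonlinearity but
  breaks the equivalence with the OLS fit being qualified for.
* **inSilico** — for each noise family (Gaussian, Rayleigh, Poisson,
  Gamma; 5 monotone magnitudes), the cohort-mean deviation of every
  column from the unperturbed baseline forms a 5-point response curve;
  the criterion is the mean over families of |corr(feature response,
  surrogate response)|, gated to zero when the response correlation's
  sign contradicts the in-vivo sign. Cohort-mean (rather than
  per-patient) responses are used: superimposed noise is an additive
  cohort-level manipulation and per-patient deviations would mostly add
  estimation noise to a 5-point curve.
* **inVitro** — |Pearson r| across phantom protocol acquisitions, where
  the imaged object is fixed and all variation is technical.
* **orthog** — `1 - |point-biserial corr(s, b)|`. The score is
  feature-independent but materialised per feature so all four criteria
  share one tensor shape and one combination rule.

Degenerate (zero-variance) columns would propagate NaNs through every
correlation; they score 0 on all criteria and are additionally excluded
from selection by a validity mask (`q_orthog` alone would score them 1).

Selection: `S^q_j = { l : Q_jl(Theta) > Q_min }` with `Q_min = 1.0`
fixed and *strict* inequality; `Q_jl = sum_c theta_c q^c_jl` over the
active criteria only. Raising any weight can only grow the sets
(monotonicity), which the suite asserts property-based.

## Loss and optimisation

`L(Theta) = L_train + L_calib` is minimised over the box
`theta_c in [0.01, 10]` per active criterion.

* `L_train` (stabilisation): −mean over features of the R² of the
  per-feature calibration fit; empty sets contribute 0.
* `L_train` (predictive): −AUC of the technome GLM on training data.
  Two evaluations exist: in-sample (default) and an inner group-aware
  10-fold CV. The headline predictive configuration uses the inner CV:
  with ~84 candidate surrogates and a few hundred rows the in-sample
  AUC of an unpenalised GLM saturates at 1.0 in the underconstrained
  regime and stops ranking selections, whereas the inner-CV AUC keeps
  penalising overfit selections using training data only.
* `L_calib = -alpha / sum(theta)` over the *active* weights (an inactive
  criterion contributes to neither `Q` nor the sum). Defaults:
  `alpha = 0.2` with all four criteria (predictive), `alpha = 0.1` with
  inVivo only (phantom-style stabilisation). The literal linear form
  `-alpha * sum(theta)` — which rewards *large* weights — is selectable
  via `calib_form="linear"` for comparison; the reciprocal form is the
  default because it is the one that favours high qualification.

**Clamp at the selection threshold.** Criterion scores are bounded by 1,
so no surrogate can clear `Q > Q_min` once `sum(theta) <= Q_min`; the
whole sub-`Q_min` region is behaviourally identical to the
overconstrained boundary. Evaluated literally there, the reciprocal term
would reward walking into its singularity (at the lower bound corner it
reaches −alpha/0.04 = −5 for alpha = 0.2, dwarfing any attainable
training loss and forcing the no-calibration solution always). The
construction objective therefore evaluates `L_calib` at
`max(sum(theta), Q_min)`. Outside the construction loop `l_calib` is the
pure reciprocal with an explicit singularity guard. Overconstrained
solutions remain reachable (any theta whose sets are empty) and are
returned as the identity calibration; the suite verifies that a
sufficiently large alpha still lands there.

**Bayesian optimisation.** Since no Bayesian-optimisation package is a
dependency, the optimiser is implemented in-package on scikit-learn's
`GaussianProcessRegressor`: inputs scaled to the unit box, Matern-5/2
kernel with a fitted white-noise term (the objective is a step function
over selection plateaus and is treated as noisy), `normalize_y`, UCB-type
acquisition `mu - kappa*sigma` minimised over a seeded uniform candidate
cloud (256 points) plus a local cloud around the incumbent. Defaults
follow the configuration used for the reference studies: 8 initial
points, 500 iterations, kappa = 5; tests and the acceptance experiments
run the budget-reduced 8+50 variant, which the suite shows beats the
median of a 500-point random search on every seed. Identical theta
vectors map to identical losses via a cache keyed on the selection
signature, which also makes trace entries exactly decomposable into
`L_train + L_calib`.

## Baselines

* **RAVEL-like**: surrogate columns are z-scored on training rows
  (standardisation before SVD is a choice; without it, high-variance
  surrogates dominate the components), the smallest number of
  right-singular components explaining ≥ 95% of training variance is
  retained, each feature is regressed on the component scores *plus the
  label* (label protection, toggleable), and only the component part is
  subtracted.
* **Naive GLM**: per feature, surrogates are ranked by correlation-based
  mRMR (MID: relevance − mean redundancy, deterministic name tie-break,
  k_max = 10) and the AIC-best subset is fitted — exhaustive enumeration
  up to 10 candidates, forward stepwise beyond. The predictive naive GLM
  uses forward-stepwise AIC over logistic fits with the features as a
  fixed base (exhaustive logistic enumeration buys nothing at this
  scale). mRMR runs per feature rather than once globally, since
  relevance is feature-specific.
* **Naive RF**: 500 trees (tests use fewer), default depth, seeded;
  regresses the feature deviation on all surrogate deviations, or
  classifies on features plus all surrogates.
* **Feature-only GLM/RF**: the uncalibrated reference points.

## Validation harness

Group-aware splits: all rows of a patient stay on one side; folds are
label-stratified at group level where possible (a choice that prevents
single-class training folds in small samples). `cv10` assigns shuffled
groups round-robin within label strata; `ssd` puts 1/5 of groups in
training. Per outer fold, everything — qualification tensors, surrogate
means, standardisation, subset selection, theta — is computed on the
training side only; the suite asserts that garbage injected into
held-out rows leaves every fitted parameter bit-identical.

Weight sweeps sample theta uniformly in the bounds on one shared SSD
split per seed (full CV per sample would add nothing to an exploratory
map), always including the two bound corners so the boundary regimes are
represented; samples are tagged OC (all sets empty), UC (≥ 90% of
surrogates selected for some feature — the regions have no canonical
numeric definition, this threshold is ours) or intermediate. The
discovery report groups each feature's qualified surrogates by CR and
orders CRs by the R² of a single-CR refit (variance attribution across
CRs sharing information is inherently ambiguous; single-CR refits are
the transparent default); features with empty sets are reported as
robust and left uncalibrated.

## Synthetic data

Defaults of the headline ("COPD-like") cohort: n = 500, two
emphysema-style attenuation features with `beta = (0.9, 0.7)`,
`gamma = (3.0, 2.6)`, feature noise sd 0.7, label prevalence 0.5,
confounding `rho = 0.3`; 7 CRs × 12 surrogates = 84 candidates: 4 clean
technical fingerprints (t + noise sd 0.05; one each in trachea, air,
adipose, heart), 7 noisy technical (sd 0.5), 8 biology-leaking decoys
(`0.4 b` + noise sd 1.0) and 65 pure-noise columns. The technical effect
is deliberately strong relative to the biological one so that the
feature-only Bayes AUC (0.742) sits well below the features+technical
ceiling (0.890) — the calibration has roughly 0.15 AUC of headroom. The
decoys' label loading is kept moderate: they must be clearly rejected by
the orthogonality criterion, yet not carry so much label signal that a
model admitting them would overshoot the features+technical ceiling and
muddy the comparison. The stabilisation preset ("linear confounding")
uses n = 200, `beta = 0`, `gamma = 2.0`, feature noise sd 0.1 and clean
surrogate noise sd 0.05, giving an analytic variance-reduction ceiling
near 0.995 and a clean target for coefficient recovery.

Perturbation series shift every responsive column's cohort mean linearly
in the noise magnitude with family-specific slopes (Gaussian 1.0,
Rayleigh 0.8, Poisson 0.6, Gamma 0.7) plus a small per-level jitter
(sd 0.02) so response curves are imperfect but monotone; decoys do not
respond at all. Phantom series draw a latent protocol severity per
acquisition that drives features and technical surrogates with their
technical loadings (16 protocols by default; measurement noise sd 0.05).

The optional 3-D image fixtures (32×32×16 volumes with ROI sphere and
air/adipose/trachea CR compartments, HU-like intensities, Gaussian
smoothing, four noise families, a radial cupping term) exist to show the
feature-level response model is the right abstraction: the compact
feature bank (mean, sd, skewness, 32-bin entropy, uniformity, 10th/90th
percentiles, gradient-magnitude mean, unit-offset co-occurrence
contrast) responds monotonically to superimposed noise exactly as the
feature-level generator assumes.

What the generator does **not** emulate: spatially non-uniform noise
(a CR far from the ROI sees different noise than the ROI itself),
feature-specific nonlinear responses to protocol changes, multi-scanner
batch structure, and non-Gaussian feature marginals. Passing tests
therefore demonstrate that the machinery — qualification, selection,
optimisation, leakage-safe evaluation — behaves correctly under the
model's assumptions, not that calibration of this size is attainable on
any particular clinical dataset.

## Numerical choices

* OLS via `lstsq` with pivoted-QR detection of rank deficiency;
  collinear surrogate columns are dropped with a warning and the fit
  repeated on the kept columns.
* Logistic fits are unpenalised (heavier regularisation would change
  what the weights Theta mean); on non-convergence — in practice
  (quasi-)separation — the fit is repeated with a small ridge and a
  warning.
* Correlations of zero-variance columns are defined as 0; AUC uses
  midranks for ties; the in-silico sign gate treats a zero in-vivo sign
  as a mismatch.
* Experiment problem sizes: 20 seeds for stochastic comparisons, 100
  seeds for coefficient recovery, 200-sample sweeps, inner-CV training
  loss at the preset scale — sized so the entire acceptance run
  completes in minutes on one core while keeping Monte-Carlo error well
  below the asserted margins.

## Known limitations

* The GP treats a piecewise-constant objective as noisy; it reliably
  finds a good plateau but the argmin within a plateau is arbitrary.
* With in-sample training AUC (the non-default option) the predictive
  loss cannot distinguish large qualified sets once separation occurs.
* `q_orthog` guards against marginal label association only; a surrogate
  interacting with the label conditionally on other covariates passes.
* The image-fixture path extracts a 10-feature bank, not a full
  radiomics library; it validates response shapes, not feature-bank
  coverage.
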