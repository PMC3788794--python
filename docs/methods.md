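# Methods

## The model

`metaoccu` fits a dynamic (multi-season) occupancy model to replicated
presence–absence surveys of a patch network. Patch *i* has a latent
occupancy state per season; between seasons an occupied patch survives with
probability `1 − ε_t` and an unoccupied one is colonised with probability
`γ_t`; within a season each of *J* surveys of an occupied patch detects the
species with probability `p_t`, while an unoccupied patch never yields a
detection (false positives are assumed impossible, which is reasonable for
a visually unmistakable species surveyed by trained observers). The model
therefore corrects the classic bias of naive occupancy — all-zero histories
at occupied patches — at the price of assuming closure within a season
(state changes only between the annual survey bouts).

The likelihood of one patch's history marginalises the latent state
sequence with a two-state forward recursion: initial vector `[ψ1, 1−ψ1]`,
transition rows `occupied → [1−ε_t, ε_t]` and `unoccupied → [γ_t, 1−γ_t]`,
and per-season emissions `Π_j p^y (1−p)^{1−y}` (occupied) or an indicator
that all non-missing detections are zero (unoccupied). Missing surveys
contribute no emission term, so partially surveyed patches retain their
information. The recursion runs in log space (`logaddexp` at season
boundaries) so long, sparse histories cannot underflow; degenerate
parameters (0 or 1) that conflict with the data yield `−inf`, never an
exception. An independent oracle, explicit enumeration of all `2^T` latent
sequences, verifies the recursion in the test suite.

## Covariates and coding

Each of ψ1, γ, ε, p is a logistic regression on up to five patch
characteristics. Coding, chosen for parsimony with ordered categories:

| covariate    | levels                    | coding                         |
|--------------|---------------------------|--------------------------------|
| size         | small / medium / large    | single numeric term 1 / 2 / 3  |
| composition  | clustered / discrete      | indicator (discrete = 1)       |
| vegetation   | none / moderate / abundant| single numeric term 1 / 2 / 3  |
| matrix       | pasture / tussock         | indicator (tussock = 1)        |
| isolation    | metres to nearest patch   | z-standardised continuous      |

The ordered-numeric coding treats a medium→large step as equal to a
small→medium step on the log-odds scale — one parameter instead of two per
three-level covariate. Isolation is standardised for optimiser
conditioning; prediction on new patches reuses the training mean/SD so the
coefficients keep their meaning. Isolation is never admitted into the ε or
p submodels (turnover events are too few to estimate it there; a
specification requesting it is rejected fast rather than failing to
converge late).

Time-varying submodels get one intercept per season (p) or per
between-season interval (γ, ε) with covariate slopes shared across years;
ψ1 is first-season occupancy and never varies. The parameter count K is
the sum over submodels of intercepts plus slopes — e.g. with the retained
covariate sets and a 3-season design, the five temporal structures have
K = 18, 19, 17, 18 and 15.

## Estimation

The summed patch log-likelihoods are maximised with L-BFGS-B on the
unconstrained log-odds scale from five fixed starts (all zeros, ±1, and
two alternating ±1 patterns; relative function tolerance 1e−10). The best
optimum is kept; failure from every start is reported as
`converged=False`, never silently dropped. Standard errors come from the
inverse observed information, computed as a central-difference Hessian of
the negative log-likelihood (step `5e−4·(1+|θ|)`; the estimates are stable
to five decimals across step sizes 1e−4 to 1e−2 on study-sized problems).
A singular information matrix flags SEs unavailable rather than raising.

AICc uses the number of patches as the sample size *n*:
`AICc = −2logL + 2K + 2K(K+1)/(n−K−1)`. Akaike weights are computed via
log-sum-exp. Candidate sets for covariate ranking hold the three non-focal
parameters at intercept-only and enumerate every non-empty covariate subset
of the focal one (31 models for ψ and γ, 15 for ε and p; the intercept-only
focal model is excluded so the sets have `2^m − 1` members, and can be
re-included by flag). A covariate is retained when its summed weight
exceeds 0.5. AICc ties are broken by fewer parameters, then label order,
for determinism.

## Validation

Predicted occupancy is scored against *naive* presence (≥1 detection in the
season's surveys). Threshold-dependent metrics — sensitivity, specificity,
correct classification rate, TSS = sensitivity + specificity − 1 — use a
threshold chosen on a 0.01-step grid as the point where sensitivity and
specificity cross (ties to the lower threshold; the 0.01 step is finer than
the two-decimal thresholds the procedure is meant to resolve). AUC uses the
Mann–Whitney formulation with ties counted half, which is exact,
tie-robust, and equals trapezoidal ROC integration on distinct scores.

k-fold cross-validation partitions patches at random (unstratified, seeded)
into k folds; each fold refits the model on the remainder, optimises the
threshold on the pooled training predictions across years, then scores the
held-out patches per year — season-1 occupancy from covariates, later
seasons via the occupancy recursion with the patch-specific γ̂, ε̂. External
validation scores season-1 predictions for an independent patch network at
a fixed threshold, overall and stratified by matrix type. Single-class
folds or strata have their threshold-dependent metrics flagged undefined
and excluded from means, with a warning.

Because the observed "truth" is naive presence, it is itself contaminated:
an occupied patch escapes detection in all *J* surveys with probability
`Π_j (1−p_j)` (about 2.6–5.8% for four surveys at p between 0.60 and 0.51),
and a correct prediction of presence there is penalised as an error. No
detectability-corrected TSS/AUC exists; every validation report therefore
carries this expected false-absence rate alongside the standard metrics so
the reader can bound the distortion.

## Synthetic-data generator

The generator draws patch networks and detection histories from exactly the
data-generating process the model assumes, with the truth returned
alongside. Defaults encode the study conditions: 289 patches with
tussock fraction 174/289; three seasons of four surveys; isolation from a
truncated normal on [10, 175] m with SD 23.8 m whose *truncated* mean is
45.5 m (the location parameter is solved numerically, since truncation at
10 m would otherwise shift the realised mean upward); covariate level
frequencies uniform (observed frequencies are not reported; they are
configurable). A `deterministic_counts` flag allocates exact category
counts for tests needing fixed composition.

Default generating coefficients put the intercepts at the reported
magnitudes — ψ1 ≈ 0.43, γ ≈ 0.27, ε ≈ 0.11 and 0.25 by interval,
p ≈ 0.60/0.51/0.53 by season — with moderate covariate effects in the
reported directions (size and tussock matrix increase occupancy,
colonisation and detection and decrease extinction; clustered composition
increases extinction and decreases detection; vegetation decreases
extinction). Effects multiply *centred* codings by default so the
intercepts remain typical-patch probabilities whatever the effect sizes;
`centred=False` applies them to the raw model codings.

What the generator does not emulate: spatially explicit dispersal
(colonisation is independent of neighbour occupancy — the fitted model has
no such term either, so this is fidelity, not a shortcut), survey-level
detection heterogeneity (weather, observer), covariate correlation
(characteristics are sampled independently), and unmodelled habitat
heterogeneity. Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to their violation in
field data.

## Problem sizes and numerical choices

The simulation studies in the test suite use 200–2000 patches per dataset
and 200 replicates for the parameter-recovery/coverage study at 500
patches — large enough that binomial noise does not dominate the 90–99%
coverage band being checked, while a full run of the suite stays fast.
Wald intervals from the observed information show the expected mild
finite-sample undercoverage for the extinction intercept (rarest event
class) at these sizes; the effect is in the data, not the Hessian, whose
standard errors are step-size stable.

Cross-validation fits omit standard errors (`compute_se=False`) since only
point predictions are scored. All randomness flows through
`numpy.random.default_rng` seeds; the same seed reproduces datasets, folds
and fits bit-identically.

## Known limitations

- Within-season closure and no false positives are assumed, as in the
  standard multi-season occupancy framework; violations bias p and ψ.
- The ordered-numeric coding constrains three-level covariate effects to be
  linear in level; a freer coding would need two parameters per covariate
  and no longer matches the intended parameter counts.
- Model selection ranks additive structures only (no interactions), and
  prediction uses the single top model, not model averaging.
- The AICc sample size is the number of patches, ignoring the effective
  information per patch (surveys × seasons); this follows standard practice
  for patch-level selection.
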