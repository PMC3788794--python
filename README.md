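# metaoccu

Dynamic (multi-season) occupancy modelling of habitat-patch metapopulations
with imperfect detection.

Many threatened species persist as metapopulations: small local populations
on discrete habitat patches (for the motivating system, lizards on
schist-rock outcrops scattered through tussock and pasture grassland) that
wink out and are re-colonised over time. Repeated presence–absence surveys
of every patch are cheap to collect but confounded by imperfect detection —
an all-zero survey history does not prove absence. `metaoccu` estimates the
metapopulation parameters from such data while modelling the detection
process explicitly, ranks the habitat covariates that drive each parameter,
and evaluates how well the resulting model predicts occupancy.

## Model

Each patch *i* carries a latent occupancy state `z_it ∈ {0,1}` that evolves
across seasons as a two-state Markov chain:

```
z_i1   ~ Bernoulli(ψ1_i)
z_it+1 ~ Bernoulli( z_it (1 − ε_ti) + (1 − z_it) γ_ti )
y_itj  ~ Bernoulli( z_it · p_ti )        for each survey j
```

where ψ1 is first-season occupancy, γ colonisation, ε extinction and p
per-survey detection. Each parameter is a logistic regression on patch
covariates (patch size, composition, vegetation cover, surrounding matrix
type, isolation distance); γ, ε and p may additionally vary between years
(year-specific intercepts, shared slopes). The latent states are
marginalised by a forward recursion and all four submodels are estimated
simultaneously by maximum likelihood. Expected occupancy propagates through
time as

```
ψ_t+1 = ψ_t (1 − ε_t) + (1 − ψ_t) γ_t
```

Model selection uses AICc (sample size = number of patches) over candidate
sets containing every covariate subset for one focal parameter at a time;
a covariate is retained when its summed Akaike weight exceeds 0.5.
Validation reports the true skill statistic (TSS), correct classification
rate and ROC AUC at a threshold chosen where sensitivity and specificity
cross, via 10-fold cross-validation and on independent data. Because
detection is imperfect, every validation report also carries the expected
false-absence rate `Π_j (1 − p_j)`.

## Worked example

```python
import metaoccu as mo

patches = mo.generate_patches(mo.SimulationConfig(n_patches=289, seed=11))
dataset, truth = mo.simulate_dataset(mo.study_truth(), patches, seed=12)

for t in range(3):
    print(f"naive occupancy season {t+1}: {mo.naive_occupancy(dataset, t):.2f}")

spec = mo.ModelSpec(
    psi=("size", "matrix"), gamma=("size", "matrix"),
    epsilon=("size", "composition", "vegetation", "matrix"),
    p=("size", "composition", "matrix"),
    epsilon_time=True, p_time=True,
)
fitted = mo.fit(dataset, spec)
print("K =", fitted.K, " -2logL = %.2f" % fitted.neg2loglik, " AICc = %.2f" % fitted.aicc)

params = mo.predict_patch_parameters(fitted, dataset.covariates)
print("mean psi1 = %.2f, mean gamma_1 = %.2f" % (params["psi1"].mean(), params["gamma_1"].mean()))
print("mean p by season:", params[["p_1", "p_2", "p_3"]].mean().round(2).tolist())
```

prints

```
naive occupancy season 1: 0.42
naive occupancy season 2: 0.52
naive occupancy season 3: 0.52
K = 18  -2logL = 3242.92  AICc = 3281.45
mean psi1 = 0.43, mean gamma_1 = 0.32
mean p by season: [0.6, 0.51, 0.54]
```

Naive occupancy (the raw fraction of patches with at least one detection)
underestimates true occupancy whenever detection is imperfect; the fitted
model separates the two, here recovering a mean first-season occupancy of
0.43 and per-survey detection probabilities near 0.5–0.6, close to the
generating values. `K = 18` counts the estimable parameters: year-specific
intercepts for the time-varying submodels plus one slope per covariate.

The same pipeline is available from a shell (`metaoccu simulate|fit|select|
temporal|validate|predict --config config.yaml`); the YAML schema is
documented in `metaoccu.config.RunConfig`.

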