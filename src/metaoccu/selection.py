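"""AICc model selection and Akaike-weight variable importance.

For each of the four parameters a candidate set contains every non-empty
additive subset of its admissible covariates (all five for psi and gamma;
isolation excluded for epsilon and p), with the other three parameters
intercept-only — 31 and 15 models respectively.  Models are ranked by AICc
with the number of patches as sample size; a covariate's importance is the
sum of Akaike weights over the candidate models that contain it, and it is
retained when that sum exceeds 0.5.  The retained covariates feed a fixed
five-model set probing which parameters vary between years.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import ALL_COVARIATES, PARAMETERS, ModelSpec
from .exceptions import DomainError, SpecError

FOCAL_COVARIATES: dict[str, tuple[str, ...]] = {
    "psi": ALL_COVARIATES,
    "gamma": ALL_COVARIATES,
    "epsilon": tuple(c for c in ALL_COVARIATES if c != "isolation"),
    "p": tuple(c for c in ALL_COVARIATES if c != "isolation"),
}

RETENTION_CUTOFF = 0.5


def aicc(neg2loglik: float, K: int, n: int) -> float:
    """Second-order (small-sample corrected) Akaike information criterion:
    ``-2logL + 2K + 2K(K+1)/(n-K-1)``."""
    if n <= K + 1:
        raise DomainError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return float(neg2loglik + 2 * K + 2 * K * (K + 1) / (n - K - 1))


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ``exp(-delta_i/2) / sum_j exp(-delta_j/2)``, computed
    stably via log-sum-exp."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    log_w = -0.5 * (a - a.min())
    return np.exp(log_w - logsumexp(log_w))


def candidate_set(
    focal: str, include_null: bool = False, covariates: tuple[str, ...] | None = None
) -> list[ModelSpec]:
    """All additive covariate subsets for one focal parameter, the other
    three parameters intercept-only and everything time-constant.

    The empty (intercept-only focal) model is excluded by default, giving
    2^m - 1 specs; ``include_null=True`` adds it back.  ``covariates``
    restricts the universe (default: every covariate admissible for the
    focal parameter).
    """
    if focal not in PARAMETERS:
        raise SpecError(f"unknown parameter {focal!r}")
    covs = FOCAL_COVARIATES[focal] if covariates is None else tuple(covariates)
    start = 0 if include_null else 1
    specs = []
    for r in range(start, len(covs) + 1):
        for subset in itertools.combinations(covs, r):
            specs.append(ModelSpec(**{focal: subset}))
    return specs


def rank_models(fits) -> pd.DataFrame:
    """Rank fitted models by AICc.

    Non-converged fits are excluded with a warning.  Ties are broken by
    fewer parameters, then by model label.  Returns a DataFrame with columns
    ``model, spec, K, neg2loglik, aicc, delta_aicc, weight``.
    """
    kept = []
    for f in fits:
        if f.converged:
            kept.append(f)
        else:
            warnings.warn(f"excluding non-converged model {f.spec.label}")
    if not kept:
        raise ValueError("no converged models to rank")
    table = pd.DataFrame(
        {
            "model": [f.spec.label for f in kept],
            "spec": [f.spec for f in kept],
            "K": [f.K for f in kept],
            "neg2loglik": [f.neg2loglik for f in kept],
            "aicc": [f.aicc for f in kept],
        }
    )
    table = table.sort_values(["aicc", "K", "model"], kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    return table


def summed_importance(ranking: pd.DataFrame, focal: str, covariate: str) -> tuple[float, bool]:
    """Summed Akaike weight of the models whose focal submodel contains the
    covariate, and whether it clears the retention cutoff (>0.5)."""
    if focal not in PARAMETERS:
        raise SpecError(f"unknown parameter {focal!r}")
    if covariate not in ALL_COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}")
    mask = [covariate in spec.covariates(focal) for spec in ranking["spec"]]
    value = float(ranking.loc[mask, "weight"].sum())
    return value, value > RETENTION_CUTOFF


def importance_table(ranking: pd.DataFrame, focal: str) -> pd.DataFrame:
    """Summed importance and retention flag for every admissible covariate of
    one focal parameter (a per-parameter column of the study's Table-1-style
    summary)."""
    rows = []
    for cov in FOCAL_COVARIATES[focal]:
        value, retained = summed_importance(ranking, focal, cov)
        rows.append((cov, value, retained))
    return pd.DataFrame(rows, columns=["covariate", "summed_weight", "retained"])


def temporal_candidate_set(retained: dict[str, list[str]]) -> list[ModelSpec]:
    """The five-model set probing temporal variation, over the retained
    covariates: {g(.) e(t) p(t)}, {g(t) e(t) p(t)}, {g(.) e(.) p(t)},
    {g(t) e(.) p(t)}, {g(.) e(.) p(.)}.  psi is first-season occupancy and
    never varies."""
    for name in PARAMETERS:
        if not retained.get(name):
            raise ValueError(f"retained covariate list for {name!r} is empty")
    base = {name: tuple(retained[name]) for name in PARAMETERS}
    structures = [
        (False, True, True),
        (True, True, True),
        (False, False, True),
        (True, False, True),
        (False, False, False),
    ]
    return [
        ModelSpec(**base, gamma_time=g, epsilon_time=e, p_time=p)
        for g, e, p in structures
    ]
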