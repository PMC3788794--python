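"""Maximum-likelihood fitting of the dynamic occupancy model.

All four submodels (psi, gamma, epsilon, p) are logistic regressions on
patch covariates, estimated simultaneously by maximising the sum over
patches of the forward-recursion log-likelihood.  Optimisation is
quasi-Newton (L-BFGS-B) on the unconstrained log-odds scale from five fixed
starting vectors; standard errors come from the inverse observed information
(central-difference Hessian) at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .data import MetapopDataset
from .design import PARAMETERS, DesignSet, ModelSpec, ParamDesign, build_design_matrices
from .exceptions import DomainError
from .likelihood import forward_log_likelihood
from .selection import aicc


def propagate_occupancy(psi_t, gamma_t, epsilon_t):
    """One step of the occupancy recursion:
    ``psi_{t+1} = psi_t (1 - epsilon_t) + (1 - psi_t) gamma_t``.

    Accepts scalars or broadcastable arrays; all arguments must lie in [0, 1].
    """
    psi_t, gamma_t, epsilon_t = (np.asarray(a, dtype=float) for a in (psi_t, gamma_t, epsilon_t))
    for name, a in (("psi_t", psi_t), ("gamma_t", gamma_t), ("epsilon_t", epsilon_t)):
        if np.isnan(a).any() or (a < 0).any() or (a > 1).any():
            raise DomainError(f"{name} must lie in [0, 1]")
    out = psi_t * (1.0 - epsilon_t) + (1.0 - psi_t) * gamma_t
    return float(out) if out.ndim == 0 else out


def occupancy_trajectory(psi1: np.ndarray, gamma: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """Season-by-season occupancy probabilities, shape (n, T), obtained by
    iterating the recursion from first-season occupancy."""
    psi1 = np.asarray(psi1, dtype=float)
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    epsilon = np.atleast_2d(np.asarray(epsilon, dtype=float))
    T = gamma.shape[1] + 1
    out = np.empty((psi1.size, T))
    out[:, 0] = psi1
    for t in range(T - 1):
        out[:, t + 1] = propagate_occupancy(out[:, t], gamma[:, t], epsilon[:, t])
    return out


def _param_block_slices(design: DesignSet) -> dict[str, slice]:
    slices, start = {}, 0
    for name in PARAMETERS:
        k = design[name].n_params
        slices[name] = slice(start, start + k)
        start += k
    return slices


def _linear_predictor(d: ParamDesign, block: np.ndarray, n_times: int) -> np.ndarray:
    """(n_patches, n_times) linear predictor; year-specific intercepts,
    shared slopes."""
    if n_times == 0 or d.n_params == 0:
        return np.zeros((d.X.shape[0], 0))
    intercepts = block[: d.n_intercepts]
    slopes = block[d.n_intercepts :]
    contrib = d.X @ slopes if slopes.size else np.zeros(d.X.shape[0])
    if d.n_intercepts == 1:
        return np.tile((intercepts[0] + contrib)[:, None], (1, n_times))
    return intercepts[None, :] + contrib[:, None]


def patch_probabilities(design: DesignSet, theta: np.ndarray) -> dict[str, np.ndarray]:
    """Back-transform a coefficient vector to per-patch probabilities:
    ``psi1`` (n,), ``gamma``/``epsilon`` (n, T-1), ``p`` (n, T)."""
    T = design.n_seasons
    slices = _param_block_slices(design)
    n_times = {"psi": 1, "gamma": T - 1, "epsilon": T - 1, "p": T}
    out = {
        name: expit(_linear_predictor(design[name], theta[slices[name]], n_times[name]))
        for name in PARAMETERS
    }
    out["psi"] = out["psi"][:, 0]
    return out


@dataclass
class FittedModel:
    """Result of one maximum-likelihood fit."""

    spec: ModelSpec
    design: DesignSet
    coefficients: np.ndarray
    neg2loglik: float
    K: int
    aicc: float
    se: np.ndarray | None
    converged: bool
    n_patches: int
    term_names: tuple[str, ...] = field(default=())

    def coefficient_table(self) -> pd.DataFrame:
        se = self.se if self.se is not None else np.full(self.K, np.nan)
        return pd.DataFrame(
            {"estimate": self.coefficients, "se": se}, index=list(self.term_names)
        )

    def summary(self) -> dict:
        return {
            "model": self.spec.label,
            "n_patches": self.n_patches,
            "K": self.K,
            "neg2loglik": self.neg2loglik,
            "aicc": self.aicc,
            "converged": self.converged,
            "se_available": self.se is not None,
        }


def _fixed_starts(k: int) -> list[np.ndarray]:
    alt = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return [np.zeros(k), np.ones(k), -np.ones(k), alt, -alt]


def observed_information(f, x: np.ndarray, step: float = 5e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``x``."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _standard_errors(nll, theta: np.ndarray) -> np.ndarray | None:
    try:
        H = observed_information(nll, theta)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if not np.isfinite(diag).all() or (diag <= 0).any():
        return None
    return np.sqrt(diag)


def fit(
    dataset: MetapopDataset,
    spec: ModelSpec,
    *,
    compute_se: bool = True,
    maxiter: int = 1000,
    ftol: float = 1e-10,
    starts: list[np.ndarray] | None = None,
) -> FittedModel:
    """Fit the dynamic occupancy model by maximum likelihood.

    Runs L-BFGS-B from five fixed starting vectors (all-zeros plus +/-1
    perturbation patterns) and keeps the best optimum.  AICc uses the number
    of patches as the sample size.  A fit that fails from every start is
    returned with ``converged=False``, never silently dropped.
    """
    if dataset.n_patches == 0:
        raise ValueError("cannot fit an empty dataset")
    design = build_design_matrices(dataset.covariates, spec, dataset.n_seasons)
    y = dataset.detections
    k = design.K

    def nll(theta: np.ndarray) -> float:
        probs = patch_probabilities(design, theta)
        ll = forward_log_likelihood(y, probs["psi"], probs["gamma"], probs["epsilon"], probs["p"])
        total = ll.sum()
        return np.inf if not np.isfinite(total) else -float(total)

    best, any_success = None, False
    for x0 in starts if starts is not None else _fixed_starts(k):
        res = minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-8},
        )
        any_success = any_success or (res.success and np.isfinite(res.fun))
        if best is None or res.fun < best.fun:
            best = res

    theta = np.asarray(best.x, dtype=float)
    converged = bool(any_success and np.isfinite(best.fun))
    se = _standard_errors(nll, theta) if (compute_se and converged) else None
    if compute_se and converged and se is None:
        warnings.warn("singular observed information: standard errors unavailable")
    neg2 = 2.0 * float(best.fun)
    return FittedModel(
        spec=spec, design=design, coefficients=theta, neg2loglik=neg2, K=k,
        aicc=aicc(neg2, k, dataset.n_patches), se=se, converged=converged,
        n_patches=dataset.n_patches, term_names=design.term_names,
    )


def predict_patch_parameters(fitted: FittedModel, patches: pd.DataFrame) -> pd.DataFrame:
    """Per-patch probabilities implied by a fitted model for (possibly new)
    patches, using the training standardisation for isolation.

    Returns a DataFrame indexed by patch id with columns ``psi1``,
    ``gamma_1..gamma_{T-1}``, ``epsilon_1..``, ``p_1..p_T``.
    """
    if not fitted.converged:
        raise ValueError("cannot predict from a non-converged fit")
    design = build_design_matrices(
        patches, fitted.spec, fitted.design.n_seasons,
        isolation_center=fitted.design.isolation_center,
    )
    probs = patch_probabilities(design, fitted.coefficients)
    T = design.n_seasons
    out = {"psi1": probs["psi"]}
    for t in range(T - 1):
        out[f"gamma_{t + 1}"] = probs["gamma"][:, t]
        out[f"epsilon_{t + 1}"] = probs["epsilon"][:, t]
    for t in range(T):
        out[f"p_{t + 1}"] = probs["p"][:, t]
    return pd.DataFrame(out, index=patches.index)


def predict_occupancy_by_season(fitted: FittedModel, patches: pd.DataFrame) -> pd.DataFrame:
    """Per-patch occupancy probability for every season, season-1 values from
    covariates and later seasons via the occupancy recursion with the
    patch-specific colonisation/extinction estimates."""
    params = predict_patch_parameters(fitted, patches)
    T = fitted.design.n_seasons
    gamma = params[[f"gamma_{t + 1}" for t in range(T - 1)]].to_numpy()
    epsilon = params[[f"epsilon_{t + 1}" for t in range(T - 1)]].to_numpy()
    traj = occupancy_trajectory(params["psi1"].to_numpy(), gamma, epsilon)
    return pd.DataFrame(
        traj, index=patches.index, columns=[f"psi_{t + 1}" for t in range(T)]
    )
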