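"""Model specifications and covariate design matrices.

Four submodels are specified on the log-odds scale: first-season occupancy
(psi), per-interval colonisation (gamma), per-interval extinction (epsilon)
and per-season detection (p).  Covariate coding:

* three-level ordered characteristics (size, vegetation) enter as a single
  numeric term coded 1/2/3 (small/none=1, medium/moderate=2, large/abundant=3);
* two-level characteristics enter as single 0/1 indicators
  (composition: clustered=0, discrete=1; matrix: pasture=0, tussock=1);
* isolation enters as a z-standardised continuous term.

A time-varying submodel receives one intercept per season (p) or per
between-season interval (gamma, epsilon) while covariate slopes are shared
across time.  psi is first-season occupancy and is always time-constant.
Isolation is never admitted into the epsilon or p submodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SpecError

ALL_COVARIATES = ("size", "composition", "vegetation", "isolation", "matrix")
PARAMETERS = ("psi", "gamma", "epsilon", "p")

ORDERED_CODES = {
    "size": {"small": 1.0, "medium": 2.0, "large": 3.0},
    "vegetation": {"none": 1.0, "moderate": 2.0, "abundant": 3.0},
}
INDICATOR_CODES = {
    "composition": {"clustered": 0.0, "discrete": 1.0},
    "matrix": {"pasture": 0.0, "tussock": 1.0},
}


def _canonical(covariates) -> tuple[str, ...]:
    covs = list(covariates)
    for c in covs:
        if c not in ALL_COVARIATES:
            raise SpecError(f"unknown covariate {c!r}; expected one of {ALL_COVARIATES}")
    return tuple(c for c in ALL_COVARIATES if c in covs)


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each submodel and which submodels vary in time."""

    psi: tuple[str, ...] = ()
    gamma: tuple[str, ...] = ()
    epsilon: tuple[str, ...] = ()
    p: tuple[str, ...] = ()
    gamma_time: bool = False
    epsilon_time: bool = False
    p_time: bool = False

    def __post_init__(self) -> None:
        for name in PARAMETERS:
            object.__setattr__(self, name, _canonical(getattr(self, name)))
        for name in ("epsilon", "p"):
            if "isolation" in getattr(self, name):
                raise SpecError(
                    f"isolation is not admitted into the {name} submodel "
                    "(too few turnover events to estimate it)"
                )

    def covariates(self, parameter: str) -> tuple[str, ...]:
        if parameter not in PARAMETERS:
            raise SpecError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)

    def time_varying(self, parameter: str) -> bool:
        if parameter == "psi":
            return False
        return getattr(self, f"{parameter}_time")

    @property
    def label(self) -> str:
        parts = []
        for name, symbol in zip(PARAMETERS, ("psi", "gamma", "epsilon", "p")):
            covs = "+".join(self.covariates(name)) or "."
            tv = "time; " if self.time_varying(name) else ""
            parts.append(f"{symbol}({tv}{covs})")
        return ", ".join(parts)

    @classmethod
    def from_config(cls, mapping: dict) -> "ModelSpec":
        """Build from a config mapping, e.g. ``{"psi": ["size", "matrix"],
        "gamma": {"covariates": ["size"], "time_varying": true}}``."""
        kwargs: dict = {}
        for name in PARAMETERS:
            block = mapping.get(name, [])
            if isinstance(block, dict):
                kwargs[name] = tuple(block.get("covariates", []))
                if name != "psi" and block.get("time_varying", False):
                    kwargs[f"{name}_time"] = True
            else:
                kwargs[name] = tuple(block)
        return cls(**kwargs)


@dataclass
class ParamDesign:
    """Design of one submodel: slope matrix plus intercept bookkeeping."""

    parameter: str
    X: np.ndarray  # (n_patches, n_slopes)
    slope_names: tuple[str, ...]
    n_intercepts: int
    time_varying: bool

    @property
    def n_params(self) -> int:
        return self.n_intercepts + len(self.slope_names)


@dataclass
class DesignSet:
    """The four submodel designs for one fitted model."""

    psi: ParamDesign
    gamma: ParamDesign
    epsilon: ParamDesign
    p: ParamDesign
    n_seasons: int
    isolation_center: tuple[float, float] | None = field(default=None)

    def __getitem__(self, parameter: str) -> ParamDesign:
        if parameter not in PARAMETERS:
            raise SpecError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)

    @property
    def K(self) -> int:
        """Total number of estimable parameters across the four submodels."""
        return sum(self[name].n_params for name in PARAMETERS)

    @property
    def term_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for param in PARAMETERS:
            d = self[param]
            if d.n_intercepts == 1:
                names.append(f"{param}:intercept")
            elif d.n_intercepts > 1:
                names.extend(f"{param}:intercept[{t + 1}]" for t in range(d.n_intercepts))
            names.extend(f"{param}:{s}" for s in d.slope_names)
        return tuple(names)


def covariate_column(
    patches: pd.DataFrame, name: str, isolation_center: tuple[float, float]
) -> np.ndarray:
    """Numeric coding of one covariate for all patches."""
    if name in ORDERED_CODES:
        codes = ORDERED_CODES[name]
    elif name in INDICATOR_CODES:
        codes = INDICATOR_CODES[name]
    elif name == "isolation":
        mean, sd = isolation_center
        return (patches["isolation_m"].to_numpy(dtype=float) - mean) / sd
    else:
        raise SpecError(f"unknown covariate {name!r}")
    try:
        return patches[name].map(codes).to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpecError(f"cannot code covariate {name!r}: {exc}") from None


def build_design_matrices(
    patches: pd.DataFrame,
    spec: ModelSpec,
    n_seasons: int,
    isolation_center: tuple[float, float] | None = None,
) -> DesignSet:
    """Construct the four design matrices for a patch covariate table.

    ``isolation_center`` fixes the (mean, sd) used to standardise isolation;
    pass the training values when building a design for new patches so the
    coding matches the fitted coefficients.
    """
    if n_seasons < 1:
        raise SpecError("need at least 1 season")
    uses_isolation = any("isolation" in spec.covariates(p) for p in PARAMETERS)
    if isolation_center is None and uses_isolation:
        iso = patches["isolation_m"].to_numpy(dtype=float)
        sd = float(iso.std(ddof=1))
        if sd == 0:
            raise SpecError("isolation has zero variance; cannot standardise")
        isolation_center = (float(iso.mean()), sd)

    designs = {}
    for param in PARAMETERS:
        covs = spec.covariates(param)
        if n_seasons == 1 and param in ("gamma", "epsilon"):
            # a single-season design has no between-season intervals
            designs[param] = ParamDesign(param, np.empty((len(patches), 0)), (), 0, False)
            continue
        cols = [covariate_column(patches, c, isolation_center) for c in covs]
        X = np.column_stack(cols) if cols else np.empty((len(patches), 0))
        if np.isnan(X).any():
            bad = [c for c, col in zip(covs, cols) if np.isnan(col).any()]
            raise SpecError(f"unknown covariate level while coding {bad} for {param}")
        if param == "psi":
            n_int = 1
        elif param == "p":
            n_int = n_seasons if spec.p_time else 1
        else:
            n_int = (n_seasons - 1) if spec.time_varying(param) else 1
        designs[param] = ParamDesign(param, X, covs, n_int, spec.time_varying(param))
    return DesignSet(
        designs["psi"], designs["gamma"], designs["epsilon"], designs["p"],
        n_seasons, isolation_center,
    )
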