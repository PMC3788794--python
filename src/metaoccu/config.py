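"""Run configuration: YAML schema shared by the CLI subcommands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import PARAMETERS, ModelSpec
from .exceptions import ConfigError
from .simulate import SimulationConfig


@dataclass
class RunConfig:
    """Parsed run configuration.

    YAML layout (all blocks optional except those a command needs)::

        seed: 1
        output_dir: out
        data:
          histories: histories.csv
          covariates: covariates.csv
        simulation:            # SimulationConfig fields
          n_patches: 289
        model:                 # ModelSpec blocks
          psi: [size, matrix]
          gamma: {covariates: [size, matrix], time_varying: false}
        selection:
          parameters: [psi, gamma, epsilon, p]
          retention_cutoff: 0.5
        temporal:              # retained covariates per parameter
          psi: [size, matrix]
          ...
        validation:
          k: 10
          threshold: 0.43
          external:
            histories: new_histories.csv
            covariates: new_covariates.csv
    """

    seed: int = 0
    output_dir: Path = Path("out")
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        seed = raw.get("seed")
        if seed is None:
            raise ConfigError("config must set a seed (all stochastic commands need one)")
        cutoff = raw.get("selection", {}).get("retention_cutoff", 0.5)
        if not 0 < cutoff < 1:
            raise ConfigError("selection.retention_cutoff must lie in (0, 1)")
        return cls(seed=int(seed), output_dir=Path(raw.get("output_dir", "out")), raw=raw)

    def block(self, name: str, required: bool = True) -> dict:
        value = self.raw.get(name)
        if value is None:
            if required:
                raise ConfigError(f"config block {name!r} is required for this command")
            return {}
        if not isinstance(value, dict):
            raise ConfigError(f"config block {name!r} must be a mapping")
        return value

    def simulation_config(self) -> SimulationConfig:
        block = dict(self.block("simulation", required=False))
        block.setdefault("seed", self.seed)
        try:
            return SimulationConfig(**block)
        except TypeError as exc:
            raise ConfigError(f"bad simulation block: {exc}") from None

    def model_spec(self) -> ModelSpec:
        return ModelSpec.from_config(self.block("model"))

    def retained_covariates(self) -> dict[str, list[str]]:
        block = self.block("temporal")
        missing = [p for p in PARAMETERS if p not in block]
        if missing:
            raise ConfigError(f"temporal block must list retained covariates for {missing}")
        return {p: list(block[p]) for p in PARAMETERS}

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
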