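"""Run configuration: model parameters plus run-level settings.

A flat YAML/JSON mapping mirrors :class:`~cisplan.pkpd.ModelParams` fields
with the run-level keys ``spacing_mm``, ``n_replicates`` and ``seed``.
Every CLI run writes its fully resolved configuration next to its outputs
so results can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pkpd import ModelParams
from .response import DEFAULT_N_REPLICATES

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    spacing_mm: float = 1.0
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        self.params.validate()
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - _PARAM_FIELDS - {"spacing_mm", "n_replicates", "seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = ModelParams(**{k: v for k, v in mapping.items() if k in _PARAM_FIELDS})
        return cls(
            params=params,
            spacing_mm=mapping.get("spacing_mm", 1.0),
            n_replicates=mapping.get("n_replicates", DEFAULT_N_REPLICATES),
            seed=mapping.get("seed", 0),
        )

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(mapping)

    def to_mapping(self) -> dict:
        out = dataclasses.asdict(self.params)
        out.update(
            spacing_mm=self.spacing_mm, n_replicates=self.n_replicates, seed=self.seed
        )
        return out

    def write_resolved(self, out_dir: str | Path, name: str = "run_config.json") -> Path:
        from . import __version__

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {"cisplan_version": __version__, **self.to_mapping()}
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path
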