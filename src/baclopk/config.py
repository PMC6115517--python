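"""Run configuration: YAML schema, validation, and the config hash recorded
in every output so a rerun with the same hash reproduces deterministic
artifacts bit-exactly."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "results"
    # initial estimates
    init_tvcl: float = 10.0
    init_tvv: float = 50.0
    init_tvka: float = 1.0
    init_omega_sd: tuple = (0.3, 0.3, 0.3)
    init_sigma: float = 0.3
    # replicate counts
    vpc_replicates: int = 500
    npde_replicates: int = 500
    bootstrap_B: int = 200
    # covariate search space: {parameter: [covariate, ...]}
    search_space: dict | None = None
    # design overrides passed to StudyDesign
    design: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_KNOWN = set(RunConfig.__dataclass_fields__)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "init_omega_sd" in raw:
        raw["init_omega_sd"] = tuple(raw["init_omega_sd"])
    cfg = RunConfig(**raw)
    if cfg.vpc_replicates < 2 or cfg.npde_replicates < 2:
        raise ValueError("replicate counts must be >= 2")
    if cfg.bootstrap_B < 2:
        raise ValueError("bootstrap_B must be >= 2")
    return cfg
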