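"""Run configuration, YAML loading with schema validation, and manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .qc import PipelineConfig

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    """Top-level configuration for CLI runs; unknown keys are rejected."""

    plasma_csv: str = ""
    csf_csv: str = ""
    out_dir: str = "silk_out"
    model: str = "three_bc_simplified"
    seed: int = 0
    n_boot: int = 1000
    mcmc_iterations: int = 200_000
    mcmc_burn_in: int = 100_000
    mcmc_chains: int = 2
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s) "
                         f"{sorted(unknown)}")
    pipe_raw = raw.pop("pipeline", {}) or {}
    pipe_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    pipe_unknown = set(pipe_raw) - pipe_known
    if pipe_unknown:
        raise ValueError(f"{path}: unknown pipeline key(s) "
                         f"{sorted(pipe_unknown)}")
    return RunConfig(pipeline=PipelineConfig(**pipe_raw), **raw)


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None):
    """Write a reproducibility manifest (config hash, seeds, versions)."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "silkdyn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
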