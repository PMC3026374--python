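"""Flat YAML run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # paths
    expression: str | None = None
    reference: str | None = None
    out_dir: str = "nsdbn_out"
    header: bool = False
    # detection
    up_cut: float = 1.2
    down_cut: float = 0.70
    up_range_lo: float = 1.0
    up_range_hi: float = 1.2
    down_range_lo: float = 0.6
    down_range_hi: float = 0.8
    grid_step: float = 0.05
    tau_max: int = 3
    # priors
    lambda_m: float = 0.3
    lambda_s: float = 2.0
    alpha: float = 1.0
    m_max: int | None = None
    min_seg_len: int = 2
    max_fan_in: int = 4
    self_loops: bool = True
    # chain
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    # synthetic
    n_genes: int = 6
    T: int = 60
    m: int = 2
    tau: int = 2
    sparsity: float = 0.2
    cpt_concentration: float = 0.02
    noise_sd: float = 0.05
    n_changes: int = 2

    def validate(self) -> "RunConfig":
        if self.burn_in >= self.iterations:
            raise ConfigError("burn_in must be smaller than iterations")
        if self.tau_max < 1:
            raise ConfigError("tau_max must be >= 1")
        if not (self.up_cut > 1 > self.down_cut > 0):
            raise ConfigError("need up_cut > 1 > down_cut > 0")
        return self


def load_config(path) -> RunConfig:
    """Load a flat key-value YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()
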