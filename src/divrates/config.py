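"""Run configuration: thresholds of the published procedure plus the
synthetic-generator settings, loadable from a flat YAML file."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .simulate import SimConfig


@dataclass
class RunConfig:
    rank: str = "family"
    rate_type: str = "total"
    monophyly_threshold: float = 0.80  # removal at >= this fraction of trees
    max_dS: float = 2.0                # saturation cutoff (strict >)
    min_bases: int = 100               # alignment floor (drop at <= this)
    welch_alpha: float = 0.05
    outlier_min_mean_rate: float = 1e-4
    outlier_max_abs_contrast: float = 2.0
    apply_monophyly: bool = True
    apply_welch: bool = True
    apply_outlier: bool = True
    apply_saturation: bool = True
    run_tree_test: bool = True
    seed: int = 0
    out_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if not (0 < self.monophyly_threshold <= 1):
            raise ValueError("monophyly_threshold must be in (0, 1]")
        if self.max_dS <= 0 or self.min_bases < 0:
            raise ValueError("invalid filter thresholds")
        if not (0 < self.welch_alpha < 1):
            raise ValueError("welch_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        return asdict(self)
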