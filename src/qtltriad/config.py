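"""Pipeline configuration: every gate and threshold in one place.

Defaults mirror the analysis conventions the pipeline implements:
MAF >= 0.5%, genome-wide significance 5e-8, 500-kb locus clumping,
1-Mb cis windows, instrument significance 1e-5, per-step BH-FDR 0.05,
HEIDI gate p > 0.05, coloc PP.H4 gate 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    maf_min: float = 0.005
    p_sig: float = 5e-8
    locus_window: int = 500_000
    cis_window: int = 1_000_000
    instr_p: float = 1e-5
    instr_fdr: float = 0.05
    prune_r2: float = 0.1
    step_fdr: float = 0.05
    heidi_alpha: float = 0.05
    heidi_p_exp: float = 1.57e-3
    heidi_r2_min: float = 0.05
    heidi_r2_max: float = 0.9
    heidi_max_snps: int = 20
    heidi_min_snps: int = 3
    keep_heidi_untestable: bool = True
    coloc_gate_enabled: bool = True
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_sd_molecular: float = 0.2
    coloc_sd_disease: float = 0.15
    pph4_gate: float = 0.5
    palindromic_eaf_band: float = 0.08
    pair_probes_after_step1: bool = True
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = {
            "maf_min": (self.maf_min, 0.0, 0.5),
            "p_sig": (self.p_sig, 0.0, 1.0),
            "instr_p": (self.instr_p, 0.0, 1.0),
            "instr_fdr": (self.instr_fdr, 0.0, 1.0),
            "step_fdr": (self.step_fdr, 0.0, 1.0),
            "heidi_alpha": (self.heidi_alpha, 0.0, 1.0),
            "heidi_p_exp": (self.heidi_p_exp, 0.0, 1.0),
            "coloc_p1": (self.coloc_p1, 0.0, 1.0),
            "coloc_p2": (self.coloc_p2, 0.0, 1.0),
            "pph4_gate": (self.pph4_gate, 0.0, 1.0),
        }
        for name, (v, lo, hi) in probs.items():
            if not (lo < v < hi or (name == "maf_min" and v == 0.0)):
                raise ConfigError(f"{name}={v} outside ({lo}, {hi})")
        if not 0.0 <= self.coloc_p12 < 1.0:
            raise ConfigError("coloc_p12 must be in [0, 1)")
        for name in ("locus_window", "cis_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.prune_r2 <= 1.0:
            raise ConfigError("prune_r2 must be in [0, 1]")
        if not 0.0 <= self.heidi_r2_min <= self.heidi_r2_max <= 1.0:
            raise ConfigError("heidi r2 band must satisfy 0 <= min <= max <= 1")
        if self.heidi_min_snps < 1 or self.heidi_max_snps < self.heidi_min_snps:
            raise ConfigError("heidi SNP caps must satisfy 1 <= min <= max")

    def heidi_kwargs(self) -> dict:
        return {
            "p_exp_max": self.heidi_p_exp,
            "r2_min": self.heidi_r2_min,
            "r2_max": self.heidi_r2_max,
            "max_snps": self.heidi_max_snps,
            "min_snps": self.heidi_min_snps,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
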