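"""Pipeline configuration with the study's decision thresholds."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and conventions for the mis-splicing pipeline.

    The mis-splicing decision surface is |dPSI| > ``dpsi_threshold`` at
    BH FDR < ``fdr_threshold``.  Microexons (miE) are SE events whose
    alternative exon is ``mie_min_len``..``mie_max_len`` nt.  RBP-motif
    proximity uses ``motif_window`` nt of flanking intron on each side of
    the exon.  delta-PSI sign convention is case - control.
    """

    dpsi_threshold: float = 0.1
    fdr_threshold: float = 0.05
    mie_min_len: int = 3
    mie_max_len: int = 33
    motif_window: int = 250
    min_coverage: int = 10
    min_samples_per_group: int = 2
    delta_sign_convention: str = "case-control"
    diff_method: str = "betabinom_lrt"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dpsi_threshold < 1:
            raise ValueError("dpsi_threshold must be in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.mie_min_len > self.mie_max_len:
            raise ValueError("mie_min_len must be <= mie_max_len")
        if self.motif_window < 0:
            raise ValueError("motif_window must be >= 0")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if self.min_samples_per_group < 2:
            raise ValueError("min_samples_per_group must be >= 2")
        if self.diff_method not in ("betabinom_lrt", "welch"):
            raise ValueError("diff_method must be 'betabinom_lrt' or 'welch'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
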