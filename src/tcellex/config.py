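"""Pipeline configuration: every stage threshold in one structured object.

The ``paper`` profile carries the published constants of the analysis this
package reimplements: 1700-gene floor, housekeeping mean >= 3, median - 3xMAD
gene-count cut, 10% mitochondrial ceiling, TPM marker gates (CD3D/CD8A >= 3,
CD4 <= 30), DEG threshold P < 0.001 with flavor-keyed mean floors (1 for
log2-TPM data, 2 for patient-centered data), top-30% stratification and
top-25% TMB pre-filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # QC (full-length flavor)
    min_genes: int = 1700
    min_hk: float = 3.0
    # QC (MAD flavor)
    mad_mult: float = 3.0
    max_mito: float = 0.10
    # marker gates (linear TPM scale)
    gate_cd3d_min: float = 3.0
    gate_cd8a_min: float = 3.0
    gate_cd4_max: float = 30.0
    gate_cd4_min: float = 3.0
    gate_cd8a_max: float = 30.0
    # DEG screen
    split_marker: str = "PDCD1"
    at_median: str = "low"  # {low, drop}
    deg_p_threshold: float = 0.001
    mean_floor: dict = field(
        default_factory=lambda: {"log2_tpm10": 1.0, "centered": 2.0}
    )
    # dynamics
    positivity_threshold: float = 0.0
    state_markers: dict = field(
        default_factory=lambda: {"CD62L": "SELL", "CD127": "IL7R", "PDCD1": "PDCD1"}
    )
    # clinical scoring
    score_target: str = "TOX"
    cd3_trio: tuple = ("CD3D", "CD3E", "CD3G")
    pseudocount: float = 1.0
    score_mode: str = "log_diff"  # {log_diff, linear_ratio}
    strat_fraction: float = 0.30
    tmb_fraction: float = 0.25
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("strat_fraction", "tmb_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ValueError(f"max_mito must lie in [0, 1]; got {self.max_mito}")
        if not 0.0 < self.deg_p_threshold < 1.0:
            raise ValueError("deg_p_threshold must lie in (0, 1)")
        if self.at_median not in ("low", "drop"):
            raise ValueError("at_median policy must be 'low' or 'drop'")
        if self.score_mode not in ("log_diff", "linear_ratio"):
            raise ValueError("score_mode must be 'log_diff' or 'linear_ratio'")
        for k, v in {"split_marker": self.split_marker, **self.state_markers}.items():
            if not v:
                raise ValueError(f"marker name for {k!r} must be non-empty")
        if not all(self.cd3_trio):
            raise ValueError("cd3_trio gene names must be non-empty")

    # -- profiles / serialization -------------------------------------------
    @classmethod
    def paper(cls) -> "PipelineConfig":
        """The printed-constants profile (also the dataclass defaults)."""
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        profile = data.pop("profile", None)
        base = asdict(cls()) if profile in (None, "paper") else asdict(cls())
        unknown = set(data) - set(base)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        base.update(data)
        if isinstance(base.get("cd3_trio"), list):
            base["cd3_trio"] = tuple(base["cd3_trio"])
        return cls(**base)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cd3_trio"] = list(d["cd3_trio"])
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def resolved(self) -> dict:
        """Plain-dict view used for run logging."""
        d = asdict(self)
        d["cd3_trio"] = list(d["cd3_trio"])
        return d
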