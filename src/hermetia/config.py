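"""Pipeline configuration with study-standard defaults.

Defaults follow the analysis settings of the study design: 1000
permutations with Bonferroni adjustment, Bray-Curtis distances, 2-D NMDS,
prevalence filtering at count >= 4 in >= 10% of samples, and a 1% relative
abundance display threshold for indicator reporting.  Unknown keys in a
config file are rejected rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    subsample_depths: list = field(default_factory=lambda: ["min", 15000, 80000])
    min_count: int = 4
    min_sample_frac: float = 0.10
    n_perm: int = 1000
    alpha: float = 0.05
    p_adjust: str = "bonferroni"
    nmds_k: int = 2
    nmds_n_starts: int = 20
    nmds_tol: float = 1e-6
    kw_alpha: float = 0.05
    lda_threshold: float = 2.0
    lda_n_boot: int = 30
    indicator_n_perm: int = 999
    report_min_rel_abund: float = 0.01
    gap_b_references: int = 50
    gap_k_max: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.kw_alpha < 1):
            raise ValueError("alpha values must be in (0, 1)")
        if self.min_count <= 0 or not (0 < self.min_sample_frac <= 1):
            raise ValueError("filter thresholds out of domain")
        if self.n_perm < 1 or self.indicator_n_perm < 1:
            raise ValueError("permutation counts must be >= 1")
        if self.nmds_k < 1 or self.nmds_n_starts < 1:
            raise ValueError("NMDS settings out of domain")
        if not (0 <= self.report_min_rel_abund < 1):
            raise ValueError("report_min_rel_abund must be in [0, 1)")
        for d in self.subsample_depths:
            if d != "min" and (not isinstance(d, int) or d <= 0):
                raise ValueError(f"invalid subsample depth {d!r}")

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: "str | Path | None" = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file and apply flag overrides; unknown keys raise."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
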