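"""Run configuration: one flat object mirroring the YAML config file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input paths.

    QC thresholds follow common chip practice (SNP missingness <= 5%,
    MAF >= 0.01, individual call rate >= 0.95, autosomes only); windows
    are fixed 1-Mb bins and regions are called where a window explains
    at least 0.5% of the SNP-explained additive variance.
    """

    trait_name: str = "trait"
    model_kind: str = "direct"  # or "maternal"
    fixed_effects: list = field(default_factory=lambda: ["sex", "dam_age"])
    covariates: list = field(default_factory=list)
    hys_column: str = "hys"
    window_size_bp: int = 1_000_000
    variance_threshold_pct: float = 0.5
    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    indiv_callrate_min: float = 0.95
    em_rounds: int = 100
    ai_tol: float = 1e-8
    max_iter: int = 50
    blend_weight: float = 0.05
    window_stat: str = "snp_variance"  # or "bv_variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("direct", "maternal"):
            raise ValueError(f"model_kind must be direct or maternal, got {self.model_kind!r}")
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        if self.variance_threshold_pct < 0:
            raise ValueError("variance_threshold_pct must be >= 0")
        for name in ("snp_missing_max", "maf_min", "indiv_callrate_min", "blend_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
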