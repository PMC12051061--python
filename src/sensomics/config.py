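"""Run configuration: one seed, all module parameters, lossless YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .correlate import CorrelationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable of the end-to-end pipeline, at the study's defaults."""

    seed: int = 0
    out_dir: str = "run"

    # synthetic scenario (ignored when user inputs are supplied)
    n_fractions: int = 50
    n_compounds: int = 300
    n_active: int = 3
    n_panelists: int = 12
    noise_sd: float = 1.0
    noise_cv: float = 0.1
    detection_limit: float = 5e4

    # optional user-supplied inputs (paths); when set, simulation is skipped
    features_path: str | None = None
    records_path: str | None = None
    category_map_path: str | None = None
    masses_path: str | None = None
    spectra_dir: str | None = None

    # NMR clustering / session design
    k_clusters: int = 7
    max_per_session: int = 7
    normalization: str = "sum"  # or "pqn"
    peak_min_height: float | None = None  # default: derived from the spectra
    integration_width: float = 0.01
    ppm_offsets: dict = field(default_factory=dict)  # per-sample manual re-referencing

    # sensory consolidation
    min_panelists: int = 2
    base_concentration: float = 3.0  # mg/L
    cluster_factors: dict = field(default_factory=dict)

    # correlation engine
    min_fractions: int = 5
    seg_min: int = 5
    seg_max: int = 9
    alpha_normality: float = 0.05
    alpha: float = 0.05
    r_min: float = 0.95
    use_adjusted: bool = True
    signed: bool = True
    top_k: int = 5
    min_count: int = 4
    gate_mode: str = "either"
    imputation: str = "feature"

    def correlation_config(self) -> CorrelationConfig:
        return CorrelationConfig(
            min_fractions=self.min_fractions,
            seg_min=self.seg_min,
            seg_max=self.seg_max,
            alpha_normality=self.alpha_normality,
            alpha=self.alpha,
            r_min=self.r_min,
            use_adjusted=self.use_adjusted,
            signed=self.signed,
            top_k=self.top_k,
            min_count=self.min_count,
            gate_mode=self.gate_mode,
            imputation=self.imputation,
        )

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**obj)
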