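"""Pipeline configuration: one declarative YAML document drives everything.

Every stochastic stage derives its seed deterministically from the global
seed via ``stage_seed(global_seed, stage)``, so each stage is independently
reproducible and a cohort is reconstructable from its config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .types import DegradationParams, RigidTransform2D

# fixed stage identifiers in the seed derivation
_STAGES = {"cohort": 1, "registration": 2, "superresolve": 3, "metrics": 4,
           "evaluate": 5, "repeat": 6}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    h = hashlib.sha256(f"{int(global_seed)}:{_STAGES[stage]}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class CohortConfig:
    subjects_per_vendor: Dict[str, int] = field(
        default_factory=lambda: {"A": 4, "B": 2, "C": 2}
    )
    n_slices: int = 16
    size_px: int = 64
    noise_sigma: float = 0.03
    blur_fwhm_px: float = 1.2
    bias_amplitude: float = 0.08
    contrast_scale: float = 0.75
    misalign_tx: float = 3.0
    misalign_theta: float = 4.0
    jitter: float = 0.25
    n_repeat_subjects: int = 9
    def degradation_defaults(self) -> DegradationParams:
        return DegradationParams(
            noise_sigma=self.noise_sigma,
            blur_fwhm_px=self.blur_fwhm_px,
            bias_amplitude=self.bias_amplitude,
            contrast_scale=self.contrast_scale,
            misalign=RigidTransform2D(),
        )


@dataclass
class RegistrationConfig:
    tol: float = 1e-4
    max_restarts: int = 3
    ncc_threshold: float = 0.95
    mode: str = "global"


@dataclass
class SRMethodConfig:
    name: str = "bicubic"            # bicubic | lanczos | espcn | srgan | tcgan
    scale: int = 2
    lanczos_a: int = 3
    base_channels: int = 32
    n_residual_blocks: int = 4
    patch_size: int = 8
    depth: int = 2
    heads: int = 2
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-3
    loss_weights: Optional[Dict[str, float]] = None


@dataclass
class MetricsConfig:
    metrics: List[str] = field(
        default_factory=lambda: ["psnr", "ssim", "perceptual", "idp"]
    )
    psi: List[float] = field(
        default_factory=lambda: [0.0, 0.10, 0.20, 0.25, 0.50, 0.75]
    )
    psnr_variant: str = "standard"
    zero_policy: str = "flag_nonzero"


@dataclass
class EvaluationConfig:
    alpha: float = 0.001
    stat_method: str = "paired_t"


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    methods: List[SRMethodConfig] = field(
        default_factory=lambda: [SRMethodConfig(name="bicubic"),
                                 SRMethodConfig(name="lanczos")]
    )
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    out_dir: str = "fieldbridge_out"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        def build(dc_cls, data):
            names = {f.name for f in fields(dc_cls)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown config keys for {dc_cls.__name__}: {sorted(unknown)}")
            return dc_cls(**data)

        d = dict(d)
        return cls(
            cohort=build(CohortConfig, d.get("cohort", {})),
            registration=build(RegistrationConfig, d.get("registration", {})),
            methods=[build(SRMethodConfig, m) for m in d.get("methods", [])]
            or [SRMethodConfig(name="bicubic"), SRMethodConfig(name="lanczos")],
            metrics=build(MetricsConfig, d.get("metrics", {})),
            evaluation=build(EvaluationConfig, d.get("evaluation", {})),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "fieldbridge_out")),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))
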