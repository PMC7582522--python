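"""Pipeline configuration with the study's printed defaults.

Defaults: detection threshold 1.75× background, 15° rotation-scan step,
classification thresholds R_max = 1.1 and α bounds 45°/135°, series-
resistance QC limit 15 MΩ, holding −85 mV, steps −150 … +50 mV in 10 mV
increments of 50 ms.  A config can be loaded from / saved to YAML; a
stable hash of its contents goes into the provenance log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionConfig
from .ephys import VoltageStepProtocol
from .synthetic import SyntheticNetworkSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    network: SyntheticNetworkSpec = field(default_factory=SyntheticNetworkSpec)
    protocol: VoltageStepProtocol = field(default_factory=VoltageStepProtocol)
    scan_step_deg: float = 15.0
    r_max_threshold: float = 1.1
    alpha_bounds_deg: tuple[float, float] = (45.0, 135.0)
    ri_threshold: float = 1.2
    normality_alpha: float = 0.05
    n_comparisons: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_bounds_deg"] = list(d["alpha_bounds_deg"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detection" in d:
            d["detection"] = DetectionConfig(**d["detection"])
        if "network" in d:
            d["network"] = SyntheticNetworkSpec(**d["network"])
        if "protocol" in d:
            d["protocol"] = VoltageStepProtocol(**d["protocol"])
        if "alpha_bounds_deg" in d:
            d["alpha_bounds_deg"] = tuple(d["alpha_bounds_deg"])
        return cls(**d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(path, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
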