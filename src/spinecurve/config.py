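"""Serialisable pipeline configuration.

One YAML document mirrors every tunable of the measurement pipeline —
detection window geometry, threshold ladder, segmenter choice, network
architecture, training recipe, phantom parameters and the global seed —
so a run is reproducible from its config file alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .detect import WindowParams
from .phantom import PhantomSpec
from .segmentation import NetworkSpec, TrainingConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    window: WindowParams = field(default_factory=WindowParams)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmenter: str = "classical"  # classical | network
    probability_threshold: float = 0.5
    expected_vertebrae: int = 17
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML-friendly: tuples -> lists
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        sub = {"window": WindowParams, "network": NetworkSpec,
               "training": TrainingConfig, "phantom": PhantomSpec}
        for name, typ in sub.items():
            if name in kw and isinstance(kw[name], dict):
                sect = dict(kw[name])
                tupled = {f.name for f in fields(typ)
                          if "tuple" in str(f.type)}
                for k in sect:
                    if k in tupled and isinstance(sect[k], list):
                        sect[k] = tuple(sect[k])
                    elif isinstance(sect[k], list):
                        sect[k] = tuple(sect[k])
                kw[name] = typ(**sect)
        return cls(**kw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
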