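"""Run configuration: a validated, nested YAML schema.

Unknown keys are rejected so typos fail loudly; every run writes its
fully-resolved configuration next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backbone: str = "efficientnet-b0"
    neck: str = "bifpn"
    channel_design: int = 3
    eca: bool = True
    hswish: bool = True
    spp: bool = True
    num_classes: int = 1
    input_side: int = 416


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total_epochs: int = 150
    freeze_epochs: int = 60
    lr_frozen: float = 1e-3
    lr_unfrozen: float = 5e-5
    batch_size: int = 8
    lr_decay: float = 0.95
    mosaic: bool = True
    lambda_noobj: float = 0.5
    ignore_threshold: float = 0.5


class DataSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    root: str = "dataset"
    train_manifest: str = "train.txt"
    test_manifest: str = "test.txt"
    anchors_file: str | None = None
    synthetic_images: int = 0
    synthetic_side: int = 416


class EvalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    conf_threshold: float = 0.5
    nms_threshold: float = 0.45
    iou_threshold: float = 0.5


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    data: DataSection = DataSection()
    eval: EvalSection = EvalSection()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def resolved_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def write_resolved(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = self.model_dump()
        payload["_meta"] = {"version": __version__,
                            "config_hash": self.resolved_hash()}
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
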