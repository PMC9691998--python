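"""The full detector: backbone + neck + heads, with the ablation
toggles of the lightweighting study and single-file checkpoints.

Ablation groups (cumulative):
    0: placeholder CSP-width backbone + PANet neck (stock-YOLOv4 stand-in)
    1: EfficientNet-b0 backbone + PANet neck
    2: + channel-reduced 3-level BiFPN neck
    3: + ECA attention on the fused levels
    4: + H-Swish neck activations
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .backbone import (BackboneConfig, CSPPlaceholderBackbone, EfficientNetB0,
                       FeaturePyramid)
from .head import (AnchorSet, HeadOutput, YoloHeads, scaled_default_anchors)
from .neck import ChannelDesign, BiFPNNeck, PANetNeck
from .postprocess import Detection, decode, diou_nms


@dataclass
class ModelConfig:
    backbone: str = "efficientnet-b0"       # efficientnet-b0 | csp-placeholder
    neck: str = "bifpn"                     # bifpn | panet
    channel_design: int = 3
    eca: bool = True
    hswish: bool = True
    spp: bool = True
    num_classes: int = 1
    input_side: int = 416
    init_seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("efficientnet-b0", "csp-placeholder"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.neck not in ("bifpn", "panet"):
            raise ValueError(f"unknown neck {self.neck!r}")
        if self.input_side % 32:
            raise ValueError("input side must be divisible by 32")

    @classmethod
    def from_ablation_group(cls, group: int, **overrides) -> "ModelConfig":
        """Build the configuration of one cumulative ablation group."""
        if group not in range(5):
            raise ValueError("ablation group must be 0..4")
        base = dict(backbone="csp-placeholder", neck="panet",
                    eca=False, hswish=False)
        if group >= 1:
            base["backbone"] = "efficientnet-b0"
        if group >= 2:
            base["neck"] = "bifpn"
        if group >= 3:
            base["eca"] = True
        if group >= 4:
            base["hswish"] = True
        base.update(overrides)
        return cls(**base)


class ConeDetector(nn.Module):
    """End-to-end detector; `forward` maps images to raw head outputs,
    `detect` adds decoding and DIoU-NMS."""

    def __init__(self, cfg: ModelConfig | None = None,
                 anchors: AnchorSet | None = None):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        nn.seed_init(self.cfg.init_seed)
        self.anchors = anchors or scaled_default_anchors(self.cfg.input_side)
        neck_act = "hswish" if self.cfg.hswish else "leaky"
        if self.cfg.backbone == "efficientnet-b0":
            self.backbone = EfficientNetB0(
                BackboneConfig(input_side=self.cfg.input_side))
            bb_channels = (40, 112, 320)
        else:
            self.backbone = CSPPlaceholderBackbone()
            bb_channels = CSPPlaceholderBackbone.WIDTHS
        if self.cfg.neck == "bifpn":
            self.neck = BiFPNNeck(bb_channels,
                                ChannelDesign(self.cfg.channel_design),
                                use_eca=self.cfg.eca, use_spp=self.cfg.spp,
                                hswish=self.cfg.hswish)
        else:
            self.neck = PANetNeck(bb_channels, use_spp=self.cfg.spp,
                                  act=neck_act)
        self.heads = YoloHeads(self.neck.out_channels, self.cfg.num_classes,
                               act=neck_act)

    def forward(self, images: Tensor | np.ndarray) -> HeadOutput:
        x = images if isinstance(images, Tensor) else Tensor(images)
        pyr = self.backbone(x)
        pyr = self.neck(pyr)
        return self.heads(pyr, self.cfg.input_side)

    def detect(self, images: np.ndarray, conf_threshold: float = 0.5,
               nms_threshold: float = 0.45) -> list[list[Detection]]:
        """Run inference on (N, 3, S, S) or (3, S, S) float images in
        [0, 1]; returns per-image suppressed detections."""
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        self.eval()
        with ag.no_grad():
            head = self.forward(arr)
        results = []
        for i in range(arr.shape[0]):
            dets = decode(head, self.anchors, conf_threshold, image_index=i)
            results.append(diou_nms(dets, nms_threshold))
        return results

    def freeze_backbone(self, frozen: bool = True):
        for p in self.backbone.parameters():
            p.requires_grad = not frozen

    def backbone_parameter_snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.backbone.named_parameters()}

    # -- checkpoints ---------------------------------------------------
    def save_checkpoint(self, path, extra: dict | None = None):
        """Single-file .npz parameter store keyed by parameter name,
        with a JSON manifest (config + key list) under `manifest`."""
        state = self.state_dict()
        manifest = {
            "format": "conedet-checkpoint-v1",
            "config": vars(self.cfg),
            "anchors": self.anchors.anchors.tolist(),
            "keys": sorted(state),
            "extra": extra or {},
        }
        np.savez(path, manifest=np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8), **state)

    @classmethod
    def load_checkpoint(cls, path) -> "ConeDetector":
        try:
            archive = np.load(path)
            manifest = json.loads(bytes(archive["manifest"]).decode())
        except Exception as exc:
            raise ValueError(f"malformed checkpoint {path}: {exc}") from exc
        if manifest.get("format") != "conedet-checkpoint-v1":
            raise ValueError(f"{path} is not a recognised checkpoint")
        cfg = ModelConfig(**manifest["config"])
        anchors = AnchorSet(np.array(manifest["anchors"]))
        model = cls(cfg, anchors)
        model.load_state_dict(
            {k: archive[k] for k in archive.files if k != "manifest"})
        return model


def images_to_batch(samples) -> np.ndarray:
    """Stack ImageSamples into a normalised (N, 3, S, S) float batch."""
    return np.stack([s.pixels.transpose(2, 0, 1).astype(np.float32) / 255.0
                     for s in samples])
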