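"""The full three-encoder segmentation network.

Each modality image passes through its own hierarchical attention encoder;
at every encoder stage the three per-modality feature maps are merged by a
gated fusion block into one pyramid level; the coarsest fused level passes
through the ASPP bottleneck; a U-Net style decoder (bilinear x2 upsampling +
3x3 convolution + ReLU, concatenating the fused skip at each level, then two
more upsampling blocks to recover full resolution) feeds a 1x1 convolution
that emits per-class logits.

Ablation switches mirror the architecture study: ``use_nvt=False`` replaces
attention blocks with convolutional blocks, ``use_mgf=False`` replaces gated
fusion with concatenation + 1x1 projection, ``use_aspp=False`` replaces the
bottleneck with a single 3x3 convolution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .aspp import Aspp, AsppConfig, DEFAULT_RATES
from .autodiff import Tensor, bilinear_resize, concat
from .encoder import Encoder, EncoderConfig
from .errors import ShapeError
from .fusion import ConcatFusion, GatedFusion
from .nn import Conv2d, Module, ModuleList
from .vocab import NUM_CLASSES


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = EncoderConfig()
    num_classes: int = NUM_CLASSES
    aspp_rates: tuple = DEFAULT_RATES
    use_mgf: bool = True
    use_nvt: bool = True
    use_aspp: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class SegmentationOutput:
    logits: Tensor   # (B, num_classes, H, W)
    probs: Tensor    # softmax over the class axis

    @property
    def num_classes(self) -> int:
        return self.logits.shape[1]


class _UpBlock(Module):
    """Bilinear x2 upsampling, optional skip concatenation, 3x3 conv + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv = Conv2d(in_channels, out_channels, 3, rng, padding=1)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        B, C, H, W = x.shape
        up = bilinear_resize(x, 2 * H, 2 * W)
        if skip is not None:
            up = concat([up, skip], axis=1)
        return self.conv(up).relu()


class MultiModalSegNet(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc_cfg = cfg.encoder
        self.encoders = ModuleList(
            Encoder(enc_cfg, rng, use_attention=cfg.use_nvt) for _ in range(3))
        dims = [enc_cfg.stage_channels(s) for s in (1, 2, 3)]
        if cfg.use_mgf:
            self.fusions = ModuleList(GatedFusion(d, rng) for d in dims)
        else:
            self.fusions = ModuleList(ConcatFusion(d, rng) for d in dims)
        e4, e8, e16 = dims
        if cfg.use_aspp:
            self.bottleneck = Aspp(AsppConfig(e16, e16, cfg.aspp_rates), rng)
        else:
            self.bottleneck = Conv2d(e16, e16, 3, rng, padding=1)
        self.up1 = _UpBlock(e16 + e8, e8, rng)
        self.up2 = _UpBlock(e8 + e4, e4, rng)
        mid = max(e4 // 2, 8)
        self.up3 = _UpBlock(e4, mid, rng)
        self.up4 = _UpBlock(mid, mid, rng)
        self.head = Conv2d(mid, cfg.num_classes, 1, rng)

    def forward(self, x1: Tensor, x2: Tensor, x3: Tensor) -> SegmentationOutput:
        for idx, x in enumerate((x2, x3), start=2):
            if x.shape != x1.shape:
                raise ShapeError(
                    f"modality {idx} input {x.shape} does not match modality 1 {x1.shape}")
        pyramids = [enc(x) for enc, x in zip(self.encoders, (x1, x2, x3))]
        fused = [self.fusions[s](*(p.levels()[s] for p in pyramids)) for s in range(3)]
        f4, f8, f16 = fused
        b = self.bottleneck(f16)
        if not self.cfg.use_aspp:
            b = b.relu()
        d = self.up1(b, f8)
        d = self.up2(d, f4)
        d = self.up4(self.up3(d))
        logits = self.head(d)
        probs = logits.softmax(axis=1)
        return SegmentationOutput(logits=logits, probs=probs)


def predict_labels(out: SegmentationOutput) -> np.ndarray:
    """Per-pixel argmax over classes; ties break toward the lowest class index."""
    return np.argmax(out.probs.data, axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# checkpointing: one .npz parameter archive + a YAML sidecar with the config


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    d["encoder"]["depths"] = list(d["encoder"]["depths"])
    d["encoder"]["num_heads"] = list(d["encoder"]["num_heads"])
    d["aspp_rates"] = list(d["aspp_rates"])
    return d


def config_hash(cfg: ModelConfig) -> str:
    return hashlib.sha256(json.dumps(_config_dict(cfg), sort_keys=True).encode()).hexdigest()


def config_from_dict(d: dict) -> ModelConfig:
    enc = d["encoder"]
    encoder = EncoderConfig(
        in_channels=enc["in_channels"], embed_dim=enc["embed_dim"],
        depths=tuple(enc["depths"]), num_heads=tuple(enc["num_heads"]),
        neighborhood_size=enc["neighborhood_size"], mlp_ratio=enc["mlp_ratio"],
        seed=enc["seed"])
    return ModelConfig(
        encoder=encoder, num_classes=d["num_classes"],
        aspp_rates=tuple(d["aspp_rates"]), use_mgf=d["use_mgf"],
        use_nvt=d["use_nvt"], use_aspp=d["use_aspp"], seed=d["seed"])


def save_checkpoint(model: MultiModalSegNet, path, extra: dict | None = None) -> Path:
    path = Path(path)
    arrays = {f"param/{n}": a for n, a in model.state_dict().items()}
    for key, value in (extra or {}).items():
        arrays[f"extra/{key}"] = np.asarray(value)
    np.savez(path, **arrays)
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {"model": _config_dict(model.cfg), "config_hash": config_hash(model.cfg)}
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))
    return path


def load_checkpoint(path) -> tuple[MultiModalSegNet, dict]:
    path = Path(path)
    sidecar = yaml.safe_load(Path(str(path) + ".yaml").read_text())
    cfg = config_from_dict(sidecar["model"])
    if config_hash(cfg) != sidecar["config_hash"]:
        raise ValueError("checkpoint config hash mismatch: sidecar was edited or corrupted")
    with np.load(path) as archive:
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
        extra = {k[len("extra/"):]: archive[k] for k in archive.files if k.startswith("extra/")}
    model = MultiModalSegNet(cfg)
    model.load_state_dict(state)
    return model, extra
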