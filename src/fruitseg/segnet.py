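"""Encoder-decoder binary segmentation network with an ASPP head.

The architecture follows the standard dilated-convolution design for
semantic segmentation: a strided residual encoder extracts features at
reduced resolution, an atrous spatial pyramid pooling (ASPP) head resamples
them with parallel dilated convolutions at several rates, a 1x1
convolution maps the concatenated pyramid to two class channels (fruit /
background), and bilinear upsampling restores input resolution.

Two backbones are available: ``tiny`` (a stem plus three residual
blocks, stride 4) sized so training converges in seconds on one CPU
core, and ``resnet18-style`` (an 18-layer-style residual encoder of the
same block type, stride 8) for larger runs.  The classifier is always 2-class; a
weight file may initialize every layer except the final classifier,
which mirrors replacing the classification head of a pretrained network
when transferring to the binary fruit task.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .nn import Adam, BilinearUpsample, Conv2d, ReLU, softmax_cross_entropy
from .samples import LabeledSample, as_rgb_image

BACKBONES = ("tiny", "resnet18-style")


@dataclass(frozen=True)
class NetworkConfig:
    backbone: str = "tiny"
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    num_classes: int = 2
    input_size: tuple[int, int] = (64, 64)
    pretrained_weights: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes != 2:
            raise ValueError("num_classes is fixed at 2 (fruit vs background)")
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        rates = tuple(self.aspp_rates)
        if len(rates) == 0 or any(
            b <= a for a, b in zip(rates, rates[1:])
        ):
            raise ValueError("aspp_rates must be non-empty and strictly increasing")


@dataclass(frozen=True)
class TrainHyperparams:
    epochs: int = 8
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss: str = "pixelwise-cross-entropy"
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss != "pixelwise-cross-entropy":
            raise ValueError("only pixelwise-cross-entropy is supported")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


class _ResBlock:
    """Two 3x3 convolutions with a (projected) identity shortcut."""

    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.proj = (
            Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            if (stride != 1 or in_ch != out_ch)
            else None
        )
        self.relu2 = ReLU()

    def forward(self, x):
        s = self.proj.forward(x) if self.proj else x
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(y + s)

    def backward(self, g):
        g = self.relu2.backward(g)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        gs = self.proj.backward(g) if self.proj else g
        return gx + gs

    def layers(self):
        out = [self.conv1, self.conv2]
        if self.proj:
            out.append(self.proj)
        return out


_BACKBONE_PLANS = {
    # stem channels, then (out_ch, stride, n_blocks) per stage.
    # tiny runs at overall stride 4: at 64x64 desk resolution a fruit body
    # is only ~15 px across, and stride 8 leaves too little spatial detail
    # for accurate boundaries.
    "tiny": (16, [(24, 2, 1), (32, 1, 1), (32, 1, 1)]),
    "resnet18-style": (32, [(32, 1, 2), (64, 2, 2), (128, 2, 2), (128, 1, 2)]),
}


class SegNet:
    """The full forward/backward graph; owned by a :class:`TrainedModel`."""

    def __init__(self, config: NetworkConfig):
        rng = np.random.default_rng(config.seed)
        stem_ch, plan = _BACKBONE_PLANS[config.backbone]
        self.stem = Conv2d(3, stem_ch, 3, stride=2, rng=rng)
        self.stem_relu = ReLU()
        self.blocks: list[_ResBlock] = []
        ch = stem_ch
        for out_ch, stride, n in plan:
            for i in range(n):
                self.blocks.append(_ResBlock(ch, out_ch, stride if i == 0 else 1, rng))
                ch = out_ch
        branch_ch = max(ch // 2, 8)
        self.aspp = [
            (Conv2d(ch, branch_ch, 3, dilation=r, rng=rng), ReLU())
            for r in config.aspp_rates
        ]
        self.head = Conv2d(branch_ch * len(self.aspp), config.num_classes, 1, rng=rng)
        self.upsample = BilinearUpsample(config.input_size)
        self.config = config

    # -- graph execution -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N,3,H,W) float32 -> (N,2,H,W) logits at input resolution."""
        h = self.stem_relu.forward(self.stem.forward(x))
        for blk in self.blocks:
            h = blk.forward(h)
        feats = [relu.forward(conv.forward(h)) for conv, relu in self.aspp]
        self._split = [f.shape[1] for f in feats]
        cat = np.concatenate(feats, axis=1)
        logits = self.head.forward(cat)
        self.upsample.out_hw = x.shape[2:]
        return self.upsample.forward(logits)

    def backward(self, grad: np.ndarray) -> None:
        g = self.upsample.backward(grad)
        g = self.head.backward(g)
        gs = np.split(g, np.cumsum(self._split)[:-1], axis=1)
        gh = None
        for (conv, relu), gb in zip(self.aspp, gs):
            gi = conv.backward(relu.backward(gb))
            gh = gi if gh is None else gh + gi
        for blk in reversed(self.blocks):
            gh = blk.backward(gh)
        self.stem.backward(self.stem_relu.backward(gh))

    # -- parameters -------------------------------------------------------
    def conv_layers(self) -> list[Conv2d]:
        out = [self.stem]
        for blk in self.blocks:
            out.extend(blk.layers())
        out.extend(conv for conv, _ in self.aspp)
        out.append(self.head)
        return out

    def param_slots(self):
        return [(name, layer) for layer in self.conv_layers() for name in ("W", "b")]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i:02d}.{name}": getattr(layer, name).copy()
            for i, layer in enumerate(self.conv_layers())
            for name in ("W", "b")
        }

    def load_state_dict(self, state: dict, skip_head: bool = False) -> None:
        layers = self.conv_layers()
        for i, layer in enumerate(layers):
            if skip_head and layer is self.head:
                continue
            for name in ("W", "b"):
                arr = np.asarray(state[f"layer{i:02d}.{name}"], dtype=np.float32)
                if arr.shape != getattr(layer, name).shape:
                    raise ValueError(
                        f"incompatible weights for layer{i:02d}.{name}: "
                        f"{arr.shape} vs {getattr(layer, name).shape}"
                    )
                setattr(layer, name, arr.copy())
                setattr(layer, "d" + name, np.zeros_like(arr))


@dataclass
class TrainedModel:
    """Network weights plus the stage configuration that produced them."""

    config: NetworkConfig
    net: SegNet
    stage_tag: str = "manual"
    training_manifest_hash: str = ""
    trained: bool = False
    history: list = field(default_factory=list)

    def copy(self) -> "TrainedModel":
        m = build_model(self.config)
        m.net.load_state_dict(self.net.state_dict())
        m.stage_tag = self.stage_tag
        m.training_manifest_hash = self.training_manifest_hash
        m.trained = self.trained
        return m


def build_model(config: NetworkConfig) -> TrainedModel:
    """Construct an untrained model; optionally seed the encoder from a
    weight file (the final 2-channel classifier always starts fresh)."""
    net = SegNet(config)
    if config.pretrained_weights is not None:
        path = Path(config.pretrained_weights)
        if not path.exists():
            raise FileNotFoundError(f"pretrained weights not found: {path}")
        with np.load(path) as npz:
            net.load_state_dict(dict(npz), skip_head=True)
    return TrainedModel(config=config, net=net)


def _prepare_arrays(
    dataset: Sequence[LabeledSample], input_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples as float32 NCHW in [-0.5, 0.5] plus int targets,
    resizing (bilinear image / nearest mask) when sizes differ."""
    xs, ys = [], []
    th, tw = input_size
    for s in dataset:
        img, m = s.image, s.mask
        if img.shape[:2] != (th, tw):
            img = resize(
                img, (th, tw), order=1, preserve_range=True, anti_aliasing=False
            )
            m = resize(m, (th, tw), order=0, preserve_range=True).astype(np.uint8)
        xs.append(np.moveaxis(img.astype(np.float32) / 255.0 - 0.5, -1, 0))
        ys.append(m.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def manifest_hash(dataset: Sequence[LabeledSample]) -> str:
    h = hashlib.sha256()
    for s in dataset:
        h.update(s.sample_id.encode())
    return h.hexdigest()[:16]


def train(
    model: TrainedModel,
    dataset: Sequence[LabeledSample],
    hp: TrainHyperparams,
    stage_tag: str | None = None,
) -> TrainedModel:
    """Fine-tune ``model`` in place on ``dataset``; returns the model.

    Pixel-wise 2-class cross-entropy, Adam, seeded shuffling. Raises if
    the loss ever becomes non-finite (training divergence) and records a
    per-epoch log in ``model.history``.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset must be non-empty")
    X, Y = _prepare_arrays(dataset, model.config.input_size)
    rng = np.random.default_rng(hp.seed)
    n_val = int(round(hp.validation_fraction * len(X)))
    if n_val:
        perm = rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xv, Yv = X[val_idx], Y[val_idx]
        X, Y = X[tr_idx], Y[tr_idx]
    opt = Adam(model.net.param_slots(), lr=hp.learning_rate)
    for epoch in range(hp.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), hp.batch_size):
            idx = order[start : start + hp.batch_size]
            logits = model.net.forward(X[idx])
            loss, grad = softmax_cross_entropy(logits, Y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            opt.zero_grad()
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if n_val:
            vloss, _ = softmax_cross_entropy(model.net.forward(Xv), Yv)
            entry["val_loss"] = float(vloss)
        model.history.append(entry)
    model.trained = True
    if stage_tag is not None:
        model.stage_tag = stage_tag
    model.training_manifest_hash = manifest_hash(dataset)
    return model


def predict_mask(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the two score channels (ties -> background)."""
    if not model.trained:
        raise ValueError("model is untrained; call train() first")
    image = as_rgb_image(image)
    x = np.moveaxis(image.astype(np.float32) / 255.0 - 0.5, -1, 0)[None]
    logits = model.net.forward(x)[0]
    # fruit wins only with a strictly higher score: argmax returns the
    # first maximum, and background is channel 0
    return np.argmax(logits, axis=0).astype(np.uint8)


def predict_masks(model: TrainedModel, images: Sequence[np.ndarray]) -> list[np.ndarray]:
    return [predict_mask(model, img) for img in images]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar (config, stage tag, hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.net.state_dict())
    weights_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar = {
        "config": {
            "backbone": model.config.backbone,
            "aspp_rates": list(model.config.aspp_rates),
            "num_classes": model.config.num_classes,
            "input_size": list(model.config.input_size),
            "seed": model.config.seed,
        },
        "stage_tag": model.stage_tag,
        "training_manifest_hash": model.training_manifest_hash,
        "trained": model.trained,
    }
    weights_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    weights_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar = json.loads(weights_path.with_suffix(".json").read_text())
    cfg = NetworkConfig(
        backbone=sidecar["config"]["backbone"],
        aspp_rates=tuple(sidecar["config"]["aspp_rates"]),
        num_classes=sidecar["config"]["num_classes"],
        input_size=tuple(sidecar["config"]["input_size"]),
        seed=sidecar["config"]["seed"],
    )
    model = build_model(cfg)
    with np.load(weights_path) as npz:
        model.net.load_state_dict(dict(npz))
    model.stage_tag = sidecar["stage_tag"]
    model.training_manifest_hash = sidecar["training_manifest_hash"]
    model.trained = sidecar["trained"]
    return model
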