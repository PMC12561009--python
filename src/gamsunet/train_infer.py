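"""Training loop and slice-wise volume inference.

Batch size 1, Adam (lr 1e-4, weight decay 1e-5), binary cross-entropy on
logits, optional flip/rotation augmentation on training slices, and
prediction thresholding at 0.5 — the published training protocol, run on
CPU.  With a fixed seed the whole train -> predict -> evaluate pipeline
is bitwise reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .io_preprocess import ImageVolume, MaskVolume, SliceSample, augment, extract_slices, znormalize
from .network import GAMSUNetPP
from .nn import autodiff as ad


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 100
    batch_size: int = 1
    threshold: float = 0.5
    seed: int = 0
    device: str = "cpu"
    augment: bool = True
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0,1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def bce_loss(probabilities, target_mask, from_logits: bool = False) -> float:
    """Mean binary cross-entropy -mean[t log p + (1-t) log(1-p)].

    Evaluation helper on arrays; the training loop itself always works in
    the numerically stable logit formulation.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(target_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if from_logits:
        z = p
        return float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log1p(-p)))


def train(network: GAMSUNetPP, train_samples: list[SliceSample],
          config: TrainConfig) -> tuple[GAMSUNetPP, TrainHistory]:
    """Optimize the network on slice samples; deterministic under seed."""
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(network.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history = TrainHistory()
    n = len(train_samples)
    for epoch in range(config.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        losses = np.empty(n, dtype=np.float64)
        for step, idx in enumerate(order):
            sample = train_samples[idx]
            if config.augment:
                sample = augment(sample, rng)
            x = sample.image.astype(np.float32)[None, None]
            t = sample.mask.astype(np.float32)[None, None]
            logits = network.forward_logits(nn.Tensor(x))
            loss = ad.bce_with_logits(logits, t)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}; aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses[step] = loss.item()
        history.epoch_loss.append(float(losses.mean()))
        history.epoch_seconds.append(time.time() - t0)
    if config.checkpoint_path:
        save_checkpoint(network, config, Path(config.checkpoint_path))
    return network, history


def predict_volume(network: GAMSUNetPP, image: ImageVolume,
                   config: TrainConfig | None = None, target: int = 256) -> MaskVolume:
    """Slice-wise inference reassembled into a 3D binary mask.

    The image volume is z-scored, sliced axially, resized to the model
    grid, passed through the network slice by slice and thresholded.
    The returned mask lives on the (target, target, Z) grid; its spacing
    is the original spacing rescaled by the in-plane resize so physical
    volume is preserved.
    """
    threshold = config.threshold if config is not None else 0.5
    normed = znormalize(image)
    dx, dy, dz = image.voxels.shape
    dummy = MaskVolume(np.zeros(image.voxels.shape, dtype=np.uint8),
                       image.spacing, image.affine, image.subject_id)
    samples = extract_slices(normed, dummy, target=target)
    out = np.zeros((target, target, dz), dtype=np.uint8)
    for s in samples:
        prob = network.predict(s.image.astype(np.float32))
        out[:, :, s.slice_index] = (prob > threshold).astype(np.uint8)
    sx, sy, sz = image.spacing
    new_spacing = (sx * dx / target, sy * dy / target, sz)
    affine = np.diag(list(new_spacing) + [1.0])
    return MaskVolume(out, new_spacing, affine, image.subject_id)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(network: GAMSUNetPP, config: TrainConfig, path: Path) -> None:
    """Weights + architecture config in one npz, keyed by parameter name."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {name: p.data for name, p in network.named_parameters()}
    meta = json.dumps({
        "network": asdict(network.config),
        "train": asdict(config),
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: Path, network: GAMSUNetPP | None = None) -> GAMSUNetPP:
    from .network import NetworkConfig

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if network is None:
            cfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in meta["network"].items()})
            network = GAMSUNetPP(cfg)
        for name, p in network.named_parameters():
            if name not in data:
                raise ValueError(f"checkpoint missing parameter {name}")
            if data[name].shape != p.data.shape:
                raise ValueError(f"checkpoint/config mismatch at {name}")
            p.data = data[name].astype(np.float32)
    return network
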