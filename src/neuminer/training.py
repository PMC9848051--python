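"""Training loop for the FNM segmentation network.

Each iteration samples random crops from the (already enhanced) training
volumes, augments them, runs the forward pass, mines false negatives from
the current prediction, and takes a Nesterov SGD step on the deeply
supervised dice + FNM-weighted cross-entropy loss with polynomial
learning-rate decay. Defaults mirror full-scale practice (initial learning
rate 0.01, momentum 0.99, weight decay 3e-5, 15 200 iterations,
160 x 160 x 128 crops, w_FN = 1.5); ``TrainConfig.tiny()`` scales the
network and schedule down to something a CPU finishes in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_sample
from .fnm import DEFAULT_WFN
from .nn import UNet3D, build_network, deep_supervision_loss, NesterovSGD, poly_lr

__all__ = ["TrainConfig", "TrainResult", "train",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.99
    weight_decay: float = 3e-5
    iterations: int = 15200
    crop_size: tuple[int, int, int] = (160, 160, 128)  # (x, y, z)
    batch_size: int = 2
    wfn: float = DEFAULT_WFN
    use_fnm: bool = True
    weighted_dice: bool = False
    levels: int = 4
    base_channels: int = 16
    head_weights: tuple[float, float] = (1.0, 0.5)
    poly_power: float = 0.9
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.wfn < 1.0:
            raise ValueError("wfn must be >= 1")
        if self.iterations <= 0 or self.batch_size <= 0:
            raise ValueError("iterations and batch_size must be positive")

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """CPU-scale profile: 2-level 8-channel net, 32^3 crops, 200 steps."""
        base = dict(levels=2, base_channels=8, crop_size=(32, 32, 32),
                    iterations=200, batch_size=1)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        aug = d.pop("augment", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__
                     and k != "augment"})
        if aug is not None:
            cfg.augment = AugmentConfig(**aug)
        cfg.crop_size = tuple(cfg.crop_size)
        cfg.head_weights = tuple(cfg.head_weights)
        return cfg


@dataclass
class TrainResult:
    network: UNet3D
    loss_log: pd.DataFrame
    config: TrainConfig


def _random_crop(image, label, crop_zyx, rng):
    starts = []
    for n, c in zip(image.shape, crop_zyx):
        if c > n:
            raise ValueError(f"crop {crop_zyx} larger than volume {image.shape}")
        starts.append(int(rng.integers(0, n - c + 1)))
    sl = tuple(slice(s, s + c) for s, c in zip(starts, crop_zyx))
    return image[sl], label[sl]


def train(dataset, cfg: TrainConfig,
          network: UNet3D | None = None) -> TrainResult:
    """Run the iteration loop on a dataset of (image, label) volume pairs.

    ``dataset`` items are float images in [0, 1] and binary labels, both
    (z, y, x). Deterministic for a given config and dataset. An existing
    ``network`` may be passed to continue training; otherwise one is built
    from the config with a seed-derived initialization.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    crop_zyx = tuple(reversed(cfg.crop_size))
    if network is None:
        network = build_network(levels=cfg.levels,
                                base_channels=cfg.base_channels,
                                seed=cfg.seed)
    opt = NesterovSGD(network.params(), lr=cfg.learning_rate,
                      momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng([cfg.seed, 1])
    rows = []
    for it in range(cfg.iterations):
        imgs, labs = [], []
        for _ in range(cfg.batch_size):
            idx = int(rng.integers(len(dataset)))
            img, lab = dataset[idx]
            img, lab = _random_crop(img, lab, crop_zyx, rng)
            img, lab = augment_sample(img, lab, rng, cfg.augment)
            imgs.append(img)
            labs.append(lab)
        x = np.stack(imgs)[:, None].astype(np.float32)
        y = np.stack(labs).astype(np.float32)
        outputs = network.forward(x)
        total, grads, stats = deep_supervision_loss(
            outputs, y, head_weights=cfg.head_weights,
            wfn=cfg.wfn, use_fnm=cfg.use_fnm,
            weighted_dice=cfg.weighted_dice)
        network.zero_grad()
        network.backward(*grads)
        lr = poly_lr(cfg.learning_rate, it, cfg.iterations, cfg.poly_power)
        opt.step(lr)
        rows.append({"iteration": it, "lr": lr, "total": total,
                     "dice": stats[0]["dice"], "ce": stats[0]["ce"],
                     "n_fn": stats[0]["n_fn"]})
    return TrainResult(network=network, loss_log=pd.DataFrame(rows), config=cfg)


def save_checkpoint(path: str | Path, network: UNet3D,
                    cfg: TrainConfig) -> None:
    """Single-file checkpoint: serialized weights plus a config snapshot."""
    state = network.state_dict()
    np.savez_compressed(path, __config__=json.dumps(cfg.to_dict()), **state)


def load_checkpoint(path: str | Path) -> tuple[UNet3D, TrainConfig]:
    with np.load(path, allow_pickle=False) as data:
        cfg = TrainConfig.from_dict(json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    network = build_network(levels=cfg.levels, base_channels=cfg.base_channels,
                            seed=cfg.seed)
    network.load_state_dict(state)
    return network, cfg
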