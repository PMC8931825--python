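"""Quasi-3D U-Net: slice-stack construction, augmentation, training, inference.

Each axial slice is predicted from a 3-channel stack of consecutive slices
(z-1, z, z+1; border slices replicate their neighbour), so a Z-slice volume
yields Z training samples with local through-plane context at 2D cost.  The
network is a standard U-Net (3x3 convolutions + leaky ReLU on the contraction
path with 2x2 max pooling, 2x2 deconvolution + skip concatenation on the
expansion path), trained with soft-Dice loss and Adam.  Two heads are used:
1-channel sigmoid for the brain-parenchyma mask, 6-channel softmax
(background + five VOIs) for the iVOI model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, zoom

from .core import ImageVolume
from .nn import (
    Adam,
    Conv2d,
    Deconv2x2,
    LeakyReLU,
    MaxPool2,
    dice_loss,
    dice_loss_and_grad_logits,
    sigmoid,
    softmax,
)

MASK = "mask"
IVOI = "ivoi"
N_CLASSES = 6  # background + 5 VOIs


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 25
    epochs: int = 20
    levels: int = 4
    base_channels: int = 32
    leaky_slope: float = 0.01
    channels: int = 3  # 3 = quasi-3D, 1 = plain 2D ablation
    in_size: int = 128
    aug_shift_frac: float = 0.05
    aug_rot_deg: float = 10.0
    aug_shear_deg: float = 5.0
    loss: str = "dice"
    optimizer: str = "adam"
    lr_schedule: str = "cosine"  # "cosine" decay from the initial rate, or "constant"
    dice_eps: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if min(self.aug_shift_frac, self.aug_rot_deg, self.aug_shear_deg) < 0:
            raise ValueError("augmentation ranges must be >= 0")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 (2D) or 3 (quasi-3D)")
        if self.loss != "dice":
            raise ValueError("only the dice loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")
        if self.in_size % 2 ** (self.levels - 1) != 0:
            raise ValueError(
                f"in_size {self.in_size} not divisible by 2^(levels-1) = {2 ** (self.levels - 1)}"
            )


def cpu_train_preset(task: str = MASK, **overrides) -> TrainConfig:
    """Small configuration for single-CPU experiments on the 64 x 64 phantom."""
    kw = dict(
        levels=3,
        base_channels=8,
        in_size=64,
        epochs=16,
        # a ~1e3-step budget needs a correspondingly larger step size than the
        # full-scale (GPU-budget) default of 1e-5; 1e-3 is the stock Adam rate
        learning_rate=1e-3,
        aug_shift_frac=0.0,
        aug_rot_deg=0.0,
        aug_shear_deg=0.0,
    )
    kw.update(overrides)
    return TrainConfig(**kw)


@dataclass
class SliceStack:
    """One training/inference sample: an H x W x C stack of consecutive slices."""

    pixels: np.ndarray  # (H, W, C) float32
    center_index: int
    subject_id: str = ""
    target: np.ndarray | None = None  # (H, W) uint8 (binary or codes 0-5)


def _resample_plane(plane: np.ndarray, size: int, order: int) -> np.ndarray:
    if plane.shape == (size, size):
        return plane
    fz = (size / plane.shape[0], size / plane.shape[1])
    return zoom(plane, fz, order=order, mode="nearest", grid_mode=True)


def make_stacks(
    vol: ImageVolume | np.ndarray,
    labels: np.ndarray | None = None,
    channels: int = 3,
    in_size: int | None = None,
    subject_id: str = "",
) -> list[SliceStack]:
    """Build one slice stack per axial slice (replicated-border neighbours).

    In-plane resampling to ``in_size`` uses bilinear interpolation for the
    image and nearest-neighbour for the target labels.
    """
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("expected a (Z, H, W) volume with at least one slice")
    nz = data.shape[0]
    size = in_size or data.shape[1]
    stacks = []
    for z in range(nz):
        if channels == 3:
            idx = (max(z - 1, 0), z, min(z + 1, nz - 1))
        else:
            idx = (z,)
        planes = [_resample_plane(data[i].astype(np.float32), size, order=1) for i in idx]
        target = None
        if labels is not None:
            target = _resample_plane(np.asarray(labels)[z], size, order=0)
        stacks.append(
            SliceStack(
                pixels=np.stack(planes, axis=-1),
                center_index=z,
                subject_id=subject_id,
                target=target,
            )
        )
    return stacks


def augment(
    stack: SliceStack,
    config: TrainConfig,
    seed: int,
    params: tuple[float, float, float, float] | None = None,
) -> SliceStack:
    """One random affine (shift, rotation, shear) shared by all channels.

    The image is resampled bilinearly, the target with nearest-neighbour.
    With all ranges zero the stack is returned unchanged.  ``params``
    ``(rot_deg, shear_deg, dy, dx)`` bypasses the random draw for a
    deterministic transform.
    """
    if params is None and (
        config.aug_shift_frac == 0 and config.aug_rot_deg == 0 and config.aug_shear_deg == 0
    ):
        return stack
    h, w = stack.pixels.shape[:2]
    if params is not None:
        theta = np.deg2rad(params[0])
        shear = np.tan(np.deg2rad(params[1]))
        dy, dx = params[2], params[3]
    else:
        rng = np.random.default_rng(seed)
        theta = np.deg2rad(rng.uniform(-config.aug_rot_deg, config.aug_rot_deg))
        shear = np.tan(np.deg2rad(rng.uniform(-config.aug_shear_deg, config.aug_shear_deg)))
        dy = rng.uniform(-config.aug_shift_frac, config.aug_shift_frac) * h
        dx = rng.uniform(-config.aug_shift_frac, config.aug_shift_frac) * w
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    mat = rot @ shr
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # pull convention: input_coord = mat @ (out - center) + center - shift
    offset = center - mat @ center - np.array([dy, dx])
    pixels = np.stack(
        [
            affine_transform(stack.pixels[..., c], mat, offset=offset, order=1, mode="constant")
            for c in range(stack.pixels.shape[-1])
        ],
        axis=-1,
    ).astype(np.float32)
    target = stack.target
    if target is not None:
        target = affine_transform(target, mat, offset=offset, order=0, mode="constant")
    return SliceStack(pixels, stack.center_index, stack.subject_id, target)


# ---------------------------------------------------------------------------
# network


class UNet:
    """Encoder-decoder with skip concatenations; see module docstring."""

    def __init__(self, config: TrainConfig, task: str = MASK, rng=None, dtype=np.float32):
        if task not in (MASK, IVOI):
            raise ValueError(f"unknown task {task!r}")
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.task = task
        self.out_channels = 1 if task == MASK else N_CLASSES
        c = config.base_channels
        slope = config.leaky_slope
        self.enc = []
        cin = config.channels
        for lvl in range(config.levels - 1):
            cout = c * 2**lvl
            self.enc.append(
                [
                    Conv2d(cin, cout, 3, rng, dtype),
                    LeakyReLU(slope),
                    Conv2d(cout, cout, 3, rng, dtype),
                    LeakyReLU(slope),
                ]
            )
            cin = cout
        cb = c * 2 ** (config.levels - 1)
        self.pools = [MaxPool2() for _ in range(config.levels - 1)]
        self.bottleneck = [
            Conv2d(cin, cb, 3, rng, dtype),
            LeakyReLU(slope),
            Conv2d(cb, cb, 3, rng, dtype),
            LeakyReLU(slope),
        ]
        self.dec = []
        cur = cb
        for lvl in reversed(range(config.levels - 1)):
            cskip = c * 2**lvl
            self.dec.append(
                {
                    "up": Deconv2x2(cur, cskip, rng, dtype),
                    "convs": [
                        Conv2d(2 * cskip, cskip, 3, rng, dtype),
                        LeakyReLU(slope),
                        Conv2d(cskip, cskip, 3, rng, dtype),
                        LeakyReLU(slope),
                    ],
                }
            )
            cur = cskip
        self.head = Conv2d(cur, self.out_channels, 1, rng, dtype, zero_init=True)

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for d in self.dec:
            yield d["up"]
            yield from d["convs"]
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self._layers())

    def describe(self) -> str:
        cfg = self.config
        return (
            f"UNet(task={self.task}, levels={cfg.levels}, base_channels={cfg.base_channels}, "
            f"in={cfg.in_size}x{cfg.in_size}x{cfg.channels}, out_channels={self.out_channels}, "
            f"parameters={self.n_params()})"
        )

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                x = layer.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        for d, skip in zip(self.dec, reversed(skips)):
            x = d["up"].forward(x)
            x = np.concatenate([skip, x], axis=-1)
            for layer in d["convs"]:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for d in reversed(self.dec):
            for layer in reversed(d["convs"]):
                dx = layer.backward(dx)
            cskip = dx.shape[-1] // 2
            dskips.append(dx[..., :cskip])
            dx = d["up"].backward(np.ascontiguousarray(dx[..., cskip:]))
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        # dskips were collected shallow-first; encoder backward runs deep-first
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            for layer in reversed(block):
                dx = layer.backward(dx)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        return sigmoid(logits) if self.task == MASK else softmax(logits)


def build_unet(config: TrainConfig, task: str = MASK, rng=None) -> UNet:
    return UNet(config, task=task, rng=rng)


# ---------------------------------------------------------------------------
# training / inference


def normalize_volume(data: np.ndarray) -> np.ndarray:
    """Per-volume z-scoring; applied identically at training and deployment."""
    data = np.asarray(data, dtype=np.float32)
    return (data - data.mean()) / (data.std() + 1e-6)


def _collect_training_stacks(records, task: str, config: TrainConfig):
    xs = []
    for rec in records:
        mr = rec.mr.data
        if task == IVOI:
            mr = mr * rec.brain_mask_gt.data  # ground-truth skull-strip at training
        vol = normalize_volume(mr)
        labels = rec.brain_mask_gt.data.astype(np.uint8) if task == MASK else rec.ivoi_gt.data
        for z, st in enumerate(
            make_stacks(vol, labels, config.channels, config.in_size, rec.mouse_id)
        ):
            # the iVOI model sees skull-stripped input, so slices without any
            # brain signal carry no information and are skipped at training
            # (the rule depends only on the input, so deployment is consistent)
            if task == IVOI and not mr[z].any():
                continue
            xs.append(st)
    return xs


def train(records, task: str, config: TrainConfig):
    """Train a U-Net on a list of subject records; returns (model, history).

    The iVOI task consumes ground-truth skull-stripped MR (at deployment the
    pipeline strips with the predicted, postprocessed mask instead).  Sample
    order, augmentation draws, and weight initialisation are all driven by
    ``config.seed``, so identical calls give bit-identical histories.
    """
    if not records:
        raise ValueError("no training records")
    if task not in (MASK, IVOI):
        raise ValueError(f"unknown task {task!r}")
    stacks = _collect_training_stacks(records, task, config)
    rng = np.random.default_rng(config.seed)
    model = UNet(config, task=task, rng=rng)
    opt = Adam(model.params(), lr=config.learning_rate)
    augmenting = config.aug_shift_frac > 0 or config.aug_rot_deg > 0 or config.aug_shear_deg > 0

    history = []
    n = len(stacks)
    steps_per_epoch = (n + config.batch_size - 1) // config.batch_size
    total_steps = max(config.epochs * steps_per_epoch, 1)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            if config.lr_schedule == "cosine":
                # decay from the initial rate to 1% of it, so the final
                # weights settle instead of bouncing around the optimum
                frac = step / total_steps
                opt.lr = config.learning_rate * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * frac)))
            batch = [stacks[i] for i in order[start : start + config.batch_size]]
            if augmenting:
                batch = [augment(s, config, int(rng.integers(2**31))) for s in batch]
            x = np.stack([s.pixels for s in batch]).astype(np.float32)
            y = np.stack([s.target for s in batch])
            logits = model.forward(x)
            loss, dlogits = dice_loss_and_grad_logits(logits, y, task, config.dice_eps)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            step += 1
        history.append({"epoch": epoch, "mean_dice_loss": float(np.mean(losses))})
    return model, pd.DataFrame(history)


def predict(vol: ImageVolume | np.ndarray, model: UNet, batch_size: int = 32) -> np.ndarray:
    """Slice-wise prediction reassembled into a probability volume.

    Returns (Z, H, W) for the mask model or (Z, H, W, 6) for the iVOI model.
    Input is z-scored with the same per-volume rule used at training.
    """
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)
    cfg = model.config
    stacks = make_stacks(normalize_volume(data), None, cfg.channels, cfg.in_size)
    x = np.stack([s.pixels for s in stacks]).astype(np.float32)
    outs = []
    for start in range(0, len(x), batch_size):
        outs.append(model.predict_proba(x[start : start + batch_size]))
    probs = np.concatenate(outs, axis=0)
    return probs[..., 0] if model.task == MASK else probs


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: UNet, path: str | Path, history: pd.DataFrame | None = None) -> Path:
    """Bundle weights + config + task into one ``.npz`` checkpoint."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    arrays = {f"p{i}": p.val for i, p in enumerate(model.params())}
    meta = json.dumps({"config": asdict(model.config), "task": model.task})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    if history is not None:
        history.to_csv(path.with_suffix(".history.csv"), index=False)
    return path


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = UNet(TrainConfig(**meta["config"]), task=meta["task"])
        for i, p in enumerate(model.params()):
            p.val[...] = data[f"p{i}"]
    return model
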