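"""Fold-wise training: synthetic pairs for training, real renders for validation.

An epoch is a fixed number of random mini-batches of patches; patches are
uniform random crops with foreground-containing crops oversampled at 1/3
probability.  Optimization is AdamW with decoupled weight decay, gradient
clipping, and a poly learning-rate schedule.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..synthgen import TrainingPair
from ..volio import IntensityVolume, LabeledVolume, reorient
from .losses import dice_ce_grad_logits
from .optim import AdamW, clip_grad_norm, poly_lr
from .unet import NetConfig, UNet3D, softmax

__all__ = ["TrainConfig", "FoldModel", "train_fold", "assign_folds", "zscore"]


@dataclass
class TrainConfig:
    epochs: int = 20
    batches_per_epoch: int = 20
    base_lr: float = 3e-4
    lr_exponent: float = 0.9
    weight_decay: float = 3e-5
    grad_clip_norm: float = 12.0
    n_folds: int = 5
    val_fraction: float = 0.2
    foreground_oversample: float = 1.0 / 3.0
    val_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


@dataclass
class FoldModel:
    """Trained network for one fold plus its class mapping and history."""

    net: UNet3D
    class_labels: tuple[int, ...]  # channel index -> label id (0 first)
    fold_index: int = 0
    history: list[dict] = field(default_factory=list)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """(C_in, X, Y, Z) network input -> (n_classes, X, Y, Z) logits."""
        if x.ndim == 3:
            x = x[None]
        return self.net.forward(x[None].astype(np.float32))[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(x), axis=0)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.net.state_dict())
        meta = {
            "class_labels": list(self.class_labels),
            "fold_index": self.fold_index,
            "net": {
                "n_stages": self.net.cfg.n_stages,
                "features_per_stage": list(self.net.cfg.features_per_stage),
                "kernel": self.net.cfg.kernel,
                "leaky_slope": self.net.cfg.leaky_slope,
                "patch_size": list(self.net.cfg.patch_size),
                "batch_size": self.net.cfg.batch_size,
                "n_classes": self.net.cfg.n_classes,
                "in_channels": self.net.cfg.in_channels,
                "deep_supervision": self.net.cfg.deep_supervision,
                "coord_channels": self.net.cfg.coord_channels,
            },
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        (directory / "history.json").write_text(json.dumps(self.history, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FoldModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        netcfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["net"].items()})
        net = UNet3D(netcfg, seed=0)
        with np.load(directory / "weights.npz") as z:
            net.load_state_dict({k: z[k] for k in z.files})
        history = json.loads((directory / "history.json").read_text()) \
            if (directory / "history.json").exists() else []
        return cls(net=net, class_labels=tuple(meta["class_labels"]),
                   fold_index=meta["fold_index"], history=history)


def assign_folds(n_subjects: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Subject-level shuffled fold assignment; fold k holds out its chunk."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    return [np.sort(chunk) for chunk in np.array_split(order, n_folds)]


#: normalization scale (mm) for the optional world-coordinate channels
COORD_SCALE_MM = 16.0


def coordinate_channels(shape, affine) -> np.ndarray:
    """(9, X, Y, Z) normalized world-coordinate features.

    Linear offsets from the FOV center (mm / COORD_SCALE_MM) plus their
    squares and pairwise products — a quadratic basis, enough for the head
    to carve ellipsoidal positional priors."""
    shape = tuple(int(s) for s in shape)
    affine = np.asarray(affine, dtype=float)
    idx = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                               indexing="ij"))
    world = np.einsum("ij,jxyz->ixyz", affine[:3, :3], idx) \
        + affine[:3, 3, None, None, None]
    center = affine[:3, :3] @ ((np.asarray(shape) - 1) / 2) + affine[:3, 3]
    c = (world - center[:, None, None, None]) / COORD_SCALE_MM
    feats = [c[0], c[1], c[2], c[0] ** 2, c[1] ** 2, c[2] ** 2,
             c[0] * c[1], c[0] * c[2], c[1] * c[2]]
    return np.stack(feats).astype(np.float32)


def network_input(image, cfg) -> np.ndarray:
    """(C, X, Y, Z) network input: z-scored intensities plus, when the
    config asks for them, the coordinate channels."""
    norm = zscore(image.data)[None]
    if getattr(cfg, "coord_channels", False):
        return np.concatenate(
            [norm, coordinate_channels(image.shape, image.affine)], axis=0)
    return norm


def zscore(data: np.ndarray) -> np.ndarray:
    d = data.astype(np.float32)
    std = float(d.std())
    if std < 1e-8:
        return np.zeros_like(d)
    return (d - d.mean()) / std


def class_mapping(labels: set[int]) -> tuple[int, ...]:
    """Channel order: background then ascending label ids (argmax tie-break
    therefore favors the lowest id)."""
    return (0,) + tuple(sorted(set(labels) - {0}))


def _labels_to_classes(data: np.ndarray, class_labels: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(data.shape, dtype=np.int64)
    for idx, lab in enumerate(class_labels):
        if lab != 0:
            out[data == lab] = idx
    return out


def _pad_to_multiple(data: np.ndarray, div: int) -> tuple[np.ndarray, tuple]:
    pads = [(0, (-s) % div) for s in data.shape]
    if any(p[1] for p in pads):
        data = np.pad(data, pads)
    return data, tuple(p[1] for p in pads)


def _sample_patch(img, cls, patch, rng, oversample_fg: float, class_voxels=None):
    """Random crop; with probability ``oversample_fg`` the crop is centered
    on a voxel of a uniformly chosen foreground class (class-balanced, so
    rare small structures are seen during training).  ``img`` is (C, X, Y, Z)."""
    shape = cls.shape
    patch = [min(p, s) for p, s in zip(patch, shape)]
    if rng.random() < oversample_fg and class_voxels:
        cidx = class_voxels[int(rng.integers(len(class_voxels)))]
        center = cidx[rng.integers(len(cidx))]
        start = [int(np.clip(c - p // 2, 0, s - p))
                 for c, p, s in zip(center, patch, shape)]
    else:
        start = [int(rng.integers(0, s - p + 1)) for p, s in zip(patch, shape)]
    sl = tuple(slice(a, a + p) for a, p in zip(start, patch))
    return img[(slice(None),) + sl], cls[sl]


def validation_dice(model: FoldModel, val_pairs, class_labels) -> float:
    """Mean foreground Dice of single-model argmax predictions.

    Volumes are reoriented to LIA to match the training orientation."""
    scores = []
    div = 2 ** (model.net.cfg.n_stages - 1)
    for image, labels in val_pairs:
        image = reorient(image, "LIA")
        labels = reorient(labels, "LIA")
        x = network_input(image, model.net.cfg)
        pads = [(0, 0)] + [(0, (-s) % div) for s in x.shape[1:]]
        padded = np.pad(x, pads) if any(p[1] for p in pads) else x
        probs = model.predict_proba(padded)
        sl = tuple(slice(0, s) for s in x.shape[1:])
        pred_cls = np.argmax(probs, axis=0)[sl]
        true_cls = _labels_to_classes(labels.data, class_labels)
        for idx in range(1, len(class_labels)):
            g = true_cls == idx
            p = pred_cls == idx
            if not g.any() and not p.any():
                continue
            denom = int(g.sum()) + int(p.sum())
            scores.append(2.0 * int((g & p).sum()) / denom if denom else 0.0)
    return float(np.mean(scores)) if scores else 0.0


def train_fold(
    train_pairs: list[TrainingPair],
    val_pairs: list[tuple[IntensityVolume, LabeledVolume]],
    net_cfg: NetConfig,
    cfg: TrainConfig,
    fold_index: int = 0,
) -> FoldModel:
    """Train one fold on synthetic pairs; validate on real (rendered) images."""
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation splits must be nonempty")
    for pair in train_pairs:
        if getattr(pair, "provenance", "synthetic") != "synthetic":
            raise ValueError("training pairs must be synthetic")

    labels: set[int] = set()
    for pair in train_pairs:
        labels.update(pair.target.present_labels())
    class_labels = class_mapping(labels)
    if net_cfg.n_classes != len(class_labels):
        from dataclasses import replace

        net_cfg = replace(net_cfg, n_classes=len(class_labels))

    rng = np.random.default_rng(cfg.seed + 1000 * fold_index)
    net = UNet3D(net_cfg, seed=cfg.seed + 1000 * fold_index)
    opt = AdamW(net.parameters(), lr=cfg.base_lr, weight_decay=cfg.weight_decay)
    model = FoldModel(net=net, class_labels=class_labels, fold_index=fold_index)

    # train in the canonical LIA orientation: inference reorients inputs to
    # LIA, so the network's learned spatial layout must match
    imgs = [network_input(reorient(p.image, "LIA"), net_cfg) for p in train_pairs]
    clss = [_labels_to_classes(reorient(p.target, "LIA").data, class_labels)
            for p in train_pairs]
    class_voxel_lists = []
    for cls in clss:
        per_class = [np.argwhere(cls == idx) for idx in range(1, len(class_labels))]
        class_voxel_lists.append([a for a in per_class if len(a)])

    for epoch in range(cfg.epochs):
        opt.lr = poly_lr(epoch, cfg)
        losses, dices, ces = [], [], []
        for _ in range(cfg.batches_per_epoch):
            xb, yb = [], []
            for _ in range(net_cfg.batch_size):
                k = int(rng.integers(len(imgs)))
                xi, yi = _sample_patch(imgs[k], clss[k], net_cfg.patch_size, rng,
                                       cfg.foreground_oversample,
                                       class_voxel_lists[k])
                xb.append(xi)
                yb.append(yi)
            x = np.stack(xb)
            y = np.stack(yb)
            net.zero_grad()
            if net_cfg.deep_supervision:
                outs = net.forward_deep(x)
                # weights halve per coarsening level
                factors = [1] + [2 ** (net_cfg.n_stages - 2 - k)
                                 for k in range(len(net.aux_heads))]
                weights = np.array([1.0 / f for f in factors])
                weights /= weights.sum()
                total = dice_term = ce_term = 0.0
                gz_main, gaux = None, []
                for out, w, f in zip(outs, weights, factors):
                    yt = y[:, ::f, ::f, ::f]
                    t, d, c, gz = dice_ce_grad_logits(out, yt)
                    total += w * t
                    dice_term += w * d
                    ce_term += w * c
                    if gz_main is None:
                        gz_main = w * gz
                    else:
                        gaux.append(w * gz)
                net.backward(gz_main, gaux=gaux)
            else:
                logits = net.forward(x)
                total, dice_term, ce_term, gz = dice_ce_grad_logits(logits, y)
                net.backward(gz)
            grads = net.gradients()
            clip_grad_norm(grads, cfg.grad_clip_norm)
            opt.step(grads)
            losses.append(total)
            dices.append(dice_term)
            ces.append(ce_term)
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_dice_loss": float(np.mean(dices)),
            "train_ce_loss": float(np.mean(ces)),
        }
        if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
            record["val_dice"] = validation_dice(model, val_pairs, class_labels)
        model.history.append(record)
    return model
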