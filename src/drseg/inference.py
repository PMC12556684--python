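"""Prediction path: sliding-window inference, fold ensembling, validated
largest-component post-processing, and the native-resolution round trip.

``segment_volume`` reorients the input to LIA, resamples it to the training
spacing, averages the per-fold softmax outputs, argmaxes, filters components
according to the validated policy, and maps the result back onto the input
grid (one-hot label resampling + inverse reorientation)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volio import (
    IntensityVolume,
    LabeledVolume,
    Orientation,
    orientation_of,
    reorient,
    resample_intensity,
    resample_labels,
)
from .network.training import FoldModel, network_input
from .network.unet import softmax

__all__ = [
    "ProbabilityMaps",
    "PostprocPolicy",
    "sliding_window_predict",
    "ensemble_segment",
    "largest_component_filter",
    "decide_postproc_policy",
    "segment_volume",
]

_CONN_TO_STRUCT = {6: 1, 18: 2, 26: 3}


@dataclass
class ProbabilityMaps:
    """Per-class soft prediction: ``probs`` is (C, X, Y, Z)."""

    probs: np.ndarray
    affine: np.ndarray
    class_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4 or self.probs.shape[0] != len(self.class_labels):
            raise ValueError("probs must be (n_classes, X, Y, Z) matching class_labels")
        sums = self.probs.sum(axis=0)
        if np.any(self.probs < -1e-6) or not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-voxel probabilities must be in [0,1] and sum to 1")

    @property
    def shape(self):
        return self.probs.shape[1:]


@dataclass
class PostprocPolicy:
    """Labels receiving largest-component filtering, plus the connectivity."""

    apply_largest_component: frozenset = frozenset()
    connectivity: int = 26

    def __post_init__(self) -> None:
        self.apply_largest_component = frozenset(int(i) for i in self.apply_largest_component)
        if self.connectivity not in _CONN_TO_STRUCT:
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, _CONN_TO_STRUCT[self.connectivity])

    def to_json(self) -> str:
        return json.dumps(
            {"apply_largest_component": sorted(self.apply_largest_component),
             "connectivity": self.connectivity}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PostprocPolicy":
        d = json.loads(text)
        return cls(frozenset(d["apply_largest_component"]), d.get("connectivity", 26))


def _gaussian_weights(patch: Sequence[int], sigma_scale: float = 0.125) -> np.ndarray:
    grids = []
    for p in patch:
        x = np.arange(p) - (p - 1) / 2
        sigma = max(p * sigma_scale, 1e-3)
        grids.append(np.exp(-0.5 * (x / sigma) ** 2))
    w = grids[0][:, None, None] * grids[1][None, :, None] * grids[2][None, None, :]
    return (w / w.max()).astype(np.float64)


def _tile_starts(size: int, patch: int, overlap: float) -> list[int]:
    if patch >= size:
        return [0]
    step = max(1, int(np.floor(patch * (1 - overlap))))
    starts = list(range(0, size - patch, step))
    starts.append(size - patch)
    return sorted(set(starts))


def sliding_window_predict(
    model: FoldModel,
    image: IntensityVolume,
    patch: Sequence[int] | None = None,
    overlap: float = 0.5,
    normalize: bool = True,
) -> ProbabilityMaps:
    """Tile the volume, accumulate Gaussian-weighted softmax outputs.

    The volume is padded so every side fits at least one patch (and the
    network's divisibility constraint); the weighted accumulation is
    normalized so per-voxel probabilities sum to 1, then cropped back.
    """
    cfg = model.net.cfg
    patch = tuple(int(p) for p in (patch or cfg.patch_size))
    div = 2 ** (cfg.n_stages - 1)
    patch = tuple(p + (-p) % div for p in patch)
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")

    if normalize:
        work = network_input(image, cfg)
    else:
        work = image.data.astype(np.float32)[None]
    spatial = work.shape[1:]
    pads = [max(0, p - s) for p, s in zip(patch, spatial)]
    if any(pads):
        work = np.pad(work, [(0, 0)] + [(0, p) for p in pads])
    spatial = work.shape[1:]

    C = cfg.n_classes
    acc = np.zeros((C,) + spatial, dtype=np.float64)
    wsum = np.zeros(spatial, dtype=np.float64)
    weights = _gaussian_weights(patch)
    starts = [_tile_starts(s, p, overlap) for s, p in zip(spatial, patch)]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + patch[0]), slice(sy, sy + patch[1]),
                      slice(sz, sz + patch[2]))
                logits = model.net.forward(work[(slice(None),) + sl][None])[0]
                probs = softmax(logits.astype(np.float64), axis=0)
                acc[(slice(None),) + sl] += probs * weights
                wsum[sl] += weights
    acc /= wsum
    crop = tuple(slice(0, s) for s in image.shape)
    return ProbabilityMaps(acc[(slice(None),) + crop], image.affine.copy(),
                           tuple(model.class_labels))


def ensemble_segment(
    prob_list: Sequence[ProbabilityMaps], lut: Mapping[int, tuple] | None = None
) -> LabeledVolume:
    """Average softmax maps across folds and argmax (ties -> lowest id)."""
    if not prob_list:
        raise ValueError("empty probability list")
    ref = prob_list[0]
    for pm in prob_list[1:]:
        if pm.shape != ref.shape or pm.class_labels != ref.class_labels:
            raise ValueError("probability maps disagree on grid or class mapping")
        if not np.allclose(pm.affine, ref.affine, atol=1e-6):
            raise ValueError("probability maps disagree on affine")
    mean = np.mean([pm.probs for pm in prob_list], axis=0)
    # class order is background-first then ascending ids, so argmax's
    # first-maximum rule implements the lowest-id tie-break
    idx = np.argmax(mean, axis=0)
    labels = np.asarray(ref.class_labels, dtype=np.int32)[idx]
    if lut is None:
        lut = {int(l): (f"label-{int(l)}", (128, 128, 128))
               for l in ref.class_labels if l != 0}
    return LabeledVolume(labels, ref.affine.copy(), dict(lut))


def largest_component_filter(seg: LabeledVolume, policy: PostprocPolicy) -> LabeledVolume:
    """Keep only the largest connected component of each policy label.

    Removed satellites become background; labels outside the policy are
    untouched.  Idempotent."""
    out = seg.data.copy()
    structure = policy.structure()
    for lab in sorted(policy.apply_largest_component):
        mask = out == lab
        if not mask.any():
            continue
        comps, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comps, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        out[mask & (comps != keep)] = 0
    return LabeledVolume(out, seg.affine.copy(), dict(seg.lut))


def _per_label_dice(gt: np.ndarray, pred: np.ndarray, lab: int) -> float | None:
    g = gt == lab
    p = pred == lab
    denom = int(g.sum()) + int(p.sum())
    if denom == 0:
        return None
    return 2.0 * int((g & p).sum()) / denom


def _ensemble_predict(models: Sequence[FoldModel], image: IntensityVolume,
                      overlap: float = 0.5, lut=None) -> LabeledVolume:
    probs = [sliding_window_predict(m, image, overlap=overlap) for m in models]
    return ensemble_segment(probs, lut=lut)


def decide_postproc_policy(
    models: Sequence[FoldModel],
    val_pairs: Sequence[tuple[IntensityVolume, LabeledVolume]],
    connectivity: int = 26,
    overlap: float = 0.5,
) -> PostprocPolicy:
    """Validate largest-component filtering label by label.

    A label enters the apply set iff its mean validation Dice over subjects
    strictly improves when only the largest component is kept (ensembled
    predictions).  Ties are excluded."""
    if not val_pairs:
        raise ValueError("validation set is empty")
    class_labels = models[0].class_labels
    segs = [(_ensemble_predict(models, img), gt) for img, gt in val_pairs]
    structure = ndimage.generate_binary_structure(3, _CONN_TO_STRUCT[connectivity])

    apply_ids = set()
    for lab in class_labels:
        if lab == 0:
            continue
        before, after = [], []
        for seg, gt in segs:
            pred = seg.data
            d0 = _per_label_dice(gt.data, pred, lab)
            mask = pred == lab
            filtered = pred.copy()
            if mask.any():
                comps, n = ndimage.label(mask, structure=structure)
                if n > 1:
                    sizes = ndimage.sum_labels(mask, comps, index=np.arange(1, n + 1))
                    keep = int(np.argmax(sizes)) + 1
                    filtered[mask & (comps != keep)] = 0
            d1 = _per_label_dice(gt.data, filtered, lab)
            if d0 is not None:
                before.append(d0)
                after.append(d1 if d1 is not None else 0.0)
        if before and float(np.mean(after)) > float(np.mean(before)):
            apply_ids.add(int(lab))
    return PostprocPolicy(frozenset(apply_ids), connectivity)


def _match_grid(seg: LabeledVolume, shape, affine) -> LabeledVolume:
    """Crop/zero-pad at the far edges so the grid matches ``shape`` exactly.

    Round-tripped shapes can differ by one trailing voxel per axis because
    shapes are rounded; the voxel-(0,0,0) anchor makes end-cropping safe."""
    data = seg.data
    sl = tuple(slice(0, min(a, b)) for a, b in zip(data.shape, shape))
    out = np.zeros(shape, dtype=data.dtype)
    out[sl] = data[sl]
    return LabeledVolume(out, np.asarray(affine, dtype=float).copy(), dict(seg.lut))


def segment_volume(
    image: IntensityVolume,
    models: Sequence[FoldModel],
    policy: PostprocPolicy | None = None,
    train_spacing=(0.7, 0.7, 0.7),
    overlap: float = 0.5,
    patch: Sequence[int] | None = None,
    lut: Mapping[int, tuple] | None = None,
) -> LabeledVolume:
    """Full prediction path; output grid and affine equal the input's.

    ``patch=None`` uses each model's training patch; ``patch="volume"``
    runs one full-volume pass (cheaper and gives the instance-normalized
    features whole-image statistics, which helps on desk-scale volumes)."""
    if not models:
        raise ValueError("no models given")
    policy = policy or PostprocPolicy()
    native_orientation = orientation_of(image)
    work = reorient(image, Orientation("LIA"))
    work_shape, work_affine = work.shape, work.affine.copy()

    train_spacing = np.broadcast_to(np.asarray(train_spacing, dtype=float), (3,))
    resampled = not np.allclose(work.spacing, train_spacing, atol=1e-6)
    if resampled:
        work = resample_intensity(work, train_spacing)

    use_patch = tuple(work.shape) if (isinstance(patch, str) and patch == "volume") \
        else patch
    prob_maps = [sliding_window_predict(m, work, patch=use_patch, overlap=overlap)
                 for m in models]
    seg = ensemble_segment(prob_maps, lut=lut)
    seg = largest_component_filter(seg, policy)

    if resampled:
        native_spacing = np.linalg.norm(work_affine[:3, :3], axis=0)
        seg = resample_labels(seg, native_spacing)
        seg = _match_grid(seg, work_shape, work_affine)
    out = reorient(seg, native_orientation)
    out = _match_grid(out, image.shape, image.affine)
    return out
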