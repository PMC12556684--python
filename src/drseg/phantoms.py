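"""Brain-like phantom label maps and rendered validation images.

Phantoms are nested ellipsoids: an extra-cerebral-like rim, a cortex-like
shell, a white-matter-like core, a ventricle-like cavity, and a configurable
number of subcortical blobs placed at stereotyped (lightly jittered) sites
with distinct sizes.  Geometry is analytic, so voxel counts have closed-form
references, and every phantom survives the full preparation, synthesis,
training and evaluation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .volio import IntensityVolume, LabeledVolume

__all__ = ["PhantomSpec", "make_phantom_labelmap", "render_validation_image",
           "default_contrast_profile"]

RIM_ID = 999
CORTEX_ID = 3
WM_ID = 2
VENTRICLE_ID = 4

# (label id, name, nominal offset from brain center and nominal semi-axes,
# both in units of the brain semi-axes) — sizes deliberately distinct so
# blobs are identifiable by shape under randomized contrast
_BLOB_SITES = [
    (10, "Left-Thalamus", (-0.30, -0.12, 0.06), (0.34, 0.30, 0.28)),
    (49, "Right-Thalamus", (0.30, -0.12, 0.06), (0.34, 0.30, 0.28)),
    (11, "Left-Caudate", (-0.32, 0.32, 0.14), (0.26, 0.32, 0.24)),
    (50, "Right-Caudate", (0.32, 0.32, 0.14), (0.26, 0.32, 0.24)),
    (12, "Left-Putamen", (-0.54, 0.10, -0.06), (0.28, 0.36, 0.26)),
    (51, "Right-Putamen", (0.54, 0.10, -0.06), (0.28, 0.36, 0.26)),
    (17, "Left-Hippocampus", (-0.38, -0.42, -0.24), (0.32, 0.26, 0.22)),
    (53, "Right-Hippocampus", (0.38, -0.42, -0.24), (0.32, 0.26, 0.22)),
]


@dataclass
class PhantomSpec:
    """Parameters of one phantom subject."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    n_subcortical: int = 8
    seed: int = 0
    rim_id: int = RIM_ID
    contrast_profile: Mapping[int, tuple[float, float]] | None = None
    snr: float = 20.0
    jitter_voxels: float = 1.0
    lut: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in np.broadcast_to(self.shape, (3,)))
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if min(self.shape) < 32:
            raise ValueError("phantom shape must be >= 32 per axis")
        if self.n_subcortical < 0 or self.n_subcortical > len(_BLOB_SITES):
            raise ValueError(f"n_subcortical must be in [0, {len(_BLOB_SITES)}]")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = 1.0
        for i in range(3):
            aff[i, i] = self.spacing[i]
        # center the FOV at the world origin, RAS-ish by default
        for i in range(3):
            aff[i, 3] = -self.spacing[i] * (self.shape[i] - 1) / 2
        return aff


def _ellipsoid(grid, center, semi):
    x, y, z = grid
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_phantom_labelmap(spec: PhantomSpec) -> LabeledVolume:
    """Deterministic-under-seed nested-ellipsoid label map.

    With ``n_subcortical=0`` exactly four nonzero labels are present: rim,
    cortex shell, white-matter core, and ventricle cavity.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape)
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")

    center = (shape - 1) / 2 + rng.uniform(-spec.jitter_voxels, spec.jitter_voxels, 3)
    brain_semi = shape * 0.40 + rng.uniform(-spec.jitter_voxels, spec.jitter_voxels, 3)
    if np.any(brain_semi < 10):
        raise ValueError("phantom shape too small to nest structures")
    jit = spec.jitter_voxels
    shell_frac = 0.84 + rng.uniform(-0.02, 0.02) * min(jit, 1.0)
    rim_semi = brain_semi + 2.5

    data = np.zeros(spec.shape, dtype=np.int32)
    data[_ellipsoid(grid, center, rim_semi)] = spec.rim_id
    data[_ellipsoid(grid, center, brain_semi)] = CORTEX_ID
    wm_semi = brain_semi * shell_frac
    data[_ellipsoid(grid, center, wm_semi)] = WM_ID

    vent_center = center + np.array([0.0, 0.0, 3.0]) + rng.uniform(-1, 1, 3) * min(jit, 1.0)
    vent_semi = brain_semi * 0.24
    data[_ellipsoid(grid, vent_center, vent_semi)] = VENTRICLE_ID

    lut = {
        spec.rim_id: ("Extra-Cerebral", (80, 80, 80)),
        CORTEX_ID: ("Cortex", (205, 62, 78)),
        WM_ID: ("White-Matter", (245, 245, 245)),
        VENTRICLE_ID: ("Ventricle", (120, 18, 134)),
    }
    for lab, name, rel, semi in _BLOB_SITES[: spec.n_subcortical]:
        c = center + np.asarray(rel) * brain_semi
        c = c + rng.uniform(-spec.jitter_voxels, spec.jitter_voxels, 3)
        blob = _ellipsoid(grid, c, np.asarray(semi) * brain_semi)
        data[blob & (data == WM_ID)] = lab  # nested: only carve inside WM
        lut[lab] = (name, (120 + 10 * (lab % 13), 60, 200 - 5 * (lab % 13)))

    out = LabeledVolume(data, spec.affine(), lut)
    if spec.lut:
        out.lut.update(spec.lut)
    return out


def default_contrast_profile(
    labelmap: LabeledVolume, snr: float, rng: np.random.Generator,
    distinct: bool = False,
) -> dict[int, tuple[float, float]]:
    """A fixed 'acquisition' contrast: one (mean, mean/snr) pair per label.

    ``distinct=True`` assigns a random permutation of evenly spaced means
    (tissues in a real acquisition rarely share intensities; independent
    draws can make two adjacent structures indistinguishable by chance)."""
    labels = labelmap.present_labels()
    if distinct:
        means = rng.permutation(np.linspace(40.0, 220.0, len(labels)))
    else:
        means = rng.uniform(40.0, 220.0, size=len(labels))
    profile: dict[int, tuple[float, float]] = {}
    for mean, lab in zip(means, labels):
        profile[lab] = (float(mean), float(mean / snr) if np.isfinite(snr) else 0.0)
    return profile


def render_validation_image(labelmap: LabeledVolume, spec: PhantomSpec) -> IntensityVolume:
    """Render a 'real-acquisition' stand-in: one fixed contrast plus noise.

    Each label's voxels are drawn from ``Normal(mean, std)`` given by
    ``spec.contrast_profile``; entries with ``std=None`` default to
    ``mean / spec.snr``.  Background stays 0.
    """
    if spec.contrast_profile is None:
        raise ValueError("spec.contrast_profile is required for rendering")
    rng = np.random.default_rng(spec.seed)
    present = labelmap.present_labels()
    missing = [lab for lab in present if lab not in spec.contrast_profile]
    if missing:
        raise ValueError(f"contrast profile missing labels {missing}")
    data = np.zeros(labelmap.shape, dtype=np.float64)
    for lab in present:
        mean, std = spec.contrast_profile[lab]
        if std is None:
            std = mean / spec.snr if np.isfinite(spec.snr) else 0.0
        where = labelmap.data == lab
        data[where] = mean + std * rng.standard_normal(int(where.sum()))
    return IntensityVolume(data.astype(np.float32), labelmap.affine.copy())
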