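"""Extra-cerebral label construction and skull-strip masking.

From a brain label map, the brain mask (union of nonzero labels) is closed,
hole-filled, and dilated by a small number of voxels; the shell of voxels
gained by dilation becomes an artificial "extra-cerebral" label that is used
during synthesis but dropped from training targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import IntensityVolume, LabeledVolume

__all__ = [
    "BinaryMask",
    "ExtraCerebralPolicy",
    "brain_mask",
    "extracerebral_mask",
    "add_extracerebral_label",
    "apply_skullstrip",
]

DEFAULT_EXTRACEREBRAL_ID = 999

#: spacing threshold (mm) separating the 5-voxel from the 4-voxel dilation
AUTO_DILATION_SPACING_MM = 0.7


@dataclass
class BinaryMask:
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class ExtraCerebralPolicy:
    """How to grow the extra-cerebral shell.

    ``dilation_voxels`` may be a positive integer or ``"auto"``, which picks
    5 voxels for high-resolution grids (max spacing <= 0.7 mm) and 4
    otherwise.  ``connectivity`` 1 is the 6-connected face cross; 3 the full
    26-neighborhood.
    """

    dilation_voxels: int | str = "auto"
    extracerebral_id: int = DEFAULT_EXTRACEREBRAL_ID
    connectivity: int = 1

    def __post_init__(self) -> None:
        if self.dilation_voxels != "auto":
            self.dilation_voxels = int(self.dilation_voxels)
            if self.dilation_voxels < 1:
                raise ValueError("dilation_voxels must be >= 1")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")

    def resolve_dilation(self, spacing) -> int:
        if self.dilation_voxels != "auto":
            return int(self.dilation_voxels)
        return 5 if float(np.max(spacing)) <= AUTO_DILATION_SPACING_MM else 4

    def structuring_element(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, self.connectivity)


def brain_mask(labelmap: LabeledVolume) -> BinaryMask:
    """Union of all nonzero labels."""
    return BinaryMask(labelmap.data > 0, labelmap.affine)


def extracerebral_mask(labelmap: LabeledVolume, policy: ExtraCerebralPolicy) -> BinaryMask:
    """Closed + hole-filled + dilated brain mask (a superset of the input)."""
    mask = labelmap.data > 0
    if not mask.any():
        raise ValueError("label map contains no nonzero voxel")
    selem = policy.structuring_element()
    closed = ndimage.binary_closing(mask, structure=selem, iterations=1)
    filled = ndimage.binary_fill_holes(closed | mask, structure=selem)
    d = policy.resolve_dilation(labelmap.spacing)
    dilated = ndimage.binary_dilation(filled, structure=selem, iterations=d)
    return BinaryMask(dilated, labelmap.affine)


def add_extracerebral_label(
    labelmap: LabeledVolume, dilated: BinaryMask, policy: ExtraCerebralPolicy
) -> LabeledVolume:
    """Assign ``policy.extracerebral_id`` to voxels gained by dilation.

    Original labels are never overwritten; the number of changed voxels is
    exactly ``|dilated| - |original brain mask|``.
    """
    if policy.extracerebral_id in labelmap.lut or policy.extracerebral_id in set(
        labelmap.present_labels()
    ):
        raise ValueError(
            f"extracerebral id {policy.extracerebral_id} collides with an existing label"
        )
    original = labelmap.data > 0
    if not np.all(dilated.data | ~original):
        raise ValueError("dilated mask does not contain the original brain mask")
    shell = dilated.data & ~original
    out = labelmap.data.copy().astype(np.int32)
    out[shell] = policy.extracerebral_id
    lut = dict(labelmap.lut)
    lut[policy.extracerebral_id] = ("Extra-Cerebral", (80, 80, 80))
    return LabeledVolume(out, labelmap.affine, lut)


def apply_skullstrip(image: IntensityVolume, mask: BinaryMask) -> IntensityVolume:
    """Zero every voxel outside the mask; inside values are untouched."""
    if image.shape != mask.shape:
        raise ValueError(f"grid mismatch: image {image.shape} vs mask {mask.shape}")
    out = image.data.copy()
    out[~mask.data] = 0
    return IntensityVolume(out, image.affine.copy())
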