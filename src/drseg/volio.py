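"""Volume I/O, canonical reorientation, and spacing resampling.

The two central objects are :class:`IntensityVolume` (scalar MR-like image)
and :class:`LabeledVolume` (integer segmentation with a lookup table), both
carrying a NIfTI-style 4x4 voxel-to-world affine.  Voxel indices are 0-based
and the affine maps the *center* of voxel ``(i, j, k)`` to world millimetres.

Resampling conventions:

* intensities: cubic B-spline interpolation, mirror boundary;
* label maps: one-hot encoding per present label, trilinear interpolation of
  each channel, argmax with ties going to the *lowest* label id;
* the world position of the center of voxel ``(0, 0, 0)`` is kept fixed and
  the field of view is preserved to within one output voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityVolume",
    "LabeledVolume",
    "Orientation",
    "FS35_LUT",
    "load_intensity",
    "load_labels",
    "save_volume",
    "read_color_table",
    "write_color_table",
    "reorient",
    "resample_intensity",
    "resample_labels",
]

_AXIS_LETTERS = {"L", "R", "A", "P", "S", "I"}
# letter -> (anatomical axis index, sign of the direction the axis points to)
_LETTER_TO_AXIS = {
    "R": (0, 1), "L": (0, -1),
    "A": (1, 1), "P": (1, -1),
    "S": (2, 1), "I": (2, -1),
}

#: direction-cosine dominance below which an affine is declared oblique
OBLIQUITY_TOL = 0.9


@dataclass(frozen=True)
class Orientation:
    """Three-letter anatomical axis code such as ``"RAS"`` or ``"LIA"``.

    Each letter names the world direction toward which the corresponding
    voxel axis points (nibabel ``axcodes`` convention).
    """

    code: str

    def __post_init__(self) -> None:
        code = self.code.upper()
        if len(code) != 3 or any(c not in _AXIS_LETTERS for c in code):
            raise ValueError(f"invalid orientation code {self.code!r}")
        axes = [_LETTER_TO_AXIS[c][0] for c in code]
        if len(set(axes)) != 3:
            raise ValueError(f"orientation {self.code!r} repeats an anatomical axis")
        object.__setattr__(self, "code", code)

    @property
    def axcodes(self) -> tuple[str, str, str]:
        return tuple(self.code)  # type: ignore[return-value]

    def ornt(self) -> np.ndarray:
        """nibabel orientation array: rows (anatomical axis, direction)."""
        return nib.orientations.axcodes2ornt(self.axcodes)


LIA = Orientation("LIA")
RAS = Orientation("RAS")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class IntensityVolume:
    """Scalar 3D image with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.data.copy(), self.affine.copy())


@dataclass
class LabeledVolume:
    """Integer 3D label map; 0 is background and every nonzero id is in ``lut``."""

    data: np.ndarray
    affine: np.ndarray
    lut: Mapping[int, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label data must be non-negative")
        self.affine = _check_affine(self.affine)
        self.lut = dict(self.lut)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in data but absent from lut")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def present_labels(self) -> list[int]:
        """Sorted nonzero label ids present in the grid."""
        u = np.unique(self.data)
        return [int(v) for v in u if v != 0]

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.data.copy(), self.affine.copy(), dict(self.lut))


# The 35 whole-brain structures of the standard FreeSurfer lookup-table
# convention (id -> (name, (R, G, B))).
FS35_LUT: dict[int, tuple[str, tuple[int, int, int]]] = {
    2: ("Left-Cerebral-White-Matter", (245, 245, 245)),
    3: ("Left-Cerebral-Cortex", (205, 62, 78)),
    4: ("Left-Lateral-Ventricle", (120, 18, 134)),
    5: ("Left-Inf-Lat-Vent", (196, 58, 250)),
    7: ("Left-Cerebellum-White-Matter", (220, 248, 164)),
    8: ("Left-Cerebellum-Cortex", (230, 148, 34)),
    10: ("Left-Thalamus", (0, 118, 14)),
    11: ("Left-Caudate", (122, 186, 220)),
    12: ("Left-Putamen", (236, 13, 176)),
    13: ("Left-Pallidum", (12, 48, 255)),
    14: ("3rd-Ventricle", (204, 182, 142)),
    15: ("4th-Ventricle", (42, 204, 164)),
    16: ("Brain-Stem", (119, 159, 176)),
    17: ("Left-Hippocampus", (220, 216, 20)),
    18: ("Left-Amygdala", (103, 255, 255)),
    24: ("CSF", (60, 60, 60)),
    26: ("Left-Accumbens-area", (255, 165, 0)),
    28: ("Left-VentralDC", (165, 42, 42)),
    31: ("Left-choroid-plexus", (0, 200, 200)),
    41: ("Right-Cerebral-White-Matter", (245, 245, 245)),
    42: ("Right-Cerebral-Cortex", (205, 62, 78)),
    43: ("Right-Lateral-Ventricle", (120, 18, 134)),
    44: ("Right-Inf-Lat-Vent", (196, 58, 250)),
    46: ("Right-Cerebellum-White-Matter", (220, 248, 164)),
    47: ("Right-Cerebellum-Cortex", (230, 148, 34)),
    49: ("Right-Thalamus", (0, 118, 14)),
    50: ("Right-Caudate", (122, 186, 220)),
    51: ("Right-Putamen", (236, 13, 176)),
    52: ("Right-Pallidum", (12, 48, 255)),
    53: ("Right-Hippocampus", (220, 216, 20)),
    54: ("Right-Amygdala", (103, 255, 255)),
    58: ("Right-Accumbens-area", (255, 165, 0)),
    60: ("Right-VentralDC", (165, 42, 42)),
    63: ("Right-choroid-plexus", (0, 200, 200)),
    77: ("WM-hypointensities", (200, 70, 255)),
}


# ---------------------------------------------------------------------------
# NIfTI and color-table I/O
# ---------------------------------------------------------------------------

def load_intensity(path: str | Path) -> IntensityVolume:
    img = nib.load(str(path))
    return IntensityVolume(np.asanyarray(img.dataobj, dtype=np.float32), img.affine)


def load_labels(path: str | Path, lut: Mapping[int, tuple] | None = None) -> LabeledVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.rint(data).astype(np.int32)
    if lut is None:
        lut = {int(v): (f"label-{int(v)}", (128, 128, 128)) for v in np.unique(data) if v != 0}
    return LabeledVolume(data, img.affine, lut)


def save_volume(vol: IntensityVolume | LabeledVolume, path: str | Path) -> None:
    data = vol.data
    if isinstance(vol, LabeledVolume):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def read_color_table(path: str | Path) -> dict[int, tuple[str, tuple[int, int, int]]]:
    """Parse a FreeSurfer-style color table: ``id name R G B A`` per line."""
    lut: dict[int, tuple[str, tuple[int, int, int]]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"malformed color-table line: {raw!r}")
        lid = int(parts[0])
        name = parts[1]
        r, g, b = (int(p) for p in parts[2:5])
        lut[lid] = (name, (r, g, b))
    return lut


def write_color_table(lut: Mapping[int, tuple], path: str | Path) -> None:
    lines = []
    for lid in sorted(lut):
        name, color = lut[lid]
        r, g, b = color
        lines.append(f"{lid} {name} {r} {g} {b} 0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reorientation
# ---------------------------------------------------------------------------

def orientation_of(vol: IntensityVolume | LabeledVolume) -> Orientation:
    """Closest cardinal orientation of ``vol``; raises on oblique affines."""
    ornt = _io_orientation_strict(vol.affine)
    codes = nib.orientations.ornt2axcodes(ornt)
    return Orientation("".join(codes))


def _io_orientation_strict(affine: np.ndarray) -> np.ndarray:
    lin = affine[:3, :3]
    cosines = lin / np.linalg.norm(lin, axis=0, keepdims=True)
    for j in range(3):
        if np.max(np.abs(cosines[:, j])) < OBLIQUITY_TOL:
            raise ValueError(
                "oblique affine: voxel axis %d has no cardinal direction with "
                "|cosine| > %.2f" % (j, OBLIQUITY_TOL)
            )
    return nib.orientations.io_orientation(affine)


def reorient(vol, target: Orientation | str):
    """Permute/flip grid axes so they point along ``target`` anatomical axes.

    World coordinates of every voxel center are unchanged; no interpolation
    is performed.  Returns the same volume type.
    """
    if isinstance(target, str):
        target = Orientation(target)
    src_ornt = _io_orientation_strict(vol.affine)
    dst_ornt = target.ornt()
    transform = nib.orientations.ornt_transform(src_ornt, dst_ornt)
    if np.array_equal(transform, np.array([[0, 1], [1, 1], [2, 1]], dtype=float)):
        return vol.copy()
    new_data = nib.orientations.apply_orientation(vol.data, transform)
    new_affine = vol.affine @ nib.orientations.inv_ornt_aff(transform, vol.shape)
    if isinstance(vol, LabeledVolume):
        return LabeledVolume(np.ascontiguousarray(new_data), new_affine, dict(vol.lut))
    return IntensityVolume(np.ascontiguousarray(new_data), new_affine)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _resample_geometry(vol, target_spacing):
    target_spacing = np.asarray(target_spacing, dtype=float)
    if target_spacing.shape != (3,):
        target_spacing = np.broadcast_to(target_spacing, (3,)).astype(float)
    if np.any(target_spacing <= 0):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    src_spacing = vol.spacing
    # voxel-space scale: output index j samples input coordinate j * step
    step = target_spacing / src_spacing
    new_shape = np.maximum(1, np.rint(np.asarray(vol.shape) / step)).astype(int)
    # keep the world position of voxel (0,0,0) center; scale direction columns
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] * step[np.newaxis, :]
    return step, tuple(int(n) for n in new_shape), new_affine


def _output_coords(step: np.ndarray, shape: tuple[int, int, int]) -> list[np.ndarray]:
    return np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, step)], indexing="ij", sparse=True
    )


def resample_intensity(vol: IntensityVolume, target_spacing) -> IntensityVolume:
    """Resample a scalar volume to ``target_spacing`` with cubic splines."""
    step, new_shape, new_affine = _resample_geometry(vol, target_spacing)
    if np.allclose(step, 1.0, atol=1e-9):
        return vol.copy()
    coords = _output_coords(step, new_shape)
    grid = np.broadcast_arrays(*coords)
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(grid), order=3, mode="mirror"
    )
    return IntensityVolume(out.astype(np.float32), new_affine)


def resample_labels(vol: LabeledVolume, target_spacing) -> LabeledVolume:
    """Resample a label map: one-hot channels, trilinear, argmax.

    Ties go to the lowest label id; the output label set is a subset of the
    input's.  Out-of-bounds regions interpolate toward background.
    """
    step, new_shape, new_affine = _resample_geometry(vol, target_spacing)
    if np.allclose(step, 1.0, atol=1e-9):
        return vol.copy()
    coords = np.stack(np.broadcast_arrays(*_output_coords(step, new_shape)))
    labels = vol.present_labels()
    best_val = np.full(new_shape, -np.inf)
    best_lab = np.zeros(new_shape, dtype=np.int32)
    # background channel first so labels only win with prob > background
    channels = [0] + labels
    for lab in channels:
        chan = (vol.data == lab).astype(np.float32)
        # edge clamp: output centers overhang the last input center by at
        # most half a voxel, which must not bleed background in
        interp = ndimage.map_coordinates(chan, coords, order=1, mode="nearest")
        better = interp > best_val  # strict: earlier (lower) ids win ties
        best_val[better] = interp[better]
        best_lab[better] = lab
    return LabeledVolume(best_lab, new_affine, dict(vol.lut))
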