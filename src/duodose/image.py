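"""Volume and mask data model, NIfTI I/O and body-mask delineation.

All volumes live on an axis-aligned grid indexed ``(x, y, z)``.  The world
coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing`` (mm); no
orientation matrix is supported because the dual-isotope SPECT, the low-dose
CT and every derived mask are co-acquired on the same axis-aligned grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "GridMismatchReport",
    "GridError",
    "DegenerateInputError",
    "FormatError",
    "read_volume",
    "write_volume",
    "check_same_grid",
    "require_same_grid",
    "body_mask",
]

#: Two grids are "the same" when spacing and origin agree within this many mm.
GRID_TOL_MM = 1e-6

#: 26-connectivity structuring element used for all component labelling.
CONN26 = np.ones((3, 3, 3), dtype=bool)


class FormatError(ValueError):
    """Raised when a file is not a readable 3D scalar NIfTI volume."""


class GridError(ValueError):
    """Raised when two volumes that must share a grid do not."""


class DegenerateInputError(ValueError):
    """Raised when an input is empty/all-zero where content is required."""


@dataclass
class VoxelGrid:
    """A 3D scalar volume with physical spacing and origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; units are defined by the caller (counts, MBq/ml, HU, Gy).
    spacing : tuple of float
        Per-axis voxel size in mm; all components strictly positive.
    origin : tuple of float
        World position (mm) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(
                f"expected a 3D volume, got {self.values.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (= cm^3); spacing is in mm."""
        return float(np.prod(self.spacing)) / 1000.0

    def copy_with(self, values: np.ndarray) -> "VoxelGrid":
        """New grid carrying ``values`` with this grid's geometry."""
        return VoxelGrid(values, self.spacing, self.origin)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world coordinates in mm."""
        return np.asarray(self.origin) + np.asarray(indices) * np.asarray(self.spacing)


@dataclass
class BinaryMask(VoxelGrid):
    """A :class:`VoxelGrid` restricted to values {0, 1}, defining a VOI."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        self.values = arr
        super().__post_init__()
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def volume_ml(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_ml

    @property
    def num_voxels(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def copy_with(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.spacing, self.origin)


@dataclass
class GridMismatchReport:
    """Result of comparing the geometry of two grids."""

    shape_a: tuple[int, ...]
    shape_b: tuple[int, ...]
    spacing_a: tuple[float, ...]
    spacing_b: tuple[float, ...]
    origin_a: tuple[float, ...]
    origin_b: tuple[float, ...]
    compatible: bool = field(init=False)
    reasons: list[str] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        self.reasons = []
        if self.shape_a != self.shape_b:
            self.reasons.append(f"shape mismatch: {self.shape_a} vs {self.shape_b}")
        if not np.allclose(self.spacing_a, self.spacing_b, rtol=0, atol=GRID_TOL_MM):
            self.reasons.append(
                f"spacing mismatch: {self.spacing_a} vs {self.spacing_b}"
            )
        if not np.allclose(self.origin_a, self.origin_b, rtol=0, atol=GRID_TOL_MM):
            self.reasons.append(f"origin mismatch: {self.origin_a} vs {self.origin_b}")
        self.compatible = not self.reasons


def check_same_grid(a: VoxelGrid, b: VoxelGrid) -> GridMismatchReport:
    """Compare geometry of two grids (shape exact; spacing/origin to 1e-6 mm)."""
    return GridMismatchReport(
        a.shape, b.shape, a.spacing, b.spacing, a.origin, b.origin
    )


def require_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    """Raise :class:`GridError` unless ``a`` and ``b`` share a grid."""
    report = check_same_grid(a, b)
    if not report.compatible:
        raise GridError("; ".join(report.reasons))


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def read_volume(path: str | os.PathLike, as_mask: bool = False) -> VoxelGrid:
    """Read a 3D NIfTI-1 volume into a :class:`VoxelGrid`.

    Spacing is taken from the header zooms and the origin from the affine
    translation; the volume is assumed axis-aligned.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    cls = BinaryMask if as_mask else VoxelGrid
    return cls(np.ascontiguousarray(data), spacing, origin)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI volume and validate it as a binary mask."""
    return read_volume(path, as_mask=True)  # type: ignore[return-value]


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VoxelGrid` as NIfTI-1; masks are stored as uint8."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    data = grid.values
    if isinstance(grid, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(grid))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def body_mask(ct: VoxelGrid, threshold: float = -500.0) -> BinaryMask:
    """Delineate the patient body on a (pseudo-)CT by thresholding.

    The mask is the largest 26-connected component of voxels above
    ``threshold`` (HU), with interior holes filled in 3D and then per axial
    slice, so internal air cavities belong to the body.
    """
    above = ct.values > threshold
    if not above.any():
        raise DegenerateInputError(
            f"no voxel above {threshold} HU; cannot delineate a body"
        )
    labels, n = ndimage.label(above, structure=CONN26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        above = labels == counts.argmax()
    filled = ndimage.binary_fill_holes(above)
    for k in range(filled.shape[2]):  # axial = fixed z
        filled[:, :, k] = ndimage.binary_fill_holes(filled[:, :, k])
    return BinaryMask(filled.astype(np.uint8), ct.spacing, ct.origin)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean array."""
    labels, n = ndimage.label(mask, structure=CONN26)
    if n <= 1:
        return mask.astype(bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()
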