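"""Healthy-liver segmentation.

Two arms are provided:

* the automatic threshold method operating on the :sup:`99m`Tc SPECT of a
  dual-isotope acquisition — the spleen (also Tc-avid) is removed first,
  the maximum of a *smoothed* copy of the image is found, and the
  *original* image is thresholded at 40% of that maximum;
* the manual-reference construction, where the healthy VOI is the liver
  mask minus tumors larger than 1 cm in diameter minus necrotic tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import (
    CONN26,
    BinaryMask,
    DegenerateInputError,
    VoxelGrid,
    largest_component,
    require_same_grid,
)
from .phantom import FWHM_TO_SIGMA

__all__ = [
    "SegmentationConfig",
    "gaussian_smooth",
    "remove_spleen",
    "automatic_healthy_mask",
    "reference_healthy_mask",
    "equivalent_sphere_diameter_mm",
]


@dataclass
class SegmentationConfig:
    """Parameters of the automatic threshold segmentation.

    threshold_fraction
        Fraction of the smoothed-image maximum used as the absolute
        threshold on the original image; the clinical protocol uses 0.40.
    smoothing_fwhm_mm
        FWHM of the Gaussian used to smooth the copy in which the maximum
        is determined.
    spleen_strategy
        ``"largest_component"`` removes everything but the largest
        provisional uptake component (the liver dwarfs the spleen);
        ``"provided_mask"`` zeroes a supplied spleen mask instead.
    min_component_ml
        Post-threshold components smaller than this are discarded as noise
        islands; 0 disables the cleanup.
    """

    threshold_fraction: float = 0.40
    smoothing_fwhm_mm: float = 10.0
    spleen_strategy: str = "largest_component"
    min_component_ml: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.spleen_strategy not in ("largest_component", "provided_mask"):
            raise ValueError(f"unknown spleen_strategy {self.spleen_strategy!r}")
        if self.min_component_ml < 0:
            raise ValueError("min_component_ml must be >= 0")


def gaussian_smooth(img: VoxelGrid, fwhm_mm: float) -> VoxelGrid:
    """Gaussian-filter a volume with a physical-units FWHM.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxels via
    the grid spacing.  Zero-padding keeps the kernel normalized, so the
    integral of an interior blob is preserved.  ``fwhm_mm = 0`` returns the
    input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return img.copy_with(np.array(img.values, dtype=float, copy=True))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(img.spacing)
    out = ndimage.gaussian_filter(
        np.asarray(img.values, dtype=float), sigma=sigma_vox, mode="constant"
    )
    return img.copy_with(out)


def _provisional_components(
    tc: VoxelGrid, config: SegmentationConfig
) -> tuple[np.ndarray, int]:
    smoothed = gaussian_smooth(tc, config.smoothing_fwhm_mm)
    m = float(smoothed.values.max())
    if m <= 0:
        raise DegenerateInputError("count image has no positive voxels")
    seg = np.asarray(tc.values) >= config.threshold_fraction * m
    return ndimage.label(seg, structure=CONN26)


def remove_spleen(
    tc_counts: VoxelGrid,
    config: SegmentationConfig,
    spleen_mask: BinaryMask | None = None,
) -> VoxelGrid:
    """Zero spleen uptake out of a 99mTc count image.

    With ``provided_mask`` the given spleen mask is zeroed.  With
    ``largest_component`` a provisional segmentation (smooth, threshold at
    ``threshold_fraction`` of the smoothed maximum, 26-connected
    components) is computed and every component except the largest by
    volume is zeroed — the liver always dominates the spleen in volume.
    """
    vals = np.array(tc_counts.values, dtype=float, copy=True)
    if config.spleen_strategy == "provided_mask":
        if spleen_mask is None:
            raise ValueError("spleen_strategy='provided_mask' requires a spleen mask")
        require_same_grid(tc_counts, spleen_mask)
        vals[spleen_mask.as_bool()] = 0.0
        return tc_counts.copy_with(vals)
    labels, n = _provisional_components(tc_counts, config)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        vals[(labels != counts.argmax()) & (labels > 0)] = 0.0
    return tc_counts.copy_with(vals)


def automatic_healthy_mask(
    tc_counts: VoxelGrid,
    config: SegmentationConfig | None = None,
    spleen_mask: BinaryMask | None = None,
) -> BinaryMask:
    """Automatic healthy-liver segmentation of a 99mTc SPECT volume.

    After spleen removal, the maximum value of a smoothed copy is
    determined and the original (unsmoothed, spleen-removed) image is
    thresholded at ``threshold_fraction`` of that maximum.  Components
    smaller than ``min_component_ml`` are discarded.  The output lives on
    the input grid — the dual-isotope acquisition is intrinsically
    registered, so no registration step is required.
    """
    config = config or SegmentationConfig()
    if not (np.asarray(tc_counts.values) > 0).any():
        raise DegenerateInputError("count image has no positive voxels")
    cleaned = remove_spleen(tc_counts, config, spleen_mask)
    smoothed = gaussian_smooth(cleaned, config.smoothing_fwhm_mm)
    m = float(smoothed.values.max())
    if m <= 0:
        raise DegenerateInputError("image is empty after spleen removal")
    seg = np.asarray(cleaned.values) >= config.threshold_fraction * m
    if config.min_component_ml > 0 and seg.any():
        labels, _ = ndimage.label(seg, structure=CONN26)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = np.flatnonzero(counts * tc_counts.voxel_volume_ml >= config.min_component_ml)
        seg = np.isin(labels, keep) & (labels > 0)
    return BinaryMask(seg.astype(np.uint8), tc_counts.spacing, tc_counts.origin)


def equivalent_sphere_diameter_mm(mask: BinaryMask) -> float:
    """Diameter (mm) of the sphere with the mask's volume: 2*(3V/4pi)^(1/3)."""
    v_mm3 = mask.num_voxels * float(np.prod(mask.spacing))
    return 2.0 * (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def reference_healthy_mask(
    liver: BinaryMask,
    tumors: list[BinaryMask] | None = None,
    necrosis: BinaryMask | None = None,
    min_tumor_diameter_mm: float = 10.0,
) -> BinaryMask:
    """Manual-reference healthy VOI: liver minus tumors minus necrosis.

    Tumors with equivalent-sphere diameter at or below
    ``min_tumor_diameter_mm`` (default 1 cm) are too small to be included
    in the VOI processing and are ignored.
    """
    out = liver.as_bool().copy()
    for t in tumors or []:
        require_same_grid(liver, t)
        if equivalent_sphere_diameter_mm(t) > min_tumor_diameter_mm:
            out &= ~t.as_bool()
    if necrosis is not None:
        require_same_grid(liver, necrosis)
        out &= ~necrosis.as_bool()
    return BinaryMask(out.astype(np.uint8), liver.spacing, liver.origin)
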