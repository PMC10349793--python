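"""Synthetic dual-isotope SPECT phantom.

Emulates the statistical structure the downstream analysis assumes: a liver
built from two overlapping ellipsoids with uniform healthy-parenchyma
:sup:`99m`Tc uptake, cold tumors (Kupffer cells are absent in tumorous
tissue) with optional necrotic cores cold in both isotopes, a Tc-avid
spleen, :sup:`166`Ho activity concentrated in tumors with lower uptake in
healthy tissue, SPECT-like Gaussian resolution blur with Poisson count
noise, and a rigid misregistration model for the manual-segmentation arm.

Geometry is deterministic; randomness enters only through
:func:`simulate_spect` (count noise) and is controlled by explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .image import BinaryMask, DegenerateInputError, VoxelGrid

__all__ = [
    "Ellipsoid",
    "Tumor",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "simulate_spect",
    "perturb_mask",
    "stage_seed",
]

#: Conversion between Gaussian FWHM and sigma: FWHM = sigma * 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Beta-decay energy deposited per unit 166Ho activity, mJ/MBq.
HO166_ENERGY_MJ_PER_MBQ = 15.87

#: Soft-tissue density, g/ml.
SOFT_TISSUE_DENSITY_G_PER_ML = 1.06


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm (world coords)."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        d = (np.asarray(points_mm) - self.center_mm) / np.asarray(self.semiaxes_mm)
        return (d**2).sum(axis=-1) <= 1.0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c, a = np.asarray(self.center_mm), np.asarray(self.semiaxes_mm)
        return c - a, c + a


@dataclass
class Tumor:
    """Spherical tumor, optionally with a concentric necrotic core."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    necrotic_core_diameter_mm: float = 0.0

    def sphere(self) -> Ellipsoid:
        r = self.diameter_mm / 2.0
        return Ellipsoid(self.center_mm, (r, r, r))

    def core(self) -> Ellipsoid | None:
        if self.necrotic_core_diameter_mm <= 0:
            return None
        r = self.necrotic_core_diameter_mm / 2.0
        return Ellipsoid(self.center_mm, (r, r, r))


def _default_liver() -> tuple[Ellipsoid, Ellipsoid]:
    return (
        Ellipsoid((105.0, 140.0, 160.0), (70.0, 55.0, 60.0)),
        Ellipsoid((145.0, 170.0, 140.0), (50.0, 45.0, 50.0)),
    )


def _default_spleen() -> Ellipsoid:
    return Ellipsoid((225.0, 110.0, 150.0), (32.0, 24.0, 42.0))


def _default_body() -> Ellipsoid:
    return Ellipsoid((150.0, 150.0, 153.6), (140.0, 125.0, 150.0))


def _default_tumors() -> list[Tumor]:
    return [
        Tumor((90.0, 125.0, 175.0), 40.0),
        Tumor((140.0, 165.0, 135.0), 30.0, necrotic_core_diameter_mm=14.0),
    ]


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition.

    Defaults describe a realistic adult study: 64^3 grid at 4.8 mm (the
    clinical SPECT pixel spacing), a ~1.3 L liver, ~0.15 L spleen, two
    tumors (one with a necrotic core), 5.4 GBq administered 166Ho and
    50 MBq 99mTc, 10 mm PSF, and a breathing-dominated misregistration of
    (8, 4, 12) mm plus 3 degrees about z for the manual arm.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.8, 4.8, 4.8)
    liver: tuple[Ellipsoid, Ellipsoid] = field(default_factory=_default_liver)
    spleen: Ellipsoid = field(default_factory=_default_spleen)
    body: Ellipsoid = field(default_factory=_default_body)
    tumors: list[Tumor] = field(default_factory=_default_tumors)
    tc_spleen_to_liver_ratio: float = 1.0
    ho_tumor_to_normal_ratio: float = 3.0
    psf_fwhm_mm: float = 10.0
    ho_total_counts: int = 5_000_000
    tc_total_counts: int = 5_000_000
    administered_activity_MBq: float = 5400.0
    tc_activity_MBq: float = 50.0
    misregistration_translation_mm: tuple[float, float, float] = (8.0, 4.0, 12.0)
    misregistration_rotation_deg_z: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tc_spleen_to_liver_ratio < 0 or self.ho_tumor_to_normal_ratio < 0:
            raise ValueError("uptake ratios must be >= 0")
        if self.ho_total_counts <= 0 or self.tc_total_counts <= 0:
            raise ValueError("total counts must be > 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        extent = np.asarray(self.shape) * np.asarray(self.spacing_mm)
        bodies: list[Ellipsoid] = [*self.liver, self.spleen, self.body]
        bodies += [t.sphere() for t in self.tumors]
        for b in bodies:
            lo, hi = b.bounds()
            if (lo < 0).any() or (hi > extent).any():
                raise ValueError(
                    f"geometry {b} exceeds the grid extent {tuple(extent)} mm"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "liver" in d:
            d["liver"] = tuple(Ellipsoid(**e) for e in d["liver"])
        for key in ("spleen", "body"):
            if key in d and isinstance(d[key], dict):
                d[key] = Ellipsoid(**d[key])
        if "tumors" in d:
            d["tumors"] = [Tumor(**t) for t in d["tumors"]]
        for key in ("shape", "spacing_mm", "misregistration_translation_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Noiseless ground truth produced by :func:`make_phantom`."""

    ho_activity: VoxelGrid  # MBq/ml
    tc_activity: VoxelGrid  # MBq/ml
    ct: VoxelGrid  # pseudo-HU
    liver: BinaryMask
    spleen: BinaryMask
    tumors: BinaryMask  # union of tumor spheres
    necrosis: BinaryMask
    healthy_truth: BinaryMask  # liver - tumors - necrosis
    body: BinaryMask
    administered_activity_MBq: float
    true_mean_dose_gy: float


def _voxel_centers(shape, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """World coordinates (mm) of all voxel centers as an (nx, ny, nz, 3) array."""
    axes = [
        origin[i] + np.arange(shape[i]) * spacing[i] for i in range(3)
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return grid


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize a :class:`PhantomSpec` into noiseless activity maps and masks.

    The healthy-liver truth is liver minus tumors minus necrosis.  99mTc
    concentration is uniform in healthy parenchyma, scaled in the spleen by
    ``tc_spleen_to_liver_ratio`` and zero in tumors and necrosis.  166Ho
    concentration is ``ho_tumor_to_normal_ratio`` times higher in viable
    tumor than in healthy tissue, zero in necrosis and outside the liver,
    and normalized so the activity integral equals the administered
    activity.
    """
    pts = _voxel_centers(spec.shape, spec.spacing_mm)
    liver = spec.liver[0].contains(pts) | spec.liver[1].contains(pts)
    spleen = spec.spleen.contains(pts)
    body = spec.body.contains(pts)
    tumors = np.zeros(spec.shape, dtype=bool)
    necrosis = np.zeros(spec.shape, dtype=bool)
    for t in spec.tumors:
        tumors |= t.sphere().contains(pts)
        core = t.core()
        if core is not None:
            necrosis |= core.contains(pts)
    tumors &= liver
    necrosis &= tumors
    healthy = liver & ~tumors  # necrosis is a subset of tumors
    viable_tumor = tumors & ~necrosis

    spacing = spec.spacing_mm
    voxel_ml = float(np.prod(spacing)) / 1000.0

    # 166Ho: concentration c in healthy tissue, ratio*c in viable tumor.
    n_healthy = int(healthy.sum())
    n_viable = int(viable_tumor.sum())
    if n_healthy == 0:
        raise ValueError("phantom has no healthy liver voxels")
    denom = (n_healthy + spec.ho_tumor_to_normal_ratio * n_viable) * voxel_ml
    c_ho = spec.administered_activity_MBq / denom
    ho = np.zeros(spec.shape)
    ho[healthy] = c_ho
    ho[viable_tumor] = spec.ho_tumor_to_normal_ratio * c_ho

    # 99mTc: uniform in healthy parenchyma and (scaled) spleen.
    n_spleen = int(spleen.sum())
    denom_tc = (n_healthy + spec.tc_spleen_to_liver_ratio * n_spleen) * voxel_ml
    c_tc = spec.tc_activity_MBq / denom_tc
    tc = np.zeros(spec.shape)
    tc[healthy] = c_tc
    tc[spleen] = spec.tc_spleen_to_liver_ratio * c_tc

    ct = np.where(body, 0.0, -1000.0)

    true_mean_dose = float(
        HO166_ENERGY_MJ_PER_MBQ * ho[healthy].mean() / SOFT_TISSUE_DENSITY_G_PER_ML
    )

    def mask(arr: np.ndarray) -> BinaryMask:
        return BinaryMask(arr.astype(np.uint8), spacing)

    return PhantomTruth(
        ho_activity=VoxelGrid(ho, spacing),
        tc_activity=VoxelGrid(tc, spacing),
        ct=VoxelGrid(ct, spacing),
        liver=mask(liver),
        spleen=mask(spleen),
        tumors=mask(tumors),
        necrosis=mask(necrosis),
        healthy_truth=mask(healthy),
        body=mask(body),
        administered_activity_MBq=spec.administered_activity_MBq,
        true_mean_dose_gy=true_mean_dose,
    )


def simulate_spect(
    activity: VoxelGrid,
    psf_fwhm_mm: float,
    total_counts: int,
    seed: int,
) -> VoxelGrid:
    """Simulate a reconstructed SPECT count volume from an activity map.

    The activity is blurred by a stationary isotropic Gaussian PSF
    (``sigma = fwhm / (2 sqrt(2 ln 2))`` in mm, normalized so the integral
    is conserved), rescaled so the expected total equals ``total_counts``,
    and Poisson-sampled voxelwise.  Projection-domain physics (collimator,
    scatter, downscatter) is out of scope; images arrive "reconstructed".
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    vals = np.asarray(activity.values, dtype=float)
    if (vals < 0).any():
        raise ValueError("activity must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise DegenerateInputError("activity volume is identically zero")
    if psf_fwhm_mm > 0:
        sigma_vox = psf_fwhm_mm * FWHM_TO_SIGMA / np.asarray(activity.spacing)
        vals = ndimage.gaussian_filter(vals, sigma=sigma_vox, mode="constant")
    lam = vals * (float(total_counts) / vals.sum())
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(float)
    return activity.copy_with(counts)


def perturb_mask(
    mask: BinaryMask,
    translation_mm: tuple[float, float, float],
    rotation_deg_z: float,
    seed: int = 0,
) -> BinaryMask:
    """Apply a rigid transform to a mask, emulating registration error.

    The rotation (about z, degrees) is applied about the mask centroid in
    world coordinates, followed by the translation; the result is resampled
    onto the same grid with nearest-neighbour interpolation.  ``seed`` is
    accepted for interface uniformity with the simulation stages but the
    transform itself is deterministic.

    A warning is emitted (and the mask clipped) if the transform pushes
    mask voxels outside the grid.
    """
    del seed  # deterministic; see docstring
    if mask.num_voxels == 0:
        raise DegenerateInputError("cannot perturb an empty mask")
    t = np.asarray(translation_mm, dtype=float)
    theta = np.deg2rad(rotation_deg_z)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    idx = np.argwhere(mask.as_bool())
    centroid = origin + idx.mean(axis=0) * spacing  # world mm

    # Forward map: p_out = R (p - c) + c + t.  Warn if any voxel leaves the grid.
    world = origin + idx * spacing
    moved = (rot @ (world - centroid).T).T + centroid + t
    moved_idx = np.rint((moved - origin) / spacing)
    hi = np.asarray(mask.shape) - 1
    if (moved_idx < 0).any() or (moved_idx > hi).any():
        warnings.warn(
            "rigid transform moves mask voxels outside the grid; mask clipped",
            stacklevel=2,
        )

    # Resampling needs the inverse map in index space:
    #   idx_in = S^-1 (R^-1 (S idx_out + o - c - t) + c - o)
    rinv = rot.T
    matrix = np.diag(1.0 / spacing) @ rinv @ np.diag(spacing)
    offset = (rinv @ (origin - centroid - t) + centroid - origin) / spacing
    out = ndimage.affine_transform(
        mask.values, matrix, offset=offset, order=0, mode="constant", cval=0,
        output=np.uint8,
    )
    return BinaryMask(out, mask.spacing, mask.origin)


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed fan-out from a single global seed."""
    return int((int(seed) * 1_000_003 + 7919 * (stage + 1)) % (2**31))
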