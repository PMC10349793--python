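# Methods

## Data model and conventions

All volumes are axis-aligned 3D grids indexed `(x, y, z)`; the world
coordinate of voxel `(i, j, k)` is `origin + index · spacing` (mm). No
orientation matrix is supported: the dual-isotope SPECT, the low-dose CT
and all derived masks are co-acquired on one grid, and the phantom writes
axis-aligned volumes. Grid equality is checked to 1e-6 mm (header
round-off). Masks are stored as unsigned 8-bit NIfTI-1.

## Automatic healthy-liver segmentation

The ⁹⁹ᵐTc image of the dual-isotope acquisition maps Kupffer-cell uptake,
i.e. healthy parenchyma plus spleen. The segmentation is:

1. **Spleen removal.** Either a provided spleen mask is zeroed, or a
   provisional segmentation (smooth → threshold at the configured fraction
   of the smoothed maximum → 26-connected components) is computed and
   every component except the largest by volume is zeroed out of the count
   image. The liver always dominates the spleen in volume, and removal
   happens *before* the maximum is taken so a hot spleen cannot set the
   threshold level.
2. **Threshold.** The maximum `M` of a Gaussian-smoothed copy
   (default FWHM 10 mm) is found, and the *original*, spleen-removed image
   is thresholded at `0.40 · M`. This is deliberate: many threshold methods
   segment the smoothed image throughout; here the smoothing only
   stabilizes the maximum against noise spikes, while the threshold is
   applied to unsmoothed voxels.
3. **Cleanup.** Connected components smaller than `min_component_ml`
   (default 1 ml) are discarded as noise islands. This post-processing is
   an extension and can be disabled with `min_component_ml = 0`.

Because the threshold is relative, the mask is invariant to positive
rescaling of the count image, and lowering the threshold fraction can only
grow the mask (both tested as properties).

## Manual-reference VOI and misregistration model

The reference healthy VOI is liver − tumors − necrosis, where only tumors
with equivalent-sphere diameter `2·(3V/4π)^{1/3}` strictly greater than
10 mm are subtracted; the diameter rule is evaluated on the mask volume
since masks are what the package receives. In synthetic mode the clinical
chain "CECT delineation + manual rigid registration" is emulated by
applying a rigid transform (rotation about z through the mask centroid,
then translation, nearest-neighbour resampling) to the ground-truth VOI.
The default misregistration, (8, 4, 12) mm translation with 3° rotation,
is dominated by the cranio-caudal (z) component, reflecting
breathing-driven liver displacement. With user-supplied clinical masks no
perturbation is applied.

## Dosimetry

Local deposition: `dose = 15.87 mJ/MBq · C / ρ` voxelwise, with
ρ = 1.06 g/ml homogeneous (no CT-derived density). Counts become MBq/ml by
distributing the administered activity over counts inside the body mask
(largest 26-connected CT component above −500 HU, holes filled in 3D and
per axial slice), assuming all activity is in the field of view. For
pre-treatment images of partial treatments the scaling activity is the
partial activity, or the sum over complementary partial treatments sharing
a group identifier. By construction the absorbed energy over the body
equals 15.87 mJ/MBq × administered activity; the pipeline asserts this to
1e-6 relative on every run.

DVH conventions (there is no reporting standard): cumulative curves use
0.1 Gy bins by default with "fraction of VOI receiving ≥ d"; D₇₀ is the
30th percentile of voxel doses with linear interpolation between order
statistics (type-7), making results bit-reproducible; V₅₀ is the
percentage of VOI voxels at or above 50 Gy.

## Agreement statistics

Dice `2|A∩B|/(|A|+|B|)`; Hausdorff distance as the classical symmetric
maximum over directed surface distances, computed on 6-connectivity
boundary voxels in physical (anisotropic) mm and reported in cm; signed
volume difference automatic − manual. Bland–Altman uses the n−1 sample SD
and defines the coefficient of reproducibility as 1.96 × SD — the only
convention consistent with limits of agreement at mean ± CoR. The paired
t test is two-sided with `t = mean(d)/(SD(d)/√n)`, df = n − 1;
zero-variance differences violate its contract and raise (cohort runs
report this gracefully instead of failing). For dose–hepatotoxicity the
worst follow-up grade (0–5, ≥ 3 significant) is summarized per grade by
median and IQR of the cumulative dose per method, with a Spearman rank
correlation — chosen because grade is ordinal; no parametric dose–grade
model is implied.

## The synthetic phantom

What it emulates: a liver built from two overlapping ellipsoids (~1.2 L),
an ellipsoidal spleen (~0.13 L), spherical tumors (cold in ⁹⁹ᵐTc) with
optional necrotic cores (cold in both isotopes), uniform concentrations
within each compartment, a stationary isotropic Gaussian PSF (default
FWHM 10 mm — the minimal resolution model that makes a 40% threshold
meaningful), and voxelwise Poisson noise on counts rescaled to a total
count budget (default 5×10⁶ per isotope). Defaults: 64³ grid at 4.8 mm
(the clinical pixel spacing), 5400 MBq ¹⁶⁶Ho and 50 MBq ⁹⁹ᵐTc, ¹⁶⁶Ho
tumor-to-normal concentration ratio 3:1, ⁹⁹ᵐTc spleen-to-liver ratio 1:1.
Geometry is deterministic; randomness enters only in the Poisson stage,
with per-stage seeds fanned out from one global seed by a fixed affine
scheme (`stage_seed`).

What it does not emulate — and hence what passing tests do not show about
clinical data: projection-domain SPECT physics (collimator response,
attenuation, scatter and ¹⁶⁶Ho downscatter, reconstruction artifacts),
heterogeneous intra-organ uptake, non-rigid breathing deformation (the
misregistration is rigid), CT tissue contrast, and realistic tumor-uptake
statistics (the 3:1 ratio is a plausible hypervascular value, not a fitted
one). With the default 3:1 ratio and ~4% tumor burden most activity lands
in healthy tissue, so phantom healthy-liver doses (~60 Gy) sit above the
clinical range; the dose *scale* is irrelevant to the segmentation and
agreement questions the phantom is for, since dosimetry is linear in
activity.

## Numerical choices and degenerate inputs

Gaussian smoothing uses zero-padding so the kernel stays normalized
(interior integrals preserved to 1e-6 relative); FWHM 0 is the identity.
Empty masks, all-zero count images, zero counts inside the body and
constant correlation inputs raise `DegenerateInputError` rather than
returning NaN. Nearest-neighbour resampling of masks keeps volume changes
below 10% for translations up to two voxels (tested). Reports are
serialized with sorted keys; re-running with the same seed and
configuration is byte-identical (stage timings are logged but excluded
from the persisted report).

## Problem sizes

The test suite and the acceptance script run on 64³ phantoms with
5×10⁶–10⁷ counts, 10-run cohorts, 2000-replicate t-test calibrations and
10⁴-pair Bland–Altman recoveries — sizes chosen so a full study is a
desk-scale computation while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

The automatic arm relies on one fixed threshold for all subjects; uptake
heterogeneity or very large cold regions can make it suboptimal. Tumor
segmentation from ⁹⁹ᵐTc cold spots is out of scope (resolution-limited and
confounded by benign cold lesions), as are DICOM ingestion, non-rigid
registration, Monte-Carlo dose transport and lung-shunt dosimetry.
Clinical cohort values quoted in the literature derive from patient images
that are not distributable; the package's synthetic cohorts characterize
the method's behavior, not those numbers.
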