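"""Voxel dosimetry for 166Ho microsphere radioembolization.

The local-deposition model is used throughout: the absorbed dose in a
voxel is proportional to the local activity concentration,

    dose [Gy] = 15.87 [mJ/MBq] * C [MBq/ml] / rho [g/ml],

where 15.87 mJ/MBq is the energy deposited by the beta decay of 1 MBq of
166Ho and rho = 1.06 g/ml is a homogeneous soft-tissue density.  Unit
bookkeeping: (mJ/MBq)(MBq/ml)/(g/ml) = mJ/g = J/kg = Gy.

Reconstructed count images are converted to MBq/ml by distributing the
administered activity over the counts inside the patient-body mask, on
the assumption that all activity is in the SPECT field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import BinaryMask, DegenerateInputError, VoxelGrid, require_same_grid
from .phantom import HO166_ENERGY_MJ_PER_MBQ, SOFT_TISSUE_DENSITY_G_PER_ML

__all__ = [
    "DosimetryConfig",
    "TreatmentRecord",
    "DVHCurve",
    "counts_to_concentration",
    "pretreatment_activity",
    "dose_from_concentration",
    "mean_dose",
    "cumulative_dvh",
    "d_metric",
    "v_metric",
    "absorbed_energy_joules",
]


@dataclass
class DosimetryConfig:
    """Physical constants of the dose conversion."""

    energy_per_activity_mj_per_mbq: float = HO166_ENERGY_MJ_PER_MBQ
    tissue_density_g_per_ml: float = SOFT_TISSUE_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        if self.energy_per_activity_mj_per_mbq <= 0:
            raise ValueError("energy_per_activity must be > 0")
        if self.tissue_density_g_per_ml <= 0:
            raise ValueError("tissue_density must be > 0")


@dataclass
class TreatmentRecord:
    """One administration: activity, pre/post flag, optional partial-treatment link."""

    patient_id: str
    procedure_kind: str  # "pre_treatment" | "post_treatment"
    administered_activity_MBq: float
    partial_treatment_group: str | None = None

    def __post_init__(self) -> None:
        if self.procedure_kind not in ("pre_treatment", "post_treatment"):
            raise ValueError(f"unknown procedure_kind {self.procedure_kind!r}")
        if self.administered_activity_MBq <= 0:
            raise ValueError("administered_activity_MBq must be > 0")


def counts_to_concentration(
    ho_counts: VoxelGrid, body: BinaryMask, activity_MBq: float
) -> VoxelGrid:
    """Convert a 166Ho count image to activity concentration (MBq/ml).

    Counts outside the body mask are discarded; inside, the administered
    activity is distributed proportionally to counts, so the activity
    integral over the body recovers ``activity_MBq`` exactly.
    """
    require_same_grid(ho_counts, body)
    if activity_MBq <= 0:
        raise ValueError("activity_MBq must be > 0")
    inside = body.as_bool()
    if not inside.any():
        raise DegenerateInputError("body mask is empty")
    vals = np.asarray(ho_counts.values, dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    total = vals[inside].sum()
    if total <= 0:
        raise DegenerateInputError("no counts inside the body mask")
    conc = np.zeros_like(vals)
    conc[inside] = activity_MBq * vals[inside] / total / ho_counts.voxel_volume_ml
    return ho_counts.copy_with(conc)


def pretreatment_activity(records: list[TreatmentRecord]) -> float:
    """Scaling activity for a pre-treatment image.

    A single treatment scales by its own (possibly partial) activity;
    complementary partial treatments sharing a ``partial_treatment_group``
    scale by the sum of their activities.
    """
    if not records:
        raise ValueError("at least one treatment record is required")
    if len(records) == 1:
        return float(records[0].administered_activity_MBq)
    groups = {r.partial_treatment_group for r in records}
    if len(groups) != 1 or None in groups:
        raise ValueError(
            "multiple records must share one partial_treatment_group to be summed"
        )
    return float(sum(r.administered_activity_MBq for r in records))


def dose_from_concentration(
    conc: VoxelGrid, config: DosimetryConfig | None = None
) -> VoxelGrid:
    """Voxelwise local-deposition dose image (Gy) from MBq/ml."""
    config = config or DosimetryConfig()
    vals = np.asarray(conc.values, dtype=float)
    if (vals < 0).any():
        raise ValueError("concentration must be non-negative")
    dose = (
        config.energy_per_activity_mj_per_mbq
        * vals
        / config.tissue_density_g_per_ml
    )
    return conc.copy_with(dose)


def _voi_doses(dose: VoxelGrid, voi: BinaryMask) -> np.ndarray:
    require_same_grid(dose, voi)
    inside = voi.as_bool()
    if not inside.any():
        raise DegenerateInputError("VOI is empty")
    return np.asarray(dose.values, dtype=float)[inside]


def mean_dose(dose: VoxelGrid, voi: BinaryMask) -> float:
    """Mean absorbed dose (Gy) over a VOI."""
    return float(_voi_doses(dose, voi).mean())


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``volume_fraction_at_or_above[i]`` is the fraction of the VOI
    receiving at least ``dose_edges[i]`` Gy; the curve starts at 1.0 for
    dose 0 and is non-increasing.
    """

    dose_edges: np.ndarray
    volume_fraction_at_or_above: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.volume_fraction_at_or_above = np.asarray(
            self.volume_fraction_at_or_above, dtype=float
        )
        if self.dose_edges.shape != self.volume_fraction_at_or_above.shape:
            raise ValueError("edges and fractions must have equal length")
        if (np.diff(self.dose_edges) <= 0).any():
            raise ValueError("dose_edges must be strictly ascending")
        f = self.volume_fraction_at_or_above
        if (np.diff(f) > 1e-12).any():
            raise ValueError("volume fractions must be non-increasing")
        if ((f < -1e-12) | (f > 1 + 1e-12)).any():
            raise ValueError("volume fractions must lie in [0, 1]")

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dose_gy": self.dose_edges,
                "volume_fraction_at_or_above": self.volume_fraction_at_or_above,
            }
        )


def cumulative_dvh(
    dose: VoxelGrid, voi: BinaryMask, bin_width_gy: float = 0.1
) -> DVHCurve:
    """Cumulative DVH of a VOI with edges 0, w, 2w, ... past the maximum dose."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    doses = _voi_doses(dose, voi)
    n_edges = int(np.ceil(doses.max() / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    sorted_d = np.sort(doses)
    # fraction with dose >= edge, via the count of doses strictly below it
    below = np.searchsorted(sorted_d, edges, side="left")
    frac = 1.0 - below / doses.size
    return DVHCurve(edges, frac)


def d_metric(dose: VoxelGrid, voi: BinaryMask, volume_fraction: float) -> float:
    """D_f: minimum dose (Gy) received by the hottest fraction ``f`` of the VOI.

    This is the (1 - f) quantile of the voxel-dose distribution, with
    linear interpolation between order statistics; D70 is the 30th
    percentile of the voxel doses.
    """
    if not 0.0 < volume_fraction < 1.0:
        raise ValueError("volume_fraction must lie in (0, 1)")
    doses = _voi_doses(dose, voi)
    return float(np.quantile(doses, 1.0 - volume_fraction))


def v_metric(dose: VoxelGrid, voi: BinaryMask, dose_threshold_gy: float) -> float:
    """V_d: percentage of the VOI receiving at least ``dose_threshold_gy``."""
    if dose_threshold_gy < 0:
        raise ValueError("dose_threshold_gy must be >= 0")
    doses = _voi_doses(dose, voi)
    return float(100.0 * np.mean(doses >= dose_threshold_gy))


def absorbed_energy_joules(
    dose: VoxelGrid, voi: BinaryMask, config: DosimetryConfig | None = None
) -> float:
    """Total energy (J) absorbed in a VOI: sum of dose times voxel mass.

    Voxel mass uses the homogeneous tissue density; with the default
    constants the energy over the body equals 15.87e-3 J/MBq times the
    administered activity, which the pipeline asserts end to end.
    """
    config = config or DosimetryConfig()
    doses = _voi_doses(dose, voi)
    voxel_mass_kg = config.tissue_density_g_per_ml * dose.voxel_volume_ml / 1000.0
    return float(doses.sum() * voxel_mass_kg)
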