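"""Segmentation-agreement and dose-toxicity statistics.

Overlap indices (Sorensen-Dice, Hausdorff distance), signed volume
difference, Bland-Altman paired-difference summaries with the coefficient
of reproducibility defined as 1.96 times the SD of the differences,
Pearson correlation, the two-sided paired t test, and the per-grade
hepatotoxicity summary with a Spearman dose-grade rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .image import BinaryMask, DegenerateInputError, require_same_grid

__all__ = [
    "BlandAltmanSummary",
    "ToxicityRecord",
    "dice",
    "hausdorff",
    "volume_difference",
    "bland_altman",
    "pearson_r",
    "paired_t_test",
    "cumulative_patient_dose",
    "toxicity_summary",
    "plot_bland_altman",
]

#: Normal-quantile factor in the coefficient of reproducibility / limits of
#: agreement (95% of paired differences fall within mean +/- 1.96 SD).
LOA_FACTOR = 1.96


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Sorensen-Dice coefficient 2|A∩B| / (|A|+|B|)."""
    require_same_grid(a, b)
    na, nb = a.num_voxels, b.num_voxels
    if na + nb == 0:
        raise DegenerateInputError("both masks are empty")
    inter = int(np.logical_and(a.as_bool(), b.as_bool()).sum())
    return 2.0 * inter / (na + nb)


def _surface_points_mm(mask: BinaryMask) -> np.ndarray:
    """World coordinates (mm) of surface voxels (6-connectivity boundary)."""
    m = mask.as_bool()
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surface = m & ~eroded
    return mask.index_to_world(np.argwhere(surface))


def hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance between mask surfaces, in cm.

    Computed on surface voxels with physical (anisotropic) spacing:
    max over the two directed distances, each the largest
    nearest-neighbour Euclidean distance from one surface to the other.
    """
    require_same_grid(a, b)
    if a.num_voxels == 0 or b.num_voxels == 0:
        raise DegenerateInputError("Hausdorff distance needs two nonempty masks")
    pa, pb = _surface_points_mm(a), _surface_points_mm(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba)) / 10.0  # mm -> cm


def volume_difference(auto: BinaryMask, manual: BinaryMask) -> float:
    """Signed volume difference, automatic minus manual, in ml."""
    require_same_grid(auto, manual)
    return auto.volume_ml - manual.volume_ml


@dataclass
class BlandAltmanSummary:
    """Paired-difference summary (differences are automatic minus manual)."""

    n: int
    mean_difference: float
    sd_difference: float
    coefficient_of_reproducibility: float = field(init=False)
    upper_limit: float = field(init=False)
    lower_limit: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sd_difference < 0:
            raise ValueError("sd_difference must be >= 0")
        self.coefficient_of_reproducibility = LOA_FACTOR * self.sd_difference
        self.upper_limit = self.mean_difference + self.coefficient_of_reproducibility
        self.lower_limit = self.mean_difference - self.coefficient_of_reproducibility

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "coefficient_of_reproducibility": self.coefficient_of_reproducibility,
            "upper_limit": self.upper_limit,
            "lower_limit": self.lower_limit,
        }


def bland_altman(
    auto_values: "np.ndarray | list[float]",
    manual_values: "np.ndarray | list[float]",
) -> BlandAltmanSummary:
    """Bland-Altman summary of paired measurements.

    Differences are automatic minus manual; the SD uses the n-1
    denominator and the limits of agreement are mean +/- 1.96 SD.
    """
    auto = np.asarray(auto_values, dtype=float)
    manual = np.asarray(manual_values, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("paired value lists must be 1D and of equal length")
    if auto.size < 2:
        raise ValueError("at least two pairs are required")
    d = auto - manual
    return BlandAltmanSummary(
        n=int(d.size),
        mean_difference=float(d.mean()),
        sd_difference=float(d.std(ddof=1)),
    )


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1D samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def paired_t_test(auto_values, manual_values) -> tuple[float, int, float]:
    """Two-sided paired t test on automatic-minus-manual differences.

    Returns ``(t, df, p)`` with ``t = mean(d) / (SD(d)/sqrt(n))`` and
    ``df = n - 1``.  Zero-variance differences are a contract violation.
    """
    auto = np.asarray(auto_values, dtype=float)
    manual = np.asarray(manual_values, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1 or auto.size < 2:
        raise ValueError("need two equal-length 1D samples with n >= 2")
    d = auto - manual
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("paired differences have zero variance")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def cumulative_patient_dose(doses_per_treatment) -> float:
    """Sum of healthy-liver mean doses over all treatments received (Gy)."""
    doses = np.asarray(doses_per_treatment, dtype=float)
    if doses.size == 0:
        raise ValueError("at least one treatment dose is required")
    if (doses < 0).any():
        raise ValueError("doses must be non-negative")
    return float(doses.sum())


@dataclass
class ToxicityRecord:
    """Worst follow-up hepatotoxicity grade with cumulative doses per method."""

    patient_id: str
    worst_grade: int
    cumulative_dose_manual_gy: float
    cumulative_dose_automatic_gy: float

    def __post_init__(self) -> None:
        if self.worst_grade not in range(6):
            raise ValueError("worst_grade must be an integer in 0..5")

    @property
    def significant(self) -> bool:
        """Grade >= 3 is considered significant hepatotoxicity."""
        return self.worst_grade >= 3


def toxicity_summary(records: list[ToxicityRecord]) -> dict:
    """Per-grade dose summary and dose-grade rank correlation.

    Returns a dict with a per-grade table (count, median and IQR of
    cumulative dose per segmentation method), the significant (grade >= 3)
    patients with their doses, and Spearman rho/p between worst grade and
    cumulative dose for each method.
    """
    if not records:
        raise ValueError("at least one toxicity record is required")
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "worst_grade": [r.worst_grade for r in records],
            "dose_manual_gy": [r.cumulative_dose_manual_gy for r in records],
            "dose_automatic_gy": [r.cumulative_dose_automatic_gy for r in records],
        }
    )
    rows = []
    for grade in range(6):
        sub = df[df.worst_grade == grade]
        row: dict = {"grade": grade, "n": int(len(sub))}
        for method in ("manual", "automatic"):
            col = sub[f"dose_{method}_gy"]
            row[f"median_dose_{method}_gy"] = float(col.median()) if len(sub) else np.nan
            row[f"iqr_dose_{method}_gy"] = (
                float(col.quantile(0.75) - col.quantile(0.25)) if len(sub) else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    significant = df[df.worst_grade >= 3].to_dict(orient="records")

    spearman = {}
    for method in ("manual", "automatic"):
        if df.worst_grade.nunique() > 1 and df[f"dose_{method}_gy"].nunique() > 1:
            res = stats.spearmanr(df.worst_grade, df[f"dose_{method}_gy"])
            spearman[method] = {"rho": float(res.statistic), "p": float(res.pvalue)}
        else:
            spearman[method] = {"rho": np.nan, "p": np.nan}

    return {"table": table, "significant": significant, "spearman": spearman}


def plot_bland_altman(auto_values, manual_values, ax=None, units: str = "Gy"):
    """Bland-Altman plot: pairwise means vs differences with limits of agreement."""
    import matplotlib.pyplot as plt

    auto = np.asarray(auto_values, dtype=float)
    manual = np.asarray(manual_values, dtype=float)
    summary = bland_altman(auto, manual)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((auto + manual) / 2.0, auto - manual, s=18)
    ax.axhline(summary.mean_difference, color="k")
    for lim in (summary.upper_limit, summary.lower_limit):
        ax.axhline(lim, color="k", linestyle="--")
    ax.set_xlabel(f"mean of methods [{units}]")
    ax.set_ylabel(f"automatic - manual [{units}]")
    return ax
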