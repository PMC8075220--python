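"""Per-subject, per-tissue distribution metrics of T1 and ΔT1.

Group-level summaries in this package always follow the median-of-medians
convention: each subject contributes one intra-subject summary per tissue,
and cohort statistics are computed over those per-subject values, never over
pooled voxels.  Pooled voxel vectors are available separately for the
voxel-wise correlation and KDE analyses.

Conventions (both surfaced as arguments rather than assumed silently):
kurtosis is Pearson (fourth standardized moment, normal = 3); quartiles use
linear interpolation, so IQR = Q3 - Q1 with the common default rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateInputError, EmptyRoiError
from .volume import DeltaT1Map, MaskSet, Volume

__all__ = ["RoiMetrics", "roi_metrics", "pooled_voxel_values", "kde_summary"]


@dataclass
class RoiMetrics:
    """Distribution summary of one map inside one tissue mask."""

    subject_id: str
    tissue: str
    n_voxels: int
    mean: float
    median: float
    variance: float
    iqr: float
    kurtosis: float  # NaN when undefined (constant ROI or n < 4)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _values_in_mask(map_like, mask: np.ndarray) -> np.ndarray:
    data = map_like.data if isinstance(map_like, (Volume, DeltaT1Map)) else np.asarray(map_like)
    if mask.shape != data.shape:
        raise EmptyRoiError("mask and map shapes differ")
    values = data[mask.astype(bool)]
    return values[np.isfinite(values)]


def roi_metrics(
    map_like,
    mask: np.ndarray,
    subject_id: str = "",
    tissue: str = "",
    quartile_method: str = "linear",
    excess_kurtosis: bool = False,
) -> RoiMetrics:
    """Summarize map values inside a mask after missing-value exclusion.

    Variance uses the sample (n-1) denominator; IQR is Q3 - Q1 with the
    requested quartile interpolation; kurtosis is Pearson by default
    (``excess_kurtosis=True`` subtracts 3) and reported as NaN for constant
    ROIs, where it is undefined.
    """
    values = _values_in_mask(map_like, mask)
    if values.size == 0:
        raise EmptyRoiError(f"ROI {tissue or '<unnamed>'} is empty after exclusion")
    q1, q3 = np.percentile(values, [25.0, 75.0], method=quartile_method)
    if values.size >= 2 and np.ptp(values) > 0:
        kurt = float(sps.kurtosis(values, fisher=excess_kurtosis, bias=True))
    else:
        kurt = float("nan")
    return RoiMetrics(
        subject_id=subject_id,
        tissue=tissue,
        n_voxels=int(values.size),
        mean=float(values.mean()),
        median=float(np.median(values)),
        variance=float(values.var(ddof=1)) if values.size > 1 else 0.0,
        iqr=float(q3 - q1),
        kurtosis=kurt,
    )


def pooled_voxel_values(
    subjects: list[tuple],
    tissue: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate paired (pre-contrast T1, ΔT1) voxel vectors across subjects.

    ``subjects`` is a list of ``(pre_t1, delta_map, masks)`` triples where
    ``masks`` is a :class:`MaskSet` (or a plain boolean array used directly).
    Voxels where either value is missing are dropped pairwise; subject order
    is preserved in the concatenation.
    """
    if not subjects:
        raise EmptyRoiError("no subjects given")
    pre_all: list[np.ndarray] = []
    delta_all: list[np.ndarray] = []
    for pre_t1, delta_map, masks in subjects:
        mask = masks[tissue] if isinstance(masks, MaskSet) else np.asarray(masks, bool)
        pre_data = pre_t1.data if isinstance(pre_t1, Volume) else np.asarray(pre_t1)
        delta_data = (
            delta_map.data if isinstance(delta_map, DeltaT1Map) else np.asarray(delta_map)
        )
        pre_vals = pre_data[mask]
        delta_vals = delta_data[mask]
        keep = np.isfinite(pre_vals) & np.isfinite(delta_vals)
        pre_all.append(pre_vals[keep])
        delta_all.append(delta_vals[keep])
    return np.concatenate(pre_all), np.concatenate(delta_all)


def kde_summary(
    values: np.ndarray,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    cut: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of a voxel-value distribution.

    Returns ``(grid, density)`` evaluated on a regular grid extending
    ``cut`` bandwidths beyond the data range; Silverman's rule by default.
    The density integrates to 1 on the grid (trapezoidal) to ~1e-3.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if np.unique(values).size < 2:
        raise DegenerateInputError("KDE requires at least two distinct values")
    kde = sps.gaussian_kde(values, bw_method=bandwidth)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - cut * bw, values.max() + cut * bw, grid_size)
    return grid, kde(grid)
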