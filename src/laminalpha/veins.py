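"""Vein masks and vein-proximity diagnostics of deveining.

Veins appear dark in mean gradient-echo EPI; an unsharp mask (image minus
its 2 mm FWHM Gaussian-smoothed copy) highlights them and a percentile
cutoff within the ROI yields the vein mask.  A surrounding-vein ring is the
four-fold 6-connected dilation minus the vein mask.  Per column, the
straight-line slope of the depth profile before and after deveining gives a
gradient change; columns are split 25/50/25 by that change, the overlap of
each class's retained voxels with the ring quantifies vein proximity, and
the most-affected quarter can be excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import check_same_grid
from .laminar import ColumnSet, DepthMap

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VeinMasks:
    vein: np.ndarray
    ring: np.ndarray
    ring_width_vox: int

    def __post_init__(self) -> None:
        if (self.vein & self.ring).any():
            raise ValueError("vein and ring masks must be disjoint")


def make_vein_mask(
    mean_epi: np.ndarray,
    roi_mask: np.ndarray,
    fwhm_mm: float = 2.0,
    cutoff_pct: float = 5.0,
    voxel_size_mm: float | tuple[float, ...] = 0.8,
) -> np.ndarray:
    """Dark-vessel mask from an unsharp-masked mean EPI.

    ``diff = mean_epi - smooth(mean_epi, fwhm)``; ROI voxels whose diff lies
    below the ``cutoff_pct``-th percentile of diff within the ROI are
    flagged.  A uniform image yields an empty mask for any cutoff below the
    50th percentile (diff is identically zero; strict comparison).
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    check_same_grid(mean_epi, roi, names=("mean_epi", "roi"))
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (mean_epi.ndim,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vs
    diff = mean_epi - ndimage.gaussian_filter(mean_epi.astype(float), sigma=sigma_vox)
    cut = np.percentile(diff[roi], cutoff_pct)
    return roi & (diff < cut)


def make_ring_mask(vein: np.ndarray, n_dilations: int = 4) -> VeinMasks:
    """Surrounding-vein ring: n 6-connected dilations of the vein mask minus it."""
    vein = np.asarray(vein, dtype=bool)
    if not vein.any():
        return VeinMasks(vein=vein, ring=np.zeros_like(vein), ring_width_vox=n_dilations)
    dil = ndimage.binary_dilation(vein, structure=_STRUCT6, iterations=n_dilations)
    return VeinMasks(vein=vein, ring=dil & ~vein, ring_width_vox=n_dilations)


# ----------------------------------------------------------------- gradients
def profile_gradient(profile: np.ndarray) -> float:
    """Least-squares slope of beta against depth index (1..6).

    Depths with no voxels (NaN) are omitted; fewer than two populated
    depths leaves the slope undefined (NaN, caller flags the column).
    """
    p = np.asarray(profile, dtype=float)
    x = np.arange(1, len(p) + 1, dtype=float)
    ok = np.isfinite(p)
    if ok.sum() < 2:
        return float("nan")
    slope = np.polyfit(x[ok], p[ok], 1)[0]
    return float(slope)


LOWER25, MIDDLE50, UPPER25 = "lower25", "middle50", "upper25"


def classify_gradient_change(slopes: pd.DataFrame) -> pd.DataFrame:
    """25/50/25 split of columns by |slope_deveined - slope_uncorrected|.

    Input needs columns ``column_id``, ``slope_uncorrected``,
    ``slope_deveined``.  Class boundaries fall at the 25th and 75th
    percentile ranks; ties are resolved by rank order (stable sort on
    delta, then column id), so equal deltas are assigned deterministically.
    """
    df = slopes.copy()
    if len(df) < 4:
        raise ValueError("need >= 4 included columns to form 25/50/25 classes")
    df["delta"] = np.abs(df["slope_deveined"] - df["slope_uncorrected"])
    order = np.lexsort((df["column_id"].to_numpy(), df["delta"].to_numpy()))
    rank = np.empty(len(df), dtype=int)
    rank[order] = np.arange(len(df))
    n = len(df)
    n_low = int(round(0.25 * n))
    n_up = int(round(0.25 * n))
    cls = np.full(n, MIDDLE50, dtype=object)
    cls[rank < n_low] = LOWER25
    cls[rank >= n - n_up] = UPPER25
    df["rank"] = rank
    df["class"] = cls
    return df


def class_ring_overlap(
    classes: pd.DataFrame,
    columns: ColumnSet,
    ring: np.ndarray,
    retained_voxels: np.ndarray,
) -> dict[str, float]:
    """Per-class percentage of retained voxels lying in the ring mask.

    A class with zero retained voxels is reported as NaN (missing).
    """
    check_same_grid(columns.labels, ring, retained_voxels, names=("columns", "ring", "retained"))
    out: dict[str, float] = {}
    for cname in (LOWER25, MIDDLE50, UPPER25):
        ids = classes.loc[classes["class"] == cname, "column_id"].to_numpy()
        sel = np.isin(columns.labels, ids) & retained_voxels
        total = int(sel.sum())
        out[cname] = float("nan") if total == 0 else 100.0 * float((sel & ring).sum()) / total
    return out


def exclude_top_columns(included_columns: np.ndarray, classes: pd.DataFrame) -> np.ndarray:
    """Included column ids minus the upper-25% gradient-change columns."""
    top = set(classes.loc[classes["class"] == UPPER25, "column_id"].tolist())
    return np.array(sorted(set(np.asarray(included_columns).tolist()) - top), dtype=int)


def gradient_change_table(
    beta_uncorrected: np.ndarray,
    beta_deveined: np.ndarray,
    columns: ColumnSet,
    depths: DepthMap,
    column_ids: np.ndarray,
) -> pd.DataFrame:
    """Per-column uncorrected and deveined profile slopes (convenience)."""
    from .devein import column_depth_means

    mu, ids = column_depth_means(beta_uncorrected, columns, depths, column_ids)
    md, _ = column_depth_means(beta_deveined, columns, depths, column_ids)
    rows = [
        {
            "column_id": int(c),
            "slope_uncorrected": profile_gradient(mu[k]),
            "slope_deveined": profile_gradient(md[k]),
        }
        for k, c in enumerate(ids)
    ]
    return pd.DataFrame(rows)
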