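"""Cortical depth profiles and repeated-measures statistics.

Depth profiles are 6-vectors of mean beta per equivolume depth, computed
over negatively responding retained voxels of the included columns, either
pooled across columns ("global mean") or per column then averaged
("column profile mean").  Profiles are range-normalised per subject,
combined over ROIs weighted by column count, and interrogated with one-
and two-way repeated-measures ANOVAs plus Bonferroni-corrected paired
post-hoc t-tests.

rm-ANOVA sums of squares are computed from the standard marginal-mean
decomposition; each within-subject effect is tested against its own
subject-by-effect interaction term.  No sphericity correction is applied
(a documented limitation).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import check_same_grid
from .laminar import ColumnSet, DepthMap


@dataclass
class DepthProfile:
    """Mean beta, SEM and voxel count per depth; NaN marks empty depths."""

    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n = np.asarray(self.n, dtype=int)


def _depth_stats(values_per_depth: list[np.ndarray]) -> DepthProfile:
    nd = len(values_per_depth)
    mean = np.full(nd, np.nan)
    sem = np.full(nd, np.nan)
    n = np.zeros(nd, dtype=int)
    for d, vals in enumerate(values_per_depth):
        n[d] = len(vals)
        if len(vals):
            mean[d] = vals.mean()
        if len(vals) >= 2:
            sem[d] = vals.std(ddof=1) / np.sqrt(len(vals))
    return DepthProfile(mean=mean, sem=sem, n=n)


def global_mean_profile(
    betamap: np.ndarray,
    columns: ColumnSet,
    depths: DepthMap,
    included_columns: np.ndarray,
    retained_voxels: np.ndarray,
    provenance: dict | None = None,
) -> DepthProfile:
    """Depth means over negative retained voxels pooled across columns.

    The negative-voxel selection is made on the map passed in, so it must
    be redone on uncorrected and deveined maps separately (deveining can
    flip signs and change which voxels qualify).
    """
    check_same_grid(betamap, columns.labels, retained_voxels, names=("beta", "columns", "retained"))
    sel_base = (
        np.isin(columns.labels, np.asarray(included_columns))
        & retained_voxels
        & np.isfinite(betamap)
        & (betamap < 0)
    )
    vals = [betamap[sel_base & (depths.bin == d)] for d in range(1, depths.n_depths + 1)]
    prof = _depth_stats(vals)
    prof.provenance = {"scheme": "global_mean", **(provenance or {})}
    return prof


def column_profile_mean(
    betamap: np.ndarray,
    columns: ColumnSet,
    depths: DepthMap,
    included_columns: np.ndarray,
    retained_voxels: np.ndarray,
    provenance: dict | None = None,
) -> DepthProfile:
    """Per-column depth profiles averaged with equal column weight."""
    check_same_grid(betamap, columns.labels, retained_voxels, names=("beta", "columns", "retained"))
    nd = depths.n_depths
    ids = np.asarray(included_columns)
    col_means = np.full((len(ids), nd), np.nan)
    for k, col in enumerate(ids):
        sel = (
            (columns.labels == col)
            & retained_voxels
            & np.isfinite(betamap)
            & (betamap < 0)
        )
        for d in range(1, nd + 1):
            v = betamap[sel & (depths.bin == d)]
            if len(v):
                col_means[k, d - 1] = v.mean()
    vals = [col_means[np.isfinite(col_means[:, d]), d] for d in range(nd)]
    prof = _depth_stats(vals)
    prof.provenance = {"scheme": "column_profile_mean", **(provenance or {})}
    return prof


def range_normalize(profile: DepthProfile, shift: bool = False) -> DepthProfile:
    """Divide by (max - min) over populated depths; range becomes 1.

    Sign and shape are preserved; ``shift=True`` additionally subtracts the
    minimum first (shift-then-scale variant).
    """
    vals = profile.mean
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("need at least two populated depths to normalise")
    rng = np.nanmax(vals) - np.nanmin(vals)
    if rng == 0:
        raise ValueError("zero range: profile is constant")
    base = (vals - np.nanmin(vals)) if shift else vals
    return replace(
        profile,
        mean=base / rng,
        sem=profile.sem / rng,
        provenance={**profile.provenance, "normalized": True},
    )


def roi_weighted_average(
    profiles: list[DepthProfile], n_columns_per_roi: list[int] | np.ndarray
) -> DepthProfile:
    """Column-count-weighted mean of per-ROI normalised profiles."""
    w = np.asarray(n_columns_per_roi, dtype=float)
    if len(w) != len(profiles) or len(profiles) == 0:
        raise ValueError("one weight per profile required")
    if w.sum() == 0:
        raise ValueError("all ROI weights are zero")
    stack = np.stack([p.mean for p in profiles])
    wm = np.where(np.isfinite(stack), w[:, None], 0.0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(stack * wm, axis=0) / wm.sum(axis=0)
    mean[wm.sum(axis=0) == 0] = np.nan
    n = np.stack([p.n for p in profiles]).sum(axis=0)
    sems = np.stack([p.sem for p in profiles])
    with np.errstate(invalid="ignore"):
        sem = np.sqrt(np.nansum((sems * wm) ** 2, axis=0)) / wm.sum(axis=0)
    return DepthProfile(mean=mean, sem=sem, n=n, provenance={"scheme": "roi_weighted"})


# ------------------------------------------------------------------ rm-ANOVA
@dataclass
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float


def rm_anova_1way(data: np.ndarray) -> AnovaEffect:
    """One-way repeated-measures ANOVA on a complete subjects x levels matrix."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a complete subjects x levels matrix, >= 2 each")
    if not np.isfinite(data).all():
        raise ValueError("missing cells in rm-ANOVA input")
    n, k = data.shape
    grand = data.mean()
    level_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_level = n * np.sum((level_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_level - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = _safe_f(ss_level, df1, ss_err, df2, ss_total)
    p = 1.0 if F == 0 else float(stats.f.sf(F, df1, df2))
    return AnovaEffect("level", float(F), df1, df2, p)


def _safe_f(ss_eff: float, df1: int, ss_err: float, df2: int, ss_total: float) -> float:
    """F ratio with degenerate (0/0 to rounding precision) cases -> 0 or inf."""
    tiny = 1e-12 * max(ss_total, 1e-300)
    if ss_err <= tiny:
        return 0.0 if ss_eff <= tiny else np.inf
    return (ss_eff / df1) / (ss_err / df2)


def rm_anova_2way(data: np.ndarray) -> dict[str, AnovaEffect]:
    """Two-way within-subject ANOVA on subjects x factorA x factorB data.

    Each effect (A, B, AxB) is tested against its own subject-interaction
    error term.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3 or y.shape[0] < 2 or y.shape[1] < 2 or y.shape[2] < 2:
        raise ValueError("need a complete subjects x A x B array, >= 2 each")
    if not np.isfinite(y).all():
        raise ValueError("missing cells in rm-ANOVA input")
    n, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_sab = ss_total - ss_s - ss_a - ss_b - ss_sa - ss_sb - ss_ab

    def effect(name: str, ss_eff: float, df1: int, ss_err: float, df2: int) -> AnovaEffect:
        F = _safe_f(ss_eff, df1, ss_err, df2, ss_total)
        p = 1.0 if F == 0 else float(stats.f.sf(F, df1, df2))
        return AnovaEffect(name, float(F), df1, df2, p)

    return {
        "A": effect("A", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        "B": effect("B", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        "AxB": effect("AxB", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    }


def posthoc_paired_t(
    data: np.ndarray, correction: str = "bonferroni", family_size: int | None = None
) -> pd.DataFrame:
    """All-pairs two-sided paired t-tests with Bonferroni adjustment."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    k = data.shape[1]
    pairs = list(combinations(range(k), 2))
    fam = family_size if family_size is not None else len(pairs)
    rows = []
    for i, j in pairs:
        diff = data[:, i] - data[:, j]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(data[:, i], data[:, j])
        rows.append(
            {
                "level_a": i + 1,
                "level_b": j + 1,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(min(1.0, p * fam)),
            }
        )
    return pd.DataFrame(rows)


def plot_profiles(
    profiles: dict[str, DepthProfile], path: str, title: str = "Cortical depth profiles"
) -> None:
    """Write a standard depth-profile figure (depth 1 = deep on the left)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, prof in profiles.items():
        x = np.arange(1, len(prof.mean) + 1)
        ax.errorbar(x, prof.mean, yerr=prof.sem, marker="o", capsize=3, label=name)
    ax.set_xlabel("cortical depth (1 = WM-adjacent, 6 = CSF-adjacent)")
    ax.set_ylabel("beta weight")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
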