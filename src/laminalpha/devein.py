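"""Draining-vein spatial deconvolution ("deveining").

Gradient-echo BOLD at a given cortical depth mixes the neural signal of
that depth with signal drained upward from all deeper depths through
ascending venules.  The forward model here is triangular accumulation: with
depth 1 deepest and local (neural) signals b_i, the measured signal is

    m_1 = b_1,    m_i = b_i + v_i * sum_{j<i} b_j       (i = 2..6)

where v_i are non-negative per-column drainage weights.  Deveining inverts
this exactly by peeling from the deepest depth:

    b_1 = m_1,    b_i = m_i - v_i * sum_{j<i} b_j.

The weights come from the voxelwise amplitude of low-frequency fluctuations
(ALFF, a venous blood-volume surrogate) scaled by a single tunable lambda:
v_i = lambda * mean-ALFF(depth i) / mean over depths, so mean(v) = lambda.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Paradigm, check_same_grid
from .laminar import ColumnSet, DepthMap

DEFAULT_LAMBDA = 0.25


@dataclass
class DrainageWeights:
    """Per-column leakage weights v_1..v_6 (rows follow column ids)."""

    v: np.ndarray            # (n_columns, n_depths)
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if (self.v < 0).any():
            raise ValueError("drainage weights must be non-negative")


@dataclass
class DeveinReport:
    columns_corrected: int
    anchored_columns: list[int]
    sign_flips: int


# ---------------------------------------------------------------------- ALFF
def compute_alff(bold: np.ndarray, paradigm: Paradigm, mask: np.ndarray) -> np.ndarray:
    """Amplitude of low-frequency fluctuations from eyes-closed periods.

    Per voxel: sample variance of the within-period-demeaned signal in each
    eyes-closed period, averaged over periods, then square-rooted to signal
    units.  NaN outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    periods = paradigm.closed_periods()
    if not periods:
        raise ValueError("paradigm has no eyes-closed volumes")
    if any(len(p) < 2 for p in periods):
        raise ValueError("every eyes-closed period needs >= 2 volumes")
    Y = bold[mask]                        # (V, T)
    var = np.zeros(Y.shape[0])
    for p in periods:
        seg = Y[:, p]
        var += seg.var(axis=1, ddof=1)
    var /= len(periods)
    out = np.full(mask.shape, np.nan)
    out[mask] = np.sqrt(var)
    return out


def drainage_weights(
    alff: np.ndarray,
    columns: ColumnSet,
    depths: DepthMap,
    lam: float = DEFAULT_LAMBDA,
) -> DrainageWeights:
    """Per-column depth-mean ALFF scaled to mean lambda.

    Depths with no voxels inherit the weight of the nearest populated
    depth; a column whose ALFF is all zero gets zero weights (deveining
    then leaves it untouched).
    """
    check_same_grid(alff, columns.labels, depths.bin, names=("alff", "columns", "depths"))
    nd = depths.n_depths
    abar = _column_depth_mean_matrix(alff, columns, depths, np.arange(columns.n_columns))
    v = np.zeros((columns.n_columns, nd))
    for col in range(columns.n_columns):
        row = abar[col].copy()
        pop = np.flatnonzero(np.isfinite(row))
        if pop.size == 0:
            continue
        for d in np.flatnonzero(~np.isfinite(row)):
            row[d] = row[pop[np.argmin(np.abs(pop - d))]]
        mean_a = row.mean()
        if mean_a > 0:
            v[col] = lam * row / mean_a
    return DrainageWeights(v=v, lam=lam)


# ------------------------------------------------------- forward and inverse
def forward_drain(local: np.ndarray, v: np.ndarray | DrainageWeights) -> np.ndarray:
    """Measured depth signals from local ones (depth 1 = deepest first)."""
    vv = v.v if isinstance(v, DrainageWeights) else np.asarray(v, dtype=float)
    b = np.asarray(local, dtype=float)
    squeeze = b.ndim == 1
    b = np.atleast_2d(b)
    vv = np.broadcast_to(np.atleast_2d(vv), b.shape)
    cum = np.cumsum(b, axis=-1)
    m = b.copy()
    m[..., 1:] += vv[..., 1:] * cum[..., :-1]
    return m[0] if squeeze else m


def spatial_deconvolve(measured: np.ndarray, v: np.ndarray | DrainageWeights) -> np.ndarray:
    """Exact inverse of :func:`forward_drain`."""
    vv = v.v if isinstance(v, DrainageWeights) else np.asarray(v, dtype=float)
    m = np.asarray(measured, dtype=float)
    squeeze = m.ndim == 1
    m = np.atleast_2d(m)
    vv = np.broadcast_to(np.atleast_2d(vv), m.shape)
    b = np.empty_like(m)
    b[..., 0] = m[..., 0]
    cum = b[..., 0].copy()
    for i in range(1, m.shape[-1]):
        b[..., i] = m[..., i] - vv[..., i] * cum
        cum = cum + b[..., i]
    return b[0] if squeeze else b


# ------------------------------------------------------------------- volumes
def _column_depth_mean_matrix(
    values: np.ndarray, columns: ColumnSet, depths: DepthMap, ids: np.ndarray
) -> np.ndarray:
    """(n_columns_total, n_depths) matrix of depth means; rows indexed by id."""
    nd = depths.n_depths
    sel = (columns.labels >= 0) & (depths.bin > 0) & np.isfinite(values)
    cols = columns.labels[sel]
    dep = depths.bin[sel] - 1
    vals = values[sel]
    sums = np.zeros((columns.n_columns, nd))
    counts = np.zeros((columns.n_columns, nd))
    np.add.at(sums, (cols, dep), vals)
    np.add.at(counts, (cols, dep), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)
    return out


def column_depth_means(
    values: np.ndarray, columns: ColumnSet, depths: DepthMap,
    column_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_sel, n_depths) depth-mean matrix over finite voxels, NaN where empty."""
    ids = np.arange(columns.n_columns) if column_ids is None else np.asarray(column_ids)
    full = _column_depth_mean_matrix(values, columns, depths, ids)
    return full[ids], ids


def devein_volume(
    betamap: np.ndarray,
    columns: ColumnSet,
    depths: DepthMap,
    alff: np.ndarray | None = None,
    lam: float = DEFAULT_LAMBDA,
    weights: DrainageWeights | None = None,
    column_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, DeveinReport]:
    """Devein a beta map column by column.

    The correction is computed on the column's depth-mean vector and
    applied additively to every voxel of the corresponding depth, which
    preserves within-depth spatial variance.  A column with no voxels at
    depth 1 is anchored at its deepest populated depth (flagged in the
    report).  Voxels outside the selected columns are untouched.
    """
    check_same_grid(betamap, columns.labels, depths.bin, names=("beta", "columns", "depths"))
    if weights is None:
        if alff is None:
            raise ValueError("need either an ALFF map or explicit drainage weights")
        weights = drainage_weights(alff, columns, depths, lam=lam)
    means, ids = column_depth_means(betamap, columns, depths, column_ids)
    out = betamap.copy()
    anchored: list[int] = []
    flips = 0
    for k, col in enumerate(ids):
        m = means[k]
        pop = np.flatnonzero(np.isfinite(m))
        if pop.size == 0:
            continue
        if pop[0] != 0:
            anchored.append(int(col))
        bhat = spatial_deconvolve(m[pop], weights.v[col][pop])
        flips += int(np.sum(np.sign(bhat) != np.sign(m[pop])))
        for d, corr in zip(pop, bhat - m[pop]):
            sel = (columns.labels == col) & (depths.bin == d + 1) & np.isfinite(betamap)
            out[sel] += corr
    return out, DeveinReport(
        columns_corrected=len(ids), anchored_columns=anchored, sign_flips=flips
    )
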