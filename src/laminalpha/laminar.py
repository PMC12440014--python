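"""Equivolume cortical depths and columns.

Assigns every grey-matter voxel a continuous equivolume depth fraction and
one of six depth bins (1 = deep / WM-adjacent, 6 = superficial /
CSF-adjacent), grows cortical columns from mid-depth seeds by within-ribbon
geodesic distance, and implements the column-inclusion and beta-threshold
rules used before deveining.

Equivolume rather than equidistant spacing matters wherever the cortex is
curved: for a sheet bent around a centre on the WM side, a bin of constant
thickness holds more tissue superficially, so equal-volume bin boundaries
sit closer to the pial surface.  Depth fractions are computed from the
Euclidean distances to the WM and CSF boundaries, locally reweighted by the
curvature of the mid-surface level set; for a cylindrical ribbon this
reduces to the closed-form equal-area shells of an annulus and for a flat
slab to plain equidistant spacing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .core import CSF, GM, WM, LabelledVolume, check_same_grid

N_DEPTHS = 6


@dataclass
class DepthMap:
    """Per-GM-voxel depth bin (1-6) and continuous equivolume fraction."""

    bin: np.ndarray        # int, 0 outside GM
    frac: np.ndarray       # float, NaN outside GM
    n_depths: int = N_DEPTHS

    @property
    def gm_mask(self) -> np.ndarray:
        return self.bin > 0


@dataclass
class ColumnSet:
    """Per-GM-voxel column id (0..n_columns-1; -1 outside GM)."""

    labels: np.ndarray
    n_columns: int
    seeds: np.ndarray      # (n_columns, 3) voxel coordinates of the seeds

    def voxels_of(self, column_id: int) -> np.ndarray:
        return np.argwhere(self.labels == column_id)


class GeometryError(ValueError):
    pass


# ------------------------------------------------------------------- depths
def _boundary_distances(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each voxel centre to the WM and CSF boundary surfaces.

    Two standard estimators are averaged: the unsigned distance transform
    to the nearest labelled voxel centre minus half a voxel, and the signed
    transform (outside minus inside), whose zero crossing sits on the
    interface.  Their lattice biases have opposite sign on curved
    boundaries, so the average tracks the true surface distance closely.
    """
    if not (lab == WM).any() or not (lab == CSF).any():
        raise GeometryError("ribbon must be bounded by both WM and CSF labels")

    def dist(label: int) -> np.ndarray:
        inside = lab == label
        d_out = ndimage.distance_transform_edt(~inside)
        d_in = ndimage.distance_transform_edt(inside)
        return 0.5 * ((d_out - 0.5) + (d_out - d_in))

    return np.maximum(dist(WM), 0.05), np.maximum(dist(CSF), 0.05)


def _safe_gradient(arr: np.ndarray) -> list[np.ndarray]:
    """np.gradient per axis, zeros along axes too short to differentiate."""
    return [
        np.gradient(arr, axis=ax) if arr.shape[ax] >= 2 else np.zeros_like(arr)
        for ax in range(arr.ndim)
    ]


def _mid_surface_curvature(d_wm: np.ndarray, d_csf: np.ndarray) -> np.ndarray:
    """Signed curvature of the depth level set, estimated as div(grad phi/|grad phi|).

    phi = d_wm - d_csf increases from WM to CSF; positive curvature means the
    centre of curvature lies on the WM side (a gyral-crown-like fold).
    Curvature varies slowly relative to the voxel grid, so both the level
    set and the divergence are smoothed fairly heavily (sigma 3) to tame
    second-derivative lattice noise.
    """
    phi = ndimage.gaussian_filter(d_wm - d_csf, sigma=3.0)
    grads = _safe_gradient(phi)
    norm = np.sqrt(sum(g**2 for g in grads))
    norm = np.where(norm < 1e-9, 1.0, norm)
    div = sum(_safe_gradient(g / norm)[ax] for ax, g in enumerate(grads))
    return ndimage.gaussian_filter(div, sigma=3.0)


def compute_depths(geom: LabelledVolume, n_depths: int = N_DEPTHS) -> DepthMap:
    """Equivolume depth fraction and bin for every GM voxel.

    For each voxel the equidistant fraction ``a = d_wm / (d_wm + d_csf)`` is
    reweighted with the local boundary-area ratio implied by the curvature
    ``s`` of the mid-surface: taking the local inner radius
    ``rho1 = 1/s - d_wm``, the fraction of tissue volume between the WM
    boundary and the voxel is ``a * (2*rho1 + a*T) / (2*rho1 + T)`` with
    ``T = d_wm + d_csf`` (the equal-area shell rule of an annulus).  Flat
    regions (|s| ~ 0) keep the equidistant fraction.
    """
    lab = geom.data
    gm = lab == GM
    if not gm.any():
        raise GeometryError("no GM voxels in the labelled volume")
    d_wm, d_csf = _boundary_distances(lab)
    T = d_wm + d_csf
    a = d_wm / T
    s = _mid_surface_curvature(d_wm, d_csf)

    frac = np.full(lab.shape, np.nan)
    av, Tv, sv = a[gm], T[gm], s[gm]
    f = av.copy()
    eps = 1e-3
    # curvature centre on the WM side
    pos = sv > eps
    rho1 = np.maximum(1.0 / sv[pos] - d_wm[gm][pos], 0.5)
    f[pos] = av[pos] * (2 * rho1 + av[pos] * Tv[pos]) / (2 * rho1 + Tv[pos])
    # curvature centre on the CSF side: mirror the rule from the CSF boundary
    neg = sv < -eps
    b = 1.0 - av[neg]
    rho2 = np.maximum(1.0 / (-sv[neg]) - d_csf[gm][neg], 0.5)
    f[neg] = 1.0 - b * (2 * rho2 + b * Tv[neg]) / (2 * rho2 + Tv[neg])

    f = np.clip(f, 1e-9, 1.0)
    frac[gm] = f
    bins = np.zeros(lab.shape, dtype=int)
    bins[gm] = np.clip(np.ceil(n_depths * f).astype(int), 1, n_depths)
    return DepthMap(bin=bins, frac=frac, n_depths=n_depths)


# ------------------------------------------------------------------ columns
_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def _gm_graph(gm: np.ndarray) -> tuple[csr_matrix, np.ndarray]:
    """26-connected graph over GM voxels, edge weight = Euclidean step."""
    ids = -np.ones(gm.shape, dtype=int)
    coords = np.argwhere(gm)
    ids[gm] = np.arange(len(coords))
    rows, cols, wts = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        shifted = coords + off
        valid = np.all((shifted >= 0) & (shifted < gm.shape), axis=1)
        sv = shifted[valid]
        nb = ids[sv[:, 0], sv[:, 1], sv[:, 2]]
        keep = nb >= 0
        rows.append(ids[coords[valid][keep][:, 0], coords[valid][keep][:, 1], coords[valid][keep][:, 2]])
        cols.append(nb[keep])
        wts.append(np.full(keep.sum(), np.linalg.norm(off)))
    graph = csr_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), len(coords)),
    )
    return graph, coords


def make_columns(
    geom: LabelledVolume, depths: DepthMap, n_columns: int, seed: int = 0
) -> ColumnSet:
    """Grow columns from mid-depth seeds.

    Seeds are chosen on the mid-depth voxel set by farthest-point sampling
    (geodesic distance restricted to the GM ribbon, from a seeded random
    start); every GM voxel joins the geodesically nearest seed, ties broken
    by the lowest seed index.
    """
    gm = geom.gm_mask
    check_same_grid(geom.data, depths.bin, names=("labels", "depths"))
    graph, coords = _gm_graph(gm)
    fr = depths.frac[gm]
    mid = np.flatnonzero(np.abs(fr - 0.5) <= 1.0 / (2 * depths.n_depths))
    if len(mid) < n_columns:
        mid = np.argsort(np.abs(fr - 0.5), kind="stable")[: max(n_columns, len(mid))]
    if n_columns < 1 or n_columns > len(mid):
        raise GeometryError(
            f"n_columns={n_columns} outside [1, {len(mid)}] (mid-depth voxel count)"
        )

    rng = np.random.default_rng(seed)
    seeds = [int(rng.choice(mid))]
    min_dist = dijkstra(graph, indices=seeds[0])
    for _ in range(1, n_columns):
        cand = mid[np.argmax(min_dist[mid])]
        seeds.append(int(cand))
        min_dist = np.minimum(min_dist, dijkstra(graph, indices=cand))

    dist = dijkstra(graph, indices=seeds)
    assign = np.argmin(dist, axis=0)  # ties -> lowest seed index
    labels = -np.ones(gm.shape, dtype=int)
    labels[gm] = assign
    return ColumnSet(labels=labels, n_columns=n_columns, seeds=coords[seeds])


# ----------------------------------------------------------- selection rules
def select_columns(columns: ColumnSet, sigmask: np.ndarray) -> np.ndarray:
    """Column ids containing >=1 significant voxel at any depth."""
    check_same_grid(columns.labels, sigmask, names=("columns", "sigmask"))
    hit = np.unique(columns.labels[(columns.labels >= 0) & sigmask])
    return np.sort(hit)


def threshold_betas(
    betamap: np.ndarray,
    columns: ColumnSet,
    included_columns: np.ndarray,
    pct: float = 5.0,
) -> np.ndarray:
    """Retain voxels of included columns with |beta| above pct% of the max |beta|.

    The reference maximum is taken over all voxels of the included columns.
    Returns a boolean retained-voxel mask.
    """
    included_columns = np.asarray(included_columns)
    if included_columns.size == 0:
        raise ValueError("no included columns: nothing to threshold")
    in_cols = np.isin(columns.labels, included_columns)
    vals = np.abs(betamap[in_cols])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("beta map has no finite values on the included columns")
    thr = pct / 100.0 * vals.max()
    return in_cols & np.isfinite(betamap) & (np.abs(betamap) > thr)
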