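"""Voxelwise GLM fitting, fixed-effects combination, cluster thresholding.

Ordinary least squares per voxel against an interest regressor plus six
motion nuisance regressors and an intercept; t statistics are mapped to z
by quantile-matching the exact t CDF to the standard normal.  Negative
clusters (z below a criterion, 26-connected) are retained against a
sign-flipping permutation null of maximum cluster size.  No prewhitening is
applied (runs are short); no spatial smoothing is used anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import check_same_grid
from .eeg_alpha import Regressor

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GLMDesign:
    """Named design matrix with a contrast selecting the interest regressor."""

    names: list[str]
    matrix: np.ndarray
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.matrix.shape[1] != len(self.names) or len(self.contrast) != len(self.names):
            raise ValueError("design names, matrix columns and contrast length disagree")

    @classmethod
    def build(
        cls,
        interest: Regressor | np.ndarray,
        motion: np.ndarray | None = None,
        name: str = "interest",
    ) -> "GLMDesign":
        """Interest regressor + optional 6 motion nuisance columns + intercept."""
        vals = interest.values if isinstance(interest, Regressor) else np.asarray(interest, float)
        if isinstance(interest, Regressor):
            name = interest.kind
        cols = [vals]
        names = [name]
        if motion is not None:
            motion = np.asarray(motion, dtype=float)
            if motion.ndim != 2 or motion.shape[0] != len(vals):
                raise ValueError("motion must be (n_vols, 6)")
            for i in range(motion.shape[1]):
                cols.append(motion[:, i])
                names.append(f"motion{i + 1}")
        cols.append(np.ones_like(vals))
        names.append("intercept")
        contrast = np.zeros(len(names))
        contrast[0] = 1.0
        return cls(names=names, matrix=np.column_stack(cols), contrast=contrast)


@dataclass
class GLMResult:
    beta: np.ndarray   # 3D, NaN outside mask
    se: np.ndarray
    t: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    df: int
    design: GLMDesign | None = None


@dataclass
class SignificanceMask:
    mask: np.ndarray
    clusters: list[dict]
    size_threshold: float
    n_perm: int
    z_crit: float
    alpha: float
    low_perm_warning: bool = False


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t to z by matching tail probabilities, symmetric for precision."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    return z


def fit_glm(bold: np.ndarray, design: GLMDesign, mask: np.ndarray) -> GLMResult:
    """Per-voxel OLS of the masked 4D data against the design."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    X = design.matrix
    T, p = X.shape
    if bold.shape[-1] != T:
        raise ValueError(f"bold time dimension {bold.shape[-1]} != design rows {T}")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    check_same_grid(bold[..., 0], mask, names=("bold", "mask"))

    Y = bold[mask].T                      # (T, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta_all
    df = T - p
    sigma2 = (resid**2).sum(axis=0) / df
    c = design.contrast
    cvar = float(c @ xtx_inv @ c)
    beta_v = c @ beta_all
    se_v = np.sqrt(sigma2 * cvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_v = np.where(se_v > 0, beta_v / np.where(se_v > 0, se_v, 1.0), 0.0)
    z_v = t_to_z(t_v, df)

    def to_map(v: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = v
        return out

    return GLMResult(
        beta=to_map(beta_v), se=to_map(se_v), t=to_map(t_v), z=to_map(z_v),
        mask=mask, df=df, design=design,
    )


def fixed_effects(per_run: list[GLMResult]) -> GLMResult:
    """Inverse-variance-weighted combination of runs on a common grid."""
    if not per_run:
        raise ValueError("need at least one run")
    mask = per_run[0].mask
    for r in per_run[1:]:
        if r.mask.shape != mask.shape or not np.array_equal(r.mask, mask):
            raise ValueError("runs are not on a common grid/mask")
    betas = np.stack([r.beta[mask] for r in per_run])
    ses = np.stack([r.se[mask] for r in per_run])
    w = 1.0 / ses**2
    beta = (w * betas).sum(axis=0) / w.sum(axis=0)
    se = 1.0 / np.sqrt(w.sum(axis=0))
    z = beta / se

    def to_map(v: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = v
        return out

    df = int(sum(r.df for r in per_run))
    return GLMResult(beta=to_map(beta), se=to_map(se), t=to_map(z), z=to_map(z),
                     mask=mask, df=df, design=per_run[0].design)


def _max_cluster_size(zmap: np.ndarray, mask: np.ndarray, z_crit: float) -> int:
    lab, n = ndimage.label((zmap < z_crit) & mask, structure=_CONN26)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_threshold(
    zmap: np.ndarray,
    mask: np.ndarray,
    z_crit: float = -2.3,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
    bold: np.ndarray | None = None,
    design: GLMDesign | None = None,
) -> SignificanceMask:
    """Cluster-corrected negative-tail significance mask.

    Voxels with z below ``z_crit`` are grouped by 26-connectivity; a cluster
    is retained when its size beats the permutation distribution of the
    maximum null cluster size at level ``alpha``.  When ``bold`` and
    ``design`` are supplied, null z-maps are rebuilt by refitting after
    flipping the signs of whole residual volumes (exchangeable under the
    null of no interest effect); otherwise an i.i.d. standard-normal z-field
    is used as a structure-free null.
    """
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    zm = np.where(np.isfinite(zmap), zmap, 0.0)
    lab, n_clust = ndimage.label((zm < z_crit) & mask, structure=_CONN26)
    sizes = np.bincount(lab.ravel())[1:] if n_clust else np.array([], dtype=int)

    null_max = np.empty(n_perm)
    if bold is not None and design is not None:
        X = design.matrix
        Y = bold[mask].T
        xtx_inv = np.linalg.inv(X.T @ X)
        pinv = xtx_inv @ X.T
        fit = X @ (pinv @ Y)
        resid = Y - fit
        # null model: nuisance-only fit plus sign-flipped residuals
        nuis = design.contrast == 0
        Xn = X[:, nuis]
        fit_nuis = Xn @ np.linalg.lstsq(Xn, Y, rcond=None)[0]
        c = design.contrast
        cvar = float(c @ xtx_inv @ c)
        df = X.shape[0] - X.shape[1]
        for i in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=(X.shape[0], 1))
            Yp = fit_nuis + flips * resid
            bet = pinv @ Yp
            rp = Yp - X @ bet
            s2 = (rp**2).sum(axis=0) / df
            tv = (c @ bet) / np.sqrt(s2 * cvar)
            zperm = np.full(mask.shape, np.inf)
            zperm[mask] = t_to_z(tv, df)
            null_max[i] = _max_cluster_size(zperm, mask, z_crit)
    else:
        for i in range(n_perm):
            zperm = np.full(mask.shape, np.inf)
            zperm[mask] = rng.standard_normal(int(mask.sum()))
            null_max[i] = _max_cluster_size(zperm, mask, z_crit)

    out = np.zeros(mask.shape, dtype=bool)
    clusters = []
    for cid, size in enumerate(sizes, start=1):
        p = (1 + np.sum(null_max >= size)) / (n_perm + 1)
        keep = p <= alpha
        clusters.append({"label": cid, "size": int(size), "p": float(p), "kept": bool(keep)})
        if keep:
            out |= lab == cid
    size_thr = float(np.quantile(null_max, 1 - alpha)) if n_perm else np.inf
    return SignificanceMask(
        mask=out, clusters=clusters, size_threshold=size_thr, n_perm=n_perm,
        z_crit=z_crit, alpha=alpha, low_perm_warning=n_perm < 100,
    )


def upsample_nn(arr: np.ndarray, factors: float | tuple[float, ...]) -> np.ndarray:
    """Nearest-neighbour upsampling by integer or rational per-axis factors."""
    arr = np.asarray(arr)
    if np.isscalar(factors):
        factors = (float(factors),) * arr.ndim
    if len(factors) != arr.ndim:
        raise ValueError("one factor per axis required")
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be positive")
    out = arr
    for ax, f in enumerate(factors):
        n_new = int(round(out.shape[ax] * f))
        idx = np.minimum((np.arange(n_new) / f).astype(int), out.shape[ax] - 1)
        out = np.take(out, idx, axis=ax)
    return out
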