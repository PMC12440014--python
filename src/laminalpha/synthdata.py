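"""Seeded synthetic laminar 7T-like subjects with known ground truth.

The anatomical substrate is a curved grey-matter ribbon: an annulus sector
(WM inside, CSF outside) extruded through a few slices.  Curvature is
nonzero on purpose — it makes equivolume depths differ from equidistant
ones — while still admitting closed-form layer boundaries for testing.

A subject bundles:

* the labelled geometry, penetrating veins and a perivascular ring,
* a global alpha-power timecourse (block modulation + AR(1) fluctuation),
* 4D BOLD built from a depth-dependent neural drive pushed through the
  draining-vein forward model, plus low-frequency venous fluctuations,
  white noise, a dark-vein baseline and optional perivascular leakage,
* the ground-truth laminar profile and the drainage weights actually used.

Drainage self-consistency: the per-column drainage weights are obtained by
a fixed-point iteration so that v = lambda * ALFF/mean(ALFF) holds on the
generated data itself — veins drain in proportion to their realised
fluctuation amplitude, which is exactly the relation the analysis assumes
when it estimates weights from ALFF.  Explicit weights can be supplied
instead (used by exact round-trip tests).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .core import CSF, GM, WM, LabelledVolume, Paradigm, spawn_seeds
from .devein import DrainageWeights, compute_alff, drainage_weights, forward_drain
from .eeg_alpha import AlphaPowerSeries, Regressor, make_boxcar, make_regressor, orthogonalize
from .laminar import ColumnSet, DepthMap, GeometryError

__all__ = [
    "Paradigm",
    "NoiseConfig",
    "VeinTruth",
    "GroundTruthProfile",
    "SubjectSim",
    "make_ribbon",
    "make_veins",
    "make_alpha_timecourse",
    "make_bold",
]

#: Low-frequency (venous) fluctuation SD per depth, deep to superficial.
#: Venous blood volume is modelled as negligible in the deepest laminae and
#: quasi-saturated from mid-depth outward, where the ascending-venule tree
#: has reached full density; this makes ALFF a meaningful CBVv surrogate
#: with most of the drainage assigned to mid/superficial depths.
DEFAULT_LOWFREQ_SD = (0.3, 0.8, 18.0, 18.2, 18.6, 19.0)


@dataclass
class NoiseConfig:
    white_sd: float = 0.6
    lowfreq_sd: tuple[float, ...] = DEFAULT_LOWFREQ_SD
    perivascular_gain: float = 1.0
    n_lowfreq_components: int = 3
    lowfreq_band_hz: tuple[float, float] = (0.01, 0.08)


@dataclass
class VeinTruth:
    """Ground-truth vein and perivascular voxel sets (boolean volumes)."""

    vein_mask: np.ndarray
    perivascular_mask: np.ndarray
    n_veins: int

    def __post_init__(self) -> None:
        if (self.vein_mask & self.perivascular_mask).any():
            raise ValueError("vein and perivascular sets must be disjoint")


@dataclass
class GroundTruthProfile:
    """Relative neural response amplitude per depth (deep first)."""

    depth_weights: np.ndarray
    shape_name: str = "custom"

    def __post_init__(self) -> None:
        self.depth_weights = np.asarray(self.depth_weights, dtype=float)
        if len(self.depth_weights) != 6:
            raise ValueError("depth_weights must have length 6")
        if (self.depth_weights < 0).any() or self.depth_weights.max() <= 0:
            raise ValueError("depth_weights must be non-negative with a positive max")

    @classmethod
    def n_shape(cls, dip: float = 0.5) -> "GroundTruthProfile":
        """Middle depths attenuated: the laminar signature of interest."""
        return cls(np.array([1.0, 1.0, dip, dip, 1.0, 1.0]), "n")

    @classmethod
    def flat(cls) -> "GroundTruthProfile":
        return cls(np.ones(6), "flat")

    @classmethod
    def superficial(cls) -> "GroundTruthProfile":
        return cls(np.array([0.08, 0.08, 0.08, 0.08, 0.3, 1.0]), "superficial")


@dataclass
class SubjectSim:
    """One synthetic subject with full ground truth."""

    geometry: LabelledVolume
    depths: DepthMap
    columns: ColumnSet
    veins: VeinTruth
    truth: GroundTruthProfile
    alpha: AlphaPowerSeries
    bold: np.ndarray
    motion: np.ndarray
    seed: int
    noise_cfg: NoiseConfig
    paradigm: Paradigm
    weights: DrainageWeights
    true_beta: np.ndarray
    task_truth: GroundTruthProfile | None = None
    true_beta_task: np.ndarray | None = None

    @property
    def mean_epi(self) -> np.ndarray:
        return self.bold.mean(axis=-1)


# ------------------------------------------------------------------ geometry
def make_ribbon(
    inner_radius_vox: float,
    outer_radius_vox: float,
    arc: float = 2 * np.pi,
    thickness_slices: int = 4,
    csf_margin_vox: int = 3,
    voxel_size_mm: float = 0.8,
) -> LabelledVolume:
    """Annulus-sector GM ribbon between WM (inside) and CSF (outside).

    Voxel centres with radius < inner are WM, within [inner, outer] GM and
    in (outer, outer + margin] CSF, all restricted to polar angle in
    [0, arc); the rest is background.
    """
    if not (2 <= inner_radius_vox < outer_radius_vox):
        raise GeometryError(
            f"need 2 <= inner ({inner_radius_vox}) < outer ({outer_radius_vox})"
        )
    if not (0 < arc <= 2 * np.pi):
        raise GeometryError("arc must be in (0, 2*pi]")
    half = int(np.ceil(outer_radius_vox + csf_margin_vox)) + 2
    n = 2 * half + 1
    yy, xx = np.meshgrid(np.arange(n) - half, np.arange(n) - half, indexing="ij")
    r = np.hypot(xx, yy)
    theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
    in_arc = theta < arc if arc < 2 * np.pi else np.ones_like(r, dtype=bool)
    plane = np.zeros((n, n), dtype=np.int8)
    plane[in_arc & (r < inner_radius_vox)] = WM
    plane[in_arc & (r >= inner_radius_vox) & (r <= outer_radius_vox)] = GM
    plane[in_arc & (r > outer_radius_vox) & (r <= outer_radius_vox + csf_margin_vox)] = CSF
    data = np.repeat(plane[:, :, None], thickness_slices, axis=2)
    return LabelledVolume(
        data,
        voxel_size_mm=(voxel_size_mm,) * 3,
        meta={
            "center": (half, half),
            "inner_radius_vox": float(inner_radius_vox),
            "outer_radius_vox": float(outer_radius_vox),
            "arc": float(arc),
        },
    )


def make_veins(
    geom: LabelledVolume, n_veins: int, ring_width_vox: int = 2, seed: int = 0
) -> VeinTruth:
    """Radial penetrating veins crossing the ribbon, plus a perivascular ring.

    Veins are radial lines of GM voxels at seeded angular positions
    (extruded through all slices); perivascular voxels lie within Chebyshev
    distance ``ring_width_vox`` of a vein voxel, vein voxels excluded.
    """
    if n_veins < 0:
        raise ValueError("n_veins must be >= 0")
    vein = np.zeros(geom.shape, dtype=bool)
    if n_veins > 0:
        if "center" not in geom.meta:
            raise GeometryError("geometry lacks annulus metadata needed to place veins")
        cy, cx = geom.meta["center"]
        arc = geom.meta.get("arc", 2 * np.pi)
        r_out = geom.meta["outer_radius_vox"]
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0.0, arc, size=n_veins)
        for th in angles:
            t = np.arange(0.0, r_out + 2.0, 0.25)
            ys = np.round(cy + t * np.sin(th)).astype(int)
            xs = np.round(cx + t * np.cos(th)).astype(int)
            ok = (ys >= 0) & (ys < geom.shape[0]) & (xs >= 0) & (xs < geom.shape[1])
            for y, x in set(zip(ys[ok].tolist(), xs[ok].tolist())):
                if geom.data[y, x, 0] == GM:
                    vein[y, x, :] = True
    if vein.any() and ring_width_vox > 0:
        dil = ndimage.binary_dilation(
            vein, structure=np.ones((3, 3, 3), dtype=bool), iterations=ring_width_vox
        )
        peri = dil & ~vein
    else:
        peri = np.zeros_like(vein)
    return VeinTruth(vein_mask=vein, perivascular_mask=peri, n_veins=n_veins)


# ------------------------------------------------------------------- signals
def make_alpha_timecourse(
    paradigm: Paradigm,
    modulation_depth: float = 0.5,
    ar1_coeff: float = 0.999,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline: float = 1.0,
) -> AlphaPowerSeries:
    """Blockwise-modulated alpha power with AR(1) spontaneous fluctuation.

    baseline*(1 + modulation_depth*closed(t)) plus an AR(1) process of
    stationary SD ``noise_sd`` (per-sample coefficient ``ar1_coeff`` at the
    EEG rate), floored at zero.
    """
    if modulation_depth < 0:
        raise ValueError("modulation_depth must be >= 0")
    if not abs(ar1_coeff) < 1:
        raise ValueError("|ar1_coeff| must be < 1")
    n = paradigm.n_eeg_samples
    t = np.arange(n) / paradigm.eeg_fs_hz
    series = baseline * (1.0 + modulation_depth * paradigm.condition_at(t).astype(float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        innov = rng.normal(0.0, noise_sd * np.sqrt(1 - ar1_coeff**2), size=n)
        series = series + sps.lfilter([1.0], [1.0, -ar1_coeff], innov)
    return AlphaPowerSeries(
        np.maximum(series, 0.0),
        fs_hz=paradigm.eeg_fs_hz,
        segment_len=paradigm.segment_len_samples,
        segment_flags=np.zeros(
            int(np.ceil(n / paradigm.segment_len_samples)), dtype=bool
        ),
    )


def _standardized(values: np.ndarray) -> np.ndarray:
    x = values - values.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _lowfreq_mixture(
    n_vox: int, paradigm: Paradigm, cfg: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-voxel unit-SD sum of seeded low-frequency sinusoids (V, T)."""
    t = paradigm.volume_midpoints()
    freqs = rng.uniform(*cfg.lowfreq_band_hz, size=cfg.n_lowfreq_components)
    phases = rng.uniform(0.0, 2 * np.pi, size=(n_vox, cfg.n_lowfreq_components))
    mix = np.zeros((n_vox, paradigm.n_vols))
    for k, f in enumerate(freqs):
        mix += np.sin(2 * np.pi * f * t[None, :] + phases[:, k, None])
    mix -= mix.mean(axis=1, keepdims=True)
    sd = mix.std(axis=1, keepdims=True)
    return mix / np.where(sd > 0, sd, 1.0)


def _ar1_series(n: int, coeff: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.normal(0.0, np.sqrt(1 - coeff**2), size=n)
    return sps.lfilter([1.0], [1.0, -coeff], innov)


def make_bold(
    geom: LabelledVolume,
    depths: DepthMap,
    columns: ColumnSet,
    veins: VeinTruth,
    truth: GroundTruthProfile,
    alpha: AlphaPowerSeries,
    paradigm: Paradigm,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    amplitude: float = 4.0,
    lambda_sim: float = 0.25,
    weights: DrainageWeights | None = None,
    task_truth: GroundTruthProfile | None = None,
    task_amplitude: float = 5.0,
    baseline: float = 100.0,
    vein_darkening: float = 0.4,
) -> SubjectSim:
    """Forward-simulate a subject's 4D BOLD run.

    Per GM voxel the neural drive is the (negative) HRF-convolved,
    volume-sampled, unit-SD alpha regressor scaled by the depth weight and
    ``amplitude``; when ``task_truth`` is given the drive instead has a
    boxcar-locked component (weights ``task_truth``) and a spontaneous
    component (alpha orthogonalised to the boxcar, weights ``truth``).  Per
    column the six depth-local drives pass through the draining forward
    model; perivascular voxels receive an extra copy of their column's
    superficial measured signal scaled by the perivascular gain.  Low-
    frequency sinusoid mixtures (per-depth SD) and white noise are added on
    top of a dark-vein baseline image.
    """
    cfg = noise_cfg or NoiseConfig()
    gm = geom.gm_mask
    if (depths.bin[gm] == 0).any():
        raise GeometryError("every GM voxel needs a depth assignment")
    seeds = spawn_seeds(seed, 4, tag="make_bold")
    rng_noise = np.random.default_rng(seeds[0])
    rng_white = np.random.default_rng(seeds[1])
    rng_motion = np.random.default_rng(seeds[2])

    nd = depths.n_depths
    n_vox = int(gm.sum())
    col_of = columns.labels[gm]
    depth_of = depths.bin[gm] - 1

    # depth-local drive profiles per component (coefficients of unit-SD regressors)
    x_alpha = _standardized(make_regressor(alpha, paradigm).values)
    if task_truth is None:
        comps = [(-amplitude * truth.depth_weights, x_alpha)]
        true_beta = -amplitude * truth.depth_weights
        true_beta_task = None
    else:
        box = make_boxcar(paradigm)
        box_series = AlphaPowerSeries(
            paradigm.condition_at(np.arange(paradigm.n_eeg_samples) / paradigm.eeg_fs_hz).astype(float),
            fs_hz=paradigm.eeg_fs_hz,
            segment_len=paradigm.segment_len_samples,
        )
        x_task = _standardized(make_regressor(box_series, paradigm).values)
        x_spont = _standardized(
            orthogonalize(Regressor(x_alpha, kind="alpha"), box).values
        )
        comps = [
            (-amplitude * truth.depth_weights, x_spont),
            (-task_amplitude * task_truth.depth_weights, x_task),
        ]
        true_beta = -amplitude * truth.depth_weights
        true_beta_task = -task_amplitude * task_truth.depth_weights

    # nuisance motion traces: smooth AR(1) series, residualised against the
    # paradigm subspace (they never enter the BOLD, so this only keeps the
    # short-run design well conditioned instead of randomly collinear)
    motion = np.column_stack(
        [_ar1_series(paradigm.n_vols, 0.9, rng_motion) for _ in range(6)]
    )
    para_basis = np.column_stack(
        [np.ones(paradigm.n_vols), make_boxcar(paradigm).values] + [x for _, x in comps]
    )
    qp, _ = np.linalg.qr(para_basis)
    motion = motion - qp @ (qp.T @ motion)
    msd = motion.std(axis=0, keepdims=True)
    motion /= np.where(msd > 0, msd, 1.0)

    # noise fields: the venous low-frequency mixture is residualised against
    # the regressor/motion subspace so that fluctuation amplitude (ALFF) and
    # response estimation decouple — ALFF carries the depth structure while
    # beta estimation noise comes from the white component alone
    lf_sd = np.asarray(cfg.lowfreq_sd, dtype=float)
    if len(lf_sd) != nd:
        raise ValueError(f"lowfreq_sd needs {nd} entries")
    noise = np.zeros((n_vox, paradigm.n_vols))
    if lf_sd.max() > 0:
        mix = _lowfreq_mixture(n_vox, paradigm, cfg, rng_noise)
        basis = np.column_stack(
            [np.ones(paradigm.n_vols), make_boxcar(paradigm).values]
            + [x for _, x in comps]
            + [motion[:, j] for j in range(motion.shape[1])]
        )
        q, _ = np.linalg.qr(basis)
        mix = mix - (mix @ q) @ q.T
        mix -= mix.mean(axis=1, keepdims=True)
        sd_row = mix.std(axis=1, keepdims=True)
        mix /= np.where(sd_row > 0, sd_row, 1.0)
        noise += mix * lf_sd[depth_of][:, None]
    if cfg.white_sd > 0:
        noise += rng_white.normal(0.0, cfg.white_sd, size=(n_vox, paradigm.n_vols))

    base_img = np.where(veins.vein_mask, baseline * (1.0 - vein_darkening), baseline)
    peri_gm = veins.perivascular_mask[gm]

    def assemble(v: np.ndarray) -> np.ndarray:
        """BOLD (V, T) for drainage weight matrix v (n_columns, nd)."""
        sig = np.zeros((n_vox, paradigm.n_vols))
        for prof, x in comps:
            m = forward_drain(np.broadcast_to(prof, (columns.n_columns, nd)), v)
            sig += m[col_of, depth_of][:, None] * x[None, :]
            if cfg.perivascular_gain != 0:
                sig[peri_gm] += (
                    cfg.perivascular_gain * m[col_of[peri_gm], nd - 1][:, None] * x[None, :]
                )
        return sig + noise + base_img[gm][:, None]

    if weights is None:
        v = np.zeros((columns.n_columns, nd))
        for _ in range(40):
            bold_flat = assemble(v)
            vol = np.zeros(geom.shape + (paradigm.n_vols,))
            vol[gm] = bold_flat
            alff = compute_alff(vol, paradigm, gm)
            v_new = drainage_weights(alff, columns, depths, lam=lambda_sim).v
            if np.max(np.abs(v_new - v)) < 1e-12:
                v = v_new
                break
            v = v_new
        weights = DrainageWeights(v=v, lam=lambda_sim)
    bold_flat = assemble(weights.v)
    bold = np.zeros(geom.shape + (paradigm.n_vols,))
    bold[gm] = bold_flat
    bg = ~gm
    bold[bg] = base_img[bg][:, None] + rng_white.normal(
        0.0, max(cfg.white_sd, 1e-12), size=(int(bg.sum()), paradigm.n_vols)
    )

    return SubjectSim(
        geometry=geom,
        depths=depths,
        columns=columns,
        veins=veins,
        truth=truth,
        alpha=alpha,
        bold=bold,
        motion=motion,
        seed=seed,
        noise_cfg=cfg,
        paradigm=paradigm,
        weights=weights,
        true_beta=true_beta,
        task_truth=task_truth,
        true_beta_task=true_beta_task,
    )
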