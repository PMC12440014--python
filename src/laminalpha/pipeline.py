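"""End-to-end analysis driver and configuration.

Chains the stages on one or more subjects: regressor construction ->
voxelwise GLM (alpha / boxcar / alpha-orthogonalised) -> cluster
thresholding -> column selection and beta thresholding -> ALFF and
deveining -> vein-proximity diagnostics -> depth profiles and group
statistics.  Every stage is also usable on its own; this module only
wires them together and handles files, seeding and the manifest.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import devein as dv
from . import eeg_alpha as ea
from . import glm as gl
from . import laminar as lm
from . import profiles as pr
from . import synthdata as sd
from . import veins as vn
from .core import Paradigm, spawn_seeds

GLM_KINDS = ("alpha", "boxcar", "alpha_orth")


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the analysis' reference values.

    lambda=0.25, beta threshold 5%, z_crit=-2.3, cluster alpha=0.05, six
    depths, four ring dilations, 30 s blocks x 4 cycles, TR 3.8 s, 68
    volumes.  The geometry and column count are desk-scale.
    """

    # paradigm
    block_len_s: float = 30.0
    n_cycles: int = 4
    tr_s: float = 3.8
    n_vols: int = 68
    eeg_fs_hz: float = 500.0
    # geometry
    inner_radius_vox: float = 10.0
    outer_radius_vox: float = 16.0
    arc: float = 2 * np.pi
    thickness_slices: int = 4
    voxel_size_mm: float = 0.8
    n_columns: int = 16
    # veins
    n_veins: int = 3
    ring_width_vox: int = 2
    n_dilations: int = 4
    cutoff_pct: float = 5.0
    # signal & noise
    amplitude: float = 4.0
    modulation_depth: float = 0.5
    alpha_noise_sd: float = 0.1
    white_sd: float = 0.6
    lowfreq_sd: tuple[float, ...] = sd.DEFAULT_LOWFREQ_SD
    perivascular_gain: float = 1.0
    truth_shape: str = "n"
    # analysis
    lam: float = 0.25
    beta_pct: float = 5.0
    z_crit: float = -2.3
    cluster_alpha: float = 0.05
    n_perm: int = 100
    # run
    n_subjects: int = 2
    seed: int = 0

    def paradigm(self) -> Paradigm:
        return Paradigm(
            block_len_s=self.block_len_s,
            n_cycles=self.n_cycles,
            tr_s=self.tr_s,
            n_vols=self.n_vols,
            eeg_fs_hz=self.eeg_fs_hz,
        )

    def noise(self) -> sd.NoiseConfig:
        return sd.NoiseConfig(
            white_sd=self.white_sd,
            lowfreq_sd=tuple(self.lowfreq_sd),
            perivascular_gain=self.perivascular_gain,
        )

    def truth(self) -> sd.GroundTruthProfile:
        return {
            "n": sd.GroundTruthProfile.n_shape,
            "flat": sd.GroundTruthProfile.flat,
            "superficial": sd.GroundTruthProfile.superficial,
        }[self.truth_shape]()


# ----------------------------------------------------------------- simulate
def make_geometry(cfg: PipelineConfig) -> tuple[sd.LabelledVolume, lm.DepthMap, lm.ColumnSet]:
    geom = sd.make_ribbon(
        cfg.inner_radius_vox,
        cfg.outer_radius_vox,
        arc=cfg.arc,
        thickness_slices=cfg.thickness_slices,
        voxel_size_mm=cfg.voxel_size_mm,
    )
    depths = lm.compute_depths(geom)
    columns = lm.make_columns(geom, depths, cfg.n_columns, seed=cfg.seed)
    return geom, depths, columns


def simulate_subject(
    cfg: PipelineConfig,
    subject_seed: int,
    geometry: tuple | None = None,
    truth: sd.GroundTruthProfile | None = None,
    task_truth: sd.GroundTruthProfile | None = None,
) -> sd.SubjectSim:
    geom, depths, columns = geometry if geometry is not None else make_geometry(cfg)
    s_vein, s_alpha, s_bold = spawn_seeds(subject_seed, 3, tag="subject")
    veins = sd.make_veins(geom, cfg.n_veins, ring_width_vox=cfg.ring_width_vox, seed=s_vein)
    paradigm = cfg.paradigm()
    alpha = sd.make_alpha_timecourse(
        paradigm,
        modulation_depth=cfg.modulation_depth,
        noise_sd=cfg.alpha_noise_sd,
        seed=s_alpha,
    )
    return sd.make_bold(
        geom,
        depths,
        columns,
        veins,
        truth if truth is not None else cfg.truth(),
        alpha,
        paradigm,
        noise_cfg=cfg.noise(),
        seed=s_bold,
        amplitude=cfg.amplitude,
        lambda_sim=cfg.lam,
        task_truth=task_truth,
    )


# ------------------------------------------------------------------ analyse
@dataclass
class KindAnalysis:
    kind: str
    glm: gl.GLMResult
    sigmask: gl.SignificanceMask
    included_columns: np.ndarray
    retained: np.ndarray
    beta_deveined: np.ndarray
    devein_report: dv.DeveinReport
    profile_uncorrected: pr.DepthProfile
    profile_deveined: pr.DepthProfile


@dataclass
class SubjectAnalysis:
    kinds: dict[str, KindAnalysis]
    alff: np.ndarray
    weights: dv.DrainageWeights
    vein_masks: vn.VeinMasks | None = None
    gradient_classes: pd.DataFrame | None = None
    overlaps: dict[str, float] | None = None
    filtered_columns: np.ndarray | None = None


def build_regressors(sim: sd.SubjectSim) -> dict[str, ea.Regressor]:
    """Alpha (unit SD), raw boxcar and alpha-orthogonalised (unit SD)."""
    repaired = (
        ea.repair_segments(
            sim.alpha,
            _segment_conditions(sim.alpha, sim.paradigm),
        )
        if sim.alpha.segment_flags is not None and sim.alpha.segment_flags.any()
        else sim.alpha
    )
    alpha_reg = ea.make_regressor(repaired, sim.paradigm)
    alpha_reg = ea.Regressor(sd._standardized(alpha_reg.values), "alpha", alpha_reg.hrf_params)
    box = ea.make_boxcar(sim.paradigm)
    orth = ea.orthogonalize(alpha_reg, box)
    orth = ea.Regressor(sd._standardized(orth.values), "alpha_orth", alpha_reg.hrf_params)
    return {"alpha": alpha_reg, "boxcar": box, "alpha_orth": orth}


def _segment_conditions(series: ea.AlphaPowerSeries, paradigm: Paradigm) -> np.ndarray:
    starts = np.arange(series.n_segments) * series.segment_len / series.fs_hz
    return np.where(paradigm.condition_at(starts), "closed", "open")


def analyze_subject(
    sim: sd.SubjectSim,
    kinds: tuple[str, ...] = ("alpha",),
    lam: float = dv.DEFAULT_LAMBDA,
    beta_pct: float = 5.0,
    z_crit: float = -2.3,
    cluster_alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    vein_stage: bool = False,
    cutoff_pct: float = 5.0,
    n_dilations: int = 4,
) -> SubjectAnalysis:
    """Run the full single-subject analysis on a simulated subject."""
    gm = sim.geometry.gm_mask
    regs = build_regressors(sim)
    alff = dv.compute_alff(sim.bold, sim.paradigm, gm)
    weights = dv.drainage_weights(alff, sim.columns, sim.depths, lam=lam)

    out_kinds: dict[str, KindAnalysis] = {}
    perm_seeds = spawn_seeds(seed, len(kinds), tag="cluster")
    for k, kind in enumerate(kinds):
        design = gl.GLMDesign.build(regs[kind], motion=sim.motion)
        res = gl.fit_glm(sim.bold, design, gm)
        sig = gl.cluster_threshold(
            res.z, gm, z_crit=z_crit, alpha=cluster_alpha, n_perm=n_perm,
            seed=perm_seeds[k], bold=sim.bold, design=design,
        )
        included = lm.select_columns(sim.columns, sig.mask)
        if included.size == 0:
            raise RuntimeError(
                f"stage column-selection: no column holds a significant voxel (kind={kind})"
            )
        retained = lm.threshold_betas(res.beta, sim.columns, included, pct=beta_pct)
        beta_dev, report = dv.devein_volume(
            res.beta, sim.columns, sim.depths, weights=weights, column_ids=included
        )
        prof_unc = pr.global_mean_profile(
            res.beta, sim.columns, sim.depths, included, retained,
            provenance={"corrected": False, "glm_kind": kind},
        )
        prof_dev = pr.global_mean_profile(
            beta_dev, sim.columns, sim.depths, included, retained,
            provenance={"corrected": True, "glm_kind": kind},
        )
        out_kinds[kind] = KindAnalysis(
            kind=kind, glm=res, sigmask=sig, included_columns=included,
            retained=retained, beta_deveined=beta_dev, devein_report=report,
            profile_uncorrected=prof_unc, profile_deveined=prof_dev,
        )

    analysis = SubjectAnalysis(kinds=out_kinds, alff=alff, weights=weights)
    if vein_stage:
        ref = out_kinds[kinds[0]]
        vein_mask = vn.make_vein_mask(
            sim.mean_epi, gm, cutoff_pct=cutoff_pct,
            voxel_size_mm=sim.geometry.voxel_size_mm[0],
        )
        masks = vn.make_ring_mask(vein_mask, n_dilations=n_dilations)
        table = vn.gradient_change_table(
            ref.glm.beta, ref.beta_deveined, sim.columns, sim.depths, ref.included_columns
        )
        classes = vn.classify_gradient_change(table)
        overlaps = vn.class_ring_overlap(classes, sim.columns, masks.ring, ref.retained)
        analysis.vein_masks = masks
        analysis.gradient_classes = classes
        analysis.overlaps = overlaps
        analysis.filtered_columns = vn.exclude_top_columns(ref.included_columns, classes)
    return analysis


def group_matrix(
    analyses: list[SubjectAnalysis], kind: str = "alpha", corrected: bool = True
) -> np.ndarray:
    """Subjects x depths matrix of range-normalised profiles.

    Subjects with any empty depth are excluded listwise (reported via a
    RuntimeWarning from numpy NaN handling is silenced; exclusion count is
    available as the difference in row count).
    """
    rows = []
    for a in analyses:
        ka = a.kinds[kind]
        prof = ka.profile_deveined if corrected else ka.profile_uncorrected
        norm = pr.range_normalize(prof)
        if np.isfinite(norm.mean).all():
            rows.append(norm.mean)
    if not rows:
        raise ValueError("no subject has a complete depth profile")
    return np.stack(rows)


# ---------------------------------------------------------------------- run
def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate and analyse ``cfg.n_subjects`` subjects, writing a manifest."""
    from . import io as lio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": [], "subjects": [], "files": []}

    def record(stage: str) -> None:
        manifest["stages"].append(stage)

    geom, depths, columns = make_geometry(cfg)
    lio.write_volume(out / "labels.nii", geom.data.astype(np.int16), geom.affine)
    lio.write_volume(out / "depth_bin.nii", depths.bin.astype(np.int16), geom.affine)
    lio.write_volume(out / "depth_frac.nii", depths.frac, geom.affine)
    lio.write_volume(out / "columns.nii", columns.labels.astype(np.int16), geom.affine)
    record("geometry")

    subj_seeds = spawn_seeds(cfg.seed, cfg.n_subjects, tag="subjects")
    analyses = []
    for i, s_seed in enumerate(subj_seeds):
        sub = f"sub-{i + 1:02d}"
        sdir = out / sub
        sdir.mkdir(exist_ok=True)
        try:
            sim = simulate_subject(cfg, s_seed, geometry=(geom, depths, columns))
        except Exception as err:  # pragma: no cover - defensive
            raise RuntimeError(f"stage simulate failed for {sub}: {err}") from err
        lio.write_volume(sdir / "bold.nii", sim.bold, geom.affine)
        lio.write_table(
            sdir / "alpha.tsv",
            pd.DataFrame(
                {
                    "time_s": np.arange(len(sim.alpha.values)) / sim.alpha.fs_hz,
                    "value": sim.alpha.values,
                }
            ),
        )
        lio.write_table(
            sdir / "motion.tsv",
            pd.DataFrame(sim.motion, columns=[f"motion{j + 1}" for j in range(6)]),
        )
        record(f"simulate:{sub}")

        regs = build_regressors(sim)
        lio.write_table(
            sdir / "design.tsv",
            pd.DataFrame({k: r.values for k, r in regs.items()}),
        )
        record(f"regressors:{sub}")

        analysis = analyze_subject(
            sim,
            kinds=GLM_KINDS,
            lam=cfg.lam,
            beta_pct=cfg.beta_pct,
            z_crit=cfg.z_crit,
            cluster_alpha=cfg.cluster_alpha,
            n_perm=cfg.n_perm,
            seed=s_seed,
            vein_stage=cfg.n_veins > 0,
            cutoff_pct=cfg.cutoff_pct,
            n_dilations=cfg.n_dilations,
        )
        for kind, ka in analysis.kinds.items():
            lio.write_volume(sdir / f"beta_{kind}.nii", ka.glm.beta, geom.affine)
            lio.write_volume(sdir / f"zmap_{kind}.nii", ka.glm.z, geom.affine)
            lio.write_volume(
                sdir / f"sigmask_{kind}.nii", ka.sigmask.mask.astype(np.int16), geom.affine
            )
            lio.write_volume(sdir / f"beta_{kind}_deveined.nii", ka.beta_deveined, geom.affine)
        lio.write_volume(sdir / "alff.nii", analysis.alff, geom.affine)
        if analysis.gradient_classes is not None:
            lio.write_table(sdir / "gradient_classes.tsv", analysis.gradient_classes)
        record(f"glm+devein+veins:{sub}")
        analyses.append(analysis)
        manifest["subjects"].append(sub)

    record("layers")
    mat = group_matrix(analyses, kind="alpha", corrected=True)
    eff = pr.rm_anova_1way(mat)
    posthoc = pr.posthoc_paired_t(mat) if mat.shape[0] >= 2 else None
    group = pd.DataFrame(
        {
            "depth": np.arange(1, 7),
            "mean": mat.mean(axis=0),
            "sem": mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.nan,
        }
    )
    lio.write_table(out / "group_profile_alpha_deveined.tsv", group)
    if posthoc is not None:
        lio.write_table(out / "posthoc_alpha.tsv", posthoc)
    record("profiles")
    record("stats")

    manifest["group_anova"] = {"F": eff.F, "df1": eff.df1, "df2": eff.df2, "p": eff.p}
    manifest["seed"] = cfg.seed
    manifest["files"] = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
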