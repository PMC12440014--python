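"""Alpha-power regressor construction for EEG-informed fMRI GLMs.

Takes a source-space EEG timecourse (or a synthetic alpha-power series),
extracts the 8-13 Hz power envelope, repairs noisy TR/4 segments, convolves
with a double-gamma haemodynamic response function and samples at the fMRI
volume grid.  Also builds the boxcar task regressor and its orthogonalised
alpha variant, and compares eyes-open vs eyes-closed band power.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import Paradigm

ALPHA_BAND = (8.0, 13.0)


@dataclass
class AlphaPowerSeries:
    """Non-negative alpha power per EEG sample.

    ``segment_flags`` marks TR/4 windows as noisy (True) or clean (False);
    a trailing partial segment inherits the last full segment's flag.
    """

    values: np.ndarray
    fs_hz: float
    segment_len: int
    segment_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.segment_len < 1:
            raise ValueError("segment_len must be >= 1")
        if self.segment_flags is not None:
            self.segment_flags = np.asarray(self.segment_flags, dtype=bool)
            if len(self.segment_flags) != self.n_segments:
                raise ValueError(
                    f"expected {self.n_segments} segment flags, got {len(self.segment_flags)}"
                )

    @property
    def n_segments(self) -> int:
        return int(np.ceil(len(self.values) / self.segment_len))

    def segment_slices(self) -> list[slice]:
        edges = list(range(0, len(self.values), self.segment_len)) + [len(self.values)]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class Regressor:
    """One value per fMRI volume, plus its provenance."""

    values: np.ndarray
    kind: str
    hrf_params: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# --------------------------------------------------------------------- filters
def bandpass_alpha(signal_in: np.ndarray, fs_hz: float, band: tuple[float, float] = ALPHA_BAND) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass into the alpha band."""
    if fs_hz <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs_hz} Hz too low for a {band[1]} Hz passband edge")
    sos = sps.butter(4, band, btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal_in, dtype=float))


def power_envelope(filtered: np.ndarray, fs_hz: float, tr_s: float = 3.8) -> AlphaPowerSeries:
    """Analytic-signal magnitude of the band-passed trace."""
    env = np.abs(sps.hilbert(np.asarray(filtered, dtype=float)))
    seg = max(1, int(round(tr_s / 4.0 * fs_hz)))
    return AlphaPowerSeries(env, fs_hz, seg)


# --------------------------------------------------------------------- repair
def repair_segments(series: AlphaPowerSeries, condition_labels: np.ndarray) -> AlphaPowerSeries:
    """Replace noisy TR/4 segments.

    A noisy segment is replaced by the mean of the clean segments among its
    four nearest neighbours (two each side) when at least two of those are
    clean, otherwise by the run-level mean over all clean segments of the
    same condition.  Clean segments are untouched; replacements only ever
    draw on clean (original) data.
    """
    if series.segment_flags is None:
        raise ValueError("segment_flags not set")
    flags = series.segment_flags
    if flags.all():
        raise ValueError("all segments are noisy; nothing to average")
    labels = np.asarray(condition_labels)
    if len(labels) != series.n_segments:
        raise ValueError("condition_labels must have one entry per segment")

    slices = series.segment_slices()
    seg_means = np.array([series.values[s].mean() for s in slices])
    out = series.values.copy()
    for i in np.flatnonzero(flags):
        window = [j for j in (i - 2, i - 1, i + 1, i + 2) if 0 <= j < len(slices)]
        clean_nb = [j for j in window if not flags[j]]
        if len(clean_nb) >= 2:
            fill = seg_means[clean_nb].mean()
        else:
            same = (~flags) & (labels == labels[i])
            if not same.any():
                same = ~flags  # no clean segment of this condition: fall back to all clean
            fill = seg_means[same].mean()
        out[slices[i]] = fill
    return replace(series, values=out, segment_flags=np.zeros_like(flags))


# ------------------------------------------------------------------------ HRF
def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_disp_s: float = 3.0,
    undershoot_disp_s: float = 3.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma HRF, unit peak, causal.

    Each lobe is a gamma density parameterised by its mean (delay) and
    standard deviation (dispersion).
    """
    t = np.asarray(t, dtype=float)

    def shape(tt: np.ndarray) -> np.ndarray:
        h = lobe_at(tt, peak_delay_s, peak_disp_s) - undershoot_ratio * lobe_at(
            tt, undershoot_delay_s, undershoot_disp_s
        )
        h[tt < 0] = 0.0
        return h

    def lobe_at(tt: np.ndarray, delay: float, disp: float) -> np.ndarray:
        shape_k = (delay / disp) ** 2
        scale = disp**2 / delay
        return stats.gamma.pdf(tt, a=shape_k, scale=scale)

    # unit-peak normalisation on a dense internal grid, so the scale does
    # not depend on where the caller samples the function
    dense = np.linspace(0.0, 2.0 * undershoot_delay_s, 4096)
    peak = np.max(np.abs(shape(dense)))
    h = shape(t)
    return h / peak if peak > 0 else h


DEFAULT_HRF = dict(
    peak_delay_s=6.0,
    undershoot_delay_s=16.0,
    peak_disp_s=3.0,
    undershoot_disp_s=3.0,
    undershoot_ratio=1.0 / 6.0,
)


def _hrf_kernel(fs_hz: float, hrf_params: dict, length_s: float = 32.0) -> np.ndarray:
    t = np.arange(0.0, length_s, 1.0 / fs_hz)
    return double_gamma_hrf(t, **hrf_params)


# ------------------------------------------------------------------ regressors
def make_regressor(
    series: AlphaPowerSeries,
    paradigm: Paradigm,
    hrf_params: dict | None = None,
    sample_at: str = "midpoint",
) -> Regressor:
    """Demean, convolve with the double-gamma HRF and sample per volume.

    The convolved series is sampled at volume temporal midpoints by default
    (``sample_at='onset'`` switches to volume onsets).
    """
    if series.fs_hz != paradigm.eeg_fs_hz:
        raise ValueError("series sampling rate differs from paradigm.eeg_fs_hz")
    n_needed = paradigm.n_eeg_samples
    if len(series.values) < n_needed:
        raise ValueError(
            f"series ({len(series.values)} samples) shorter than the run ({n_needed} samples)"
        )
    params = dict(DEFAULT_HRF if hrf_params is None else hrf_params)
    x = series.values[:n_needed] - series.values[:n_needed].mean()
    kernel = _hrf_kernel(series.fs_hz, params)
    conv = sps.fftconvolve(x, kernel, mode="full")[:n_needed]
    offset = 0.5 if sample_at == "midpoint" else 0.0
    idx = np.minimum(
        ((np.arange(paradigm.n_vols) + offset) * paradigm.tr_s * series.fs_hz).astype(int),
        n_needed - 1,
    )
    return Regressor(conv[idx], kind="alpha", hrf_params=params)


def make_boxcar(paradigm: Paradigm) -> Regressor:
    """1 for volumes whose midpoint falls in eyes-closed, else 0."""
    return Regressor(paradigm.volume_closed().astype(float), kind="boxcar")


def orthogonalize(reg: Regressor, against: Regressor) -> Regressor:
    """Residual of projecting ``reg`` onto [``against``, constant]."""
    y = reg.values
    a = against.values
    if len(y) != len(a):
        raise ValueError("regressors must have equal length")
    a_dm = a - a.mean()
    norm = np.linalg.norm(a_dm)
    if norm < 1e-12 * max(1.0, np.abs(a).max()):
        raise ValueError("cannot orthogonalize against a constant/zero regressor")
    X = np.column_stack([a_dm, np.ones_like(a)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return Regressor(resid, kind=f"{reg.kind}_orth", hrf_params=reg.hrf_params)


# ------------------------------------------------------------------ statistics
@dataclass
class ConditionComparison:
    t: float
    p: float
    mean_open: float
    mean_closed: float
    n_pairs: int


def compare_conditions(series: AlphaPowerSeries, paradigm: Paradigm) -> ConditionComparison:
    """Paired t-test of eyes-closed vs eyes-open mean alpha power.

    Pairing unit is the open/closed block cycle within the run.
    """
    n = min(len(series.values), paradigm.n_eeg_samples)
    t_samp = np.arange(n) / series.fs_hz
    closed = paradigm.condition_at(t_samp)
    cycle_len = 2.0 * paradigm.block_len_s
    cycle = np.floor_divide(t_samp, cycle_len).astype(int)
    n_cycles = min(paradigm.n_cycles, cycle.max() + 1)
    if n_cycles < 2:
        raise ValueError("need at least 2 block pairs for a paired test")
    open_means, closed_means = [], []
    for c in range(n_cycles):
        in_cycle = cycle == c
        open_means.append(series.values[:n][in_cycle & ~closed].mean())
        closed_means.append(series.values[:n][in_cycle & closed].mean())
    open_means = np.array(open_means)
    closed_means = np.array(closed_means)
    if np.allclose(closed_means, open_means):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(closed_means, open_means)
    return ConditionComparison(
        t=float(t_stat),
        p=float(p),
        mean_open=float(open_means.mean()),
        mean_closed=float(closed_means.mean()),
        n_pairs=int(n_cycles),
    )
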