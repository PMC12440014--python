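"""Shared primitives: the block paradigm and labelled anatomical volumes.

The experiment alternates 30 s eyes-open and eyes-closed blocks while BOLD
volumes are acquired every ``tr_s`` seconds and EEG is sampled at
``eeg_fs_hz``.  Everything downstream (regressor construction, eyes-closed
ALFF windows, boxcar models) derives its timing from :class:`Paradigm`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tissue labels used throughout (CSF=1, WM=2, GM=3; 0 = background).
CSF, WM, GM = 1, 2, 3

OPEN, CLOSED = "open", "closed"


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class Paradigm:
    """Timing of the eyes-open / eyes-closed block experiment.

    Defaults: 30 s blocks, four open/closed cycles, TR 3.8 s, 68 volumes,
    EEG at 500 Hz.  The block sequence starts with ``order[0]`` and
    repeats periodically for the whole run (volumes acquired after the
    last scheduled cycle keep alternating).
    """

    block_len_s: float = 30.0
    n_cycles: int = 4
    order: tuple[str, str] = (OPEN, CLOSED)
    tr_s: float = 3.8
    n_vols: int = 68
    eeg_fs_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_vols < 1:
            raise ValueError("n_vols must be >= 1")
        if sorted(self.order) != [CLOSED, OPEN]:
            raise ValueError(f"order must be a permutation of (open, closed), got {self.order}")
        if self.block_len_s * 2 * self.n_cycles > self.n_vols * self.tr_s + self.tr_s:
            raise ValueError("block schedule longer than the acquired run")

    # ------------------------------------------------------------------ timing
    @property
    def run_duration_s(self) -> float:
        return self.n_vols * self.tr_s

    @property
    def n_eeg_samples(self) -> int:
        return int(round(self.run_duration_s * self.eeg_fs_hz))

    @property
    def segment_len_samples(self) -> int:
        """EEG segment length (TR/4 windows) in samples."""
        return max(1, int(round(self.tr_s / 4.0 * self.eeg_fs_hz)))

    def condition_at(self, t: np.ndarray | float) -> np.ndarray:
        """Boolean eyes-closed indicator at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        block = np.floor_divide(t, self.block_len_s).astype(int) % 2
        closed_first = self.order[0] == CLOSED
        return (block == 0) if closed_first else (block == 1)

    def volume_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_vols) + 0.5) * self.tr_s

    def volume_closed(self) -> np.ndarray:
        """Per-volume eyes-closed indicator (midpoint rule)."""
        return self.condition_at(self.volume_midpoints())

    def closed_periods(self) -> list[np.ndarray]:
        """Contiguous runs of eyes-closed volume indices."""
        closed = self.volume_closed()
        periods: list[np.ndarray] = []
        start = None
        for i, c in enumerate(closed):
            if c and start is None:
                start = i
            elif not c and start is not None:
                periods.append(np.arange(start, i))
                start = None
        if start is not None:
            periods.append(np.arange(start, self.n_vols))
        return periods


@dataclass
class LabelledVolume:
    """3D integer volume with CSF=1, WM=2, GM=3 labels (0 = background)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data)
        present = np.unique(self.data)
        if not np.isin(present, [0, CSF, WM, GM]).all():
            raise ValueError(f"labels must be within {{0,1,2,3}}, found {present}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    @property
    def gm_mask(self) -> np.ndarray:
        return self.mask(GM)


def check_same_grid(*arrays: np.ndarray, names: tuple[str, ...] | None = None) -> None:
    shapes = [np.asarray(a).shape for a in arrays]
    if len(set(shapes)) > 1:
        labels = names if names else tuple(f"array{i}" for i in range(len(arrays)))
        raise GridMismatchError(
            "grid mismatch: " + ", ".join(f"{n}{s}" for n, s in zip(labels, shapes))
        )


def spawn_seeds(seed: int, n: int, tag: str = "") -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one global seed.

    A stage tag keeps per-stage streams distinct so stages can be rerun in
    isolation reproducibly.
    """
    entropy = [seed] + [ord(c) for c in tag]
    ss = np.random.SeedSequence(entropy)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]
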