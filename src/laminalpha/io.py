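"""Volume and table I/O: NIfTI-1 via nibabel, TSV via pandas.

All volumes of one analysis share a single affine; combining maps with
different affines raises a :class:`~laminalpha.core.GridMismatchError`
naming both files.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import GridMismatchError


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def check_affines(paths_and_affines: list[tuple[str, np.ndarray]], atol: float = 1e-6) -> None:
    """Raise if any affine differs from the first, naming both files."""
    if not paths_and_affines:
        return
    ref_name, ref = paths_and_affines[0]
    for name, aff in paths_and_affines[1:]:
        if not np.allclose(ref, aff, atol=atol):
            raise GridMismatchError(f"affine mismatch between {ref_name} and {name}")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def upsampled_affine(affine: np.ndarray, factors: tuple[float, ...]) -> np.ndarray:
    """Affine for a nearest-neighbour upsampled volume (voxel size / factor)."""
    out = np.asarray(affine, dtype=float).copy()
    for ax, f in enumerate(factors):
        out[:3, ax] /= f
    return out
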