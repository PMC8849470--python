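"""On-disk layout of synthetic (or real) beta datasets.

One subject directory holds one 4-D NIfTI per run (condition as the 4th
axis), a 3-D binary mask, and a conditions.tsv naming the 4th-axis
entries.  The same layout can be assembled from per-run beta images of
a real study.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError
from .volume import VolumeGrid

__all__ = ["write_dataset", "read_dataset"]


def write_dataset(
    out_dir: str | Path,
    betas: np.ndarray,
    grid: VolumeGrid,
    condition_labels: Sequence[str],
) -> list[Path]:
    """Write run-wise beta volumes + mask + condition labels; returns paths."""
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 5 or betas.shape[2:] != grid.shape:
        raise ConfigError("betas must be (runs, conditions, x, y, z) on the grid")
    if betas.shape[1] != len(condition_labels):
        raise ConfigError("condition_labels length does not match betas")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(betas.shape[0]):
        vol4 = np.moveaxis(betas[r], 0, -1)  # x, y, z, condition
        p = out / f"beta_run{r:02d}.nii.gz"
        nib.save(nib.Nifti1Image(vol4, grid.affine), str(p))
        paths.append(p)
    mask_path = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine), str(mask_path))
    paths.append(mask_path)
    labels_path = out / "conditions.tsv"
    pd.DataFrame({"condition": list(condition_labels)}).to_csv(
        labels_path, sep="\t", index=False
    )
    paths.append(labels_path)
    return paths


def read_dataset(in_dir: str | Path) -> tuple[np.ndarray, VolumeGrid, tuple[str, ...]]:
    """Read the layout written by :func:`write_dataset`."""
    src = Path(in_dir)
    run_files = sorted(src.glob("beta_run*.nii.gz")) + sorted(src.glob("beta_run*.nii"))
    if not run_files:
        raise ConfigError(f"no beta_run*.nii[.gz] files in {src}")
    mask_img = nib.load(str(src / "mask.nii.gz")) if (src / "mask.nii.gz").exists() \
        else nib.load(str(src / "mask.nii"))
    mask = np.asarray(mask_img.get_fdata()) > 0
    grid = VolumeGrid(mask.shape, mask, mask_img.affine)
    labels = tuple(
        pd.read_csv(src / "conditions.tsv", sep="\t", dtype=str)["condition"]
    )
    runs = []
    for f in run_files:
        vol4 = np.asarray(nib.load(str(f)).get_fdata(), dtype=float)
        if vol4.shape[:3] != grid.shape or vol4.shape[3] != len(labels):
            raise ConfigError(f"{f} does not match mask/labels layout")
        runs.append(np.moveaxis(vol4, -1, 0))
    return np.stack(runs), grid, labels
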