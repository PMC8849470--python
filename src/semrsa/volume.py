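"""Voxel grids and statistic maps, with NIfTI serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigError

__all__ = ["VolumeGrid", "StatMap", "save_map", "load_map"]

#: statistic kinds a StatMap may carry
STATISTICS = ("fisher_z", "r", "t", "p", "tfce", "tfce_z", "beta")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with a brain mask and a voxel-to-mm affine."""

    shape: tuple[int, int, int]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ConfigError(f"volume shape must be 3 positive ints, got {shape}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise ConfigError(
                f"mask shape {mask.shape} does not match volume shape {shape}"
            )
        if not mask.any():
            raise ConfigError("mask must contain at least one voxel")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ConfigError("affine must be 4x4")
        mask.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full(cls, shape, affine=None) -> "VolumeGrid":
        """Grid whose mask covers the whole volume."""
        shape = tuple(int(s) for s in shape)
        return cls(shape, np.ones(shape, dtype=bool),
                   np.eye(4) if affine is None else affine)


@dataclass(frozen=True)
class StatMap:
    """Per-voxel statistic on a grid; NaN marks unevaluated voxels."""

    values: np.ndarray
    grid: VolumeGrid
    statistic: str = "fisher_z"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ConfigError(
                f"map shape {v.shape} does not match grid shape {self.grid.shape}"
            )
        if self.statistic not in STATISTICS:
            raise ConfigError(f"unknown statistic {self.statistic!r}")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)


def save_map(stat_map: StatMap, path: str | Path) -> None:
    img = nib.Nifti1Image(stat_map.values.astype(np.float64), stat_map.grid.affine)
    img.header["descrip"] = stat_map.statistic.encode()
    nib.save(img, str(path))


def load_map(path: str | Path, grid: VolumeGrid | None = None,
             statistic: str = "fisher_z") -> StatMap:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    if grid is None:
        grid = VolumeGrid.full(values.shape, affine=img.affine)
    return StatMap(values, grid, statistic)
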