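"""Searchlight representational similarity mapping.

A spherical neighborhood is centered on every masked voxel; within each
neighborhood the cross-validated correlation RDM is computed from the
run-wise beta patterns of the member voxels and compared (optionally
with partial-correlation nuisance control) to a model RDM.  The Fisher-z
of the comparison is written back to the sphere center, yielding one
brain map of model-brain correspondence per subject and model.

Two engines produce identical maps: ``direct`` literally runs the
rdm_core operations per neighborhood (the reference), while ``fast``
obtains every neighborhood's correlation sums at once by convolving the
masked beta volumes with the spherical kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import AlignmentError, ConfigError, DegeneratePatternError
from .rdm import RDM, PatternSet, FISHER_CLAMP, crossval_correlation_rdm, \
    partial_compare_rdms, unordered_half_splits
from .volume import StatMap, VolumeGrid

__all__ = [
    "Neighborhood",
    "SearchlightResult",
    "sphere_offsets",
    "iter_neighborhoods",
    "searchlight_rsa",
]

DEFAULT_RADIUS = 3.0
DEFAULT_MIN_VOXELS = 10

# relative variance floor below which a neighborhood pattern counts as constant
_VAR_REL_TOL = 1e-12


@dataclass(frozen=True)
class Neighborhood:
    center: tuple[int, int, int]
    members: np.ndarray  # (m, 3) voxel coordinates, center included

    @property
    def size(self) -> int:
        return self.members.shape[0]


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with dx²+dy²+dz² <= radius².

    Lexicographically ordered; always contains (0, 0, 0).  Radius is in
    voxel units with an isotropic Euclidean metric (the study's voxels
    are 3 mm isotropic); radius 3 gives the familiar 123-voxel sphere.
    """
    if radius < 0:
        raise ConfigError("radius must be nonnegative")
    r = int(math.floor(radius))
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    keep = (offs ** 2).sum(axis=1) <= radius ** 2 + 1e-12
    return offs[keep]


def iter_neighborhoods(
    grid: VolumeGrid, radius: float = DEFAULT_RADIUS,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> Iterator[Neighborhood]:
    """One neighborhood per masked voxel, members clipped to the mask.

    Neighborhoods smaller than ``min_voxels`` after clipping are
    skipped (count them by comparing against ``grid.n_voxels``).
    """
    offs = sphere_offsets(radius)
    shape = np.asarray(grid.shape)
    centers = np.argwhere(grid.mask)
    for center in centers:
        pts = center[None, :] + offs
        inside = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[inside]
        pts = pts[grid.mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        if pts.shape[0] < max(min_voxels, 1):
            continue
        yield Neighborhood(center=tuple(int(c) for c in center), members=pts)


@dataclass(frozen=True)
class SearchlightResult:
    """Fisher-z map plus bookkeeping of skipped / degenerate centers."""

    zmap: StatMap
    rmap: StatMap
    n_centers: int
    n_skipped_min_voxels: int
    n_degenerate: int


def _check_model_alignment(condition_labels, model: RDM, controls: Sequence[RDM]):
    labels = tuple(str(w) for w in condition_labels)
    for rdm in (model, *controls):
        if rdm.condition_labels != labels:
            raise AlignmentError(
                "model/control RDM labels do not match the beta condition labels"
            )
    if len(labels) < 3:
        raise ConfigError("searchlight RSA needs at least 3 conditions")


def _residualize(design: np.ndarray, x: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def _compare_triangles(
    tri: np.ndarray, model: RDM, controls: Sequence[RDM], method: str
) -> np.ndarray:
    """Correlate per-center RDM triangles (n_pairs, n_centers) with a model."""
    m = model.lower_triangle().astype(float)
    if method == "spearman":
        tri = stats.rankdata(tri, axis=0)
        m = stats.rankdata(m)
        ctrl = [stats.rankdata(c.lower_triangle()) for c in controls]
    elif method == "pearson":
        ctrl = [c.lower_triangle().astype(float) for c in controls]
    else:
        raise ConfigError(f"unknown method {method!r}")
    if ctrl:
        design = np.column_stack([np.ones(m.size), *ctrl])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ConfigError("control RDMs are collinear on the lower triangle")
        tri = _residualize(design, tri)
        m = _residualize(design, m)
    else:
        tri = tri - tri.mean(axis=0, keepdims=True)
        m = m - m.mean()
    mn = np.linalg.norm(m)
    if mn == 0.0:
        raise DegeneratePatternError("model RDM triangle has zero variance")
    tn = np.linalg.norm(tri, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tri.T @ m) / (tn * mn)
    return np.clip(r, -1.0, 1.0)


def _fast_triangles(betas, mask, splits, kernel, min_voxels):
    """Per-center cross-validated RDM lower triangles via sphere convolution.

    For every unordered half split the within/between correlation terms
    of each condition pair only require, per neighborhood, sums of the
    member voxels' values, squares and products — all obtainable in one
    pass by convolving the masked volumes with the spherical kernel.
    """
    n_cond = betas.shape[1]
    fmask = mask.astype(float)
    conv = lambda v: ndimage.convolve(v, kernel, mode="constant", cval=0.0)
    counts = np.rint(conv(fmask)).astype(int)
    centers = np.nonzero(mask)
    m = counts[centers].astype(float)
    ok_size = m >= max(min_voxels, 2)
    n_centers = m.size
    n_pairs = n_cond * (n_cond - 1) // 2
    tri = np.zeros((n_pairs, n_centers))
    valid = ok_size.copy()

    iu, ju = np.tril_indices(n_cond, k=-1)
    for a_runs, b_runs in splits:
        half = []
        for runs in (a_runs, b_runs):
            h = betas[list(runs)].mean(axis=0)
            # subtract the within-mask mean per condition before masking:
            # neighborhood covariances are translation invariant, and the
            # smaller magnitudes keep the sum formulas accurate
            mu = h[:, mask].mean(axis=1)
            h = (h - mu[:, None, None, None]) * fmask
            half.append(h)
        a, b = half
        Sa = np.stack([conv(a[i])[centers] for i in range(n_cond)])
        Sb = np.stack([conv(b[i])[centers] for i in range(n_cond)])
        Saa = np.stack([conv(a[i] ** 2)[centers] for i in range(n_cond)])
        Sbb = np.stack([conv(b[i] ** 2)[centers] for i in range(n_cond)])
        var_a = Saa - Sa ** 2 / m
        var_b = Sbb - Sb ** 2 / m
        valid &= np.all(var_a > _VAR_REL_TOL * (Saa + 1e-300), axis=0)
        valid &= np.all(var_b > _VAR_REL_TOL * (Sbb + 1e-300), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(var_a * var_b)
            diag = np.stack(
                [conv(a[i] * b[i])[centers] for i in range(n_cond)]
            )
            corr_diag = (diag - Sa * Sb / m) / denom
            for p, (i, j) in enumerate(zip(iu, ju)):
                cij = (conv(a[i] * b[j])[centers] - Sa[i] * Sb[j] / m) / np.sqrt(
                    var_a[i] * var_b[j]
                )
                cji = (conv(a[j] * b[i])[centers] - Sa[j] * Sb[i] / m) / np.sqrt(
                    var_a[j] * var_b[i]
                )
                tri[p] += 0.5 * (corr_diag[i] + corr_diag[j]) - 0.5 * (cij + cji)
    tri /= len(splits)
    valid &= np.all(np.isfinite(tri), axis=0)
    n_skipped = int(n_centers - ok_size.sum())
    n_degenerate = int(ok_size.sum() - valid.sum())
    return tri, valid, centers, n_skipped, n_degenerate


def searchlight_rsa(
    betas: np.ndarray,
    condition_labels: Sequence[str],
    grid: VolumeGrid,
    model: RDM,
    controls: Sequence[RDM] = (),
    radius: float = DEFAULT_RADIUS,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    method: str = "pearson",
    engine: str = "fast",
) -> SearchlightResult:
    """Map model-brain RDM correspondence across a masked volume.

    Parameters
    ----------
    betas:
        Run-wise condition beta volumes, shape (n_runs, n_conditions,
        nx, ny, nz), aligned to ``grid``.
    model, controls:
        Model RDM and optional nuisance RDMs, label-aligned with
        ``condition_labels``.
    radius, min_voxels:
        Sphere radius in voxels and the minimum neighborhood size after
        clipping to the mask; smaller neighborhoods are skipped and
        carry the NaN sentinel.
    engine:
        ``"fast"`` (convolution, default) or ``"direct"`` (explicit
        per-neighborhood loop).  Both produce the same map.

    Returns
    -------
    SearchlightResult with Fisher-z and raw-r maps (NaN where skipped or
    degenerate) and skip counts.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 5:
        raise ConfigError("betas must have shape (runs, conditions, x, y, z)")
    if betas.shape[2:] != grid.shape:
        raise AlignmentError("beta volumes are not aligned to the grid")
    if betas.shape[1] != len(condition_labels):
        raise ConfigError("condition_labels length does not match betas")
    _check_model_alignment(condition_labels, model, controls)

    zvol = np.full(grid.shape, np.nan)
    rvol = np.full(grid.shape, np.nan)
    if engine == "fast":
        splits = unordered_half_splits(betas.shape[0])
        offs = sphere_offsets(radius)
        r_int = int(math.floor(radius))
        kernel = np.zeros((2 * r_int + 1,) * 3)
        kernel[offs[:, 0] + r_int, offs[:, 1] + r_int, offs[:, 2] + r_int] = 1.0
        tri, valid, centers, n_skip, n_degen = _fast_triangles(
            betas, grid.mask, splits, kernel, min_voxels
        )
        r = np.full(valid.size, np.nan)
        if valid.any():
            r[valid] = _compare_triangles(tri[:, valid], model, controls, method)
        bad = valid & ~np.isfinite(r)
        n_degen += int(bad.sum())
        rvol[centers] = r
        with np.errstate(invalid="ignore"):
            zvol[centers] = np.arctanh(
                np.clip(r, -1.0 + FISHER_CLAMP, 1.0 - FISHER_CLAMP)
            )
        n_centers = valid.size
    elif engine == "direct":
        n_centers = grid.n_voxels
        n_visited = 0
        n_degen = 0
        for nb in iter_neighborhoods(grid, radius=radius, min_voxels=min_voxels):
            n_visited += 1
            pats = betas[:, :, nb.members[:, 0], nb.members[:, 1], nb.members[:, 2]]
            try:
                pset = PatternSet(pats, tuple(condition_labels))
                neural = crossval_correlation_rdm(pset)
                cmp = partial_compare_rdms(neural, model, controls, method=method)
            except DegeneratePatternError:
                n_degen += 1
                continue
            rvol[nb.center] = cmp.r
            zvol[nb.center] = cmp.z
        n_skip = n_centers - n_visited
    else:
        raise ConfigError(f"unknown engine {engine!r}")

    return SearchlightResult(
        zmap=StatMap(zvol, grid, "fisher_z"),
        rmap=StatMap(rvol, grid, "r"),
        n_centers=n_centers,
        n_skipped_min_voxels=int(n_skip),
        n_degenerate=int(n_degen),
    )
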