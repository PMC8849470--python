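"""Group-level inference over subject correspondence maps.

Subject-wise Fisher-z maps are combined with voxelwise one-sided
one-sample t-tests.  Family-wise error over clusters is controlled by a
sign-flip permutation null of the maximum cluster extent (a stand-in
for parametric random-field cluster inference; equivalence with SPM
numbers is not claimed).  Threshold-free cluster enhancement (TFCE)
with a sign-permutation null provides an alternative map-level test,
and Benjamini-Hochberg FDR handles ROI model families.

The one-sample sign-flip null assumes subject maps are exchangeable
and symmetrically distributed around zero under H0, which holds for
Fisher-z correlation maps computed from independent subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigError
from .volume import StatMap, VolumeGrid

__all__ = [
    "TfceParams",
    "ClusterTable",
    "group_ttest_map",
    "cluster_threshold",
    "tfce",
    "tfce_permutation_z",
    "fdr_correct",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY:
        raise ConfigError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])


@dataclass(frozen=True)
class TfceParams:
    """TFCE integration and permutation settings.

    E and H are the standard extent/height exponents (0.5 and 2).  The
    step ``dh`` may be given explicitly; when None it is max/n_steps,
    derived symmetrically from observed and permuted maps so the
    observed statistic remains exchangeable with its null.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100
    n_permutations: int = 1000
    seed: int = 0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ConfigError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ConfigError("dh must be positive")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.n_permutations < 100:
            raise ConfigError("need at least 100 permutations")
        _structure(self.connectivity)


@dataclass(frozen=True)
class ClusterTable:
    """Suprathreshold clusters with permutation-FWE p-values.

    ``table`` has one row per cluster (cluster_id, n_voxels, peak
    coordinates, peak_stat, p_fwe, significant); ``labels`` is the
    labeled cluster volume (0 = background) for ROI extraction.
    """

    table: pd.DataFrame
    labels: np.ndarray
    grid: VolumeGrid
    extent_threshold: float
    provenance: str = ""

    @property
    def n_clusters(self) -> int:
        return len(self.table)


def _stack_listwise(subject_maps: Sequence[StatMap]) -> tuple[np.ndarray, np.ndarray, VolumeGrid]:
    """Stack subject values, returning (data S x voxels, valid mask, grid).

    Voxels carrying the NaN sentinel in any subject are excluded
    listwise so every permutation sees the same voxel set.
    """
    if len(subject_maps) < 2:
        raise ConfigError("need at least 2 subjects")
    grid = subject_maps[0].grid
    for sm in subject_maps[1:]:
        if sm.grid.shape != grid.shape:
            raise ConfigError("subject maps are not aligned to one grid")
    stack = np.stack([sm.values for sm in subject_maps])
    valid = np.all(np.isfinite(stack), axis=0) & grid.mask
    if not valid.any():
        raise ConfigError("no voxel has complete data across subjects")
    return stack[:, valid], valid, grid


def _t_one_sample(data: np.ndarray) -> np.ndarray:
    """One-sample t along axis 0; +/-inf where variance is 0 and mean != 0."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    t = np.where((sd == 0) & (mean > 0), np.inf, t)
    t = np.where((sd == 0) & (mean < 0), -np.inf, t)
    return t


def group_ttest_map(subject_maps: Sequence[StatMap]) -> tuple[StatMap, StatMap]:
    """Voxelwise one-sided (greater-than-zero) one-sample t-test.

    Returns the t map and the one-sided p map; NaN marks voxels excluded
    listwise.  Zero-variance voxels follow the degenerate contract:
    t = +/-inf with p = 0 / 1, and t = 0, p = 0.5 for all-zero data.
    """
    data, valid, grid = _stack_listwise(subject_maps)
    n = data.shape[0]
    t = _t_one_sample(data)
    p = stats.t.sf(t, df=n - 1)
    tvol = np.full(grid.shape, np.nan)
    pvol = np.full(grid.shape, np.nan)
    tvol[valid] = t
    pvol[valid] = p
    return StatMap(tvol, grid, "t"), StatMap(pvol, grid, "p")


def _sign_matrix(n_subjects: int, n_permutations: int, seed: int) -> np.ndarray:
    """Sign-flip patterns; exhaustive when 2^n does not exceed the request."""
    if 2 ** n_subjects <= n_permutations:
        combos = np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
        return combos
    rng = np.random.default_rng(seed)
    return rng.choice([1.0, -1.0], size=(n_permutations, n_subjects))


def _perm_t(data: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for every sign pattern, (P, voxels); squares are flip-invariant."""
    n = data.shape[0]
    sq = (data ** 2).sum(axis=0)
    mean = signs @ data / n
    var = (sq - n * mean ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.where(var <= 0, np.where(mean > 0, np.inf,
                 np.where(mean < 0, -np.inf, 0.0)), t)
    return t


def _cluster_sizes(binary: np.ndarray, structure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def cluster_threshold(
    t_map: StatMap,
    subject_maps: Sequence[StatMap],
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
    n_permutations: int = 1000,
    seed: int = 0,
    provenance: str = "",
) -> ClusterTable:
    """Cluster-extent FWE control by sign-flip permutation.

    Voxels with one-sided p < ``voxel_p`` are labeled into connected
    components; the null distribution of the maximum component extent is
    built by recomputing the thresholded t-map under random sign flips
    of the subject maps.  A cluster is significant iff its extent
    exceeds the (1 - ``cluster_alpha``) quantile of that null.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_alpha < 1):
        raise ConfigError("voxel_p and cluster_alpha must lie in (0, 1)")
    data, valid, grid = _stack_listwise(subject_maps)
    n = data.shape[0]
    t_crit = stats.t.isf(voxel_p, df=n - 1)
    structure = _structure(connectivity)

    signs = _sign_matrix(n, n_permutations, seed)
    null_max = np.zeros(signs.shape[0])
    chunk = max(1, int(2e7 // max(data.shape[1], 1)))
    vol = np.zeros(grid.shape, dtype=bool)
    pos = 0
    for start in range(0, signs.shape[0], chunk):
        t_perm = _perm_t(data, signs[start:start + chunk])
        for row in t_perm:
            vol[:] = False
            vol[valid] = row > t_crit
            _, sizes = _cluster_sizes(vol, structure)
            null_max[pos] = sizes.max() if sizes.size else 0
            pos += 1
    extent_threshold = float(np.quantile(null_max, 1.0 - cluster_alpha))

    supra = np.nan_to_num(t_map.values, nan=-np.inf) > t_crit
    labels, sizes = _cluster_sizes(supra & valid, structure)
    rows = []
    for cid, size in enumerate(sizes, start=1):
        coords = np.argwhere(labels == cid)
        vals = t_map.values[coords[:, 0], coords[:, 1], coords[:, 2]]
        peak = coords[np.argmax(vals)]
        p_fwe = float((1 + np.sum(null_max >= size)) / (1 + null_max.size))
        rows.append(
            dict(
                cluster_id=cid,
                n_voxels=int(size),
                peak_x=int(peak[0]),
                peak_y=int(peak[1]),
                peak_z=int(peak[2]),
                peak_stat=float(np.max(vals)),
                p_fwe=p_fwe,
                significant=bool(size > extent_threshold),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_voxels", "peak_x", "peak_y", "peak_z",
            "peak_stat", "p_fwe", "significant",
        ],
    )
    return ClusterTable(
        table=table,
        labels=labels,
        grid=grid,
        extent_threshold=extent_threshold,
        provenance=provenance,
    )


def _tfce_values(values: np.ndarray, E: float, H: float, dh: float,
                 structure: np.ndarray) -> np.ndarray:
    """Raw TFCE integral; NaN treated as background, negatives contribute 0."""
    v = np.nan_to_num(values, nan=0.0)
    out = np.zeros_like(v)
    vmax = v.max(initial=0.0)
    if vmax <= 0 or dh <= 0:
        return out
    h = dh
    while h <= vmax + 1e-12:
        supra = v >= h
        labels, sizes = _cluster_sizes(supra, structure)
        if sizes.size == 0:
            break
        extent = sizes[labels[supra] - 1].astype(float)
        out[supra] += extent ** E * h ** H * dh
        h += dh
    return out


def tfce(stat_map: StatMap, params: TfceParams) -> StatMap:
    """Threshold-free cluster enhancement of one statistic map.

    Each voxel accumulates extent^E * height^H * dh over thresholds up
    to its own height, where extent is the size of the suprathreshold
    component containing it.  When ``params.dh`` is None the step is
    the map maximum over ``n_steps``.
    """
    v = np.nan_to_num(stat_map.values, nan=0.0)
    dh = params.dh
    if dh is None:
        vmax = float(v.max(initial=0.0))
        if vmax <= 0:
            return StatMap(np.zeros(stat_map.values.shape), stat_map.grid, "tfce")
        dh = vmax / params.n_steps
    out = _tfce_values(stat_map.values, params.E, params.H, dh,
                       _structure(params.connectivity))
    return StatMap(out, stat_map.grid, "tfce")


def tfce_permutation_z(
    subject_maps: Sequence[StatMap],
    params: TfceParams,
    use_t: bool = True,
    mode: str = "rank",
) -> StatMap:
    """TFCE group map z-scored against a sign-flip permutation null.

    The group t-map (or mean map with ``use_t=False``) is TFCE-enhanced;
    the same enhancement is applied to every sign-flipped group map.
    ``mode='rank'`` (default) converts the per-voxel rank of the
    observed value within its null into a p-value and then a normal
    z-score — exactly calibrated under exchangeability.  ``mode='meansd'``
    z-scores against the null mean and standard deviation instead.

    If the requested permutation count reaches the number of distinct
    sign patterns (2^n subjects), the null is enumerated exhaustively.
    """
    if mode not in ("rank", "meansd"):
        raise ConfigError("mode must be 'rank' or 'meansd'")
    data, valid, grid = _stack_listwise(subject_maps)
    structure = _structure(params.connectivity)
    signs = _sign_matrix(data.shape[0], params.n_permutations, params.seed)

    stat = _t_one_sample(data) if use_t else data.mean(axis=0)
    t_perm = _perm_t(data, signs) if use_t else signs @ data / data.shape[0]
    # cap infinities (zero-variance voxels) at a finite height for integration
    finite_max = np.nanmax(np.where(np.isfinite(t_perm), t_perm, np.nan),
                           initial=0.0)
    finite_max = max(finite_max,
                     np.max(stat[np.isfinite(stat)], initial=0.0))
    stat = np.clip(stat, -1e30, finite_max)
    t_perm = np.clip(t_perm, -1e30, finite_max)

    dh = params.dh
    if dh is None:
        gmax = max(float(np.max(t_perm, initial=0.0)),
                   float(np.max(stat, initial=0.0)))
        if gmax <= 0:
            return StatMap(np.where(valid, 0.0, np.nan), grid, "tfce_z")
        dh = gmax / params.n_steps

    vol = np.zeros(grid.shape)

    def enhance(flat: np.ndarray) -> np.ndarray:
        vol[:] = 0.0
        vol[valid] = flat
        return _tfce_values(vol, params.E, params.H, dh, structure)[valid]

    obs = enhance(stat)
    if mode == "rank":
        count = np.zeros_like(obs)
        for row in t_perm:
            count += enhance(row) >= obs
        p = (1.0 + count) / (1.0 + signs.shape[0])
        z = stats.norm.isf(p)
    else:
        null = np.stack([enhance(row) for row in t_perm])
        sd = null.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (obs - null.mean(axis=0)) / sd
        z = np.where(sd == 0, 0.0, z)
    zvol = np.full(grid.shape, np.nan)
    zvol[valid] = z
    return StatMap(zvol, grid, "tfce_z")


def fdr_correct(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Rejects the i smallest p-values where i is the largest index with
    p_(i) <= (i/m) q.  Returns (rejected flags, adjusted p-values); the
    adjusted values use the standard monotone min transform.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ConfigError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return reject, adjusted
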