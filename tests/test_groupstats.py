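"""Group t-maps, permutation cluster inference, TFCE, and FDR."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from semrsa.errors import ConfigError
from semrsa.groupstats import (
    TfceParams,
    cluster_threshold,
    fdr_correct,
    group_ttest_map,
    tfce,
    tfce_permutation_z,
)
from semrsa.simulate import generate_null_maps
from semrsa.volume import StatMap, VolumeGrid


def maps_from_stack(stack):
    grid = VolumeGrid.full(stack.shape[1:])
    return [StatMap(v, grid, "fisher_z") for v in stack]


# ---------------------------------------------------------------------------
# one-sample t maps


def test_ttest_hand_computed_oracle():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    stack = np.tile(vals[:, None, None, None], (1, 2, 2, 2))
    tmap, pmap = group_ttest_map(maps_from_stack(stack))
    want_t = 3.0 / (np.std(vals, ddof=1) / np.sqrt(5))
    assert tmap.values[0, 0, 0] == pytest.approx(want_t, abs=1e-12)
    assert want_t == pytest.approx(4.2426, abs=1e-4)
    assert pmap.values[0, 0, 0] == pytest.approx(stats.t.sf(want_t, 4), abs=1e-12)


def test_ttest_degenerate_contracts():
    stack = np.zeros((4, 2, 1, 1))
    stack[:, 1, 0, 0] = 2.5  # zero variance, nonzero mean
    tmap, pmap = group_ttest_map(maps_from_stack(stack))
    assert tmap.values[0, 0, 0] == 0.0 and pmap.values[0, 0, 0] == 0.5
    assert np.isposinf(tmap.values[1, 0, 0]) and pmap.values[1, 0, 0] == 0.0


def test_ttest_listwise_nan_propagation():
    stack = np.random.default_rng(0).standard_normal((5, 2, 2, 2))
    stack[2, 0, 0, 0] = np.nan
    tmap, _ = group_ttest_map(maps_from_stack(stack))
    assert np.isnan(tmap.values[0, 0, 0])
    assert np.isfinite(tmap.values[1, 1, 1])
    with pytest.raises(ConfigError):
        group_ttest_map(maps_from_stack(stack)[:1])


# ---------------------------------------------------------------------------
# cluster-extent inference


def test_cluster_components_hand_counted():
    # two disjoint blobs of 5 and 9 voxels under 26-connectivity
    vol = np.zeros((10, 10, 10))
    blob5 = [(1, 1, 1), (1, 1, 2), (2, 2, 2), (3, 3, 3), (3, 3, 4)]  # diagonal chain
    for c in blob5:
        vol[c] = 5.0
    vol[7:10, 7, 7] = 5.0
    vol[7:10, 8, 7] = 5.0
    vol[7:10, 7, 8] = 5.0  # 9 voxels
    rng = np.random.default_rng(1)
    stack = vol[None] + 0.01 * rng.standard_normal((8,) + vol.shape)
    maps = maps_from_stack(stack)
    tmap, _ = group_ttest_map(maps)
    table = cluster_threshold(tmap, maps, voxel_p=0.001, connectivity=26,
                              n_permutations=100, seed=0)
    assert sorted(table.table["n_voxels"]) == [5, 9]
    # 6-connectivity splits the diagonal chain
    table6 = cluster_threshold(tmap, maps, voxel_p=0.001, connectivity=6,
                               n_permutations=100, seed=0)
    assert len(table6.table) > 2


def test_cluster_threshold_empty_for_null_maps():
    maps = maps_from_stack(np.zeros((5, 6, 6, 6)))
    tmap, _ = group_ttest_map(maps)
    table = cluster_threshold(tmap, maps, n_permutations=100, seed=0)
    assert table.n_clusters == 0


def test_cluster_threshold_deterministic_in_seed():
    rng = np.random.default_rng(3)
    stack = rng.standard_normal((10, 8, 8, 8)) * 0.5
    stack[:, 2:5, 2:5, 2:5] += 1.0
    maps = maps_from_stack(stack)
    tmap, _ = group_ttest_map(maps)
    a = cluster_threshold(tmap, maps, n_permutations=200, seed=7)
    b = cluster_threshold(tmap, maps, n_permutations=200, seed=7)
    assert a.table.equals(b.table)
    assert a.extent_threshold == b.extent_threshold


def test_cluster_recovery_of_planted_signal():
    rng = np.random.default_rng(4)
    stack = 0.3 * rng.standard_normal((20, 12, 12, 12))
    stack[:, 4:8, 4:8, 4:8] += 0.8
    maps = maps_from_stack(stack)
    tmap, _ = group_ttest_map(maps)
    table = cluster_threshold(tmap, maps, n_permutations=300, seed=0)
    sig = table.table[table.table["significant"]]
    assert len(sig) >= 1
    best = sig.sort_values("n_voxels", ascending=False).iloc[0]
    assert 4 <= best["peak_x"] < 8
    assert best["p_fwe"] < 0.05


# ---------------------------------------------------------------------------
# TFCE


def test_tfce_closed_form_single_voxel_and_block():
    grid = VolumeGrid.full((9, 9, 9))
    h0 = 2.0
    params = TfceParams(E=0.5, H=2.0, dh=h0 / 1000, n_permutations=100)
    single = np.zeros(grid.shape)
    single[4, 4, 4] = h0
    got = tfce(StatMap(single, grid, "t"), params).values[4, 4, 4]
    assert got == pytest.approx(h0 ** 3 / 3, rel=0.01)

    block = np.zeros(grid.shape)
    block[2:4, 2:4, 2:4] = h0  # flat 8-voxel block
    out = tfce(StatMap(block, grid, "t"), params).values
    want = np.sqrt(8) * h0 ** 3 / 3
    np.testing.assert_allclose(out[2:4, 2:4, 2:4], want, rtol=0.01)


def test_tfce_zero_map_and_negative_values():
    grid = VolumeGrid.full((5, 5, 5))
    params = TfceParams(n_permutations=100)
    zero = tfce(StatMap(np.zeros(grid.shape), grid, "t"), params)
    assert np.all(zero.values == 0)
    neg = np.zeros(grid.shape)
    neg[2, 2, 2] = -3.0
    assert np.all(tfce(StatMap(neg, grid, "t"), params).values == 0)


def test_tfce_monotone_in_map_scale():
    rng = np.random.default_rng(5)
    grid = VolumeGrid.full((8, 8, 8))
    v = np.abs(rng.standard_normal(grid.shape))
    params = TfceParams(dh=0.01, n_permutations=100)
    lo = tfce(StatMap(v, grid, "t"), params).values
    hi = tfce(StatMap(2.0 * v, grid, "t"), params).values
    nz = lo > 0
    assert np.all(hi[nz] > lo[nz])


def test_tfce_permutation_z_recovers_planted_signal():
    rng = np.random.default_rng(6)
    stack = 0.3 * rng.standard_normal((12, 10, 10, 10))
    stack[:, 3:7, 3:7, 3:7] += 0.6
    maps = maps_from_stack(stack)
    z = tfce_permutation_z(maps, TfceParams(n_permutations=200, seed=1,
                                            n_steps=50))
    # rank-based z saturates at the minimum attainable p, so the maximum
    # is attained by a set of voxels; the planted block must be in it
    zmax = np.nanmax(z.values)
    assert zmax > 1.96
    assert np.nanmax(z.values[3:7, 3:7, 3:7]) == zmax
    ties = np.argwhere(z.values == zmax)
    inside = [(3 <= a < 7 and 3 <= b < 7 and 3 <= c < 7) for a, b, c in ties]
    assert np.mean(inside) > 0.75


def test_tfce_permutation_exhaustive_for_few_subjects():
    maps = generate_null_maps(4, (6, 6, 6), seed=2)
    params = TfceParams(n_permutations=100, seed=0, n_steps=20)
    a = tfce_permutation_z(maps, params)
    b = tfce_permutation_z(maps, TfceParams(n_permutations=100, seed=99,
                                            n_steps=20))
    # 2^4 = 16 patterns < 100 requested -> exhaustive null, seed irrelevant
    np.testing.assert_array_equal(a.values, b.values)


def test_tfce_meansd_mode_runs():
    maps = generate_null_maps(8, (6, 6, 6), seed=3)
    z = tfce_permutation_z(maps, TfceParams(n_permutations=100, seed=0,
                                            n_steps=20), mode="meansd")
    assert np.all(np.isfinite(z.values))


def test_tfce_params_validation():
    with pytest.raises(ConfigError):
        TfceParams(E=0.0)
    with pytest.raises(ConfigError):
        TfceParams(dh=-0.1)
    with pytest.raises(ConfigError):
        TfceParams(n_permutations=50)


# ---------------------------------------------------------------------------
# FDR


def brute_force_bh(p, q):
    """Literal step-up definition, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def test_fdr_hand_computed_example():
    reject, adjusted = fdr_correct([0.01, 0.02, 0.03, 0.04, 0.2], q=0.05)
    np.testing.assert_array_equal(reject, [True, True, True, True, False])
    np.testing.assert_allclose(adjusted, [0.05, 0.05, 0.05, 0.05, 0.2])


def test_fdr_edge_cases():
    reject, _ = fdr_correct([1.0, 1.0, 1.0], q=0.05)
    assert not reject.any()
    reject, adjusted = fdr_correct([0.0, 0.0], q=0.05)
    assert reject.all() and np.all(adjusted == 0)
    with pytest.raises(ConfigError):
        fdr_correct([0.5, 1.5], q=0.05)
    with pytest.raises(ConfigError):
        fdr_correct([0.5], q=1.5)


@pytest.mark.parametrize("seed", range(5))
def test_fdr_matches_bruteforce_and_statsmodels(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        m = int(rng.integers(1, 40))
        p = np.round(rng.random(m), 3)
        q = float(rng.choice([0.01, 0.05, 0.1]))
        reject, adjusted = fdr_correct(p, q)
        np.testing.assert_array_equal(reject, brute_force_bh(p, q))
        sm_reject, sm_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
        np.testing.assert_array_equal(reject, sm_reject)
        np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)
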