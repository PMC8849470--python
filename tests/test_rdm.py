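"""Cross-validated RDMs, model RDMs, and RDM comparison."""

import itertools
import math

import numpy as np
import pytest

from semrsa.errors import (
    AlignmentError,
    CollinearityError,
    ConfigError,
    DegeneratePatternError,
    MissingWordError,
)
from semrsa.rdm import (
    RDM,
    PatternSet,
    compare_rdms,
    correlation_distance_rdm,
    crossval_correlation_rdm,
    feature_difference_rdm,
    fisher_z,
    frequency_rdm,
    partial_compare_rdms,
    unordered_half_splits,
)

from conftest import random_pattern_set


# ---------------------------------------------------------------------------
# independent brute-force oracle for the cross-validated correlation distance


def brute_force_crossval_rdm(patterns: np.ndarray) -> np.ndarray:
    """Enumerate every unordered 50/50 split and all four correlation terms."""
    n_runs, n_cond, _ = patterns.shape
    k = n_runs // 2
    seen = set()
    splits = []
    for combo in itertools.combinations(range(n_runs), k):
        rest = tuple(r for r in range(n_runs) if r not in combo)
        key = frozenset((frozenset(combo), frozenset(rest)))
        if key not in seen:
            seen.add(key)
            splits.append((combo, rest))
    out = np.zeros((n_cond, n_cond))
    for i in range(n_cond):
        for j in range(n_cond):
            if i == j:
                continue
            vals = []
            for a, b in splits:
                ma = patterns[list(a)].mean(axis=0)
                mb = patterns[list(b)].mean(axis=0)
                within = (np.corrcoef(ma[i], mb[i])[0, 1]
                          + np.corrcoef(ma[j], mb[j])[0, 1]) / 2
                between = (np.corrcoef(ma[i], mb[j])[0, 1]
                           + np.corrcoef(ma[j], mb[i])[0, 1]) / 2
                vals.append(within - between)
            out[i, j] = np.mean(vals)
    return out


def test_unordered_half_splits_counts():
    assert len(unordered_half_splits(2)) == 1
    assert len(unordered_half_splits(4)) == 3
    assert len(unordered_half_splits(10)) == 126  # the 10-run design
    # odd counts: floor/ceil halves, each unordered split once
    assert len(unordered_half_splits(5)) == math.comb(5, 2)
    for a, b in unordered_half_splits(6):
        assert sorted(a + b) == list(range(6))


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("n_runs", [2, 4, 6])
def test_crossval_rdm_matches_bruteforce(seed, n_runs):
    ps = random_pattern_set(seed, n_runs=n_runs, n_conditions=4, n_channels=6)
    got = crossval_correlation_rdm(ps).matrix
    want = brute_force_crossval_rdm(ps.patterns)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_crossval_rdm_odd_run_count_matches_bruteforce():
    ps = random_pattern_set(3, n_runs=5, n_conditions=3, n_channels=7)
    np.testing.assert_allclose(
        crossval_correlation_rdm(ps).matrix,
        brute_force_crossval_rdm(ps.patterns),
        atol=1e-12,
    )


def test_identical_conditions_have_zero_dissimilarity(rng):
    base = rng.standard_normal((4, 1, 6))
    patterns = np.concatenate([base, base], axis=1)  # two identical conditions
    patterns = np.concatenate([patterns, rng.standard_normal((4, 1, 6))], axis=1)
    rdm = crossval_correlation_rdm(PatternSet(patterns, ("a", "b", "c")))
    assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_noiseless_run_invariant_patterns_give_one_minus_r(rng):
    base = rng.standard_normal((3, 8))
    patterns = np.repeat(base[None], 4, axis=0)  # identical across runs
    rdm = crossval_correlation_rdm(PatternSet(patterns, ("a", "b", "c")))
    for i, j in itertools.combinations(range(3), 2):
        expected = 1.0 - np.corrcoef(base[i], base[j])[0, 1]
        assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)


def test_crossval_rdm_invariant_to_run_order(rng):
    ps = random_pattern_set(9, n_runs=6, n_conditions=4)
    perm = np.random.default_rng(1).permutation(6)
    shuffled = PatternSet(ps.patterns[perm], ps.condition_labels)
    np.testing.assert_allclose(
        crossval_correlation_rdm(ps).matrix,
        crossval_correlation_rdm(shuffled).matrix,
        atol=1e-12,
    )


def test_crossval_rdm_equivariant_to_condition_permutation():
    ps = random_pattern_set(11, n_conditions=5)
    perm = [3, 0, 4, 1, 2]
    shuffled = PatternSet(
        ps.patterns[:, perm], tuple(ps.condition_labels[i] for i in perm)
    )
    a = crossval_correlation_rdm(ps)
    b = crossval_correlation_rdm(shuffled)
    np.testing.assert_allclose(
        b.matrix, a.matrix[np.ix_(perm, perm)], atol=1e-12
    )


def test_crossval_rdm_unbiased_under_pure_noise():
    # expectation of the cross-validated distance is 0 for pure noise
    means = []
    for seed in range(500):
        ps = random_pattern_set(seed, n_runs=4, n_conditions=3, n_channels=10)
        rdm = crossval_correlation_rdm(ps)
        means.append(rdm.lower_triangle().mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(means.size)
    assert abs(means.mean()) < 3 * se + 1e-12


def test_degenerate_pattern_error_names_condition():
    patterns = np.ones((2, 3, 4))
    patterns[:, :2] = np.random.default_rng(0).standard_normal((2, 2, 4))
    with pytest.raises(DegeneratePatternError, match="w02"):
        crossval_correlation_rdm(
            PatternSet(patterns, ("w00", "w01", "w02"))
        )


def test_pattern_set_validation():
    with pytest.raises(ConfigError):
        PatternSet(np.zeros((1, 3, 4)), ("a", "b", "c"))  # one run
    with pytest.raises(ConfigError):
        PatternSet(np.zeros((2, 3, 1)), ("a", "b", "c"))  # one channel
    with pytest.raises(ConfigError):
        PatternSet(np.zeros((2, 2, 4)), ("a", "a"))  # duplicate labels


# ---------------------------------------------------------------------------
# model RDM constructors


def test_correlation_distance_examples():
    v = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0], [3.0, 2.0, 1.0]])
    rdm = correlation_distance_rdm(v, ("a", "b", "c"))
    for i, j in itertools.combinations(range(3), 2):
        assert rdm.matrix[i, j] == pytest.approx(
            1.0 - np.corrcoef(v[i], v[j])[0, 1], abs=1e-12
        )
    # duplicated rows -> 0; sign-flipped centered rows -> 2
    x = np.array([1.0, -2.0, 1.0])
    m = correlation_distance_rdm(np.stack([x, x, -x]), ("a", "b", "c")).matrix
    assert m[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert m[0, 2] == pytest.approx(2.0, abs=1e-12)


def test_correlation_distance_rejects_constant_row():
    with pytest.raises(DegeneratePatternError, match="b"):
        correlation_distance_rdm(np.array([[1.0, 2.0], [5.0, 5.0]]), ("a", "b"))


def test_feature_difference_examples():
    rdm = feature_difference_rdm({"a": 1.0, "b": 4.0, "c": 9.0})
    assert rdm.matrix[1, 0] == 3.0
    assert rdm.matrix[2, 0] == 8.0
    assert rdm.matrix[2, 1] == 5.0
    shifted = feature_difference_rdm({"a": 101.0, "b": 104.0, "c": 109.0})
    np.testing.assert_array_equal(rdm.matrix, shifted.matrix)
    constant = feature_difference_rdm({"a": 2.0, "b": 2.0, "c": 2.0})
    assert np.all(constant.matrix == 0)
    with pytest.raises(MissingWordError, match="d"):
        feature_difference_rdm({"a": 1.0}, condition_labels=("a", "d"))


def test_frequency_rdm_log_scale():
    counts = {"a": 100, "b": 10, "c": 1}
    rdm = frequency_rdm(counts)
    assert rdm.matrix[1, 0] == pytest.approx(1.0)  # one decade apart
    assert rdm.matrix[2, 0] == pytest.approx(2.0)
    raw = frequency_rdm(counts, log10_scale=False)
    assert raw.matrix[1, 0] == pytest.approx(90 / 111)


# ---------------------------------------------------------------------------
# comparison


def _random_rdm(seed, n=4):
    rng = np.random.default_rng(seed)
    labels = tuple(f"w{i:02d}" for i in range(n))
    return correlation_distance_rdm(rng.standard_normal((n, 6)), labels)


def test_compare_rdms_self_correlation_clamped():
    a = _random_rdm(0)
    cmp = compare_rdms(a, a)
    assert cmp.r == pytest.approx(1.0)
    assert cmp.z == pytest.approx(math.atanh(1 - 1e-7))
    assert cmp.n_entries == 6


def test_compare_rdms_matches_direct_triangle_correlation():
    a, b = _random_rdm(1), _random_rdm(2)
    want = np.corrcoef(a.lower_triangle(), b.lower_triangle())[0, 1]
    assert compare_rdms(a, b).r == pytest.approx(want, abs=1e-12)


def test_compare_rdms_affine_invariance_and_spearman():
    a = _random_rdm(3)
    b = RDM(0.25 * a.matrix + 3.0 * (1 - np.eye(a.n_conditions)),
            a.condition_labels)
    assert compare_rdms(a, b, method="pearson").r == pytest.approx(1.0)
    # monotone transform -> Spearman 1 even where Pearson is not
    c = RDM(np.exp(a.matrix) - np.eye(a.n_conditions) * np.exp(0),
            a.condition_labels)
    assert compare_rdms(a, c, method="spearman").r == pytest.approx(1.0)


def test_compare_rdms_errors():
    a = _random_rdm(4)
    b = _random_rdm(5)
    mislabeled = RDM(b.matrix, tuple(reversed(b.condition_labels)))
    with pytest.raises(AlignmentError):
        compare_rdms(a, mislabeled)
    flat = RDM(np.ones((4, 4)) - np.eye(4), a.condition_labels)
    with pytest.raises(DegeneratePatternError):
        compare_rdms(a, flat)


def test_partial_compare_reduces_to_plain_without_controls():
    a, b = _random_rdm(6), _random_rdm(7)
    assert partial_compare_rdms(a, b, []) == compare_rdms(a, b)


@pytest.mark.parametrize("seed", range(20))
def test_partial_single_control_matches_closed_form(seed):
    x, y, z = (_random_rdm(seed * 3 + k, n=6) for k in range(3))
    rxy = compare_rdms(x, y).r
    rxz = compare_rdms(x, z).r
    ryz = compare_rdms(y, z).r
    want = (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    got = partial_compare_rdms(x, y, [z]).r
    assert got == pytest.approx(want, abs=1e-12)


def test_partial_with_linear_function_of_control_is_degenerate():
    z = _random_rdm(8)
    neural = RDM(2.0 * z.matrix, z.condition_labels)  # exact linear function
    predictor = _random_rdm(9)
    assert compare_rdms(neural, predictor).r == compare_rdms(z, predictor).r
    with pytest.raises(DegeneratePatternError):
        partial_compare_rdms(neural, predictor, [z])


def test_partial_collinear_controls_rejected():
    x, y, z = _random_rdm(10), _random_rdm(11), _random_rdm(12)
    z2 = RDM(3.0 * z.matrix, z.condition_labels)
    with pytest.raises(CollinearityError):
        partial_compare_rdms(x, y, [z, z2])


def test_partial_with_many_uncorrelated_controls_barely_moves_r():
    # with long triangles, projecting out random controls is a small rotation
    rng = np.random.default_rng(0)
    n = 46  # 1035 lower-triangle entries
    labels = tuple(f"w{i:02d}" for i in range(n))
    deltas = []
    for rep in range(6):
        x = correlation_distance_rdm(rng.standard_normal((n, 30)), labels)
        y = correlation_distance_rdm(rng.standard_normal((n, 30)), labels)
        ctrl = [
            correlation_distance_rdm(rng.standard_normal((n, 30)), labels)
            for _ in range(3)
        ]
        deltas.append(abs(
            partial_compare_rdms(x, y, ctrl).r - compare_rdms(x, y).r
        ))
    assert np.median(deltas) < 0.05


def test_fisher_z_values():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(math.atanh(0.5))
    assert fisher_z(1.0) == pytest.approx(math.atanh(1 - 1e-7))
    assert math.isfinite(fisher_z(-1.0))
    with pytest.raises(ConfigError):
        fisher_z(1.1)


# ---------------------------------------------------------------------------
# RDM container


def test_rdm_invariants_and_io(tmp_path):
    rdm = _random_rdm(13, n=5)
    assert np.array_equal(rdm.matrix, rdm.matrix.T)
    assert np.all(np.diag(rdm.matrix) == 0)
    sub = rdm.subset(("w03", "w01"))
    assert sub.condition_labels == ("w03", "w01")
    assert sub.matrix[0, 1] == rdm.matrix[3, 1]
    dropped = rdm.drop(["w00"])
    assert dropped.condition_labels == ("w01", "w02", "w03", "w04")
    path = tmp_path / "rdm.tsv"
    rdm.to_tsv(path)
    back = RDM.from_tsv(path)
    assert back.condition_labels == rdm.condition_labels
    np.testing.assert_allclose(back.matrix, rdm.matrix, atol=1e-12)


def test_rdm_rejects_asymmetry_and_nonfinite():
    m = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ConfigError):
        RDM(m, ("a", "b"))
    with pytest.raises(ConfigError):
        RDM(np.array([[0.0, np.nan], [np.nan, 0.0]]), ("a", "b"))
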