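"""Synthetic data with planted ground truth.

Every input the pipeline consumes can be generated here: run-wise beta
volumes whose multi-voxel geometry inside a planted region follows a
known reference RDM plus Gaussian noise, nuisance RDMs with a chosen
correlation to that reference, toy corpora whose co-occurrence
statistics encode a planted two-cluster word similarity structure with
per-word concreteness labels, affect-grid style ratings, and pure-null
statistic maps for calibration studies.

The defaults mirror the study design where it states them (61 words,
10 runs, 19 subjects, 9x9 affect grid); volume size, noise level and
latent dimensionality are desk-scale choices documented in the methods
note, not reported quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .rdm import RDM, correlation_distance_rdm
from .volume import StatMap, VolumeGrid

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCorpusSpec",
    "generate_geometry",
    "generate_geometry_from_clusters",
    "generate_subject_patterns",
    "generate_nuisance_rdm",
    "generate_corpus",
    "generate_ratings",
    "generate_null_maps",
    "two_cluster_corpus_spec",
    "cluster_rdm",
    "block_region",
    "signal_scale_for_snr",
    "condition_words",
]


def condition_words(n: int) -> tuple[str, ...]:
    """Synthetic stand-ins for the word stimuli: w00, w01, ..."""
    return tuple(f"w{i:02d}" for i in range(n))


def block_region(corner: Sequence[int], size: Sequence[int]) -> np.ndarray:
    """Voxel coordinates of an axis-aligned block, as an (m, 3) array."""
    ranges = [np.arange(c, c + s) for c, s in zip(corner, size)]
    g = np.meshgrid(*ranges, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic fMRI dataset.

    ``signal_region`` is an (m, 3) array of voxel coordinates (may be
    empty for a pure-null dataset).  ``signal_scale`` multiplies the
    projected latent patterns; use :func:`signal_scale_for_snr` to set
    it from a target per-voxel SNR.
    """

    n_conditions: int = 61
    n_runs: int = 10
    volume_shape: tuple[int, int, int] = (20, 20, 20)
    signal_region: np.ndarray = field(
        default_factory=lambda: block_region((7, 7, 7), (6, 6, 6))
    )
    noise_sd: float = 1.0
    pattern_dim: int = 8
    n_subjects: int = 19
    signal_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 3:
            raise ConfigError("n_conditions must be >= 3")
        if self.n_runs < 2:
            raise ConfigError("n_runs must be >= 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.pattern_dim < 2:
            raise ConfigError("pattern_dim must be >= 2")
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ConfigError("volume_shape must be 3 positive integers")
        region = np.asarray(self.signal_region, dtype=int).reshape(-1, 3)
        if region.size and (
            region.min() < 0 or np.any(region >= np.asarray(shape))
        ):
            raise ConfigError("signal_region exceeds the volume bounds")
        if region.shape[0] and region.shape[0] <= self.pattern_dim:
            raise ConfigError(
                "signal_region must contain more voxels than pattern_dim "
                "(needed for an orthonormal voxel projection)"
            )
        region.flags.writeable = False
        object.__setattr__(self, "volume_shape", shape)
        object.__setattr__(self, "signal_region", region)


@dataclass(frozen=True)
class GroundTruth:
    """Planted representational geometry of a simulation."""

    reference_rdm: RDM
    condition_vectors: np.ndarray  # conditions x pattern_dim, rows centered
    signal_region: np.ndarray | None = None
    nuisance_rdms: tuple[RDM, ...] = ()


def generate_geometry(n_conditions: int, pattern_dim: int, seed: int) -> GroundTruth:
    """Draw latent condition vectors and the reference RDM they imply.

    Rows are mean-centered so that the correlation-distance RDM of the
    vectors equals their cosine-distance matrix; combined with the
    centered orthonormal voxel projection of
    :func:`generate_subject_patterns` this makes noiseless voxel-space
    RDMs reproduce the reference exactly, not just approximately.
    """
    if n_conditions < 3:
        raise ConfigError("n_conditions must be >= 3 (a 1-entry lower triangle "
                          "has no defined correlation downstream)")
    if pattern_dim < 2:
        raise ConfigError("pattern_dim must be >= 2")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_conditions, pattern_dim))
    v = v - v.mean(axis=1, keepdims=True)
    rdm = correlation_distance_rdm(v, condition_words(n_conditions))
    return GroundTruth(reference_rdm=rdm, condition_vectors=v)


def generate_geometry_from_clusters(
    spec: SyntheticCorpusSpec,
    pattern_dim: int = 8,
    jitter: float = 0.4,
    seed: int = 0,
) -> GroundTruth:
    """Latent geometry whose similarity structure follows corpus clusters.

    Each word's condition vector is its cluster centroid (centroids are
    orthogonalized Gaussians) plus Gaussian jitter, then row-centered.
    The implied reference RDM is small within clusters and large between
    them, so brain data planted with it is predictable from embeddings
    trained on the matching corpus — the synthetic analogue of semantic
    structure shared between brain and distributional model.
    """
    if pattern_dim < 2:
        raise ConfigError("pattern_dim must be >= 2")
    words = tuple(spec.vocabulary)
    clusters = np.asarray([spec.cluster_assignment[w] for w in words])
    uniq = np.unique(clusters)
    if pattern_dim < len(uniq):
        raise ConfigError("pattern_dim must be >= the number of clusters")
    rng = np.random.default_rng(seed)
    cent = rng.standard_normal((len(uniq), pattern_dim))
    q, _ = np.linalg.qr(cent.T)
    cent = q.T[: len(uniq)] * np.sqrt(pattern_dim)
    v = cent[np.searchsorted(uniq, clusters)] + jitter * rng.standard_normal(
        (len(words), pattern_dim)
    )
    v = v - v.mean(axis=1, keepdims=True)
    rdm = correlation_distance_rdm(v, words)
    return GroundTruth(reference_rdm=rdm, condition_vectors=v)


def signal_scale_for_snr(snr: float, noise_sd: float,
                         region_size: int, pattern_dim: int) -> float:
    """Signal scale giving approx ``snr`` = per-voxel signal sd / noise sd.

    The orthonormal projection spreads latent unit variance over the
    region, so per-voxel signal sd is about sqrt(pattern_dim /
    region_size) at scale 1.
    """
    return snr * noise_sd * np.sqrt(region_size / pattern_dim)


def generate_subject_patterns(
    truth: GroundTruth, cfg: SimulationConfig, subject_seed: int
) -> tuple[np.ndarray, VolumeGrid]:
    """Run-wise condition beta volumes for one subject.

    Inside the signal region, voxel v's beta for condition c in run r is
    ``signal_scale * <condition_vectors[c], mixing[v]> + N(0, noise_sd^2)``
    with a per-subject mixing matrix fixed across runs (the signal is
    stable; only noise varies run to run).  Outside the region the betas
    are pure noise.  The mixing columns are mean-centered and
    orthonormal, so noiseless region-wide pattern correlations equal the
    latent-space correlations exactly.
    """
    if truth.condition_vectors.shape[0] != cfg.n_conditions:
        raise ConfigError("truth and config disagree on n_conditions")
    if truth.condition_vectors.shape[1] != cfg.pattern_dim:
        raise ConfigError("truth and config disagree on pattern_dim")
    rng = np.random.default_rng(subject_seed)
    shape = cfg.volume_shape
    betas = rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_runs, cfg.n_conditions) + shape
    ) if cfg.noise_sd > 0 else np.zeros((cfg.n_runs, cfg.n_conditions) + shape)
    region = cfg.signal_region
    if region.shape[0]:
        k = region.shape[0]
        mixing = rng.standard_normal((k, cfg.pattern_dim))
        mixing = mixing - mixing.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(mixing)  # centered orthonormal columns
        signal = cfg.signal_scale * truth.condition_vectors @ q.T  # (C, k)
        betas[:, :, region[:, 0], region[:, 1], region[:, 2]] += signal[None]
    grid = VolumeGrid.full(shape)
    return betas, grid


def generate_nuisance_rdm(truth: GroundTruth, target_r: float, seed: int) -> RDM:
    """A nuisance RDM with a chosen lower-triangle correlation to the truth.

    Emulates control models (ratings, DNN layers) that are mildly
    correlated with the semantic model.  Built by mixing the reference
    lower triangle with seeded noise orthogonalized against it, so the
    achieved Pearson r equals ``target_r`` up to rounding.
    """
    if not -1.0 < target_r < 1.0:
        raise ConfigError("target_r must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    ref = truth.reference_rdm
    u = ref.lower_triangle()
    u = u - u.mean()
    u = u / np.linalg.norm(u)
    w = rng.standard_normal(u.size)
    w = w - w.mean()
    w = w - (w @ u) * u
    w = w / np.linalg.norm(w)
    v = target_r * u + np.sqrt(1.0 - target_r ** 2) * w
    n = ref.n_conditions
    m = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = v
    m[j, i] = v
    return RDM(m, ref.condition_labels)


# ---------------------------------------------------------------------------
# toy corpora


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """A toy corpus with planted cluster-wise co-occurrence structure.

    Sentences are Markov samples over the vocabulary: each token is
    drawn from a Zipfian marginal (word w has base weight
    rank(w)^-zipf_exponent, so the corpus has the heavy-tailed frequency
    profile of natural language), with odds boosted by
    ``within_cluster_boost`` for words sharing the previous token's
    cluster.  Boost 0 gives an unstructured corpus; zipf_exponent 0 a
    uniform one.
    """

    vocabulary: tuple[str, ...]
    cluster_assignment: dict
    concreteness_z: dict
    n_sentences: int = 5000
    sentence_length: int = 8
    within_cluster_boost: float = 20.0
    zipf_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        vocab = tuple(self.vocabulary)
        if len(vocab) != len(set(vocab)) or not vocab:
            raise ConfigError("vocabulary must be nonempty and unique")
        for w in vocab:
            if w not in self.cluster_assignment:
                raise ConfigError(f"word {w!r} has no cluster assignment")
            if w not in self.concreteness_z:
                raise ConfigError(f"word {w!r} has no concreteness value")
        if self.n_sentences < 1:
            raise ConfigError("n_sentences must be >= 1")
        if self.sentence_length < 2:
            raise ConfigError("sentence_length must be >= 2 (no co-occurrence "
                              "is possible otherwise)")
        if self.within_cluster_boost < 0:
            raise ConfigError("within_cluster_boost must be nonnegative")
        if self.zipf_exponent < 0:
            raise ConfigError("zipf_exponent must be nonnegative")
        object.__setattr__(self, "vocabulary", vocab)


def two_cluster_corpus_spec(
    n_words: int = 40,
    n_sentences: int = 5000,
    sentence_length: int = 8,
    within_cluster_boost: float = 20.0,
    zipf_exponent: float = 1.0,
    seed: int = 0,
) -> SyntheticCorpusSpec:
    """Convenience spec: half 'abstract' (z<0) and half 'concrete' (z>0) words.

    Cluster membership coincides with the concreteness split, standing
    in for a corpus in which abstract words keep abstract company.  The
    vocabulary interleaves the clusters in frequency rank, so both
    clusters contain common and rare words under the Zipfian marginal.
    """
    if n_words < 4 or n_words % 2:
        raise ConfigError("n_words must be an even number >= 4")
    half = n_words // 2
    abstract = [f"abs{i:02d}" for i in range(half)]
    concrete = [f"con{i:02d}" for i in range(half)]
    rng = np.random.default_rng(seed)
    z_abs = -rng.uniform(0.5, 2.0, size=half)
    z_con = rng.uniform(0.5, 2.0, size=half)
    vocab = tuple(w for pair in zip(abstract, concrete) for w in pair)
    clusters = {w: 0 for w in abstract} | {w: 1 for w in concrete}
    z = dict(zip(abstract, z_abs)) | dict(zip(concrete, z_con))
    return SyntheticCorpusSpec(
        vocabulary=vocab,
        cluster_assignment=clusters,
        concreteness_z=z,
        n_sentences=n_sentences,
        sentence_length=sentence_length,
        within_cluster_boost=within_cluster_boost,
        zipf_exponent=zipf_exponent,
        seed=seed,
    )


def cluster_rdm(spec: SyntheticCorpusSpec,
                words: Sequence[str] | None = None) -> RDM:
    """The planted similarity structure: 0 within a cluster, 1 between."""
    words = tuple(spec.vocabulary if words is None else words)
    g = np.asarray([spec.cluster_assignment[w] for w in words])
    m = (g[:, None] != g[None, :]).astype(float)
    return RDM(m, words)


def generate_corpus(spec: SyntheticCorpusSpec) -> list[list[str]]:
    """Sample the corpus described by ``spec`` (ordered, prefix-fragmentable)."""
    rng = np.random.default_rng(spec.seed)
    vocab = np.asarray(spec.vocabulary)
    n_words = vocab.size
    clusters = np.asarray([spec.cluster_assignment[w] for w in vocab])
    unique_clusters = np.unique(clusters)
    base = np.arange(1, n_words + 1, dtype=float) ** -spec.zipf_exponent
    # per previous-cluster categorical distribution over the vocabulary
    dists = {}
    for g in unique_clusters:
        w = base * (1.0 + spec.within_cluster_boost * (clusters == g))
        dists[int(g)] = w / w.sum()
    tokens = np.empty((spec.n_sentences, spec.sentence_length), dtype=int)
    tokens[:, 0] = rng.choice(n_words, size=spec.n_sentences, p=base / base.sum())
    for t in range(1, spec.sentence_length):
        prev_cluster = clusters[tokens[:, t - 1]]
        col = np.empty(spec.n_sentences, dtype=int)
        for g in unique_clusters:
            idx = np.nonzero(prev_cluster == g)[0]
            if idx.size:
                col[idx] = rng.choice(n_words, size=idx.size, p=dists[int(g)])
        tokens[:, t] = col
    return [[str(vocab[i]) for i in row] for row in tokens]


def generate_ratings(words: Sequence[str], seed: int) -> pd.DataFrame:
    """Affect-grid style valence/arousal ratings, uniform on [1, 9].

    One value per word per scale, bounded like a 9x9 grid response.
    """
    words = list(words)
    if not words:
        raise ConfigError("word list must be nonempty")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "word": words,
            "valence": rng.uniform(1.0, 9.0, size=len(words)),
            "arousal": rng.uniform(1.0, 9.0, size=len(words)),
        }
    )


def generate_null_maps(
    n_subjects: int, shape: Sequence[int], seed: int
) -> list[StatMap]:
    """Subject maps of i.i.d. standard normal values (an exchangeable null).

    Used to calibrate the group-inference layer directly; a full
    searchlight run on noise-only volumes exercises the same null at
    smaller scale in the searchlight tests.
    """
    rng = np.random.default_rng(seed)
    grid = VolumeGrid.full(tuple(int(s) for s in shape))
    return [
        StatMap(rng.standard_normal(grid.shape), grid, "fisher_z")
        for _ in range(n_subjects)
    ]
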