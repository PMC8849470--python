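"""Representational dissimilarity matrices (RDMs) and their comparison.

An RDM is a symmetric condition-by-condition matrix of pairwise
dissimilarities with a zero diagonal.  Neural RDMs are built from
multi-voxel activation patterns with a cross-validated correlation
distance (within-condition minus between-condition correlations across
independent halves of the runs), model RDMs from feature vectors
(1 - Pearson r) or scalar word properties (absolute differences).
RDMs live in different spaces (brain, embedding model, rating norms) and
are compared by correlating their lower triangles, optionally partialing
out control RDMs, with a Fisher transform for group statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    CollinearityError,
    ConfigError,
    DegeneratePatternError,
    MissingWordError,
)

__all__ = [
    "RDM",
    "PatternSet",
    "RdmComparison",
    "crossval_correlation_rdm",
    "correlation_distance_rdm",
    "feature_difference_rdm",
    "frequency_rdm",
    "compare_rdms",
    "partial_compare_rdms",
    "fisher_z",
    "unordered_half_splits",
]

#: correlations are clamped to +/- (1 - FISHER_CLAMP) before atanh
FISHER_CLAMP = 1e-7

_SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class RDM:
    """Symmetric dissimilarity matrix indexed by condition labels.

    Entries of cross-validated neural RDMs may be negative (the
    distance estimate is unbiased around zero for indistinguishable
    conditions); no non-negativity is imposed.
    """

    matrix: np.ndarray
    condition_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        labels = tuple(str(w) for w in self.condition_labels)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConfigError(f"RDM matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(labels):
            raise ConfigError(
                f"{len(labels)} labels for a {m.shape[0]}x{m.shape[0]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")
        if not np.all(np.isfinite(m)):
            raise ConfigError("RDM entries must be finite")
        if np.max(np.abs(m - m.T), initial=0.0) > _SYMMETRY_TOL:
            raise ConfigError("RDM matrix is not symmetric")
        # enforce exact conventions: symmetrize and zero the diagonal
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "condition_labels", labels)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    def lower_triangle(self) -> np.ndarray:
        """Lower-off-diagonal entries as a vector (row-major order)."""
        i, j = np.tril_indices(self.n_conditions, k=-1)
        return self.matrix[i, j]

    def subset(self, labels: Sequence[str]) -> "RDM":
        """Sub-RDM restricted to ``labels`` (in the given order)."""
        idx = []
        for w in labels:
            try:
                idx.append(self.condition_labels.index(w))
            except ValueError:
                raise MissingWordError(f"condition {w!r} not in RDM") from None
        ix = np.asarray(idx)
        return RDM(self.matrix[np.ix_(ix, ix)], tuple(labels))

    def drop(self, labels: Iterable[str]) -> "RDM":
        """Sub-RDM with ``labels`` removed (original order kept)."""
        gone = set(labels)
        keep = [w for w in self.condition_labels if w not in gone]
        return self.subset(keep)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.matrix, index=self.condition_labels, columns=self.condition_labels
        )
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))


@dataclass(frozen=True)
class PatternSet:
    """Run-wise condition activation patterns: runs x conditions x channels.

    Channels are voxels for brain data but the type is agnostic.  Every
    run must contain every condition (the experiment presents all words
    in each run).
    """

    patterns: np.ndarray
    condition_labels: tuple[str, ...]
    run_ids: tuple = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=float)
        labels = tuple(str(w) for w in self.condition_labels)
        if p.ndim != 3:
            raise ConfigError(
                f"patterns must be runs x conditions x channels, got shape {p.shape}"
            )
        n_runs, n_cond, n_chan = p.shape
        if n_runs < 2:
            raise ConfigError("need at least 2 runs for cross-validation")
        if n_chan < 2:
            raise ConfigError("need at least 2 channels")
        if n_cond != len(labels):
            raise ConfigError("condition_labels length does not match patterns")
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")
        if not np.all(np.isfinite(p)):
            raise ConfigError("patterns must be finite")
        run_ids = tuple(self.run_ids) if self.run_ids else tuple(range(n_runs))
        if len(run_ids) != n_runs:
            raise ConfigError("run_ids length does not match patterns")
        p.flags.writeable = False
        object.__setattr__(self, "patterns", p)
        object.__setattr__(self, "condition_labels", labels)
        object.__setattr__(self, "run_ids", run_ids)

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_channels(self) -> int:
        return self.patterns.shape[2]


@dataclass(frozen=True)
class RdmComparison:
    """Result of correlating two RDMs over their lower triangles."""

    r: float
    z: float
    n_entries: int
    method: str
    controls_used: int = 0


def unordered_half_splits(n_runs: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered 50/50 splits of ``n_runs`` run indices.

    For an even run count each unordered pair of complementary halves is
    returned once (10 runs -> 126 splits).  For an odd count the halves
    have sizes floor(n/2) and ceil(n/2); each such unordered split is
    returned once.
    """
    if n_runs < 2:
        raise ConfigError("need at least 2 runs to split")
    k = n_runs // 2
    runs = range(n_runs)
    splits = []
    for combo in itertools.combinations(runs, k):
        if n_runs % 2 == 0 and 0 not in combo:
            continue  # complementary halves are the same unordered split
        a = tuple(combo)
        b = tuple(r for r in runs if r not in set(combo))
        splits.append((a, b))
    return splits


def _row_normalize(x: np.ndarray, labels: Sequence[str], split_desc: str) -> np.ndarray:
    """Center rows and scale them to unit norm; error on constant rows."""
    for i in range(x.shape[0]):
        row = x[i]
        if np.all(row == row[0]):
            raise DegeneratePatternError(
                f"condition {labels[i]!r} has a constant half-averaged pattern "
                f"in split {split_desc}; correlation undefined"
            )
    c = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    bad = np.nonzero(norms.ravel() == 0.0)[0]
    if bad.size:
        raise DegeneratePatternError(
            f"condition {labels[bad[0]]!r} has zero pattern variance "
            f"in split {split_desc}"
        )
    return c / norms


def crossval_correlation_rdm(patterns: PatternSet) -> RDM:
    """Cross-validated correlation-distance RDM of a pattern set.

    The runs are split into two halves in every possible unordered
    50/50 way; patterns are averaged within each half.  For a pair of
    conditions (i, j) the within-condition correlation is the mean of
    corr(i_A, i_B) and corr(j_A, j_B) and the between-condition
    correlation is the mean of corr(i_A, j_B) and corr(j_A, i_B), all
    Pearson over channels.  The dissimilarity is within minus between,
    averaged over splits.  Entries may be negative; the expectation is
    zero for statistically indistinguishable conditions.
    """
    if not isinstance(patterns, PatternSet):
        patterns = PatternSet(np.asarray(patterns), tuple(map(str, range(np.asarray(patterns).shape[1]))))
    p = patterns.patterns
    labels = patterns.condition_labels
    splits = unordered_half_splits(patterns.n_runs)
    acc = np.zeros((patterns.n_conditions, patterns.n_conditions))
    for a_runs, b_runs in splits:
        desc = f"{a_runs}|{b_runs}"
        a = _row_normalize(p[list(a_runs)].mean(axis=0), labels, desc)
        b = _row_normalize(p[list(b_runs)].mean(axis=0), labels, desc)
        corr = a @ b.T  # corr[i, j] = corr(i_A, j_B)
        d = np.diag(corr)
        acc += (d[:, None] + d[None, :]) / 2.0 - (corr + corr.T) / 2.0
    acc /= len(splits)
    np.fill_diagonal(acc, 0.0)
    return RDM(acc, labels)


def correlation_distance_rdm(
    vectors: np.ndarray, condition_labels: Sequence[str] | None = None
) -> RDM:
    """RDM of 1 - Pearson correlation between rows of a feature matrix."""
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ConfigError("vectors must be conditions x features with >=2 features")
    labels = (
        tuple(str(w) for w in condition_labels)
        if condition_labels is not None
        else tuple(map(str, range(v.shape[0])))
    )
    for i in range(v.shape[0]):
        if np.all(v[i] == v[i, 0]):
            raise DegeneratePatternError(
                f"condition {labels[i]!r} has a constant feature vector"
            )
    c = v - v.mean(axis=1, keepdims=True)
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    m = 1.0 - c @ c.T
    np.fill_diagonal(m, 0.0)
    return RDM(m, labels)


def feature_difference_rdm(values: Mapping[str, float] | pd.Series,
                           condition_labels: Sequence[str] | None = None) -> RDM:
    """RDM of pairwise absolute differences of a scalar word property.

    Used for valence and arousal ratings and, on a log scale, for word
    frequency.  Translation invariant by construction.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    labels = tuple(values.keys()) if condition_labels is None else tuple(condition_labels)
    vals = []
    for w in labels:
        if w not in values:
            raise MissingWordError(f"no value for condition {w!r}")
        x = float(values[w])
        if not math.isfinite(x):
            raise ConfigError(f"value for condition {w!r} is not finite")
        vals.append(x)
    x = np.asarray(vals)
    m = np.abs(x[:, None] - x[None, :])
    return RDM(m, labels)


def frequency_rdm(counts: Mapping[str, float],
                  condition_labels: Sequence[str] | None = None,
                  log10_scale: bool = True) -> RDM:
    """Word-frequency control RDM: |difference| of (log10) relative frequency.

    Frequency effects are conventionally log-scaled; set
    ``log10_scale=False`` for raw relative-frequency differences.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ConfigError("counts must sum to a positive total")
    rel = {w: c / total for w, c in counts.items()}
    for w, f in rel.items():
        if f <= 0:
            raise ConfigError(f"count for {w!r} must be positive")
    if log10_scale:
        rel = {w: math.log10(f) for w, f in rel.items()}
    return feature_difference_rdm(rel, condition_labels)


def fisher_z(r: float) -> float:
    """Fisher transform atanh(r), with r clamped away from +/-1.

    The clamp (1e-7) keeps z finite for perfect correlations, which
    arise for self-comparisons and duplicated model RDMs.
    """
    if not -1.0 <= r <= 1.0:
        raise ConfigError(f"correlation {r} outside [-1, 1]")
    return math.atanh(np.clip(r, -1.0 + FISHER_CLAMP, 1.0 - FISHER_CLAMP))


def _check_aligned(rdms: Sequence[RDM]) -> None:
    labels = rdms[0].condition_labels
    for other in rdms[1:]:
        if other.condition_labels != labels:
            raise AlignmentError(
                "RDM condition labels differ or are ordered differently"
            )
    if len(labels) < 3:
        raise ConfigError("need at least 3 conditions (>=3 lower-triangle entries)")


def _triangle(rdm: RDM, method: str) -> np.ndarray:
    v = rdm.lower_triangle()
    if np.all(v == v[0]):
        raise DegeneratePatternError("RDM lower triangle is constant")
    if method == "spearman":
        v = stats.rankdata(v)
    elif method != "pearson":
        raise ConfigError(f"unknown method {method!r}")
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise DegeneratePatternError("zero-variance vector in RDM correlation")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def compare_rdms(a: RDM, b: RDM, method: str = "pearson") -> RdmComparison:
    """Correlate the lower triangles of two label-aligned RDMs.

    ``method`` is Pearson (default; the natural companion of the Fisher
    transform) or Spearman (Pearson on ranks).  Returns the correlation
    and its Fisher z.
    """
    _check_aligned([a, b])
    x = _triangle(a, method)
    y = _triangle(b, method)
    r = _pearson(x, y)
    return RdmComparison(r=r, z=fisher_z(r), n_entries=x.size, method=method)


def partial_compare_rdms(
    neural: RDM, predictor: RDM, controls: Sequence[RDM] = (), method: str = "pearson"
) -> RdmComparison:
    """Partial correlation between two RDMs, controlling for others.

    Both lower triangles are regressed (with intercept) on the control
    triangles and the residuals are correlated.  If the controls explain
    the same variance in the neural RDM as the predictor does, the
    partial correlation vanishes.  With no controls this reduces exactly
    to :func:`compare_rdms`.  For ``method='spearman'`` all triangles
    are rank-transformed first (partial Spearman).
    """
    if len(controls) == 0:
        return compare_rdms(neural, predictor, method=method)
    _check_aligned([neural, predictor, *controls])
    x = _triangle(neural, method)
    y = _triangle(predictor, method)
    design = np.column_stack(
        [np.ones(x.size)] + [_triangle(c, method) for c in controls]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("control RDMs are collinear on the lower triangle")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    scale = max(float(np.abs(x).max()), float(np.abs(y).max()), 1.0)
    if np.linalg.norm(rx) <= 1e-12 * scale or np.linalg.norm(ry) <= 1e-12 * scale:
        raise DegeneratePatternError(
            "residual variance is zero: an RDM is an exact linear function "
            "of the controls"
        )
    r = _pearson(rx, ry)
    return RdmComparison(
        r=r, z=fisher_z(r), n_entries=x.size, method=method, controls_used=len(controls)
    )
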