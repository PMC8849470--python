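"""Region-of-interest analyses and model-family evaluation.

An ROI is defined from a significant cluster of the searchlight group
map (recording which model defined it), an ROI-level cross-validated
RDM is computed over all its voxels, and families of model RDMs —
e.g. embeddings trained on nested corpus fragments or on abstract-only /
concrete-only corpora — are evaluated against the per-subject ROI RDMs:
one-sided t vs zero with FDR across the family, and paired comparisons
against a reference (full) model.  The model that defined the ROI is
never itself tested against zero (selection-circularity guard).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError, DegeneratePatternError
from .groupstats import ClusterTable, fdr_correct
from .rdm import RDM, PatternSet, compare_rdms, crossval_correlation_rdm
from .volume import VolumeGrid

__all__ = [
    "RoiMask",
    "ModelFamilyResult",
    "roi_from_clusters",
    "roi_rdm",
    "evaluate_model_family",
    "word_deletion_robustness",
]


@dataclass(frozen=True)
class RoiMask:
    """A set of voxel coordinates on a grid, with provenance."""

    voxels: np.ndarray  # (m, 3)
    grid: VolumeGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        if v.shape[0] == 0:
            raise ConfigError("ROI must contain at least one voxel")
        if v.min() < 0 or np.any(v >= np.asarray(self.grid.shape)):
            raise ConfigError("ROI voxels exceed the grid bounds")
        v.flags.writeable = False
        object.__setattr__(self, "voxels", v)

    @property
    def size(self) -> int:
        return self.voxels.shape[0]


def roi_from_clusters(table: ClusterTable, selector: int,
                      provenance: str | None = None) -> RoiMask:
    """ROI mask of one cluster from a cluster table.

    ``selector`` is the cluster_id; provenance defaults to the table's
    own provenance (which records the defining model/statistic).
    """
    if table.n_clusters == 0:
        raise ConfigError("cluster table is empty")
    ids = set(table.table["cluster_id"].tolist())
    if selector not in ids:
        raise ConfigError(f"cluster {selector} not in table (have {sorted(ids)})")
    voxels = np.argwhere(table.labels == selector)
    prov = provenance if provenance is not None else (
        f"cluster {selector} defined by {table.provenance or 'unspecified model'}"
    )
    return RoiMask(voxels=voxels, grid=table.grid, provenance=prov)


def roi_rdm(betas: np.ndarray, condition_labels: Sequence[str],
            roi: RoiMask) -> RDM:
    """Cross-validated correlation RDM over all ROI voxels.

    Identical computation to a searchlight neighborhood, with the ROI as
    the (single) neighborhood.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 5 or betas.shape[2:] != roi.grid.shape:
        raise AlignmentError("betas are not aligned to the ROI grid")
    if roi.size < 2:
        raise DegeneratePatternError(
            "ROI has a single voxel; pattern correlation over one channel "
            "is undefined"
        )
    v = roi.voxels
    patterns = betas[:, :, v[:, 0], v[:, 1], v[:, 2]]
    return crossval_correlation_rdm(
        PatternSet(patterns, tuple(str(w) for w in condition_labels))
    )


@dataclass(frozen=True)
class ModelFamilyResult:
    """Per-subject Fisher z and family-level statistics.

    ``subject_z``: subjects x models DataFrame of Fisher z.
    ``table``: one row per model with mean_r, mean_z, t, p (one-sided vs
    zero), p_fdr across the tested family, and the paired two-sided
    comparison against the reference model.  The reference row carries
    NaN for the vs-zero statistics when it defined the ROI.
    """

    subject_z: pd.DataFrame
    table: pd.DataFrame
    reference: str | None
    q: float


def evaluate_model_family(
    roi_rdms: Sequence[RDM],
    family: Mapping[str, RDM],
    reference: str | None = None,
    q: float = 0.05,
    reference_defined_roi: bool = True,
    method: str = "pearson",
) -> ModelFamilyResult:
    """Evaluate a family of model RDMs against per-subject ROI RDMs.

    For every subject and model the RDMs are correlated (lower
    triangles, Fisher z).  Each model is tested against zero with a
    one-sided t-test, FDR-corrected across the tested family; models
    are additionally compared to the reference with paired two-sided
    t-tests on Fisher z.  When ``reference_defined_roi`` is true the
    reference model receives no vs-zero test (it selected the ROI).
    """
    if len(roi_rdms) < 2:
        raise ConfigError("need at least 2 subjects")
    if not family:
        raise ConfigError("model family is empty")
    if reference is not None and reference not in family:
        raise ConfigError(f"reference {reference!r} not in family")
    names = list(family)
    rvals = np.empty((len(roi_rdms), len(names)))
    zvals = np.empty_like(rvals)
    for s, neural in enumerate(roi_rdms):
        for m, name in enumerate(names):
            cmp = compare_rdms(neural, family[name], method=method)
            rvals[s, m] = cmp.r
            zvals[s, m] = cmp.z
    subject_z = pd.DataFrame(
        zvals, columns=names, index=[f"sub{s:02d}" for s in range(len(roi_rdms))]
    )

    guard = reference if (reference is not None and reference_defined_roi) else None
    tested = [n for n in names if n != guard]
    t_by_name, p_by_name = {}, {}
    for m, name in enumerate(names):
        if name in tested:
            res = stats.ttest_1samp(zvals[:, m], 0.0, alternative="greater")
            t_by_name[name] = float(res.statistic)
            p_by_name[name] = float(res.pvalue)
    if tested:
        _, adj = fdr_correct([p_by_name[n] for n in tested], q=q)
        fdr_by_name = dict(zip(tested, adj))
    else:
        fdr_by_name = {}

    rows = []
    ref_idx = names.index(reference) if reference is not None else None
    for m, name in enumerate(names):
        row = dict(
            model=name,
            mean_r=float(rvals[:, m].mean()),
            mean_z=float(zvals[:, m].mean()),
            t=t_by_name.get(name, np.nan),
            p=p_by_name.get(name, np.nan),
            p_fdr=float(fdr_by_name[name]) if name in fdr_by_name else np.nan,
        )
        if ref_idx is not None and m != ref_idx:
            diff = zvals[:, ref_idx] - zvals[:, m]
            if np.allclose(diff, 0.0):
                row["diff_t_vs_reference"], row["diff_p"] = 0.0, 1.0
            else:
                res = stats.ttest_rel(zvals[:, ref_idx], zvals[:, m])
                row["diff_t_vs_reference"] = float(res.statistic)
                row["diff_p"] = float(res.pvalue)
        else:
            row["diff_t_vs_reference"] = np.nan
            row["diff_p"] = np.nan
        rows.append(row)
    return ModelFamilyResult(
        subject_z=subject_z,
        table=pd.DataFrame(rows),
        reference=reference,
        q=q,
    )


def word_deletion_robustness(
    neural_rdms: Sequence[RDM],
    model: RDM,
    mode: str = "leave_one_out",
    subset_max: int = 30,
    n_repeats: int = 100,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """Stability of the brain-model correlation under word deletion.

    ``leave_one_out`` deletes each word in turn; ``random_subsets``
    deletes ``n_repeats`` random subsets of sizes drawn uniformly from
    1..``subset_max``.  Rows/columns are dropped from both the neural
    and the model RDMs before recomputing the comparison; the table
    reports the across-subject mean r per deletion.
    """
    words = model.condition_labels
    k = len(words)
    if k < 4:
        raise ConfigError("need at least 4 conditions to delete any word")
    if mode == "leave_one_out":
        deletions = [(w,) for w in words]
    elif mode == "random_subsets":
        if subset_max < 1 or subset_max > k - 3:
            raise ConfigError(
                f"subset_max must leave >=3 conditions (1..{k - 3})"
            )
        rng = np.random.default_rng(seed)
        deletions = []
        for _ in range(n_repeats):
            size = int(rng.integers(1, subset_max + 1))
            deletions.append(tuple(
                words[i] for i in sorted(rng.choice(k, size=size, replace=False))
            ))
    else:
        raise ConfigError("mode must be 'leave_one_out' or 'random_subsets'")

    rows = []
    for gone in deletions:
        if k - len(gone) < 3:
            raise ConfigError("deletion leaves fewer than 3 conditions")
        sub_model = model.drop(gone)
        rs = [
            compare_rdms(neural.drop(gone), sub_model, method=method).r
            for neural in neural_rdms
        ]
        rows.append(dict(
            deleted_words=",".join(gone),
            n_deleted=len(gone),
            mean_r=float(np.mean(rs)),
        ))
    return pd.DataFrame(rows)
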