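"""End-to-end orchestration: simulate -> embeddings -> searchlight -> group -> ROI.

A single structured config (YAML/JSON-compatible dict) drives all
stages with full seed control: every stochastic stage receives a seed
derived deterministically from the global seed, so a rerun with the
same config reproduces every artifact.  A manifest records each
produced file with its stage and content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DependencyError
from .embeddings import (
    model_rdm_from_embeddings,
    train_embeddings,
    write_corpus,
)
from .sgns import EmbeddingHyperparams
from .groupstats import cluster_threshold, group_ttest_map, TfceParams, tfce_permutation_z
from .io import write_dataset
from .rdm import RDM
from .roi import evaluate_model_family, roi_from_clusters, roi_rdm
from .searchlight import searchlight_rsa
from .simulate import (
    SimulationConfig,
    block_region,
    generate_corpus,
    generate_geometry,
    generate_geometry_from_clusters,
    generate_ratings,
    generate_subject_patterns,
    signal_scale_for_snr,
    two_cluster_corpus_spec,
)
from .volume import save_map

__all__ = ["load_config", "validate_config", "run_pipeline", "DEMO_CONFIG"]

logger = logging.getLogger(__name__)

#: a small end-to-end demonstration configuration (completes in minutes)
DEMO_CONFIG: dict = {
    "seed": 7,
    "out_dir": "semrsa_demo",
    "corpus": {
        "n_words": 12,
        "n_sentences": 4000,
        "sentence_length": 8,
        "within_cluster_boost": 20.0,
    },
    "simulate": {
        "n_runs": 4,
        "volume_shape": [14, 14, 14],
        "region_corner": [4, 4, 4],
        "region_size": [5, 5, 5],
        "noise_sd": 1.0,
        "pattern_dim": 6,
        "n_subjects": 6,
        "snr": 1.0,
    },
    "embeddings": {
        "fragment_sizes": [500, 2000, 4000],
        "dimensions": 16,
        "window_size": 5,
        "min_count": 1,
        "iterations": 3,
    },
    "searchlight": {"radius": 2.0, "min_voxels": 10, "method": "pearson"},
    "group": {
        "voxel_p": 0.001,
        "cluster_alpha": 0.05,
        "connectivity": 26,
        "n_permutations": 500,
    },
    "roi": {"q": 0.05},
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def _derive_seeds(global_seed: int, names: Sequence[str]) -> dict:
    """Named stage seeds derived deterministically from the global seed."""
    rng = np.random.default_rng(int(global_seed))
    draws = rng.integers(0, 2 ** 31, size=len(names))
    return {name: int(s) for name, s in zip(names, draws)}


def validate_config(config: dict) -> list[str]:
    """All invariant violations across stage configs; empty iff runnable."""
    problems: list[str] = []
    if "seed" not in config:
        problems.append("missing global 'seed'")
    if "out_dir" not in config:
        problems.append("missing 'out_dir'")
    sim = config.get("simulate", {})
    if sim:
        if sim.get("n_runs", 10) < 2:
            problems.append(
                "simulate.n_runs must be >= 2 (the cross-validated RDM needs "
                "two half-splits of the runs)"
            )
        if sim.get("noise_sd", 1.0) < 0:
            problems.append("simulate.noise_sd must be nonnegative")
        if "corpus" not in config and sim.get("n_conditions", 61) < 3:
            problems.append("simulate.n_conditions must be >= 3")
    corpus = config.get("corpus", {})
    if corpus:
        if corpus.get("sentence_length", 8) < 2:
            problems.append("corpus.sentence_length must be >= 2")
        if corpus.get("n_sentences", 1) < 1:
            problems.append("corpus.n_sentences must be >= 1")
        if corpus.get("within_cluster_boost", 0.0) < 0:
            problems.append("corpus.within_cluster_boost must be nonnegative")
    sl = config.get("searchlight", {})
    if sl.get("radius", 3.0) < 0:
        problems.append("searchlight.radius must be nonnegative")
    if sl.get("min_voxels", 10) < 1:
        problems.append("searchlight.min_voxels must be >= 1")
    grp = config.get("group", {})
    for key, lo, hi in (("voxel_p", 0.0, 1.0), ("cluster_alpha", 0.0, 1.0)):
        val = grp.get(key)
        if val is not None and not lo < val < hi:
            problems.append(f"group.{key} must lie in ({lo}, {hi})")
    if grp.get("connectivity", 26) not in (6, 18, 26):
        problems.append("group.connectivity must be 6, 18 or 26")
    emb = config.get("embeddings", {})
    if emb:
        if "corpus" not in config:
            problems.append("embeddings stage requires a corpus stage")
        sizes = emb.get("fragment_sizes", [])
        if not sizes or any(n < 1 for n in sizes):
            problems.append("embeddings.fragment_sizes must be positive")
    if "group" in config and "searchlight" not in config:
        problems.append("group stage requires searchlight outputs")
    if "roi" in config and "group" not in config:
        problems.append("roi stage requires group outputs")
    if "searchlight" in config and "simulate" not in config:
        problems.append("searchlight stage requires simulated data")
    return problems


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes as ``manifest.json``) a manifest mapping each
    produced file to its producing stage and sha256; identical configs
    give identical hashes.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid pipeline config: " + "; ".join(problems))
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config["seed"], [
        "geometry", "subjects", "corpus", "embeddings", "group", "ratings",
    ])
    manifest: dict = {"files": {}, "provenance": {
        "tool": "semrsa", "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
    }}

    def record(stage: str, path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = {
            "stage": stage, "sha256": _hash_file(path),
        }

    # ---- corpus + geometry ------------------------------------------------
    spec = None
    corpus = None
    if "corpus" in config:
        c = config["corpus"]
        spec = two_cluster_corpus_spec(
            n_words=c.get("n_words", 40),
            n_sentences=c.get("n_sentences", 5000),
            sentence_length=c.get("sentence_length", 8),
            within_cluster_boost=c.get("within_cluster_boost", 20.0),
            seed=seeds["corpus"],
        )
        corpus = generate_corpus(spec)
        write_corpus(corpus, out / "corpus.txt")
        record("corpus", out / "corpus.txt")
        pd.DataFrame({
            "word": spec.vocabulary,
            "z": [spec.concreteness_z[w] for w in spec.vocabulary],
        }).to_csv(out / "concreteness.tsv", sep="\t", index=False)
        record("corpus", out / "concreteness.tsv")

    sim = config.get("simulate")
    betas_by_subject = []
    grid = None
    words: tuple[str, ...] = ()
    truth = None
    if sim is not None:
        if spec is not None:
            truth = generate_geometry_from_clusters(
                spec, pattern_dim=sim.get("pattern_dim", 8),
                seed=seeds["geometry"],
            )
            words = truth.reference_rdm.condition_labels
        else:
            truth = generate_geometry(
                sim.get("n_conditions", 61), sim.get("pattern_dim", 8),
                seeds["geometry"],
            )
            words = truth.reference_rdm.condition_labels
        region = block_region(sim.get("region_corner", (7, 7, 7)),
                              sim.get("region_size", (6, 6, 6)))
        noise_sd = sim.get("noise_sd", 1.0)
        scale = signal_scale_for_snr(
            sim.get("snr", 1.0), noise_sd if noise_sd > 0 else 1.0,
            region.shape[0], sim.get("pattern_dim", 8),
        )
        cfg = SimulationConfig(
            n_conditions=len(words),
            n_runs=sim.get("n_runs", 10),
            volume_shape=tuple(sim.get("volume_shape", (20, 20, 20))),
            signal_region=region,
            noise_sd=noise_sd,
            pattern_dim=sim.get("pattern_dim", 8),
            n_subjects=sim.get("n_subjects", 19),
            signal_scale=scale,
            seed=seeds["subjects"],
        )
        truth.reference_rdm.to_tsv(out / "reference_rdm.tsv")
        record("simulate", out / "reference_rdm.tsv")
        sub_rng = np.random.default_rng(seeds["subjects"])
        sub_seeds = sub_rng.integers(0, 2 ** 31, size=cfg.n_subjects)
        for s in range(cfg.n_subjects):
            betas, grid = generate_subject_patterns(truth, cfg, int(sub_seeds[s]))
            betas_by_subject.append(betas)
            for p in write_dataset(out / f"sub{s:02d}", betas, grid, words):
                record("simulate", p)
        ratings = generate_ratings(words, seeds["ratings"])
        ratings.to_csv(out / "ratings.tsv", sep="\t", index=False)
        record("simulate", out / "ratings.tsv")

    # ---- embedding model family ------------------------------------------
    family: dict[str, RDM] = {}
    if "embeddings" in config:
        if corpus is None:
            raise DependencyError("embeddings stage is missing the corpus stage")
        e = config["embeddings"]
        hp = EmbeddingHyperparams(
            dimensions=e.get("dimensions", 300),
            window_size=e.get("window_size", 5),
            min_count=e.get("min_count", 1),
            iterations=e.get("iterations", 50),
        )
        target_words = words if words else tuple(spec.vocabulary)
        for n in sorted(e["fragment_sizes"]):
            model = train_embeddings(corpus[:n], hp, seed=seeds["embeddings"])
            name = f"frag{n}"
            family[name] = model_rdm_from_embeddings(model, target_words)
            family[name].to_tsv(out / f"model_rdm_{name}.tsv")
            record("embeddings", out / f"model_rdm_{name}.tsv")

    # ---- searchlight ------------------------------------------------------
    zmaps = []
    if "searchlight" in config:
        if not betas_by_subject:
            raise DependencyError("searchlight stage is missing simulated data")
        sl = config["searchlight"]
        if family:
            model_name = max(family, key=lambda k: int(k.removeprefix("frag")))
            model = family[model_name]
        else:
            model_name, model = "reference", truth.reference_rdm
        for s, betas in enumerate(betas_by_subject):
            res = searchlight_rsa(
                betas, words, grid, model,
                radius=sl.get("radius", 3.0),
                min_voxels=sl.get("min_voxels", 10),
                method=sl.get("method", "pearson"),
            )
            zmaps.append(res.zmap)
            p = out / f"sub{s:02d}_zmap_{model_name}.nii.gz"
            save_map(res.zmap, p)
            record("searchlight", p)
            logger.info(
                "searchlight sub%02d: %d centers, %d skipped, %d degenerate",
                s, res.n_centers, res.n_skipped_min_voxels, res.n_degenerate,
            )
        manifest["searchlight_model"] = model_name

    # ---- group statistics -------------------------------------------------
    clusters = None
    if "group" in config:
        if not zmaps:
            raise DependencyError("group stage is missing searchlight maps")
        g = config["group"]
        tmap, pmap = group_ttest_map(zmaps)
        save_map(tmap, out / "group_t.nii.gz")
        record("group", out / "group_t.nii.gz")
        clusters = cluster_threshold(
            tmap, zmaps,
            voxel_p=g.get("voxel_p", 0.001),
            cluster_alpha=g.get("cluster_alpha", 0.05),
            connectivity=g.get("connectivity", 26),
            n_permutations=g.get("n_permutations", 1000),
            seed=seeds["group"],
            provenance=manifest.get("searchlight_model", "model"),
        )
        clusters.table.to_csv(out / "clusters.tsv", sep="\t", index=False)
        record("group", out / "clusters.tsv")
        if g.get("tfce"):
            params = TfceParams(
                n_permutations=g.get("n_permutations", 1000),
                seed=seeds["group"],
                connectivity=g.get("connectivity", 26),
            )
            save_map(tfce_permutation_z(zmaps, params), out / "group_tfce_z.nii.gz")
            record("group", out / "group_tfce_z.nii.gz")

    # ---- ROI model-family analysis ---------------------------------------
    if "roi" in config:
        if clusters is None:
            raise DependencyError("roi stage is missing the group cluster table")
        sig = clusters.table[clusters.table["significant"]]
        if sig.empty:
            logger.warning("no significant cluster; skipping ROI analysis")
            manifest["roi"] = "skipped: no significant cluster"
        else:
            best = sig.sort_values("n_voxels", ascending=False).iloc[0]
            mask = roi_from_clusters(clusters, int(best["cluster_id"]))
            rdms = [roi_rdm(b, words, mask) for b in betas_by_subject]
            reference = manifest.get("searchlight_model")
            result = evaluate_model_family(
                rdms, family if family else {"reference": truth.reference_rdm},
                reference=reference if family else None,
                q=config["roi"].get("q", 0.05),
            )
            result.table.to_csv(out / "roi_model_family.tsv", sep="\t", index=False)
            record("roi", out / "roi_model_family.tsv")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
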