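"""Staged end-to-end runs: simulate -> deg -> cluster -> [enrich] ->
network -> predict -> permtest.

Every stage persists its outputs and the next stage reads them back from
disk, so any stage can be re-run in isolation (``from_stage``).  A run
directory gets the verbatim config, a version stamp, a JSON manifest
with a content hash for every artifact, and a FAILED marker if a stage
raises.  One global seed deterministically derives per-stage seeds, so a
stage re-run reproduces its output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (ExpressionMatrix, read_expression, read_gene_list,
                         read_gmt, read_network, write_edge_list,
                         write_expression, write_gene_list, write_network,
                         write_ranked_list)
from .deg import DEGTable, run_deg_pipeline
from .clustering import cluster_summary, kmeans_profiles
from .coexpression import correlation_network, threshold_grid
from .enrichment import enrich
from .prediction import (median_optimal_threshold, nested_prediction,
                         outer_loocv, permutation_test)
from .synthetic import SyntheticSpec, generate, read_truth, write_truth

STAGES = ("simulate", "deg", "cluster", "enrich", "network", "predict", "permtest")

_SCHEMA: dict[str, set[str]] = {
    "": {"rng_seed", "out_dir", "log_level", "input", "simulate", "deg",
         "cluster", "enrich", "network", "predict", "permtest"},
    "input": {"expression", "design"},
    "simulate": {"n_background", "n_module_true_neighbors", "n_seeds", "n_drift",
                 "baseline_log2", "noise_sd_log2", "module_noise_sd_log2",
                 "module_loading_range", "drift_fold", "replicates"},
    "deg": {"fc_threshold", "q_threshold", "drift_fold", "low_intensity_q",
            "pooled_fdr"},
    "cluster": {"k_up", "k_down", "n_init", "standardize"},
    "enrich": {"gmt"},
    "network": {"direction", "export_tau", "absolute"},
    "predict": {"k", "grid_start", "grid_stop", "grid_step", "outlier_rank",
                "outlier_policy", "seeds_file"},
    "permtest": {"B", "tau_policy"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check(self.raw, "")
        for section in _SCHEMA:
            if section and section in self.raw and self.raw[section] is not None:
                self._check(self.raw[section], section)

    @staticmethod
    def _check(d: dict, section: str) -> None:
        if not isinstance(d, dict):
            raise ValueError(f"config section {section or '<root>'} must be a mapping")
        unknown = set(d) - _SCHEMA[section]
        if unknown:
            where = f" in section {section!r}" if section else ""
            raise ValueError(f"unknown config key {sorted(unknown)[0]!r}{where}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def get(self, section: str, key: str, default=None):
        return (self.raw.get(section) or {}).get(key, default)

    @property
    def rng_seed(self) -> int:
        return int(self.raw.get("rng_seed", 0))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path | None = None,
            from_stage: str = "simulate") -> dict:
    """Execute the pipeline, returning the artifact manifest.

    ``from_stage`` skips earlier stages, reusing their persisted outputs
    in ``out_dir`` (staged-rerun contract).
    """
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}")
    out = Path(out_dir if out_dir is not None else config.raw.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.raw, sort_keys=True))
    (out / "VERSION").write_text(f"uvkinet {__version__}\n")
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()

    start = STAGES.index(from_stage)
    try:
        for stage in STAGES[start:]:
            _run_stage(stage, config, out)
    except Exception as e:
        failed.write_text(f"{type(e).__name__}: {e}\n")
        raise

    manifest = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage: str, config: RunConfig, out: Path) -> None:
    seed = stage_seed(config.rng_seed, stage)
    if stage == "simulate":
        if config.raw.get("input"):
            matrix = read_expression(config.get("input", "expression"),
                                     config.get("input", "design"))
            write_expression(matrix, out / "expression.tsv", out / "design.tsv")
        else:
            sim = dict(config.raw.get("simulate") or {})
            if "module_loading_range" in sim:
                sim["module_loading_range"] = tuple(sim["module_loading_range"])
            spec = SyntheticSpec(rng_seed=seed, **sim)
            matrix, design, truth = generate(spec)
            write_expression(matrix, out / "expression.tsv", out / "design.tsv")
            write_truth(truth, out / "truth.tsv")
        return

    if stage == "deg":
        matrix = read_expression(out / "expression.tsv", out / "design.tsv")
        deg = run_deg_pipeline(
            matrix,
            fc_threshold=config.get("deg", "fc_threshold", 1.0),
            q_threshold=config.get("deg", "q_threshold", 0.05),
            drift_fold=config.get("deg", "drift_fold", 1.5),
            low_intensity_q=config.get("deg", "low_intensity_q", 0.20),
            pooled_fdr=config.get("deg", "pooled_fdr", False),
        )
        deg.to_tsv(out / "deg.tsv")
        return

    if stage == "cluster":
        deg = DEGTable.from_tsv(out / "deg.tsv")
        summaries = {}
        for direction, k in (("up", config.get("cluster", "k_up", 3)),
                             ("down", config.get("cluster", "k_down", 5))):
            profiles = deg.profiles(direction)
            if len(profiles) < max(k, 1):
                continue
            clustering = kmeans_profiles(
                profiles, k=k, rng_seed=seed,
                n_init=config.get("cluster", "n_init", 50),
                direction=direction,
                standardize=config.get("cluster", "standardize", False),
            )
            clustering.assignments.rename("cluster").to_csv(
                out / f"clusters_{direction}.tsv", sep="\t", index_label="gene_id")
            summ = cluster_summary(clustering)
            summaries[direction] = {
                "k": k, "inertia": clustering.inertia,
                "sizes": summ["size"].tolist(),
            }
        (out / "clusters_summary.yaml").write_text(yaml.safe_dump(summaries))
        return

    if stage == "enrich":
        gmt_path = config.get("enrich", "gmt")
        if not gmt_path:
            return
        deg = DEGTable.from_tsv(out / "deg.tsv")
        sets = read_gmt(gmt_path)
        background = deg.up_genes + deg.down_genes + deg.genes("not_significant")
        for direction in ("up", "down"):
            sel = deg.genes(direction)
            if sel:
                res = enrich(sel, background, sets)
                res.table.to_csv(out / f"enrich_{direction}.tsv", sep="\t", index=False)
        return

    if stage == "network":
        deg = DEGTable.from_tsv(out / "deg.tsv")
        direction = config.get("network", "direction", "down")
        profiles = deg.profiles(None if direction == "all" else direction)
        net = correlation_network(profiles)
        write_network(net, out / "network.tsv")
        tau = config.get("network", "export_tau")
        if tau is not None:
            write_edge_list(net, float(tau), out / "edges.sif", out / "edges.tsv",
                            absolute=config.get("network", "absolute", False))
        return

    if stage == "predict":
        net = read_network(out / "network.tsv")
        seeds = _load_seeds(config, out, net.gene_ids)
        write_gene_list(seeds, out / "seeds_used.txt")
        grid = threshold_grid(config.get("predict", "grid_start", 0.001),
                              config.get("predict", "grid_stop", 0.999),
                              config.get("predict", "grid_step", 0.001))
        result = nested_prediction(
            net, seeds, grid, k=min(config.get("predict", "k", 50),
                                    net.n_genes - len(seeds)),
            outlier_rank=config.get("predict", "outlier_rank", 200),
            outlier_policy=config.get("predict", "outlier_policy", "evaluation"),
        )
        write_ranked_list(result.ranking, out / "ranking.tsv")
        pd.DataFrame({"gene_id": list(result.top_k)}).to_csv(
            out / "top_candidates.txt", index=False, header=False)
        folds = pd.DataFrame(
            [(f.test_seed, f.optimal_tau, f.test_rank, f.excluded_outlier or "")
             for f in result.folds],
            columns=["test_seed", "optimal_tau", "test_rank", "excluded_outlier"])
        folds.to_csv(out / "loocv_folds.tsv", sep="\t", index=False)
        (out / "prediction_summary.yaml").write_text(yaml.safe_dump({
            "median_tau": result.median_tau,
            "observed_median_rank": result.observed_median_rank,
            "pool_size": result.pool_size,
            "n_seeds": len(seeds),
        }))
        return

    if stage == "permtest":
        net = read_network(out / "network.tsv")
        seeds = read_gene_list(out / "seeds_used.txt")
        summary = yaml.safe_load((out / "prediction_summary.yaml").read_text())
        res = permutation_test(
            net, seeds, B=config.get("permtest", "B", 999), rng_seed=seed,
            tau_policy=config.get("permtest", "tau_policy", "fixed"),
            tau=summary["median_tau"],
        )
        (out / "permtest.yaml").write_text(yaml.safe_dump({
            "observed": res.observed, "B": res.n_reps, "n_leq": res.n_leq,
            "p": res.p, "rng_seed": res.rng_seed, "tau_policy": res.tau_policy,
            "tau": res.tau,
        }))
        return


def _load_seeds(config: RunConfig, out: Path, network_genes: list[str]) -> list[str]:
    """Seed list: explicit file if configured, else the synthetic truth's
    planted seeds restricted to the network."""
    seeds_file = config.get("predict", "seeds_file")
    if seeds_file:
        seeds = read_gene_list(seeds_file)
    elif (out / "truth.tsv").exists():
        seeds = read_truth(out / "truth.tsv").seeds
    else:
        raise ValueError("no seeds: set predict.seeds_file or run the simulate stage")
    present = set(network_genes)
    seeds = [s for s in seeds if s in present]
    if len(seeds) < 4:
        raise ValueError("fewer than 4 seed genes present in the network")
    return seeds
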