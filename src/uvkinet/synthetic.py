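"""Synthetic UV time-course expression generator with ground truth.

Emulates the study design the downstream analysis assumes: three
replicates per group, UV-exposed skin sampled at weeks {1, 2, 4, 6, 8}
plus non-irradiated controls at weeks 1 and 8.  Genes fall into four
roles:

* ``seed`` / ``true_neighbor`` — a planted co-expressed module.  Every
  module gene follows one shared latent kinetic (the week-2-recovery
  repression archetype) scaled by a per-gene loading a_g, with small
  log-scale noise, so module genes are mutually highly correlated.
* ``background`` — each gene follows its own kinetic archetype (or is
  flat) with larger noise.
* ``drift`` — intrinsic-aging genes whose expression drifts linearly in
  week in *both* groups, so the week-8 control mean sits exactly
  ``drift_fold`` above the week-1 control mean.  These are the genes the
  control-drift filter exists to exclude.

Noise is Normal on the log2 scale (log-normal intensities), the standard
multiplicative error model for array intensities.  Identical specs
(including the seed) produce bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleDesign, VALID_WEEKS

# Kinetic archetypes on the log2 fold-change scale over weeks {1,2,4,6,8}.
# 1-3 are up-regulation kinetics (non-negative), 4-8 down-regulation
# kinetics (non-positive), "flat" is the null profile.  Values are
# generator defaults chosen as qualitative shape matches only:
#   1 acute induction, week-2 recovery, late re-induction
#   2 subacute induction emerging at weeks 2-4
#   3 immediate induction, maintained
#   4 early repression, week-2 recovery, mild mid-course, late repression
#   5 continuous decline
#   6 early repression, full week-2 recovery, sustained re-repression
#   7 early repression held to week 4, further late decline
#   8 like 4/6 but with a much deeper first-week fall
ARCHETYPES: dict[int | str, np.ndarray] = {
    1: np.array([1.5, 0.2, 0.6, 1.6, 1.8]),
    2: np.array([0.0, 0.6, 1.2, 1.5, 1.5]),
    3: np.array([1.2, 1.4, 1.4, 1.4, 1.4]),
    4: np.array([-1.0, 0.0, -0.3, -1.2, -1.5]),
    5: np.array([-0.4, -0.8, -1.2, -1.6, -2.0]),
    6: np.array([-1.2, 0.0, -1.0, -1.4, -1.6]),
    7: np.array([-1.0, -1.0, -1.0, -1.5, -1.9]),
    8: np.array([-2.0, -0.6, -1.2, -1.8, -2.0]),
    "flat": np.zeros(5),
}

MODULE_ARCHETYPE = 6  # shared latent kinetic of the planted module

_ROLES = ("seed", "true_neighbor", "background", "drift")


def archetype_template(archetype_id: int | str) -> np.ndarray:
    """Deterministic log2 fold-change template at weeks {1,2,4,6,8}."""
    try:
        return ARCHETYPES[archetype_id].copy()
    except KeyError:
        raise ValueError(f"unknown archetype id: {archetype_id!r}") from None


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults are the conditions exercised throughout the test-bed: a 511
    gene down-regulation-rich universe (450 background + 11 seeds + 50
    true neighbors) plus 25 intrinsic-drift genes, 3 replicates per
    group, module noise sd 0.10 log2 units against a background noise sd
    of 0.25.
    """

    n_background: int = 450
    n_module_true_neighbors: int = 50
    n_seeds: int = 11
    n_drift: int = 25
    archetype_assignments: dict | None = None  # gene_id -> archetype id
    baseline_log2: float = 8.0
    noise_sd_log2: float = 0.25
    module_noise_sd_log2: float = 0.10
    module_loading_range: tuple[float, float] = (0.8, 1.2)
    drift_fold: float = 2.0
    replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_module_true_neighbors", "n_seeds", "n_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd_log2 < 0 or self.module_noise_sd_log2 < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.drift_fold <= 1:
            raise ValueError("drift_fold must be > 1")
        lo, hi = self.module_loading_range
        if not (0 < lo <= hi):
            raise ValueError("module_loading_range must satisfy 0 < lo <= hi")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for variance estimation")


@dataclass(frozen=True)
class TruthTable:
    """Ground-truth labels for one generated instance."""

    table: pd.DataFrame  # gene_id, role, archetype, direction

    def genes(self, role: str) -> list[str]:
        if role not in _ROLES:
            raise ValueError(f"unknown role {role!r}")
        return list(self.table.loc[self.table["role"] == role, "gene_id"])

    @property
    def seeds(self) -> list[str]:
        return self.genes("seed")

    @property
    def true_neighbors(self) -> list[str]:
        return self.genes("true_neighbor")


def _default_assignments(background_ids: list[str]) -> dict[str, int | str]:
    cycle: list[int | str] = [1, 2, 3, 4, 5, 6, 7, 8, "flat"]
    return {g: cycle[i % len(cycle)] for i, g in enumerate(background_ids)}


def _make_design(replicates: int) -> SampleDesign:
    rows = []
    for week in (1, 8):
        for r in range(1, replicates + 1):
            rows.append((f"ctrl_w{week}_r{r}", "control", week, r))
    for week in VALID_WEEKS:
        for r in range(1, replicates + 1):
            rows.append((f"uv_w{week}_r{r}", "uv", week, r))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "group", "week", "replicate"])
    )


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SampleDesign, TruthTable]:
    """Draw one synthetic study: matrix + design + truth labels.

    log2 intensity of gene g in sample s is
    ``baseline_log2 + effect_g(week_s, group_s) + Normal(0, sd_g)``; the
    returned matrix carries ``2**log2`` linear intensities.
    """
    rng = np.random.default_rng(spec.rng_seed)
    design = _make_design(spec.replicates)

    seeds = [f"seed{i + 1:02d}" for i in range(spec.n_seeds)]
    neighbors = [f"mod{i + 1:03d}" for i in range(spec.n_module_true_neighbors)]
    background = [f"bg{i + 1:04d}" for i in range(spec.n_background)]
    drift = [f"drift{i + 1:02d}" for i in range(spec.n_drift)]
    genes = seeds + neighbors + background + drift

    assignments = dict(_default_assignments(background))
    if spec.archetype_assignments:
        unknown = set(spec.archetype_assignments) - set(genes)
        if unknown:
            raise ValueError(f"archetype assignment for unknown gene {sorted(unknown)[0]!r}")
        assignments.update(spec.archetype_assignments)

    latent = archetype_template(MODULE_ARCHETYPE)
    week_index = {w: i for i, w in enumerate(VALID_WEEKS)}
    lo, hi = spec.module_loading_range
    loadings = rng.uniform(lo, hi, size=spec.n_seeds + spec.n_module_true_neighbors)
    drift_slope = np.log2(spec.drift_fold) / 7.0  # per-week intrinsic drift

    n_samples = len(design.sample_ids)
    log2 = np.full((len(genes), n_samples), spec.baseline_log2)
    sds = np.empty(len(genes))

    truth_rows = []
    module_set = set(seeds) | set(neighbors)
    for gi, g in enumerate(genes):
        if g in module_set:
            role = "seed" if g in seeds else "true_neighbor"
            arch = MODULE_ARCHETYPE
            template = loadings[gi] * latent
            sds[gi] = spec.module_noise_sd_log2
            direction = "down"
        elif g in drift:
            role, arch = "drift", "flat"
            template = np.zeros(5)
            sds[gi] = spec.noise_sd_log2
            direction = "none"
        else:
            role = "background"
            arch = assignments.get(g, "flat")
            template = archetype_template(arch)
            sds[gi] = spec.noise_sd_log2
            if arch == "flat":
                direction = "none"
            else:
                direction = "up" if int(arch) <= 3 else "down"
        truth_rows.append((g, role, arch, direction))

        for si, (_, row) in enumerate(design.table.iterrows()):
            week, group = row["week"], row["group"]
            if role == "drift":
                log2[gi, si] += drift_slope * (week - 1)
            elif group == "uv":
                log2[gi, si] += template[week_index[week]]

    noise = rng.normal(0.0, 1.0, size=log2.shape) * sds[:, None]
    values = 2.0 ** (log2 + noise)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=design.sample_ids), design
    )
    truth = TruthTable(
        pd.DataFrame(truth_rows, columns=["gene_id", "role", "archetype", "direction"])
    )
    return matrix, design, truth


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "archetype": str})
    # archetype ids are ints 1-8 or the string "flat"
    df["archetype"] = [int(a) if a.isdigit() else a for a in df["archetype"]]
    return TruthTable(df)
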