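"""Seed-gene neighborhood prediction with nested leave-one-out CV.

The guilt-by-association inference: genes directly connected to known
seed genes (here, collagen-regulatory genes) in a thresholded
co-expression network are candidate members of the same process.  The
binarization threshold tau is the single hyperparameter and is tuned by
nested LOOCV:

* outer loop — each seed in turn is held out as a test gene; its rank by
  neighborhood score (computed from the remaining seeds) measures
  predictive performance;
* inner loop — within each outer fold, each *training* seed is in turn
  held out and ranked across the whole threshold grid; the tau
  minimizing the mean inner rank (after excluding a detected outlier
  seed) is that fold's optimal threshold.

The final candidate list uses all seeds on the network binarized at the
median of the per-fold optimal thresholds.  Significance of the observed
median test rank is assessed against random seed sets of the same size
(permutation test, add-one p estimator).

Ranks are fractional (ties get the mean of the spanned ranks) for all
evaluation statistics; emitted candidate lists are ordered
deterministically by score descending, then gene id ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coexpression import WeightedNetwork, threshold_grid

DEFAULT_OUTLIER_RANK = 200.0


def rank_with_ties(scores: pd.Series) -> pd.Series:
    """Descending fractional ranks: highest score gets rank 1; tied scores
    share the mean of the ranks they span."""
    vals = np.asarray(scores, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    return pd.Series(rankdata(-vals, method="average"), index=scores.index, name="rank")


# ---------------------------------------------------------------------------
# internals: vectorized scoring over the threshold grid
# ---------------------------------------------------------------------------


def _seed_adjacency(W: np.ndarray, scoring_idx: np.ndarray) -> np.ndarray:
    """r values of every gene against each scoring seed, with self-pairs
    suppressed so a seed never counts an edge to itself."""
    Rs = W[:, scoring_idx].copy()
    for col, s in enumerate(scoring_idx):
        Rs[s, col] = -np.inf
    return Rs


def _held_out_rank_over_grid(W: np.ndarray, scoring_idx: np.ndarray,
                             held_out: int, grid: np.ndarray) -> np.ndarray:
    """Fractional rank of ``held_out`` at every threshold.

    Pool = all genes except the scoring seeds (the held-out gene is in
    the pool).  Scores are seed-connection counts at each tau.
    """
    Rs = _seed_adjacency(W, scoring_idx)
    # scores[g, t] = number of scoring seeds with r(g, seed) >= grid[t]
    scores = (Rs[:, :, None] >= grid[None, None, :]).sum(axis=1)
    pool = np.ones(W.shape[0], dtype=bool)
    pool[scoring_idx] = False
    pool[held_out] = True
    s_h = scores[held_out]
    pool_scores = scores[pool]
    greater = (pool_scores > s_h).sum(axis=0)
    ties = (pool_scores == s_h).sum(axis=0)  # includes the held-out itself
    return greater + (ties + 1) / 2.0


def _held_out_rank_at_tau(W: np.ndarray, scoring_idx: np.ndarray,
                          held_out: int, tau: float) -> float:
    Rs = _seed_adjacency(W, scoring_idx)
    scores = (Rs >= tau).sum(axis=1)
    pool = np.ones(W.shape[0], dtype=bool)
    pool[scoring_idx] = False
    pool[held_out] = True
    s_h = scores[held_out]
    pool_scores = scores[pool]
    greater = int((pool_scores > s_h).sum())
    ties = int((pool_scores == s_h).sum())
    return greater + (ties + 1) / 2.0


# ---------------------------------------------------------------------------
# inner loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InnerLoopResult:
    traces: pd.DataFrame          # rows = held-out training seeds, cols = grid
    mean_trace: pd.Series         # mean over traces, outlier excluded
    optimal_tau: float
    outlier: str | None


def detect_outlier(traces: pd.DataFrame, rank_cap: float = DEFAULT_OUTLIER_RANK) -> str | None:
    """The outlier seed: its inner-loop rank exceeds ``rank_cap`` at EVERY
    threshold; among qualifiers, the one with the largest maximum rank
    (ties broken by gene id).  None if no trace qualifies."""
    qualifies = (traces > rank_cap).all(axis=1)
    if not qualifies.any():
        return None
    maxima = traces.loc[qualifies].max(axis=1)
    best = maxima.max()
    return sorted(maxima.index[maxima == best])[0]


def inner_loocv(network: WeightedNetwork, training_seeds: list[str],
                grid: np.ndarray | None = None,
                outlier_rank: float = DEFAULT_OUTLIER_RANK) -> InnerLoopResult:
    """Tune tau on the training seeds by leave-one-out ranking.

    For each held-out training seed, the remaining seeds score the
    network at every threshold and the held-out gene's rank is recorded;
    the optimal tau minimizes the mean rank across folds (an outlier
    trace, if detected, is excluded from the mean).  Ties in the argmin
    resolve to the smallest tau.
    """
    if len(training_seeds) < 3:
        raise ValueError("inner loop needs at least 3 training seeds")
    if grid is None:
        grid = threshold_grid()
    grid = np.asarray(grid, dtype=float)
    W = network.weights
    idx = network.index_of(training_seeds)

    rows = {}
    for i, held in enumerate(training_seeds):
        scoring = np.delete(idx, i)
        rows[held] = _held_out_rank_over_grid(W, scoring, idx[i], grid)
    traces = pd.DataFrame.from_dict(rows, orient="index", columns=grid)

    outlier = detect_outlier(traces, outlier_rank)
    used = traces.drop(index=outlier) if outlier is not None else traces
    mean_trace = used.mean(axis=0)
    optimal_tau = float(grid[int(np.argmin(mean_trace.to_numpy()))])
    return InnerLoopResult(traces, mean_trace, optimal_tau, outlier)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OuterFoldResult:
    test_seed: str
    optimal_tau: float
    test_rank: float
    excluded_outlier: str | None


@dataclass(frozen=True)
class OuterLoocvResult:
    folds: tuple[OuterFoldResult, ...]
    median_rank: float
    pool_size: int

    @property
    def optimal_taus(self) -> list[float]:
        return [f.optimal_tau for f in self.folds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.test_seed, f.optimal_tau, f.test_rank, f.excluded_outlier or "")
             for f in self.folds],
            columns=["test_seed", "optimal_tau", "test_rank", "excluded_outlier"],
        )


def outer_loocv(network: WeightedNetwork, seeds: list[str],
                grid: np.ndarray | None = None,
                outlier_rank: float = DEFAULT_OUTLIER_RANK,
                outlier_policy: str = "evaluation") -> OuterLoocvResult:
    """Leave-one-seed-out evaluation with per-fold tau tuning.

    ``outlier_policy``: "evaluation" drops the detected inner outlier
    only from the tuning average (default); "scoring" also removes it
    from the seeds that score the test gene.
    """
    if len(seeds) < 4:
        raise ValueError("outer loop needs at least 4 seeds")
    if outlier_policy not in ("evaluation", "scoring"):
        raise ValueError(f"unknown outlier policy {outlier_policy!r}")
    if grid is None:
        grid = threshold_grid()
    grid = np.asarray(grid, dtype=float)
    W = network.weights
    idx = network.index_of(seeds)

    folds = []
    for i, test in enumerate(seeds):
        training = [s for s in seeds if s != test]
        inner = inner_loocv(network, training, grid, outlier_rank)
        scoring_names = training
        if outlier_policy == "scoring" and inner.outlier is not None:
            scoring_names = [s for s in training if s != inner.outlier]
        scoring = network.index_of(scoring_names)
        rank = _held_out_rank_at_tau(W, scoring, idx[i], inner.optimal_tau)
        folds.append(OuterFoldResult(test, inner.optimal_tau, rank, inner.outlier))

    median_rank = float(np.median([f.test_rank for f in folds]))
    pool_size = network.n_genes - (len(seeds) - 1)
    return OuterLoocvResult(tuple(folds), median_rank, pool_size)


def median_optimal_threshold(taus, grid: np.ndarray | None = None) -> float:
    """Median of per-fold optimal thresholds; an even-length median (mean
    of the central pair) is snapped to the nearest grid value, ties
    toward the smaller."""
    taus = np.asarray(list(taus), dtype=float)
    if taus.size == 0:
        raise ValueError("no thresholds given")
    med = float(np.median(taus))
    if grid is None:
        grid = threshold_grid()
    grid = np.asarray(grid, dtype=float)
    dist = np.abs(grid - med)
    return float(grid[int(np.argmin(dist))])  # argmin takes first -> smaller tau


# ---------------------------------------------------------------------------
# final prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionResult:
    median_tau: float
    ranking: pd.DataFrame             # gene_id, score, rank (deterministic order)
    top_k: tuple[str, ...]
    folds: tuple[OuterFoldResult, ...]
    observed_median_rank: float | None
    pool_size: int


def final_prediction(network: WeightedNetwork, seeds: list[str], tau: float,
                     k: int = 50,
                     folds: tuple[OuterFoldResult, ...] = (),
                     observed_median_rank: float | None = None,
                     absolute: bool = False) -> PredictionResult:
    """Rank all non-seed genes by connections to the full seed set at tau
    and return the top-k candidates (pure top-k; no score cutoff)."""
    from .coexpression import neighborhood_scores

    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    scores = neighborhood_scores(network, seeds, tau, absolute=absolute)
    if k > len(scores):
        raise ValueError(f"k={k} exceeds candidate pool size {len(scores)}")
    ranks = rank_with_ties(scores)
    df = pd.DataFrame({"gene_id": scores.index, "score": scores.to_numpy(),
                       "rank": ranks.to_numpy()})
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    top = tuple(df["gene_id"].head(k))
    return PredictionResult(float(tau), df, top, tuple(folds),
                            observed_median_rank, len(scores))


def nested_prediction(network: WeightedNetwork, seeds: list[str],
                      grid: np.ndarray | None = None, k: int = 50,
                      outlier_rank: float = DEFAULT_OUTLIER_RANK,
                      outlier_policy: str = "evaluation") -> PredictionResult:
    """Full procedure: outer LOOCV -> median optimal tau -> final top-k."""
    if grid is None:
        grid = threshold_grid()
    outer = outer_loocv(network, seeds, grid, outlier_rank, outlier_policy)
    tau = median_optimal_threshold(outer.optimal_taus, grid)
    return final_prediction(network, seeds, tau, k=k, folds=outer.folds,
                            observed_median_rank=outer.median_rank)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_reps: int
    n_leq: int
    p: float
    rng_seed: int
    tau_policy: str
    tau: float | None
    null_statistics: np.ndarray = field(repr=False, default=None)


def _loocv_median_rank_fixed_tau(W: np.ndarray, seed_idx: np.ndarray,
                                 tau: float) -> float:
    """Median leave-one-out rank of a seed set at a fixed threshold."""
    m = W.shape[0]
    A = W[:, seed_idx] >= tau
    for col, s in enumerate(seed_idx):
        A[s, col] = False
    row_sum = A.sum(axis=1)
    pool_base = np.ones(m, dtype=bool)
    pool_base[seed_idx] = False
    ranks = np.empty(len(seed_idx))
    for i, t in enumerate(seed_idx):
        scores = row_sum - A[:, i]  # connections to the other seeds only
        pool = pool_base.copy()
        pool[t] = True
        s_t = scores[t]
        pool_scores = scores[pool]
        greater = int((pool_scores > s_t).sum())
        ties = int((pool_scores == s_t).sum())
        ranks[i] = greater + (ties + 1) / 2.0
    return float(np.median(ranks))


def permutation_test(network: WeightedNetwork, seeds: list[str], B: int,
                     rng_seed: int, tau_policy: str = "fixed",
                     tau: float | None = None,
                     grid: np.ndarray | None = None,
                     outlier_rank: float = DEFAULT_OUTLIER_RANK,
                     outlier_policy: str = "evaluation") -> PermutationResult:
    """Compare the seeds' median LOOCV rank against random seed sets.

    Null replicate: ``len(seeds)`` genes drawn uniformly without
    replacement from all network genes.  With ``tau_policy="fixed"``
    (default) the statistic for observed and null alike is the median
    leave-one-out rank at a single tau (the nested procedure's median
    optimal tau, computed here if not supplied) — the fast policy that
    makes large B practical.  ``tau_policy="nested"`` re-runs the full
    nested tuning per replicate.  p = (#{null <= observed} + 1)/(B + 1);
    lower ranks mean stronger seed coherence.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tau_policy not in ("fixed", "nested"):
        raise ValueError(f"unknown tau policy {tau_policy!r}")
    if network.n_genes - len(seeds) < 1 or len(seeds) > network.n_genes:
        raise ValueError("pool smaller than seed count")
    if grid is None:
        grid = threshold_grid()
    rng = np.random.default_rng(rng_seed)
    W = network.weights
    m = network.n_genes

    if tau_policy == "fixed":
        if tau is None:
            outer = outer_loocv(network, seeds, grid, outlier_rank, outlier_policy)
            tau = median_optimal_threshold(outer.optimal_taus, grid)
        observed = _loocv_median_rank_fixed_tau(W, network.index_of(seeds), tau)
        null = np.empty(B)
        for b in range(B):
            draw = rng.choice(m, size=len(seeds), replace=False)
            null[b] = _loocv_median_rank_fixed_tau(W, draw, tau)
    else:
        outer = outer_loocv(network, seeds, grid, outlier_rank, outlier_policy)
        observed = outer.median_rank
        tau = median_optimal_threshold(outer.optimal_taus, grid)
        gene_arr = np.asarray(network.gene_ids)
        null = np.empty(B)
        for b in range(B):
            draw = list(gene_arr[rng.choice(m, size=len(seeds), replace=False)])
            null[b] = outer_loocv(network, draw, grid, outlier_rank,
                                  outlier_policy).median_rank

    n_leq = int((null <= observed).sum())
    p = (n_leq + 1) / (B + 1)
    return PermutationResult(float(observed), B, n_leq, float(p), rng_seed,
                             tau_policy, float(tau) if tau is not None else None,
                             null_statistics=null)
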