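"""Pearson co-expression networks over kinetic profiles.

Each gene's log2 fold-change trajectory over weeks {1,2,4,6,8} is one
vector; the weighted network is the gene x gene Pearson correlation
matrix of those vectors.  Binary adjacency views are obtained by
thresholding at tau on the *signed* r (edge iff r >= tau) across the
standard grid 0.001..0.999 in steps of 0.001; use ``absolute=True`` to
threshold |r| instead.  A constant (zero-variance) profile has no
defined correlation: its r values are stored as 0 and the gene flagged,
so it can never pass a positive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GRID_STEP = 0.001


def threshold_grid(start: float = 0.001, stop: float = 0.999,
                   step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Strictly increasing threshold grid in (0, 1); default 999 values."""
    n = int(round((stop - start) / step)) + 1
    grid = np.round(start + step * np.arange(n), 9)
    if grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    if not (np.diff(grid) > 0).all():
        raise ValueError("threshold grid must be strictly increasing")
    return grid


@dataclass
class WeightedNetwork:
    """Symmetric Pearson weight matrix with unit diagonal."""

    gene_ids: list[str]
    weights: np.ndarray
    constant_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        m = len(self.gene_ids)
        if W.shape != (m, m):
            raise ValueError("weight matrix shape does not match gene ids")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(W).max() > 1 + 1e-12:
            raise ValueError("|r| exceeds 1 beyond tolerance")
        W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(W, 1.0)
        self.weights = W

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene not in network: {e.args[0]!r}") from None

    def binarize(self, tau: float, absolute: bool = False) -> np.ndarray:
        """Boolean adjacency at threshold tau (zero diagonal)."""
        if not (0 < tau < 1):
            raise ValueError("tau must be in (0, 1)")
        W = np.abs(self.weights) if absolute else self.weights
        adj = W >= tau
        np.fill_diagonal(adj, False)
        return adj

    def subnetwork(self, genes) -> "WeightedNetwork":
        idx = self.index_of(genes)
        sub = self.weights[np.ix_(idx, idx)]
        kept = set(np.asarray(self.gene_ids)[idx])
        return WeightedNetwork(list(genes), sub,
                               frozenset(g for g in self.constant_genes if g in kept))


def correlation_network(profiles: pd.DataFrame) -> WeightedNetwork:
    """Pearson correlation network over per-gene profile vectors.

    ``profiles``: rows = genes, columns = the shared week grid (>= 3
    points).  Gene order is preserved; the result is invariant to it up
    to the corresponding permutation.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if profiles.shape[1] < 3:
        raise ValueError("profiles must cover at least 3 time points")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    sd = X.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.corrcoef(X)
    W = np.asarray(W, dtype=float)
    if constant.any():
        W[constant, :] = 0.0
        W[:, constant] = 0.0
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    flagged = frozenset(np.asarray(profiles.index.astype(str))[constant])
    return WeightedNetwork(list(profiles.index.astype(str)), W, flagged)


def neighborhood_scores(network: WeightedNetwork, seeds: list[str], tau: float,
                        adjacency: np.ndarray | None = None,
                        absolute: bool = False) -> pd.Series:
    """Integer count of direct connections to seed genes, per non-seed gene.

    The score of a gene ranges from 0 (no seed connection) up to
    ``len(seeds)``.  Seeds themselves are excluded from the scored pool.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    seed_idx = network.index_of(seeds)
    adj = network.binarize(tau, absolute=absolute) if adjacency is None else adjacency
    scores = adj[:, seed_idx].sum(axis=1)
    mask = np.ones(network.n_genes, dtype=bool)
    mask[seed_idx] = False
    genes = np.asarray(network.gene_ids)[mask]
    return pd.Series(scores[mask], index=genes, name="score")
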