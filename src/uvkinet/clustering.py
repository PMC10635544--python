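"""K-means clustering of kinetic (log2 fold-change) profiles.

Up- and downregulated genes are clustered separately (defaults k=3 up,
k=5 down).  Distance is Euclidean on the raw log2fc vectors — magnitude
distinguishes kinetic classes (a deep first-week fall is a different
kinetic from a shallow one), so profiles are not standardized by
default.  Lloyd's algorithm, best of ``n_init`` seeded restarts by
inertia, deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import GeneSet


@dataclass(frozen=True)
class KineticClustering:
    direction: str
    k: int
    assignments: pd.Series        # gene_id -> cluster label (0..k-1)
    centroids: pd.DataFrame       # k x weeks
    inertia: float
    rng_seed: int
    n_init: int

    def members(self, label: int) -> list[str]:
        return sorted(self.assignments.index[self.assignments == label])


def kmeans_profiles(profiles: pd.DataFrame, k: int, rng_seed: int,
                    n_init: int = 50, max_iter: int = 300,
                    direction: str = "unspecified",
                    standardize: bool = False) -> KineticClustering:
    """Cluster gene kinetic profiles (rows = genes, columns = weeks).

    ``standardize`` optionally z-scores each gene's profile first, making
    the clustering shape-only.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profiles) < k:
        raise ValueError(f"k={k} exceeds number of profiles ({len(profiles)})")
    X = profiles.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                random_state=rng_seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    return KineticClustering(
        direction=direction, k=k,
        assignments=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=centroids, inertia=float(km.inertia_),
        rng_seed=rng_seed, n_init=n_init,
    )


def cluster_summary(clustering: KineticClustering) -> pd.DataFrame:
    """Per-cluster size, centroid and sorted member list."""
    rows = []
    for label in range(clustering.k):
        members = clustering.members(label)
        rows.append({
            "cluster": label,
            "size": len(members),
            "centroid": clustering.centroids.loc[label].to_numpy(),
            "members": members,
        })
    return pd.DataFrame(rows).set_index("cluster")


def set_concentration(clustering: KineticClustering, gene_set: GeneSet,
                      clusters: list[int]) -> tuple[int, int, float]:
    """How strongly a gene set concentrates in a union of clusters.

    Returns (hits-in-union, set members present in the clustering, fraction).
    This is the quantity behind statements like "14 of 17 matrix genes
    fall in two of five kinetic clusters"; the enrichment module turns it
    into a fold/test.
    """
    present = [g for g in gene_set.members if g in clustering.assignments.index]
    union = set()
    for c in clusters:
        union.update(clustering.members(c))
    hits = sum(g in union for g in present)
    frac = hits / len(present) if present else float("nan")
    return hits, len(present), frac


def save_profile_heatmap(profiles: pd.DataFrame, clustering: KineticClustering,
                         path) -> None:
    """Quick-look heatmap of profiles ordered by cluster (genes x weeks)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clustering.assignments.sort_values(kind="stable").index
    X = profiles.loc[order].to_numpy()
    fig, ax = plt.subplots(figsize=(4, 6))
    vmax = max(1.0, np.abs(X).max())
    im = ax.imshow(X, aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(X.shape[1]), [str(c) for c in profiles.columns])
    ax.set_xlabel("week")
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
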