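"""2D projection of learned embeddings and class-separation scoring."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score


@dataclass
class Projection2D:
    coords: np.ndarray
    labels: np.ndarray
    subclass: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels must align with coords rows")


def project_umap(embeddings: np.ndarray, labels=None, subclass=None,
                 n_neighbors: int = 15, min_dist: float = 0.1,
                 seed: int = 0) -> Projection2D:
    """UMAP projection of an embedding matrix to 2D, deterministic given seed."""
    import umap  # deferred: numba compilation is slow at import

    E = np.asarray(embeddings, dtype=np.float64)
    if E.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    if len(E) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, got {len(E)}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(E)
    labels = np.zeros(len(E)) if labels is None else np.asarray(labels)
    return Projection2D(coords=coords, labels=labels,
                        subclass=None if subclass is None else np.asarray(subclass),
                        params={"n_neighbors": n_neighbors, "min_dist": min_dist,
                                "seed": seed})


def separation_score(X, labels) -> tuple[float, bool]:
    """Mean silhouette (Euclidean) of a projection or embedding matrix.

    Returns (score, degenerate); all-identical points give (0.0, True)."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("need at least 2 points per class")
    if np.allclose(X, X[0]):
        return 0.0, True
    return float(silhouette_score(X, labels)), False


def scatter_projection(projection: Projection2D, path: str | None = None,
                       title: str = "Bimodal embedding projection"):
    """Scatter plot colored by subclass (fallback: binary label)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = projection.subclass if projection.subclass is not None else projection.labels
    for g in np.unique(groups):
        m = groups == g
        ax.scatter(projection.coords[m, 0], projection.coords[m, 1],
                   s=12, alpha=0.75, label=str(g))
    ax.legend(fontsize=8)
    ax.set_title(title)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
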