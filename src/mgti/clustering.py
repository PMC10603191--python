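"""Gene clustering: Ward hierarchy cut at k, refined by k-means to a fixpoint.

Ward linkage on Euclidean distance provides the initial partition; its
cluster centroids seed Lloyd iterations that stop when the assignment of
genes to clusters no longer changes (or after ``max_iter`` sweeps). The
within-cluster sum of squares is recorded per iteration and is
non-increasing by construction. The cluster count can be fixed (default 4)
or chosen by mean silhouette over a candidate range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, DomainError


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # gene -> 1..k
    k: int
    inertia: float
    n_iterations: int
    inertia_history: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "cluster": list(self.labels.values())}
        )


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _as_matrix(features: pd.DataFrame | dict) -> tuple[list[str], np.ndarray]:
    if isinstance(features, dict):
        features = pd.DataFrame.from_dict(features, orient="index")
    genes = [str(g) for g in features.index]
    x = features.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DomainError("feature matrix contains non-finite values")
    return genes, x


def _inertia(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((x - centers[labels]) ** 2).sum())


def cluster_genes(
    features: pd.DataFrame | dict,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    metric: str = "euclidean",
    standardize: bool = True,
) -> ClusterAssignment:
    """Ward/Euclidean hierarchical partition refined by k-means.

    ``metric`` selects the distance used for the hierarchical stage
    (euclidean, cityblock or correlation); the Lloyd refinement always
    minimizes squared Euclidean distortion on the (optionally
    standardized) features. Deterministic: the seeding is the
    hierarchical partition, not random.
    """
    genes, x = _as_matrix(features)
    n = len(genes)
    if k < 1 or k > n:
        raise ConfigurationError(f"k={k} out of range for {n} genes")
    if standardize:
        x = _standardize(x)

    if k == 1:
        center = x.mean(axis=0, keepdims=True)
        labels = np.zeros(n, dtype=int)
        return ClusterAssignment(
            labels={g: 1 for g in genes},
            k=1,
            inertia=_inertia(x, labels, center),
            n_iterations=0,
            inertia_history=[_inertia(x, labels, center)],
        )

    if metric == "euclidean":
        z = linkage(x, method="ward")
    elif metric in ("cityblock", "correlation"):
        z = linkage(cdist(x, x, metric=metric)[np.triu_indices(n, 1)], method="average")
    else:
        raise ConfigurationError(f"unsupported metric {metric!r}")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    centers = np.vstack([x[labels == c].mean(axis=0) for c in range(k)])

    history = [_inertia(x, labels, centers)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = cdist(x, centers, metric="sqeuclidean")
        new_labels = d.argmin(axis=1)
        for c in range(k):  # keep empty clusters at their previous center
            if (new_labels == c).any():
                centers[c] = x[new_labels == c].mean(axis=0)
        if np.array_equal(new_labels, labels):
            history.append(_inertia(x, labels, centers))
            break
        labels = new_labels
        history.append(_inertia(x, labels, centers))
    return ClusterAssignment(
        labels={g: int(c) + 1 for g, c in zip(genes, labels)},
        k=k,
        inertia=history[-1],
        n_iterations=n_iter,
        inertia_history=history,
    )


def choose_k(
    features: pd.DataFrame | dict, k_range: range | list[int], seed: int = 0
) -> int:
    """Cluster count maximizing mean silhouette; ties go to the smallest k."""
    genes, x = _as_matrix(features)
    n = len(genes)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ConfigurationError(f"k_range must lie within [2, {n - 1}]")
    if np.allclose(x, x[0]):
        raise DomainError("degenerate features: all genes identical")
    best_k, best_score = None, -np.inf
    for k in ks:
        assign = cluster_genes(features, k, seed=seed)
        lab = np.array([assign.labels[g] for g in genes])
        if len(np.unique(lab)) < 2:
            continue
        score = silhouette_score(_standardize(x), lab, metric="euclidean")
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        raise DomainError("silhouette undefined for every candidate k")
    return best_k
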