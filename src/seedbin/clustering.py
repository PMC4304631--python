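"""Phase 2: k-means over group seed signatures, and label propagation.

Lloyd's algorithm minimises the within-cluster sum of squared Euclidean
distances between seed signature vectors and their cluster means,

    sum_j sum_{G_i in C_j} || f_i - mean_j ||^2 ,

with each mean the arithmetic average of its cluster's vectors.  Means are
initialised by drawing k distinct feature vectors without replacement;
iteration alternates nearest-mean assignment (ties broken toward the lowest
cluster index) and mean recomputation, stopping when the means are exactly
stable or ``max_iter`` is reached.  Reads then inherit the cluster label of
their phase-1 group.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .grouping import Group
from .io import AssignmentTable, ReadSet
from .signature import SignatureVector


@dataclass
class ClusterModel:
    """Fitted k-means model over p group signatures.

    ``labels[i]`` is the cluster of group i; ``objective`` the final
    within-cluster sum of squares; ``objective_history`` its value after
    each Lloyd iteration; ``n_repairs`` counts empty-cluster reseedings.
    """

    means: np.ndarray
    labels: np.ndarray
    iterations_run: int
    objective: float
    objective_history: list[float] = field(default_factory=list)
    n_repairs: int = 0

    @property
    def k(self) -> int:
        return self.means.shape[0]


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
    else:
        rows = [
            f.values if isinstance(f, SignatureVector) else np.asarray(f, float)
            for f in features
        ]
        X = np.vstack(rows).astype(float)
    if X.ndim != 2:
        raise ValueError("features must form a 2-D matrix")
    return X


def kmeans_objective(features, labels, means) -> float:
    """Within-cluster sum of squared distances for given labels and means."""
    X = _as_matrix(features)
    labels = np.asarray(labels)
    means = np.asarray(means, dtype=float)
    return float(((X - means[labels]) ** 2).sum())


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> ClusterModel:
    p = len(X)
    # Initial means: k distinct rows drawn without replacement (fall back to
    # arbitrary rows if fewer than k distinct vectors exist).
    uniq = np.unique(X, axis=0)
    pool = uniq if len(uniq) >= k else X
    means = pool[rng.choice(len(pool), size=k, replace=False)].copy()

    history: list[float] = []
    labels = np.zeros(p, dtype=int)
    n_repairs = 0
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        d2 = cdist(X, means, "sqeuclidean")
        labels = d2.argmin(axis=1)  # argmin -> lowest index on ties
        # Empty-cluster repair: reseed each empty cluster with the point
        # farthest from its currently assigned mean (donor clusters must
        # keep at least one member).
        for j in range(k):
            if np.any(labels == j):
                continue
            cost = d2[np.arange(p), labels].copy()
            sizes = np.bincount(labels, minlength=k)
            cost[sizes[labels] < 2] = -np.inf
            donor = int(np.argmax(cost))
            labels[donor] = j
            means[j] = X[donor]
            n_repairs += 1
        new_means = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        history.append(float(((X - new_means[labels]) ** 2).sum()))
        if np.array_equal(new_means, means):
            means = new_means
            break
        means = new_means
    objective = float(((X - means[labels]) ** 2).sum())
    return ClusterModel(
        means=means,
        labels=labels,
        iterations_run=iterations,
        objective=objective,
        objective_history=history,
        n_repairs=n_repairs,
    )


def run_kmeans(
    features,
    k: int,
    *,
    max_iter: int = 100,
    random_state: int | np.random.Generator | None = None,
    restarts: int = 1,
) -> ClusterModel:
    """Cluster p feature vectors into k clusters with Lloyd's algorithm.

    Parameters
    ----------
    features : sequence of :class:`SignatureVector` or a (p, d) array.
    k : number of clusters, 1 <= k <= p.
    max_iter : iteration cap per restart (default 100).
    random_state : seed or generator driving initialisation.
    restarts : number of independent initialisations; the model with the
        lowest objective wins (default 1: a single run).
    """
    X = _as_matrix(features)
    p = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(
            f"k={k} exceeds the number of feature vectors p={p}; "
            "decrease k or produce more groups (e.g. a smaller m)"
        )
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    best: ClusterModel | None = None
    for _ in range(restarts):
        model = _lloyd(X, k, rng, max_iter)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    return best


def propagate_labels(
    groups: Sequence[Group], model: ClusterModel, reads: ReadSet
) -> AssignmentTable:
    """Assign every read the cluster of its containing group."""
    if len(model.labels) != len(groups):
        raise ValueError("model does not label every group")
    cluster_of_read: dict[int, int] = {}
    for g in groups:
        c = int(model.labels[g.index])
        for i in g.members:
            cluster_of_read[i] = c
    if len(cluster_of_read) != len(reads):
        raise ValueError("groups do not cover every read")
    return AssignmentTable(
        (reads[i].id, cluster_of_read[i]) for i in range(len(reads))
    )


def write_model(model: ClusterModel, path_means, path_labels) -> None:
    """Dump cluster means and group labels as TSV."""
    with open(path_means, "w") as fh:
        for j in range(model.k):
            row = "\t".join(format(v, ".10g") for v in model.means[j])
            fh.write(f"{j}\t{row}\n")
    with open(path_labels, "w") as fh:
        for i, c in enumerate(model.labels):
            fh.write(f"{i}\t{int(c)}\n")
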