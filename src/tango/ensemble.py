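"""Model-vs-model ensemble analysis.

All pairwise global MCQ values form a symmetric dissimilarity matrix which
feeds three downstream views: a classical (Torgerson–Gower) MDS embedding
into the plane, PAM k-medoids clustering operating directly on the matrix,
and an average-linkage (UPGMA) dendrogram.

Classical MDS double-centers the squared dissimilarities,
B = −½ · J · D∘D · J with J = I − 11ᵀ/n, eigendecomposes B and embeds on
the top eigenvectors scaled by the square roots of their eigenvalues.
MCQ values are angular, not Euclidean, so negative eigenvalues can occur;
they are clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .comparison import DEFAULT_ANGLES, global_mcq, pair_residues
from .errors import ConfigError, MatrixError
from .model import NucleicChain
from .torsion_core import AngleKind, chain_torsions

__all__ = [
    "DissimilarityMatrix",
    "MdsEmbedding",
    "ClusterAssignment",
    "Dendrogram",
    "dissimilarity_matrix",
    "classical_mds",
    "k_medoids",
    "dendrogram",
]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # (n, n) degrees; NaN = undefined entry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise MatrixError("dissimilarity matrix must be square and match labels")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def require_defined(self) -> np.ndarray:
        if np.isnan(self.values).any():
            raise MatrixError(
                "dissimilarity matrix has undefined entries; downstream "
                "analyses require a fully defined matrix"
            )
        return self.values


@dataclass
class MdsEmbedding:
    labels: list[str]
    coords: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray  # the eigenvalues used (after clamping)
    degenerate: bool = False  # n < 3: the embedding is a line at best


@dataclass
class ClusterAssignment:
    k: int
    labels: list[str]
    medoid_indices: list[int]
    assignment: np.ndarray  # (n,) cluster index = position in medoid_indices
    total_cost: float

    @property
    def medoid_labels(self) -> list[str]:
        return [self.labels[i] for i in self.medoid_indices]


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (average/UPGMA)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize as newick; branch lengths follow the UPGMA ultrametric
        (every leaf sits at depth height/2 below its subtree root)."""
        tree = sch.to_tree(self.linkage)

        def clean(label: str) -> str:
            return "".join("_" if ch in "(),:; \t\n" else ch for ch in label)

        def rec(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{clean(self.labels[node.id])}:{parent_height / 2.0:.6f}"
            left = rec(node.get_left(), node.dist)
            right = rec(node.get_right(), node.dist)
            bl = (parent_height - node.dist) / 2.0
            return f"({left},{right}):{bl:.6f}"

        if tree.is_leaf():
            return f"{clean(self.labels[tree.id])}:0.000000;"
        left = rec(tree.get_left(), tree.dist)
        right = rec(tree.get_right(), tree.dist)
        return f"({left},{right});"


def dissimilarity_matrix(
    models: Sequence[NucleicChain],
    sel: Sequence[AngleKind] = DEFAULT_ANGLES,
    labels: Optional[Sequence[str]] = None,
) -> DissimilarityMatrix:
    """All-pairs global MCQ matrix over ``models``.

    Pairing between each pair of chains is by sequence LCS.  A pair with an
    empty pairing (or no defined differences) yields a NaN entry plus a
    warning; the diagonal is exactly zero.
    """
    if len(models) < 2:
        raise ConfigError("at least two models are required")
    if labels is None:
        labels = [f"model_{i + 1}" for i in range(len(models))]
    labels = list(labels)
    if len(labels) != len(models):
        raise ConfigError("labels must match the number of models")
    torsions = [chain_torsions(m) for m in models]
    seqs = [m.sequence for m in models]
    n = len(models)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairing = pair_residues(seqs[i], seqs[j])
            g = global_mcq(torsions[i], torsions[j], pairing, sel)
            if not g.defined:
                warnings.warn(
                    f"no comparable residues between {labels[i]!r} and "
                    f"{labels[j]!r}; entry left undefined",
                    stacklevel=2,
                )
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = g.degrees
    return DissimilarityMatrix(labels=labels, values=values)


def classical_mds(m: DissimilarityMatrix, dims: int = 2) -> MdsEmbedding:
    """Torgerson–Gower scaling of a dissimilarity matrix into ``dims`` axes."""
    d = m.require_defined()
    n = m.n
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1][:dims]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    coords = coords - coords.mean(axis=0)
    return MdsEmbedding(
        labels=list(m.labels),
        coords=coords,
        eigenvalues=lam,
        degenerate=n < 3,
    )


def _assignment_cost(d: np.ndarray, medoids: Sequence[int]) -> tuple[np.ndarray, float]:
    dist = d[:, list(medoids)]
    assign = np.argmin(dist, axis=1)
    return assign, float(dist[np.arange(len(d)), assign].sum())


def _build_init(d: np.ndarray, k: int, first: Optional[int] = None) -> list[int]:
    # Greedy BUILD: start from `first` (default: the 1-medoid optimum), then
    # add the point that most reduces total cost; ties resolved by the
    # smallest index (argmin).
    n = len(d)
    medoids = [int(np.argmin(d.sum(axis=1))) if first is None else int(first)]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        costs = np.array(
            [
                np.minimum(nearest, d[:, j]).sum() if j not in medoids else np.inf
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmin(costs)))
    return medoids


def _swap_descent(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    medoids = list(medoids)
    _, cost = _assignment_cost(d, medoids)
    n = len(d)
    while True:
        best = None
        for mi, med in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                _, c = _assignment_cost(d, trial)
                if c < cost - 1e-12 and (best is None or c < best[0]):
                    best = (c, mi, h)
        if best is None:
            return medoids, cost
        cost, mi, h = best
        medoids[mi] = h


def k_medoids(
    m: DissimilarityMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 0,
) -> ClusterAssignment:
    """PAM clustering on the dissimilarity matrix.

    Deterministic multi-start: a greedy BUILD initialization is seeded from
    every point in turn and refined by steepest-descent SWAP passes (cost
    never increases); the best run wins, ties going to the first start.
    Single-start PAM is easily trapped in local optima on small non-metric
    matrices; seeding BUILD from each point removes that failure mode while
    staying deterministic.  ``n_restarts`` optional random
    re-initializations use ``seed``; the default 0 keeps the result fully
    deterministic.
    """
    d = m.require_defined()
    n = m.n
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} must be in [1, {n}]")
    medoids, cost = _swap_descent(d, _build_init(d, k))
    for first in range(n):
        cand, c = _swap_descent(d, _build_init(d, k, first))
        if c < cost - 1e-12:
            medoids, cost = cand, c
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init = list(rng.choice(n, size=k, replace=False))
        cand, c = _swap_descent(d, init)
        if c < cost - 1e-12:
            medoids, cost = cand, c
    medoids = sorted(medoids)
    assign, cost = _assignment_cost(d, medoids)
    return ClusterAssignment(
        k=k,
        labels=list(m.labels),
        medoid_indices=medoids,
        assignment=assign,
        total_cost=cost,
    )


def dendrogram(m: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering of the matrix."""
    d = m.require_defined()
    condensed = squareform(d, checks=False)
    z = sch.linkage(condensed, method="average")
    return Dendrogram(labels=list(m.labels), linkage=z)
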