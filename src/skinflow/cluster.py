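"""Experiment-level clustering: centered PCA, Chebyshev complete linkage,
and optimal leaf ordering ("swiveling").

Samples are observations and genes are features.  PCA is centered but
unscaled; hierarchical clustering runs on the leading component scores
with complete linkage under the Chebyshev (max-coordinate) distance, and
the dendrogram's subtree flips are chosen to minimise the sum of
distances between adjacent leaves (exact dynamic program).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA


def pca_samples(transformed: pd.DataFrame, n_components: int = 6) -> pd.DataFrame:
    """Centered, unscaled PCA scores of samples.

    ``transformed`` is genes x samples (log2 scale); rows of the result
    are samples, columns the first ``min(n_components, n_samples - 1)``
    principal component scores.  Features (genes) are centered but not
    scaled to unit variance.
    """
    X = transformed.to_numpy().T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("need at least two samples for PCA")
    k = min(n_components, X.shape[0] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return pd.DataFrame(
        scores,
        index=transformed.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )


def chebyshev_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Chebyshev (max absolute coordinate difference) distances."""
    d = cdist(scores.to_numpy(), scores.to_numpy(), metric="chebyshev")
    return pd.DataFrame(d, index=scores.index, columns=scores.index)


@dataclass
class _Node:
    id: int
    height: float
    left: "_Node | None" = None
    right: "_Node | None" = None
    leaves: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class Dendrogram:
    """Complete-linkage merge tree with an optimised leaf order."""

    labels: list[str]
    root: _Node
    merges: list[tuple[int, int, float]]  # (cluster a, cluster b, height)
    leaf_order: list[int]
    distances: np.ndarray  # leaf-leaf distance matrix used for ordering

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def adjacency_objective(self, order: list[int] | None = None) -> float:
        """Sum of distances between adjacent leaves of an order."""
        order = self.leaf_order if order is None else order
        return float(
            sum(
                self.distances[order[i], order[i + 1]]
                for i in range(len(order) - 1)
            )
        )


def hclust_cheb(scores: pd.DataFrame) -> Dendrogram:
    """Complete-linkage hierarchical clustering with Chebyshev distance.

    Agglomeration ties are broken toward the lowest cluster-index pair for
    determinism; leaf order is then optimised by exact dynamic programming
    over subtree flips.
    """
    labels = list(scores.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    dist = cdist(scores.to_numpy(), scores.to_numpy(), metric="chebyshev")

    nodes: dict[int, _Node] = {
        i: _Node(id=i, height=0.0, leaves=[i]) for i in range(n)
    }
    cluster_dist = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        (a, b), h = min(
            ((pair, d) for pair, d in cluster_dist.items()),
            key=lambda kv: (kv[1], kv[0]),
        )
        new = _Node(
            id=next_id,
            height=h,
            left=nodes[a],
            right=nodes[b],
            leaves=nodes[a].leaves + nodes[b].leaves,
        )
        merges.append((a, b, h))
        active -= {a, b}
        # complete linkage: distance to the merged cluster is the max
        for c in active:
            da = cluster_dist.pop((min(a, c), max(a, c)))
            db = cluster_dist.pop((min(b, c), max(b, c)))
            cluster_dist[(min(c, next_id), max(c, next_id))] = max(da, db)
        del cluster_dist[(a, b)]
        nodes[next_id] = new
        active.add(next_id)
        next_id += 1

    root = nodes[next_id - 1]
    order = optimal_leaf_order(root, dist)
    return Dendrogram(
        labels=labels, root=root, merges=merges, leaf_order=order, distances=dist
    )


def optimal_leaf_order(root: _Node, dist: np.ndarray) -> list[int]:
    """Exact optimal leaf ordering by DP over subtree end-leaves.

    For each subtree, computes the minimal internal adjacency cost for
    every achievable (first leaf, last leaf) pair; merging two subtrees
    adds the distance between the inner boundary leaves.  The returned
    order minimises the sum of adjacent-leaf distances over all flip
    configurations of the tree.
    """

    # table: node id -> {(first, last): (cost, backpointer)}
    table: dict[int, dict[tuple[int, int], tuple[float, tuple | None]]] = {}

    def solve(node: _Node) -> None:
        if node.is_leaf:
            table[node.id] = {(node.id, node.id): (0.0, None)}
            return
        solve(node.left)
        solve(node.right)
        out: dict[tuple[int, int], tuple[float, tuple]] = {}
        for first_child, second_child in (
            (node.left, node.right),
            (node.right, node.left),
        ):
            for (fa, la), (ca, _) in table[first_child.id].items():
                for (fb, lb), (cb, _) in table[second_child.id].items():
                    cost = ca + cb + dist[la, fb]
                    key = (fa, lb)
                    if key not in out or cost < out[key][0]:
                        out[key] = (cost, (first_child.id, (fa, la), (fb, lb)))
        table[node.id] = out

    def backtrack(node: _Node, key: tuple[int, int]) -> list[int]:
        if node.is_leaf:
            return [node.id]
        _, bp = table[node.id][key]
        first_id, key_a, key_b = bp
        if first_id == node.left.id:
            first, second = node.left, node.right
        else:
            first, second = node.right, node.left
        return backtrack(first, key_a) + backtrack(second, key_b)

    solve(root)
    best_key = min(table[root.id], key=lambda k: (table[root.id][k][0], k))
    return backtrack(root, best_key)


def to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths = merge-height differences.

    Children are written in the optimised leaf order.
    """
    pos = {leaf: i for i, leaf in enumerate(dend.leaf_order)}

    def render(node: _Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{dend.labels[node.id]}:{length:.10g}"
        left, right = node.left, node.right
        # orient children to match the optimised order
        if min(pos[l] for l in left.leaves) > min(pos[l] for l in right.leaves):
            left, right = right, left
        return (
            f"({render(left, node.height)},{render(right, node.height)})"
            f":{length:.10g}"
        )

    root = dend.root
    body = render(root, root.height)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"
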