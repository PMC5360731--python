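"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, closed forms, graph
walks) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive local alignment (affine gaps)


def brute_force_local_score(a, b, matrix, gap_open=10.0, gap_extend=1.0):
    """Best local alignment score by enumerating every alignment path.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend``. Exponential — only for tiny sequences.
    """
    best = 0.0

    def rec(i, j, state, score):
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "A", score - (gap_extend if state == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", score - (gap_extend if state == "B" else gap_open))

    for i in range(len(a)):
        for j in range(len(b)):
            rec(i, j, None, 0.0)
    return best


# ---------------------------------------------------------------------------
# random additive trees and a least-squares topology oracle


class AdditiveTree:
    """Random unrooted binary tree with positive branch lengths."""

    def __init__(self, n_leaves: int, rng: np.random.Generator):
        self.adj: dict[str, dict[str, float]] = {}
        self._next_internal = 0
        c = self._new_internal()
        leaves = [f"T{k + 1}" for k in range(n_leaves)]
        for leaf in leaves[:3]:
            self._add_edge(c, leaf, rng.uniform(0.1, 1.0))
        for leaf in leaves[3:]:
            edges = [
                (u, v) for u in self.adj for v in self.adj[u] if u < v
            ]
            u, v = edges[rng.integers(len(edges))]
            length = self.adj[u][v]
            w = self._new_internal()
            t = rng.uniform(0.2, 0.8)
            self._del_edge(u, v)
            self._add_edge(u, w, length * t)
            self._add_edge(w, v, length * (1 - t))
            self._add_edge(w, leaf, rng.uniform(0.1, 1.0))
        self.leaves = leaves

    def _new_internal(self) -> str:
        self._next_internal += 1
        return f"_i{self._next_internal}"

    def _add_edge(self, u, v, length):
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    def _del_edge(self, u, v):
        del self.adj[u][v]
        del self.adj[v][u]

    def distance_matrix(self) -> np.ndarray:
        n = len(self.leaves)
        d = np.zeros((n, n))
        for i, leaf in enumerate(self.leaves):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v, length in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + length
                        stack.append(v)
            for j, other in enumerate(self.leaves):
                d[i, j] = dist[other]
        return d

    def edges_with_sides(self):
        """(side leaf-set frozenset, length) for every edge."""
        out = []
        for u in self.adj:
            for v, length in self.adj[u].items():
                if u > v:
                    continue
                side = self._leaves_beyond(v, u)
                out.append((frozenset(side), length))
        return out

    def _leaves_beyond(self, start, blocked):
        seen, stack, found = {blocked, start}, [start], []
        while stack:
            u = stack.pop()
            if not u.startswith("_i"):
                found.append(u)
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return found

    def canonical_splits(self):
        """{canonical side: length} for internal edges plus pendant lengths."""
        leaves = set(self.leaves)
        first = min(leaves)
        internal, pendant = {}, {}
        for side, length in self.edges_with_sides():
            if len(side) == 1:
                pendant[next(iter(side))] = length
            elif len(side) == len(leaves) - 1:
                pendant_leaf = next(iter(leaves - side))
                pendant[pendant_leaf] = length
            else:
                key = frozenset(leaves - side) if first in side else side
                internal[key] = length
        return internal, pendant


def phylo_tree_splits(ptree):
    """Same (internal, pendant) decomposition for a fitted PhyloTree."""
    leaves = set(ptree.leaf_labels)
    first = min(leaves)
    internal, pendant = {}, {}
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        length = node.edge.length or 0.0
        if len(side) == 1:
            pendant[next(iter(side))] = length
        elif len(side) == len(leaves) - 1:
            pendant[next(iter(leaves - side))] = length
        else:
            key = frozenset(leaves - side) if first in side else side
            internal[key] = length
    return internal, pendant


def least_squares_topology_4(ids, d):
    """Best 4-taxon topology by OLS branch-length fit over all three.

    Returns the canonical frozenset of the winning cherry not containing
    the smallest id, or None for a star (all residuals equal).
    """
    a, b, c, e = range(4)
    pairs = list(itertools.combinations(range(4), 2))
    y = np.array([d[i, j] for i, j in pairs])
    best = (np.inf, None)
    for cherry in ([a, b], [a, c], [a, e]):
        other = [k for k in range(4) if k not in cherry]
        # params: 4 pendant lengths + internal edge
        X = np.zeros((6, 5))
        for row, (i, j) in enumerate(pairs):
            X[row, i] = X[row, j] = 1.0
            same = ({i, j} == set(cherry)) or ({i, j} == set(other))
            if not same:
                X[row, 4] = 1.0
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = float(((X @ coef - y) ** 2).sum())
        if resid < best[0] - 1e-12:
            side = frozenset(ids[k] for k in other)
            best = (resid, side)
    return best[1]


# ---------------------------------------------------------------------------
# naive average-linkage agglomeration


def naive_average_linkage_merges(dist: np.ndarray):
    """Merge sequence [(cluster_a, cluster_b, height), ...] as frozensets.

    Unweighted average linkage (UPGMA-style distance update) computed by
    re-averaging the full pairwise matrix at every step.
    """
    n = dist.shape[0]
    clusters = {k: frozenset([k]) for k in range(n)}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = (np.inf, None, None)
        for a, b in itertools.combinations(keys, 2):
            h = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        merges.append((clusters[a], clusters[b], h))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return merges
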