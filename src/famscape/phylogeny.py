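"""Distance-based phylogeny and anchor-guided group assignment.

p-distances (pairwise gap deletion) from a protein alignment feed a
neighbor-joining tree; family members are then labelled by their nearest
functionally characterized anchor sequence, with a monophyly audit per label.
No substitution-model correction is applied by default — the family is
analysed at the p-distance level, the simplest defensible choice when no
model is prescribed.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "MSA",
    "DistanceMatrix",
    "PhyloTree",
    "GroupAssignment",
    "pairwise_distance",
    "neighbor_joining",
    "assign_groups",
]


@dataclass
class MSA:
    """A protein multiple alignment: unique ids, equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        for i, r in zip(self.ids, self.rows):
            if not r.replace("-", ""):
                raise ValueError(f"{i}: row is all gaps")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    def subset(self, ids) -> "MSA":
        return MSA(list(ids), [self.row(i) for i in ids])

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")
        self.values = v


def pairwise_distance(msa: MSA) -> DistanceMatrix:
    """p-distance with pairwise gap deletion.

    For each pair, columns with a gap in either row are excluded; the
    distance is mismatches / compared columns. A pair with no comparable
    columns is an error naming the pair.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.frombuffer(
        "".join(msa.rows).encode(), dtype="S1"
    ).reshape(len(msa), msa.n_columns)
    gap = arr == b"-"
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~gap[i] & ~gap[j]
            nv = int(valid.sum())
            if nv == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            mism = int(((arr[i] != arr[j]) & valid).sum())
            d[i, j] = d[j, i] = mism / nv
    return DistanceMatrix(list(msa.ids), d)


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths, wrapping a dendropy tree."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".6f",
        ).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(
            dendropy.Tree.get(data=text, schema="newick")
        )

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length (sum of branch lengths) distances between leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(self.leaf_labels)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
        return DistanceMatrix(labels, d)

    def edge_sides(self) -> set[frozenset]:
        """Leaf sets below each edge (one side of every bipartition)."""
        sides = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            sides.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
        return sides

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized to the side not
        containing the lexicographically smallest leaf."""
        leaves = set(self.leaf_labels)
        first = min(leaves)
        out = set()
        for side in self.edge_sides():
            if not 1 < len(side) < len(leaves) - 1:
                continue
            if first in side:
                side = frozenset(leaves - side)
            out.add(side)
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou–Nei) with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (m−2)·d(i,j) − r_i − r_j is
    joined; among equal Q the pair with the smallest (i, j) position in the
    current node order wins. Branch lengths follow the standard formulas;
    negative lengths are clamped to zero and the deficit logged. Requires
    ≥ 3 taxa (two taxa form a trivial single-edge tree via a separate path).
    """
    ids = list(dm.ids)
    n = len(ids)
    taxa = dendropy.TaxonNamespace(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        seed = dendropy.Node()
        for label in ids:
            child = dendropy.Node(taxon=taxa.get_taxon(label))
            child.edge.length = dm.values[0, 1] / 2.0
            seed.add_child(child)
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
        tree.is_rooted = False
        return PhyloTree(tree)

    nodes = [dendropy.Node(taxon=taxa.get_taxon(label)) for label in ids]
    D = dm.values.copy()
    active = list(range(n))

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            logger.info("NJ: clamped negative branch %.6g on %s|%s", x, a, b)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: smallest (i, j) among ties
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li, str(i), str(j))
        nodes[j].edge.length = clamp(lj, str(j), str(i))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_d = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_d
        D[active, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    center = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = clamp(length, str(idx), "center")
        center.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree)


@dataclass
class GroupAssignment:
    """Nearest-anchor group labels with ties and monophyly audit."""

    assignments: dict[str, str]
    anchors: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)
    ties: list[str] = field(default_factory=list)
    monophyly_violations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts:
            for label in self.assignments.values():
                self.counts[label] = self.counts.get(label, 0) + 1


def assign_groups(tree: PhyloTree, anchors: Mapping[str, str]) -> GroupAssignment:
    """Label each non-anchor leaf with its nearest anchor's group.

    Nearness is path length (sum of branch lengths). A leaf equidistant
    (within 1e-9) to anchors of two labels takes the lexicographically
    smaller label and is flagged as a tie. For every label, monophyly of
    {anchors + assigned leaves} is audited and violations reported.
    """
    if not anchors:
        raise ValueError("at least one anchor is required")
    leaves = set(tree.leaf_labels)
    missing = sorted(set(anchors) - leaves)
    if missing:
        raise ValueError(f"anchors missing from tree: {missing}")

    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    anchor_items = sorted(anchors.items())
    assignments: dict[str, str] = {}
    ties: list[str] = []
    for leaf in sorted(leaves - set(anchors)):
        best_label, best_d = None, np.inf
        tied = False
        for aid, label in anchor_items:
            d = pdm.distance(taxa[leaf], taxa[aid])
            if d < best_d - 1e-9:
                best_label, best_d, tied = label, d, False
            elif abs(d - best_d) <= 1e-9 and label != best_label:
                tied = True
                if label < best_label:
                    best_label = label
        assignments[leaf] = best_label
        if tied:
            ties.append(leaf)

    sides = tree.edge_sides()
    all_leaves = frozenset(leaves)
    violations = []
    for label in sorted(set(anchors.values())):
        group = frozenset(
            [a for a, lb in anchors.items() if lb == label]
            + [g for g, lb in assignments.items() if lb == label]
        )
        if len(group) <= 1 or group == all_leaves:
            continue
        if group not in sides and (all_leaves - group) not in sides:
            violations.append(label)
    return GroupAssignment(
        assignments=assignments,
        anchors=dict(anchors),
        ties=ties,
        monophyly_violations=violations,
    )
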