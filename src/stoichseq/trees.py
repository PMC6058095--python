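"""Phylogenetic trees: neighbor joining, corrected protein distances,
and newick interchange.

Trees are stored rooted for traversal convenience but represent
unrooted phylogenies: the root is an arbitrary (usually trifurcating)
internal node and, under a reversible substitution model, likelihoods
do not depend on its placement.  Branch lengths are expected
substitutions per site.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "TreeNode",
    "Tree",
    "protein_distance",
    "pairwise_distance_matrix",
    "nj_tree",
    "MAX_DISTANCE",
]

#: Saturation value for pairwise distances whose mismatch fraction
#: exceeds the Poisson-correction domain.
MAX_DISTANCE = 10.0


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0            # branch above this node; 0 at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self


@dataclass
class Tree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.postorder() if n.is_leaf]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    # -- interchange ------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(render(c) for c in node.children)
            label = node.name or ""
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon else None,
                length=float(dnode.edge.length or 0.0),
            )
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        root = convert(dtree.seed_node)
        root.length = 0.0
        return cls(root=root)

    # -- analysis helpers -------------------------------------------------

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-canonical
        leaf set of one side; topology comparison for unrooted trees."""
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset[str]] = set()

        def collect(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(collect(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        for child in self.root.children:
            collect(child)
        return out

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def below(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            per_child = [
                {k: v + c.length for k, v in below(c).items()} for c in node.children
            ]
            for da, db in itertools.combinations(per_child, 2):
                for i, di in da.items():
                    for j, dj in db.items():
                        dist[i, j] = dist[j, i] = di + dj
            merged: dict[int, float] = {}
            for d in per_child:
                merged.update(d)
            return merged

        below(self.root)
        return names, dist


# ---------------------------------------------------------------------------
# Distances


def protein_distance(row_i: str, row_j: str, max_distance: float = MAX_DISTANCE) -> float:
    """Poisson-corrected amino-acid distance between two aligned rows.

    With ``p`` the mismatch fraction over sites where both rows carry a
    residue, d = -(19/20) ln(1 - (20/19) p): the 20-state analogue of
    the Jukes-Cantor correction.  At p >= 0.95 the correction diverges
    and the distance saturates at ``max_distance`` with a warning.
    """
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows must have equal length")
    shared = mismatch = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a == "-" or b == "-":
            continue
        shared += 1
        if a != b:
            mismatch += 1
    if shared == 0:
        raise ValueError("no shared ungapped sites between rows")
    p = mismatch / shared
    if p >= 19 / 20:
        warnings.warn(
            f"mismatch fraction {p:.3f} saturates the Poisson correction; "
            f"capping distance at {max_distance}",
            stacklevel=2,
        )
        return max_distance
    return -(19 / 20) * float(np.log(1.0 - (20 / 19) * p))


def pairwise_distance_matrix(rows: list[str], max_distance: float = MAX_DISTANCE) -> np.ndarray:
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(rows[i], rows[j], max_distance)
    return d


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(names: list[str], distances: np.ndarray) -> Tree:
    """Saitou-Nei neighbor joining.

    Agglomerates the pair minimizing the Q criterion
    ``Q_ij = (n-2) d_ij - r_i - r_j`` (r = row sums), with the standard
    branch-length formulas; negative branch lengths are clamped to 0.
    No subsequent branch-length optimization is applied — NJ lengths
    are final.  The returned tree is unrooted, represented with a
    trifurcating root (a single edge for two taxa).
    """
    d = np.asarray(distances, dtype=float).copy()
    n = len(names)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distances must be symmetric, non-negative, zero-diagonal")

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    if n == 2:
        half = d[0, 1] / 2
        nodes[0].length = nodes[1].length = half
        return Tree(root=TreeNode(children=nodes))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    return Tree(root=TreeNode(children=[nodes[i], nodes[j], nodes[k]]))
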