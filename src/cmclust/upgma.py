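"""UPGMA average-linkage hierarchical clustering with Newick output.

The baseline against which chaotic map clustering is compared.  At each
step the two clusters at smallest average-linkage distance are merged;
the distance between clusters A and B is the arithmetic mean of all
leaf-pair distances d(x, y), x in A, y in B (size-weighted "true" UPGMA,
not WPGMA).  The merge node sits at height d/2, so the tree is rooted
and ultrametric.  Ties are broken on the lexicographically smallest
(cluster, cluster) label pair so trees are reproducible across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import LabeledSquareMatrix

__all__ = ["UPGMANode", "upgma_tree", "to_newick", "write_newick", "cophenetic_distances"]


@dataclass(frozen=True)
class UPGMANode:
    """A rooted subtree: leaves have a label and height 0, internal nodes
    carry two children and the merge height (half the linkage distance)."""

    height: float
    label: str | None = None
    children: tuple["UPGMANode", ...] = ()
    # lexicographically smallest leaf label below this node; used for
    # deterministic tie-breaking and canonical child ordering
    min_label: str = field(default="", compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def upgma_tree(D: LabeledSquareMatrix) -> UPGMANode:
    """Build the UPGMA tree of a distance matrix.

    Linkage distances after a merge follow the size-weighted update
    d(A+B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|), which keeps
    d(.,.) equal to the mean over all leaf pairs.
    """
    if D.kind != "distance":
        raise ValueError("upgma_tree expects a distance matrix")
    if D.n < 2:
        raise ValueError("need at least two items")
    if np.isnan(D.values).any():
        raise ValueError("distance matrix contains NaN")

    active: dict[int, UPGMANode] = {
        i: UPGMANode(0.0, label=l, min_label=l) for i, l in enumerate(D.labels)
    }
    sizes: dict[int, int] = {i: 1 for i in range(D.n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(D.n):
        for j in range(i + 1, D.n):
            dist[(i, j)] = float(D.values[i, j])
    next_id = D.n

    def pair_key(i: int, j: int) -> tuple[str, str]:
        a, b = active[i].min_label, active[j].min_label
        return (a, b) if a < b else (b, a)

    while len(active) > 1:
        (i, j), dmin = min(
            dist.items(), key=lambda kv: (kv[1], pair_key(*kv[0]))
        )
        a, b = active.pop(i), active.pop(j)
        children = (a, b) if a.min_label < b.min_label else (b, a)
        node = UPGMANode(
            dmin / 2.0, children=children, min_label=children[0].min_label
        )
        na, nb = sizes.pop(i), sizes.pop(j)
        new_dist = {}
        for k in active:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_dist[(min(k, next_id), max(k, next_id))] = (
                na * dik + nb * djk
            ) / (na + nb)
        del dist[(i, j)]
        dist.update(new_dist)
        active[next_id] = node
        sizes[next_id] = na + nb
        next_id += 1
    return next(iter(active.values()))


def to_newick(tree: UPGMANode, precision: int = 10) -> str:
    """Newick string with branch lengths parent_height - child_height."""

    def render(node: UPGMANode, parent_height: float) -> str:
        length = parent_height - node.height
        blen = f"{length:.{precision}g}"
        if node.is_leaf:
            return f"{node.label}:{blen}"
        inner = ",".join(render(ch, node.height) for ch in node.children)
        return f"({inner}):{blen}"

    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(render(ch, tree.height) for ch in tree.children)
    return f"({inner});"


def write_newick(tree: UPGMANode, path, precision: int = 10) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, precision) + "\n")


def cophenetic_distances(tree: UPGMANode, labels: list[str] | None = None) -> LabeledSquareMatrix:
    """Leaf-pair distances implied by the tree: 2 x height of the LCA.

    For an ultrametric input matrix the cophenetic matrix reproduces the
    input exactly; in general it is the UPGMA approximation of it.
    """
    if labels is None:
        labels = sorted(tree.leaves())
    index = {l: k for k, l in enumerate(labels)}
    n = len(labels)
    coph = np.zeros((n, n))

    def walk(node: UPGMANode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        below: list[list[str]] = [walk(ch) for ch in node.children]
        for gi in range(len(below)):
            for gj in range(gi + 1, len(below)):
                for la in below[gi]:
                    for lb in below[gj]:
                        coph[index[la], index[lb]] = coph[index[lb], index[la]] = (
                            2.0 * node.height
                        )
        return [l for grp in below for l in grp]

    walk(tree)
    return LabeledSquareMatrix(tuple(labels), coph, "distance")
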