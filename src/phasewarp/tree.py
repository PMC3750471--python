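"""Rooted ultrametric trees (dendrograms) with Newick export.

UPGMA produces rooted binary trees in which every internal node carries a
height equal to half the merge distance of its two subclusters, so the
cophenetic distance between any two leaves is twice the height of their
lowest common ancestor.  Nodes may additionally carry a jackknife support
percentage.  Topologies are compared through their informative bipartitions
(splits), the standard representation that is stable under re-rooting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterator, List, Optional, Tuple

import numpy as np

Split = FrozenSet[FrozenSet[str]]


@dataclass
class TreeNode:
    """One node of a dendrogram: a leaf (label set) or an internal merge."""

    height: float = 0.0
    label: Optional[str] = None
    children: Tuple["TreeNode", ...] = ()
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Depth-first traversal, parents before children."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_labels(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        return [lab for c in self.children for lab in c.leaf_labels()]


@dataclass
class Dendrogram:
    """A rooted tree with ultrametric node heights and optional supports."""

    root: TreeNode
    taxa: FrozenSet[str] = field(init=False)

    def __post_init__(self) -> None:
        self.taxa = frozenset(self.root.leaf_labels())

    def leaf_labels(self) -> List[str]:
        return self.root.leaf_labels()

    def internal_nodes(self, include_root: bool = True) -> List[TreeNode]:
        nodes = [n for n in self.root.walk() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def clades(self, include_root: bool = False) -> List[FrozenSet[str]]:
        """Leaf sets of internal nodes (root excluded by default)."""
        return [
            frozenset(n.leaf_labels())
            for n in self.internal_nodes(include_root=include_root)
        ]

    def splits(self) -> set:
        """Informative bipartitions: both sides have >= 2 taxa."""
        out = set()
        for clade in self.clades(include_root=False):
            other = self.taxa - clade
            if len(clade) >= 2 and len(other) >= 2:
                out.add(frozenset((clade, other)))
        return out

    def cophenetic_matrix(self, labels: Optional[List[str]] = None) -> np.ndarray:
        """Pairwise cophenetic distances (2 x LCA height), in label order."""
        if labels is None:
            labels = self.leaf_labels()
        index = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))

        def recurse(node: TreeNode) -> List[str]:
            if node.is_leaf:
                return [node.label]
            groups = [recurse(c) for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for la in groups[a]:
                        for lb in groups[b]:
                            i, j = index[la], index[lb]
                            mat[i, j] = mat[j, i] = 2.0 * node.height
            return [lab for g in groups for lab in g]

        recurse(self.root)
        return mat

    def to_newick(self, include_support: bool = False) -> str:
        """Newick with branch lengths (parent height - child height).

        With ``include_support``, internal-node jackknife percentages are
        written as internal node labels.
        """
        def fmt(x: float) -> str:
            return repr(round(float(x), 10))

        def render(node: TreeNode, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                text = node.label
            else:
                inner = ",".join(render(c, node.height) for c in node.children)
                text = f"({inner})"
                if include_support and node.support is not None:
                    sup = node.support
                    text += fmt(sup) if sup != int(sup) else str(int(sup))
            if parent_height is not None:
                text += f":{fmt(parent_height - node.height)}"
            return text

        return render(self.root, None) + ";"


def robinson_foulds(a: Dendrogram, b: Dendrogram) -> int:
    """Robinson-Foulds distance: symmetric difference of informative splits.

    Both trees must be over the same taxon set.
    """
    if a.taxa != b.taxa:
        raise ValueError("trees are over different taxon sets")
    return len(a.splits() ^ b.splits())


def restricted_split(split: Split, surviving: FrozenSet[str]) -> Optional[Split]:
    """Restrict a bipartition to surviving taxa; None if uninformative."""
    sides = [side & surviving for side in split]
    if len(sides) != 2 or min(len(s) for s in sides) < 2:
        return None
    return frozenset(frozenset(s) for s in sides)
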