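"""Distance-matrix construction, UPGMA clustering and OTU-jackknife support.

The pairwise DTW distances of a signal set form a symmetric zero-diagonal
matrix which is min-max normalized to [0, 1] — the raw distance scale has no
physical meaning for the dendrogram, only the relative similarities matter.
UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the closest pair of clusters, updating distances as the size-weighted mean
of member distances; node height is half the merge distance, so the tree is
ultrametric by construction.

Node robustness is assessed by OTU jackknifing: each replicate removes a
random number of taxa, rebuilds the tree from the *subset* of the
precomputed pairwise distances (taxon removal cannot change the remaining
pairwise DTW distances — unlike multiple alignment, where it can), and an
original node counts as recovered when its bipartition, restricted to the
surviving taxa, appears in the pseudotree.  Support is the percentage of
testable replicates in which the node was recovered.  Bootstrap resampling
of columns is deliberately not offered: the method's distances depend on
whole-signal trends, not exchangeable positions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Union

import numpy as np

from .dtw import dtw_distance
from .errors import ParameterError
from .signal_transform import GenomicSignal
from .tree import Dendrogram, TreeNode, restricted_split

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with taxon labels."""

    labels: List[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ParameterError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ParameterError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ParameterError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ParameterError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def subset(self, keep: Sequence[str]) -> "DistanceMatrix":
        """Matrix restricted to the given labels (in the given order)."""
        idx = [self.labels.index(lab) for lab in keep]
        return DistanceMatrix(
            labels=list(keep),
            values=self.values[np.ix_(idx, idx)],
            normalized=self.normalized,
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        """PHYLIP-like square format: label column + full symmetric matrix."""
        with open(path, "w") as handle:
            handle.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                handle.write(lab + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "DistanceMatrix":
        lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
        labels = lines[0].split("\t")[1:]
        rows = [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]]
        return cls(labels=labels, values=np.array(rows))


def pairwise_matrix(
    signals: Sequence[GenomicSignal], method: str = "path_cost"
) -> DistanceMatrix:
    """All n(n-1)/2 pairwise DTW distances of a preprocessed signal set.

    Defaults to the path-cost distance (accumulated cost / aligned length):
    unlike the warped-pair Euclidean form it cannot decrease under heavy
    warping, so it stays monotone in divergence — the property cluster
    analysis needs.  Pass ``method="warped_euclidean"`` for the warped-pair
    variant.
    """
    if len(signals) < 2:
        raise ParameterError("pairwise matrix needs at least 2 signals")
    labels = [s.source_id for s in signals]
    if len(set(labels)) != len(labels):
        raise ParameterError("signal source ids must be unique")
    n = len(signals)
    values = np.zeros((n, n))
    n_pairs = n * (n - 1) // 2
    logger.info("pairwise_matrix: %d signals, %d DTW alignments", n, n_pairs)
    for i, j in itertools.combinations(range(n), 2):
        dist = dtw_distance(signals[i], signals[j], method=method)
        values[i, j] = values[j, i] = dist
        logger.debug("DTW %s vs %s: %.6g", labels[i], labels[j], dist)
    return DistanceMatrix(labels=labels, values=values, normalized=False)


def normalize_matrix(m: DistanceMatrix) -> DistanceMatrix:
    """Min-max rescale the off-diagonal distances to [0, 1].

    The diagonal stays zero.  If all off-diagonal distances are equal they
    all map to 0 (with a logged warning) — degenerate but harmless.
    """
    mask = ~np.eye(m.n, dtype=bool)
    off = m.values[mask]
    lo, hi = off.min(), off.max()
    values = np.zeros_like(m.values)
    if hi == lo:
        logger.warning("normalize_matrix: all off-diagonal distances equal; "
                       "normalized matrix is all zeros")
    else:
        values[mask] = (m.values[mask] - lo) / (hi - lo)
    return DistanceMatrix(labels=list(m.labels), values=values, normalized=True)


def upgma(m: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal distance matrix.

    Merges the closest pair at each step (ties broken on the
    lexicographically smallest pair of cluster representative labels);
    distances to the merged cluster are the size-weighted arithmetic mean of
    the member distances; node height is half the merge distance.
    """
    if m.n < 2:
        raise ParameterError("UPGMA needs at least 2 taxa")
    # cluster id -> (node, size, representative label = smallest member)
    clusters: Dict[int, TreeNode] = {
        k: TreeNode(height=0.0, label=lab) for k, lab in enumerate(m.labels)
    }
    sizes = {k: 1 for k in clusters}
    reps = {k: lab for k, lab in enumerate(m.labels)}
    dist: Dict[frozenset, float] = {
        frozenset((i, j)): float(m.values[i, j])
        for i, j in itertools.combinations(range(m.n), 2)
    }
    next_id = m.n
    while len(clusters) > 1:
        def sort_key(pair):
            a, b = sorted(pair, key=lambda k: reps[k])
            return (dist[pair], reps[a], reps[b])

        best = min(dist, key=sort_key)
        a, b = sorted(best, key=lambda k: reps[k])
        merge_dist = dist[best]
        node = TreeNode(
            height=merge_dist / 2.0, children=(clusters[a], clusters[b])
        )
        for k in clusters:
            if k in (a, b):
                continue
            da = dist[frozenset((a, k))]
            db = dist[frozenset((b, k))]
            dist[frozenset((next_id, k))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        for k in list(dist):
            if a in k or b in k:
                del dist[k]
        clusters[next_id] = node
        sizes[next_id] = sizes[a] + sizes[b]
        reps[next_id] = min(reps[a], reps[b])
        for k in (a, b):
            del clusters[k], sizes[k], reps[k]
        next_id += 1
    return Dendrogram(root=next(iter(clusters.values())))


@dataclass
class JackknifeReport:
    """Per-node support from OTU-jackknife pseudotrees.

    ``supports`` maps each original informative clade (as a frozenset of
    taxon labels) to its support percentage; ``testable`` counts the
    replicates in which the node's restricted bipartition was informative.
    """

    supports: Dict[FrozenSet[str], float]
    testable: Dict[FrozenSet[str], int]
    recovered: Dict[FrozenSet[str], int]
    replicates: int
    seed: int
    scheme: str
    tree: Dendrogram = field(repr=False, default=None)

    def annotate(self, tree: Dendrogram) -> Dendrogram:
        """Attach support percentages to matching internal nodes."""
        for node in tree.internal_nodes(include_root=False):
            clade = frozenset(node.leaf_labels())
            support = self.supports.get(clade)
            if support is not None and not np.isnan(support):
                node.support = support
        return tree

    def write_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            handle.write(f"# replicates={self.replicates} seed={self.seed} "
                         f"scheme={self.scheme}\n")
            handle.write("clade\tsupport_pct\ttestable\trecovered\n")
            for clade in sorted(self.supports, key=lambda c: (len(c), sorted(c))):
                handle.write(
                    ",".join(sorted(clade))
                    + f"\t{self.supports[clade]:.6g}"
                    + f"\t{self.testable[clade]}"
                    + f"\t{self.recovered[clade]}\n"
                )


def jackknife_matrix(
    m: DistanceMatrix,
    replicates: int = 1000,
    seed: int = 0,
    fixed_removals: Optional[int] = None,
) -> JackknifeReport:
    """OTU jackknife over an existing pairwise distance matrix.

    Each replicate removes r taxa (r uniform on [1, n-3] unless
    ``fixed_removals`` pins it, e.g. 0 for a degenerate self-check), rebuilds
    the UPGMA tree from the subset matrix, and scores each original
    informative node by the recovery of its restricted bipartition.
    """
    n = m.n
    if n < 4:
        raise ParameterError("jackknife needs at least 4 taxa")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    # Removal draws use sorted labels so supports do not depend on the
    # input order of the taxa, only on the seed and the label set.
    canonical = sorted(m.labels)
    original = upgma(m)
    taxa = original.taxa
    node_splits = {}
    for node in original.internal_nodes(include_root=False):
        clade = frozenset(node.leaf_labels())
        other = taxa - clade
        if len(clade) >= 2 and len(other) >= 2:
            node_splits[clade] = frozenset((clade, other))
    testable = {c: 0 for c in node_splits}
    recovered = {c: 0 for c in node_splits}
    for _ in range(replicates):
        r = fixed_removals if fixed_removals is not None else int(
            rng.integers(1, n - 3 + 1)
        )
        removed = set(rng.choice(canonical, size=r, replace=False)) if r else set()
        surviving = [lab for lab in m.labels if lab not in removed]
        surviving_set = frozenset(surviving)
        pseudo = upgma(m.subset(surviving))
        pseudo_splits = pseudo.splits()
        for clade, split in node_splits.items():
            restricted = restricted_split(split, surviving_set)
            if restricted is None:
                continue
            testable[clade] += 1
            if restricted in pseudo_splits:
                recovered[clade] += 1
    supports = {
        c: (100.0 * recovered[c] / testable[c]) if testable[c] else float("nan")
        for c in node_splits
    }
    report = JackknifeReport(
        supports=supports,
        testable=testable,
        recovered=recovered,
        replicates=replicates,
        seed=seed,
        scheme=(f"uniform removals r in [1, {n - 3}]"
                if fixed_removals is None else f"fixed removals r={fixed_removals}"),
        tree=original,
    )
    report.annotate(original)
    return report


def jackknife(
    signals: Sequence[GenomicSignal],
    replicates: int = 1000,
    seed: int = 0,
    fixed_removals: Optional[int] = None,
) -> JackknifeReport:
    """OTU jackknife from preprocessed signals.

    Pairwise DTW distances are computed once and subset per replicate —
    removing a taxon cannot change the distances among the remaining ones.
    """
    m = normalize_matrix(pairwise_matrix(signals))
    return jackknife_matrix(
        m, replicates=replicates, seed=seed, fixed_removals=fixed_removals
    )
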