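"""Synthetic gene families for end-to-end testing without downloads.

The generator emulates the structure the signal-DTW method exploits in real
vertebrate gene sets: a gene is an alternation of **conserved exon blocks**
(identical trend across species, slowly accumulating point substitutions)
and **length-variable intron blocks** (non-coding spacers whose lengths
differ between species, shifting the conserved blocks along the sequence).
A root gene is evolved down a known tree.  Exon sites mutate with
probability 1 - exp(-rate * branch_length) per site (Jukes-Cantor-like:
uniform over the three alternative bases).  Introns evolve faster and
loosely: their sites substitute at ``intron_rate_multiplier`` times the exon
rate, and with probability 1 - exp(-indel_rate * branch_length) an intron
redraws its length from the configured range by deleting or inserting a
contiguous segment at a random position — content is mostly retained, so
divergence accumulates smoothly (clock-like) while the conserved exon
blocks shift position between lineages, which is exactly the phenomenon the
warping alignment is built to absorb.  Leaves are returned together with
the true tree, so downstream topology recovery can be scored.

Default sizes mirror a skeletal-muscle alpha-actin (ACTA1) gene family:
7 exons x 162 bp (a 377-residue protein plus stop, ~1134 bp coding) and 6
introns of 200-400 bp, giving totals around 2900 +/- 200 bp, with a
two-clade 10-leaf tree (two well-separated groups of five, mimicking a
deep split such as mammal/bird).  The preset tree's merge heights are
geometrically spaced (0.004 / 0.03 / 0.25 / root 2.0): signal distances
estimated from a single gene carry substantial sampling noise, so tree
levels must differ by large ratios for cluster analysis to resolve them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np

from .errors import ParameterError
from .sequence_io import DNASequence
from .tree import Dendrogram, TreeNode

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneFamilyParams:
    """Parameters of a simulated gene family.

    ``substitution_rate`` is expected substitutions per exon site per unit
    branch length (introns substitute ``intron_rate_multiplier`` times
    faster); ``indel_rate_intron`` is the intron length-change rate per
    unit branch length.  ``tree`` is a preset name (see :func:`preset_tree`)
    or a :class:`Dendrogram` with leaf labels.
    """

    n_exons: int = 7
    exon_length: int = 162
    intron_length_range: Tuple[int, int] = (200, 400)
    tree: Union[str, Dendrogram] = "two_clade_10"
    substitution_rate: float = 0.1
    indel_rate_intron: float = 0.5
    intron_rate_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1 or self.exon_length < 1:
            raise ParameterError("exon count and length must be positive")
        lo, hi = self.intron_length_range
        if lo < 1 or hi < lo:
            raise ParameterError("invalid intron length range")
        if self.substitution_rate < 0 or self.indel_rate_intron < 0:
            raise ParameterError("rates must be non-negative")
        if self.intron_rate_multiplier < 0:
            raise ParameterError("intron_rate_multiplier must be non-negative")


def preset_tree(name: str) -> Dendrogram:
    """Named example topologies with branch lengths (node heights).

    ``two_clade_10``: ten leaves in two clades — a quartet clade
    ``((A1,A2),(A3,A4))`` and a six-leaf clade
    ``(((B1,B2),(B3,B4)),(B5,B6))`` — with geometrically spaced merge
    heights 0.004 / 0.03 / 0.25 and a deep root at height 2.0.  Every
    non-cherry merge decision is backed by several leaf pairs (no lone deep
    leaves), which keeps cluster analysis reliable against the sampling
    noise of single-gene signal distances.
    ``balanced_4``: ((A,B),(C,D)) with equal shallow clades.
    """
    if name == "two_clade_10":
        def cherry(a: str, b: str, height: float) -> TreeNode:
            return TreeNode(height=height, children=(
                TreeNode(label=a), TreeNode(label=b)))

        def quartet(labels: List[str]) -> TreeNode:
            return TreeNode(height=0.03, children=(
                cherry(labels[0], labels[1], 0.004),
                cherry(labels[2], labels[3], 0.004)))

        left = quartet(["A1", "A2", "A3", "A4"])
        right = TreeNode(height=0.25, children=(
            quartet(["B1", "B2", "B3", "B4"]),
            cherry("B5", "B6", 0.004)))
        return Dendrogram(root=TreeNode(height=2.0, children=(left, right)))
    if name == "balanced_4":
        ab = TreeNode(height=0.1, children=(
            TreeNode(label="A"), TreeNode(label="B")))
        cd = TreeNode(height=0.1, children=(
            TreeNode(label="C"), TreeNode(label="D")))
        return Dendrogram(root=TreeNode(height=1.0, children=(ab, cd)))
    raise ParameterError(f"unknown preset tree {name!r}")


def _random_block(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate_exon(
    rng: np.random.Generator, block: np.ndarray, p_sub: float
) -> np.ndarray:
    out = block.copy()
    hits = np.nonzero(rng.random(out.size) < p_sub)[0]
    for pos in hits:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def simulate_family(params: GeneFamilyParams) -> Tuple[List[DNASequence], Dendrogram]:
    """Evolve a root exon/intron gene down the tree; return leaves + truth.

    Fully reproducible from ``params.seed``.  Leaves are returned in tree
    (left-to-right) order.
    """
    tree = params.tree if isinstance(params.tree, Dendrogram) else preset_tree(
        params.tree
    )
    rng = np.random.default_rng(params.seed)
    lo, hi = params.intron_length_range
    # blocks: list of ("exon"|"intron", uint8 array), alternating, exon ends
    blocks = []
    for k in range(params.n_exons):
        blocks.append(("exon", _random_block(rng, params.exon_length)))
        if k < params.n_exons - 1:
            blocks.append(
                ("intron", _random_block(rng, int(rng.integers(lo, hi + 1))))
            )

    leaves: List[DNASequence] = []

    def resize_intron(block: np.ndarray) -> np.ndarray:
        """Redraw the length by deleting/inserting a contiguous segment."""
        new_len = int(rng.integers(lo, hi + 1))
        if new_len < block.size:
            start = int(rng.integers(0, block.size - new_len + 1))
            return np.concatenate(
                [block[:start], block[start + block.size - new_len:]]
            )
        if new_len > block.size:
            pos = int(rng.integers(0, block.size + 1))
            insert = _random_block(rng, new_len - block.size)
            return np.concatenate([block[:pos], insert, block[pos:]])
        return block

    def evolve(node: TreeNode, parent_blocks, parent_height: float) -> None:
        t = parent_height - node.height
        if t < 0:
            raise ParameterError(
                "tree is not ultrametric-consistent (child above parent)"
            )
        p_sub = 1.0 - math.exp(-params.substitution_rate * t)
        p_sub_intron = 1.0 - math.exp(
            -params.substitution_rate * params.intron_rate_multiplier * t
        )
        p_resize = 1.0 - math.exp(-params.indel_rate_intron * t)
        child_blocks = []
        for kind, block in parent_blocks:
            if kind == "exon":
                child_blocks.append((kind, _mutate_exon(rng, block, p_sub)))
            else:
                block = _mutate_exon(rng, block, p_sub_intron)
                if rng.random() < p_resize:
                    block = resize_intron(block)
                child_blocks.append((kind, block))
        if node.is_leaf:
            seq = np.concatenate([b for _, b in child_blocks])
            leaves.append(
                DNASequence(id=node.label, seq=seq.tobytes().decode("ascii"))
            )
        else:
            for child in node.children:
                evolve(child, child_blocks, node.height)

    for child in tree.root.children:
        evolve(child, blocks, tree.root.height)
    if not tree.root.children:  # single-leaf degenerate tree
        evolve(tree.root, blocks, tree.root.height)
    return leaves, tree


def perturb_sequence(
    seq: DNASequence, n_substitutions: int, seed: int = 0
) -> DNASequence:
    """Substitute exactly ``n_substitutions`` uniformly chosen positions.

    Each chosen position is changed to a different base, so the Hamming
    distance to the input is exactly ``n_substitutions``.
    """
    if n_substitutions > len(seq):
        raise ParameterError(
            f"n_substitutions ({n_substitutions}) exceeds sequence length "
            f"({len(seq)})"
        )
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.seq.encode("ascii"), dtype=np.uint8).copy()
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return DNASequence(id=seq.id, seq=arr.tobytes().decode("ascii"))


def write_manifest(params: GeneFamilyParams, path: Union[str, Path]) -> None:
    """Plain-text key-value record of the generating parameters."""
    lo, hi = params.intron_length_range
    tree_desc = params.tree if isinstance(params.tree, str) else "custom"
    with open(path, "w") as handle:
        handle.write(f"n_exons = {params.n_exons}\n")
        handle.write(f"exon_length = {params.exon_length}\n")
        handle.write(f"intron_length_min = {lo}\n")
        handle.write(f"intron_length_max = {hi}\n")
        handle.write(f"tree = {tree_desc}\n")
        handle.write(f"substitution_rate = {params.substitution_rate}\n")
        handle.write(f"indel_rate_intron = {params.indel_rate_intron}\n")
        handle.write(f"intron_rate_multiplier = {params.intron_rate_multiplier}\n")
        handle.write(f"seed = {params.seed}\n")
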