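"""Shared fixtures: the default synthetic family and its derived objects."""

import numpy as np
import pytest

import phasewarp as pw


@pytest.fixture(scope="session")
def family10():
    """Default two-clade 10-leaf synthetic gene family (seed 0)."""
    return pw.simulate_family(pw.GeneFamilyParams(seed=0))


@pytest.fixture(scope="session")
def signals10(family10):
    seqs, _ = family10
    return [pw.preprocess(pw.cumulated_phase(s)) for s in seqs]


@pytest.fixture(scope="session")
def matrix10(signals10):
    return pw.normalize_matrix(pw.pairwise_matrix(signals10))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


def random_ultrametric(rng, n):
    """Random ultrametric matrix built by agglomerating at increasing heights.

    Returns (labels, matrix, tree).  Cophenetic distances of the returned
    tree equal the matrix exactly by construction.
    """
    labels = [f"T{k:02d}" for k in range(n)]
    nodes = [pw.TreeNode(height=0.0, label=lab) for lab in labels]
    heights = np.sort(rng.uniform(0.5, 50.0, size=n - 1))
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = pw.TreeNode(height=float(h), children=(nodes[i], nodes[j]))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = pw.Dendrogram(root=nodes[0])
    return labels, tree.cophenetic_matrix(labels), tree
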