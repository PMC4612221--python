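import numpy as np
import pytest

from funfams import profilemodel, simulate, treebuild, treecut
from funfams.seqio import Alignment, Sequence


def make_alignment(rows):
    """Alignment from a list of gapped strings (auto ids) or (id, row) pairs."""
    if rows and isinstance(rows[0], str):
        rows = [(f"s{i}", r) for i, r in enumerate(rows)]
    return Alignment(rows)


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic superfamily with its annotations."""
    cfg = simulate.SimulationConfig(seed=3)
    seqs, truth = simulate.simulate_superfamily(cfg)
    go, ec, dag = simulate.simulate_annotations(truth, cfg)
    return cfg, seqs, truth, go, ec, dag


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Full pipeline on the default simulation with an 80/20 member split.

    Returns (truth, go, ec, dag, train, test, tree, families, decisions,
    models) — shared by the classification and assignment tests to avoid
    rebuilding the tree repeatedly.
    """
    cfg, seqs, truth, go, ec, dag = default_sim
    train, test = [], []
    for s in seqs:
        (test if int(s.id[-3:]) >= 16 else train).append(s)
    clusters = treebuild.precluster(train)
    clusters = treebuild.filter_clusters(clusters, go)
    clusters = treebuild.remove_fragments(clusters)
    tree = treebuild.build_tree(clusters)
    families, decisions = treecut.cut_tree(tree)
    models = [profilemodel.build_model(f) for f in families]
    return truth, go, ec, dag, train, test, tree, families, decisions, models


def majority_subfamily(family, truth):
    from collections import Counter

    return Counter(truth.subfamily_of[m] for m in family.members).most_common(1)[0][0]


def partition_purity(families, truth):
    from collections import Counter

    n = sum(len(f.members) for f in families)
    hits = sum(
        Counter(truth.subfamily_of[m] for m in f.members).most_common(1)[0][1]
        for f in families
    )
    return hits / n
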