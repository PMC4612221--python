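"""Cutting the cluster tree into functional families (FunFams).

Every internal node of the agglomeration tree receives a coherence decision
(:mod:`funfams.coherence`) computed on its member sub-alignment, with the
two children's sequences forming the SDP-scoring groups. Two cut strategies
are provided:

* ``subtree`` (default) — merge acceptance: a node may stand as one family
  only if *every* internal node in its subtree is coherent; the cut is the
  set of maximal such nodes. This matches the semantics of deciding, parent
  by parent during agglomeration, whether two children may merge.
* ``first_coherent`` — top-down descent stopping at the first coherent
  node. Cheaper, but blind to divergence buried below a node whose own
  two groups happen to look homogeneous (e.g. a root whose children each
  mix several functional groups).

Both strategies always yield a partition of the tree's sequences.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import coherence, conservation
from .errors import UsageError
from .groupsim import GroupedAlignment
from .seqio import Alignment
from .treebuild import ClusterTree

CUT_STRATEGIES = ("subtree", "first_coherent")


@dataclass
class FunFam:
    """One functional family produced by the tree cut."""

    family_id: str
    members: tuple[str, ...]
    alignment: Alignment
    source_node: int
    profile: conservation.ConservationProfile


def node_decision(
    tree: ClusterTree,
    node_id: int,
    rule: str = "strict_gap",
    matrix: str = "BLOSUM62",
    weighting: str = "henikoff",
    **coherence_kwargs,
) -> coherence.CoherenceDecision:
    """Coherence decision for one internal node of the tree.

    Sequence-weighted (Henikoff) conservation is the pipeline default: it
    keeps per-column scores continuous, so the DOPS informativeness gate
    reflects genuine alignment diversity rather than score ties.
    """
    left, right = tree.children(node_id)
    aln = tree.node_alignment(node_id)
    group_of = {m: 1 for m in left.members}
    group_of.update({m: 2 for m in right.members})
    ga = GroupedAlignment(aln=aln, group_of=group_of)
    return coherence.evaluate_parent(
        ga, matrix=matrix, rule=rule, weighting=weighting, **coherence_kwargs
    )


def cut_tree(
    tree: ClusterTree,
    rule: str = "strict_gap",
    strategy: str = "subtree",
    matrix: str = "BLOSUM62",
    weighting: str = "henikoff",
    conserved_threshold: float = 0.7,
    **coherence_kwargs,
) -> tuple[list[FunFam], dict[int, coherence.CoherenceDecision]]:
    """Cut the tree into FunFams; returns (families, per-node decision log)."""
    if strategy not in CUT_STRATEGIES:
        raise UsageError(
            f"unknown cut strategy {strategy!r}; expected one of {CUT_STRATEGIES}"
        )
    decisions: dict[int, coherence.CoherenceDecision] = {}

    def decide(nid: int) -> coherence.CoherenceDecision:
        if nid not in decisions:
            decisions[nid] = node_decision(
                tree, nid, rule=rule, matrix=matrix, weighting=weighting,
                **coherence_kwargs
            )
        return decisions[nid]

    family_nodes: list[int] = []

    if strategy == "subtree":
        coherent: dict[int, bool] = {}

        def post(nid: int) -> bool:
            node = tree.nodes[nid]
            if node.children is None:
                coherent[nid] = True
            else:
                left_ok = post(node.children[0])
                right_ok = post(node.children[1])
                coherent[nid] = left_ok and right_ok and decide(nid).fc == 1
            return coherent[nid]

        post(tree.root)

        def collect(nid: int) -> None:
            if coherent[nid]:
                family_nodes.append(nid)
                return
            for child in tree.nodes[nid].children:
                collect(child)

        collect(tree.root)
    else:  # first_coherent: stop at the first coherent node from the root
        def descend(nid: int) -> None:
            node = tree.nodes[nid]
            if node.children is None or decide(nid).fc == 1:
                family_nodes.append(nid)
                return
            for child in node.children:
                descend(child)

        descend(tree.root)

    families = []
    for i, nid in enumerate(family_nodes, start=1):
        aln = tree.node_alignment(nid)
        prof = conservation.score_columns(aln, matrix=matrix)
        families.append(
            FunFam(
                family_id=f"F{i}",
                members=tuple(tree.nodes[nid].members),
                alignment=aln,
                source_node=nid,
                profile=prof,
            )
        )
    _check_partition(tree, families)
    return families, decisions


def _check_partition(tree: ClusterTree, families: list[FunFam]) -> None:
    all_members = [m for f in families for m in f.members]
    if len(all_members) != len(set(all_members)) or set(all_members) != set(
        tree.nodes[tree.root].members
    ):
        raise UsageError("cut did not partition the tree's sequences")


def funfam_summary(
    funfams: list[FunFam], conserved_threshold: float = 0.7
) -> pd.DataFrame:
    """Per-family summary: size, conserved-position count, DOPS, source node."""
    if not funfams:
        raise UsageError("no families to summarize")
    rows = []
    for fam in funfams:
        n_cons = len(
            conservation.conserved_positions(fam.profile, conserved_threshold)
        )
        rows.append(
            {
                "family_id": fam.family_id,
                "size": len(fam.members),
                "n_conserved": n_cons,
                "dops": round(fam.profile.dops, 3),
                "source_node": fam.source_node,
            }
        )
    return pd.DataFrame(rows)
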