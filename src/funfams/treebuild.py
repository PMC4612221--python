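"""Starting-cluster construction and bottom-up agglomerative tree building.

The pipeline mirrors the classical superfamily protocol: sequences are
greedily pre-clustered at 90% identity, clusters lacking any reliably
annotated member are removed (a family must be able to donate annotations),
fragments shorter than 80% of the average sequence length are dropped, and
the surviving clusters are agglomerated into a single binary tree.

Cluster-to-cluster similarity is the mean, over master-alignment columns
where both clusters are non-gap-majority, of 1 minus the Jensen-Shannon
divergence (base 2) between their per-column residue frequency profiles.
At each step the best-scoring pair merges; ties break toward the smallest
node-id pair, making the tree deterministic.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence as TypingSequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import jensenshannon

from . import align
from .errors import IntegrityError, UsageError
from .matrices import AMINO_ACIDS
from .seqio import Alignment, AnnotationTable, Sequence

Cluster = list[Sequence]

N_STANDARD = len(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# Starting clusters
# ---------------------------------------------------------------------------

def precluster(
    seqs: TypingSequence[Sequence], identity: float = 0.90
) -> list[Cluster]:
    """Greedy incremental clustering at the given identity.

    Sequences are visited longest-first; each joins the first cluster whose
    representative (founder) it matches at >= ``identity``, else founds a
    new cluster.
    """
    if not seqs:
        raise UsageError("precluster needs at least one sequence")
    order = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: list[Cluster] = []
    for seq in order:
        for cluster in clusters:
            if align.ungapped_identity(cluster[0], seq) >= identity:
                cluster.append(seq)
                break
        else:
            clusters.append([seq])
    return clusters


def filter_clusters(
    clusters: list[Cluster], annotations: AnnotationTable
) -> list[Cluster]:
    """Keep only clusters with >= 1 member carrying a high-quality GO record."""
    annotated = annotations.accessions_with_high_quality()
    return [c for c in clusters if any(s.id in annotated for s in c)]


def remove_fragments(
    clusters: list[Cluster], fraction: float = 0.8
) -> list[Cluster]:
    """Drop members shorter than ``fraction`` x the average sequence length.

    The average is taken over all members of all clusters (one superfamily
    -wide value); clusters emptied by the filter are dropped.
    """
    if not clusters:
        raise UsageError("remove_fragments needs at least one cluster")
    lengths = [len(s) for c in clusters for s in c]
    cutoff = fraction * (sum(lengths) / len(lengths))
    out: list[Cluster] = []
    for cluster in clusters:
        kept = [s for s in cluster if len(s) >= cutoff]
        if kept:
            out.append(kept)
    return out


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterNode:
    id: int
    members: tuple[str, ...]          # sequence ids
    children: tuple[int, int] | None  # None for leaves
    step: int | None = None           # merge step index (internal nodes)
    score: float | None = None        # merge similarity (internal nodes)


class ClusterTree:
    """Binary agglomeration tree over starting clusters.

    Leaves are the starting clusters; the root holds every sequence. The
    master alignment the tree was built over is retained so per-node
    sub-alignments can be extracted.
    """

    def __init__(self, nodes: dict[int, ClusterNode], root: int, master: Alignment):
        self.nodes = nodes
        self.root = root
        self.master = master
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise IntegrityError("root id missing from node table")
        seen_leaf_members: list[str] = []
        for node in self.nodes.values():
            if node.children is None:
                seen_leaf_members.extend(node.members)
                continue
            if len(node.children) != 2:
                raise IntegrityError(f"node {node.id} is not binary")
            a, b = (self.nodes[c] for c in node.children)
            if set(node.members) != set(a.members) | set(b.members):
                raise IntegrityError(
                    f"node {node.id} members are not the union of its children"
                )
            if set(a.members) & set(b.members):
                raise IntegrityError(f"node {node.id} children overlap")
        if len(seen_leaf_members) != len(set(seen_leaf_members)):
            raise IntegrityError("leaves do not partition the sequences")
        if set(seen_leaf_members) != set(self.nodes[self.root].members):
            raise IntegrityError("root members differ from the leaf union")

    def leaves(self) -> list[ClusterNode]:
        return [n for n in self.nodes.values() if n.children is None]

    def children(self, node_id: int) -> tuple[ClusterNode, ClusterNode]:
        node = self.nodes[node_id]
        if node.children is None:
            raise UsageError(f"node {node_id} is a leaf")
        return self.nodes[node.children[0]], self.nodes[node.children[1]]

    def node_alignment(self, node_id: int) -> Alignment:
        return self.master.subalignment(
            self.nodes[node_id].members, drop_all_gap_columns=True
        )

    def to_newick(self) -> str:
        def rec(nid: int) -> str:
            node = self.nodes[nid]
            if node.children is None:
                return f"N{nid}"
            a, b = node.children
            return f"({rec(a)},{rec(b)})N{nid}"

        return rec(self.root) + ";"

    def write(self, newick_path: str | Path, sidecar_path: str | Path) -> None:
        Path(newick_path).write_text(self.to_newick() + "\n", encoding="utf-8")
        payload = {
            f"N{n.id}": {
                "members": sorted(n.members),
                "children": None if n.children is None else list(n.children),
                "step": n.step,
                "score": n.score,
            }
            for n in self.nodes.values()
        }
        payload["root"] = f"N{self.root}"
        Path(sidecar_path).write_text(
            json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
        )


def _cluster_profile(master_enc: np.ndarray, row_idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """(freqs (C, 20), nongap fraction (C,)) for the given master rows."""
    rows = master_enc[row_idx]
    n_cols = rows.shape[1]
    freqs = np.zeros((n_cols, N_STANDARD))
    for c in range(n_cols):
        col = rows[:, c]
        col = col[(col >= 0) & (col < N_STANDARD)]  # drop gaps and X
        if len(col):
            freqs[c] = np.bincount(col, minlength=N_STANDARD)
    totals = freqs.sum(axis=1)
    nz = totals > 0
    freqs[nz] /= totals[nz, None]
    nongap = (rows >= 0).mean(axis=0)
    return freqs, nongap


def profile_similarity(
    p1: np.ndarray, ng1: np.ndarray, p2: np.ndarray, ng2: np.ndarray,
    majority: float = 0.5,
) -> float:
    """Mean per-column (1 - JSD) over columns where both are non-gap majority."""
    ok = (ng1 >= majority) & (ng2 >= majority)
    ok &= (p1.sum(axis=1) > 0) & (p2.sum(axis=1) > 0)
    if not ok.any():
        return 0.0
    jsd = jensenshannon(p1[ok], p2[ok], base=2, axis=1) ** 2
    jsd = np.nan_to_num(jsd, nan=0.0)
    return float(np.mean(1.0 - jsd))


def build_tree(
    clusters: list[Cluster],
    aligner: Callable[[list[Sequence]], Alignment] = align.default_aligner,
    metric: Callable[..., float] = profile_similarity,
) -> ClusterTree:
    """Agglomerate starting clusters into a binary tree.

    Pairwise similarities between starting-cluster profiles (over the
    master alignment) are agglomerated by average linkage: the score of a
    cluster pair is the mean profile similarity over their constituent
    starting clusters. Merging the best pair at each step (UPGMA) avoids
    the chaining that centroid-profile merging exhibits — a merged profile
    smooths toward the background composition and would otherwise attract
    every remaining cluster one by one.
    """
    if not clusters:
        raise UsageError("build_tree needs at least one starting cluster")
    # deterministic leaf order: by smallest member id
    clusters = sorted(clusters, key=lambda c: min(s.id for s in c))
    all_seqs = [s for c in clusters for s in c]
    ids = [s.id for s in all_seqs]
    if len(set(ids)) != len(ids):
        raise UsageError("clusters share sequence ids")
    master = aligner(all_seqs)
    master_enc = master.encoded()
    row_of = {rid: i for i, rid in enumerate(master.ids)}

    nodes: dict[int, ClusterNode] = {}
    profiles: list[tuple[np.ndarray, np.ndarray]] = []
    n = len(clusters)
    for i, cluster in enumerate(clusters):
        members = tuple(s.id for s in cluster)
        nodes[i] = ClusterNode(id=i, members=members, children=None)
        profiles.append(_cluster_profile(master_enc, [row_of[m] for m in members]))

    if n == 1:
        return ClusterTree(nodes, root=0, master=master)

    # condensed leaf-leaf distance matrix (1 - profile similarity)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(1.0 - metric(*profiles[i], *profiles[j]))
    linkage = hierarchy.linkage(np.array(condensed), method="average")
    for step, (a, b, dist, _count) in enumerate(linkage):
        a, b = int(a), int(b)
        nid = n + step
        members = tuple(nodes[a].members) + tuple(nodes[b].members)
        nodes[nid] = ClusterNode(
            id=nid, members=members, children=(a, b), step=step,
            score=1.0 - float(dist),
        )
    return ClusterTree(nodes, root=2 * n - 2, master=master)


def write_clusters_tsv(clusters: list[Cluster], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cluster\tmember\n")
        for i, cluster in enumerate(clusters):
            for seq in cluster:
                fh.write(f"{i}\t{seq.id}\n")
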