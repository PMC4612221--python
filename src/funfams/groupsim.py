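"""Column scoring for specificity determination between two sequence groups.

Given an alignment whose rows are partitioned into two pre-defined groups
(the two children of a tree node), each column receives a score gs in [0, 1]:

    gs = mean(s_w(1), s_w(2)) * (1 - s_b)

where s_w(g) is the mean pairwise normalized similarity within group g's
non-gap residues and s_b the mean similarity across group pairs. A column
conserved identically in both groups scores 0; a column conserved on a
different, dissimilar residue in each group scores near 1 — the signature
of a specificity-determining position (SDP).

Classification thresholds: gs <= 0.3 marks a conserved position, and
0.7 < gs <= 1 marks an SDP; the open interval between is ambiguous. A column
is undefined (scored NaN) when either group has fewer than the required
fraction of non-gap residues.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import UsageError
from .matrices import ALPHABET, normalized_similarity
from .seqio import Alignment

CONSERVED_MAX_GS = 0.3
SDP_MIN_GS = 0.7


@dataclass
class GroupedAlignment:
    """An alignment plus a two-group row partition."""

    aln: Alignment
    group_of: dict[str, int]  # row id -> 1 | 2

    def __post_init__(self):
        ids = set(self.aln.ids)
        if set(self.group_of) != ids:
            raise UsageError("group assignment must cover exactly the alignment rows")
        groups = set(self.group_of.values())
        if groups != {1, 2}:
            raise UsageError("both groups must be non-empty and labelled 1 and 2")

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        labels = np.array([self.group_of[rid] for rid in self.aln.ids])
        return labels == 1, labels == 2


@dataclass
class SDPProfile:
    """Per-column gs scores (NaN = undefined) with SDP/conserved counts."""

    gs: np.ndarray
    n_sdp: int
    n_c: int


def _within_similarity(counts: np.ndarray, n: int, sim: np.ndarray, diag_sum: float) -> float:
    """Mean pairwise similarity among n residues given their count vector."""
    if n == 1:
        # single residue present: self-similarity taken as 1
        return 1.0
    total = counts @ sim @ counts - diag_sum
    return float(total / (n * (n - 1)))


def score_sdp(
    ga: GroupedAlignment,
    matrix: str | np.ndarray = "BLOSUM62",
    min_nongap_fraction: float = 0.5,
) -> SDPProfile:
    """Score every column of a grouped alignment for specificity."""
    sim = normalized_similarity(matrix) if isinstance(matrix, str) else np.asarray(matrix)
    enc = ga.aln.encoded()
    m1, m2 = ga.group_masks()
    n_cols = enc.shape[1]
    gs = np.full(n_cols, np.nan)
    n_letters = sim.shape[0]
    for c in range(n_cols):
        col = enc[:, c]
        parts = []
        ok = True
        for mask in (m1, m2):
            sub = col[mask]
            nongap = sub[sub >= 0]
            if len(sub) == 0 or len(nongap) / len(sub) < min_nongap_fraction or len(nongap) == 0:
                ok = False
                break
            counts = np.bincount(nongap, minlength=n_letters).astype(float)
            diag_sum = float(np.sum(sim[nongap, nongap]))
            parts.append((counts, len(nongap), diag_sum))
        if not ok:
            continue
        (c1, n1, d1), (c2, n2, d2) = parts
        s_w1 = _within_similarity(c1, n1, sim, d1)
        s_w2 = _within_similarity(c2, n2, sim, d2)
        s_b = float(c1 @ sim @ c2) / (n1 * n2)
        gs[c] = np.clip(((s_w1 + s_w2) / 2.0) * (1.0 - s_b), 0.0, 1.0)
    n_sdp, n_c = classify_columns_from_scores(gs)
    return SDPProfile(gs=gs, n_sdp=n_sdp, n_c=n_c)


def classify_columns_from_scores(gs: np.ndarray) -> tuple[int, int]:
    defined = gs[~np.isnan(gs)]
    n_sdp = int(np.sum((defined > SDP_MIN_GS) & (defined <= 1.0)))
    n_c = int(np.sum(defined <= CONSERVED_MAX_GS))
    return n_sdp, n_c


def classify_columns(profile: SDPProfile) -> tuple[int, int]:
    """(n_sdp, n_c) per the half-open intervals; mid-range columns in neither."""
    return classify_columns_from_scores(profile.gs)


def column_class(g: float) -> str:
    if np.isnan(g):
        return "undefined"
    if g <= CONSERVED_MAX_GS:
        return "conserved"
    if g > SDP_MIN_GS:
        return "sdp"
    return "ambiguous"


def write_sdp_tsv(ga: GroupedAlignment, profile: SDPProfile, path: str | Path) -> None:
    """Export per-column gs with group consensus residues (1-based columns)."""
    enc = ga.aln.encoded()
    m1, m2 = ga.group_masks()

    def consensus(mask: np.ndarray, c: int) -> str:
        sub = enc[mask, c]
        nongap = sub[sub >= 0]
        if len(nongap) == 0:
            return "-"
        return ALPHABET[int(np.bincount(nongap).argmax())]

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# column\tconsensus_group1\tconsensus_group2\tgs\tclass\n")
        for c, g in enumerate(profile.gs):
            gs_txt = "NA" if np.isnan(g) else f"{g:.4f}"
            fh.write(
                f"{c + 1}\t{consensus(m1, c)}\t{consensus(m2, c)}\t{gs_txt}\t"
                f"{column_class(g)}\n"
            )
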