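"""Per-column residue conservation scoring and alignment diversity (DOPS).

The column score is the (optionally sequence-weighted) mean pairwise
normalized similarity of the column's non-gap residues, multiplied by the
column's non-gap fraction, so both substitution and deletion erode it. It
lies in [0, 1]: 1 for a fully occupied, single-residue column; 0 for a
column with fewer than two residues. Columns scoring >= 0.7 are called
highly conserved.

DOPS (Diversity of Position Scores) summarizes how varied the column scores
of an alignment are: 0 when every column has the same score, 100 when no two
columns share one. It is used to gate SDP analysis — alignments of near
-identical sequences give flat, uninformative conservation profiles.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import UsageError
from .matrices import AMINO_ACIDS, normalized_similarity
from .seqio import Alignment

N_STANDARD = len(AMINO_ACIDS)


@dataclass
class ConservationProfile:
    """Per-column conservation scores plus the alignment-level DOPS."""

    scores: np.ndarray        # (n_columns,), each in [0, 1]
    n_effective: np.ndarray   # (n_columns,), non-gap residue count
    dops: float               # in [0, 100]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.n_effective = np.asarray(self.n_effective, dtype=int)


def henikoff_weights(aln: Alignment) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights (sum to n_rows)."""
    enc = aln.encoded()
    n_rows, n_cols = enc.shape
    w = np.zeros(n_rows)
    for c in range(n_cols):
        col = enc[:, c]
        mask = col >= 0
        if not mask.any():
            continue
        vals, counts = np.unique(col[mask], return_counts=True)
        r = len(vals)
        contrib = np.zeros(n_rows)
        lookup = dict(zip(vals.tolist(), counts.tolist()))
        for i in np.nonzero(mask)[0]:
            contrib[i] = 1.0 / (r * lookup[col[i]])
        w += contrib
    if w.sum() == 0:
        return np.ones(n_rows)
    return w * (n_rows / w.sum())


def _column_score(col: np.ndarray, weights: np.ndarray, sim: np.ndarray) -> tuple[float, int]:
    """Weighted mean pairwise similarity of one encoded column, times its
    non-gap fraction.

    The mean runs over all ordered residue pairs including self-pairs, so
    the score is a pure function of the column's (weighted) residue
    frequency profile — in particular it is exactly invariant under row
    duplication.
    """
    mask = col >= 0
    n_eff = int(mask.sum())
    if n_eff < 2:
        return 0.0, n_eff
    res = col[mask]
    w = weights[mask]
    # weighted count vector over the 21-letter alphabet
    counts = np.zeros(sim.shape[0])
    np.add.at(counts, res, w)
    score = float(counts @ sim @ counts) / float(w.sum()) ** 2
    score *= n_eff / len(col)
    return float(np.clip(score, 0.0, 1.0)), n_eff


def score_columns(
    aln: Alignment,
    matrix: str | np.ndarray = "BLOSUM62",
    weighting: Literal["none", "henikoff"] = "none",
    dops_precision: int = 3,
) -> ConservationProfile:
    """Score every column of an alignment and compute its DOPS.

    ``matrix`` is either a matrix name to normalize or a pre-normalized
    (21, 21) similarity array (unit diagonal over standard residues, zero X).
    """
    sim = normalized_similarity(matrix) if isinstance(matrix, str) else np.asarray(matrix)
    enc = aln.encoded()
    n_rows, n_cols = enc.shape
    if weighting == "henikoff":
        weights = henikoff_weights(aln)
    elif weighting == "none":
        weights = np.ones(n_rows)
    else:
        raise UsageError(f"unknown weighting {weighting!r}")
    scores = np.empty(n_cols)
    n_eff = np.empty(n_cols, dtype=int)
    for c in range(n_cols):
        scores[c], n_eff[c] = _column_score(enc[:, c], weights, sim)
    profile = ConservationProfile(scores=scores, n_effective=n_eff, dops=0.0)
    profile.dops = dops(profile, precision=dops_precision)
    return profile


def dops(profile: ConservationProfile, precision: int = 3) -> float:
    """Diversity of Position Scores: 100 * (u - 1) / (p - 1).

    ``u`` is the number of distinct column scores (rounded to ``precision``
    decimals so float noise does not inflate distinctness) and ``p`` the
    number of columns. A single-column profile returns 0.
    """
    p = len(profile.scores)
    if p == 0:
        raise UsageError("cannot compute DOPS of an empty profile")
    if p == 1:
        return 0.0
    u = len(np.unique(np.round(profile.scores, precision)))
    return 100.0 * (u - 1) / (p - 1)


def conserved_positions(profile: ConservationProfile, threshold: float = 0.7) -> list[int]:
    """0-based indices of columns scoring >= ``threshold``, ascending."""
    return [int(i) for i in np.nonzero(profile.scores >= threshold)[0]]


def write_profile_tsv(profile: ConservationProfile, path: str | Path, threshold: float = 0.7) -> None:
    """Export per-column scores (1-based columns) with a conserved flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# column\tscore\tis_conserved\n")
        for i, s in enumerate(profile.scores, start=1):
            fh.write(f"{i}\t{s:.4f}\t{int(s >= threshold)}\n")
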