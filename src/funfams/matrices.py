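"""Residue alphabet, normalized substitution similarities and background frequencies.

All column-scoring modules share a single similarity convention: a symmetric
matrix over the 20 standard residues with unit self-similarity and minimum 0.
Starting from a log-odds substitution matrix S (default BLOSUM62), entries are
first scaled to correlations s(a,b)/sqrt(s(a,a)*s(b,b)) so every diagonal is
exactly 1, then min-max mapped onto [0, 1] while keeping the diagonal at 1.
The unknown residue 'X' has similarity 0 to everything, including itself.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard amino acids, in a fixed order used for all count vectors.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Full residue alphabet accepted in sequences: standard residues plus X.
ALPHABET = AMINO_ACIDS + "X"

#: Gap character stored internally ('.' is normalized to '-' on input).
GAP = "-"

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

# Robinson & Robinson (1991) amino-acid background frequencies, the standard
# null model for profile log-odds scoring; order matches AMINO_ACIDS.
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


@lru_cache(maxsize=4)
def normalized_similarity(name: str = "BLOSUM62") -> np.ndarray:
    """Return the (21, 21) normalized similarity matrix over ``ALPHABET``.

    Entries for the 20 standard residues lie in [0, 1] with diagonal exactly
    1; the X row and column are all zero.
    """
    raw = substitution_matrices.load(name)
    n = len(AMINO_ACIDS)
    s = np.empty((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = raw[a, b]
    diag = np.sqrt(np.diag(s))
    corr = s / np.outer(diag, diag)
    lo = corr.min()
    norm = (corr - lo) / (1.0 - lo)
    out = np.zeros((n + 1, n + 1))
    out[:n, :n] = norm
    return out


@lru_cache(maxsize=4)
def raw_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return the raw (21, 21) log-odds matrix over ``ALPHABET`` (X rows 0)."""
    raw = substitution_matrices.load(name)
    n = len(AMINO_ACIDS)
    out = np.zeros((n + 1, n + 1))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = raw[a, b]
    return out


def encode(residues: str) -> np.ndarray:
    """Encode a (possibly gapped) residue string as int indices.

    Standard residues and X map to their ``ALPHABET`` index; the gap maps
    to -1.
    """
    out = np.empty(len(residues), dtype=np.int64)
    for i, ch in enumerate(residues):
        if ch == GAP:
            out[i] = -1
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise KeyError(f"residue {ch!r} is not in the alphabet") from None
    return out
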