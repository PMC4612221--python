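"""Internal pairwise/progressive alignment utilities.

Two jobs live here, both deliberately simple and pluggable:

* ``ungapped_identity`` — the identity measure used by the greedy
  pre-clusterer: matches along the best ungapped (diagonal) local alignment,
  divided by the shorter sequence length.
* ``mafft_align`` / ``progressive_align`` / ``default_aligner`` — builders
  of the single master superfamily alignment. MAFFT is used when present
  on PATH (it is the field-standard choice for this step); the internal
  star-style progressive aligner (longest-first, global affine-gap DP over
  expected substitution scores) is a dependency-free fallback whose
  alignments are rougher on deeply diverged sets. Any drop-in aligner
  producing an :class:`~funfams.seqio.Alignment` may replace either.
"""
from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from .errors import UsageError
from .matrices import GAP, encode, raw_matrix
from .seqio import Alignment, Sequence

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
NEG = -1e30


def ungapped_identity(a: Sequence | str, b: Sequence | str) -> float:
    """Identity = matches on the best ungapped diagonal / shorter length."""
    sa = a.residues if isinstance(a, Sequence) else a
    sb = b.residues if isinstance(b, Sequence) else b
    if not sa or not sb:
        raise UsageError("cannot compute identity of an empty sequence")
    ea, eb = encode(sa), encode(sb)
    # per-diagonal match counts: bin the (i, j) match matrix by i - j
    eq = ea[:, None] == eb[None, :]
    i_idx, j_idx = np.nonzero(eq)
    if len(i_idx) == 0:
        return 0.0
    diag = np.bincount(i_idx - j_idx + len(eb) - 1,
                       minlength=len(ea) + len(eb) - 1)
    return int(diag.max()) / min(len(ea), len(eb))


def _profile_counts(rows: np.ndarray, n_letters: int) -> np.ndarray:
    """Per-column residue frequency matrix (n_cols, n_letters), gaps/X dropped."""
    n_cols = rows.shape[1]
    counts = np.zeros((n_cols, n_letters))
    for c in range(n_cols):
        col = rows[:, c]
        col = col[(col >= 0) & (col < n_letters)]
        if len(col):
            counts[c] = np.bincount(col, minlength=n_letters)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


def _align_seq_to_profile(
    profile_scores: np.ndarray, seq: np.ndarray,
    gap_open: float, gap_extend: float,
) -> tuple[list[int], list[int]]:
    """Global affine NW of a sequence against per-column profile scores.

    ``profile_scores[c, a]`` is the expected substitution score of residue
    ``a`` at profile column ``c``. Returns two aligned index lists with -1
    marking a gap, covering all profile columns and all sequence positions.
    """
    n, m = profile_scores.shape[0], len(seq)  # profile cols, sequence length
    s = np.zeros((n, m))
    std = profile_scores.shape[1]
    for i in range(n):
        s[i] = np.where(seq < std, profile_scores[i][np.minimum(seq, std - 1)], 0.0)
        s[i][seq >= std] = 0.0  # X scores 0
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in profile (insertion in sequence)
    Y = np.full((n + 1, m + 1), NEG)  # gap in sequence
    M[0, 0] = 0.0
    X[0, 1:] = -gap_open - gap_extend * np.arange(m)
    Y[1:, 0] = -gap_open - gap_extend * np.arange(n)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        prev = np.stack([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        ptr_m[i, 1:] = prev.argmax(axis=0)
        M[i, 1:] = prev.max(axis=0) + s[i - 1]
        # Y: gap in sequence, vertical move
        y_cand = np.stack([M[i - 1, :] - gap_open, Y[i - 1, :] - gap_extend])
        ptr_y[i] = y_cand.argmax(axis=0) * 2  # 0 -> from M, 2 -> from Y
        Y[i] = y_cand.max(axis=0)
        # X: gap in profile, horizontal scan within the row
        for j in range(1, m + 1):
            from_m = M[i, j - 1] - gap_open
            from_x = X[i, j - 1] - gap_extend
            if from_m >= from_x:
                X[i, j] = from_m
                ptr_x[i, j] = 0
            else:
                X[i, j] = from_x
                ptr_x[i, j] = 1
    # traceback from the best final state
    finals = [M[n, m], X[n, m], Y[n, m]]
    state = int(np.argmax(finals))
    i, j = n, m
    prof_idx: list[int] = []
    seq_idx: list[int] = []
    while i > 0 or j > 0:
        if state == 0:  # match
            prof_idx.append(i - 1)
            seq_idx.append(j - 1)
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:  # gap in profile: sequence residue alone
            prof_idx.append(-1)
            seq_idx.append(j - 1)
            state = int(ptr_x[i, j])
            j -= 1
        else:  # gap in sequence
            prof_idx.append(i - 1)
            seq_idx.append(-1)
            state = 0 if ptr_y[i, j] == 0 else 2
            i -= 1
        if i == 0 and j > 0 and state != 1:
            state = 1
        if j == 0 and i > 0 and state != 2:
            state = 2
    prof_idx.reverse()
    seq_idx.reverse()
    return prof_idx, seq_idx


def progressive_align(
    seqs: list[Sequence],
    matrix: str = "BLOSUM62",
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Alignment:
    """Build a master alignment by adding sequences longest-first."""
    if not seqs:
        raise UsageError("cannot align an empty sequence list")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise UsageError("duplicate sequence ids")
    if len(seqs) == 1:
        return Alignment([(seqs[0].id, seqs[0].residues)])
    sub = raw_matrix(matrix)
    std = sub.shape[0] - 1  # number of standard residues
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i].id))
    first = seqs[order[0]]
    aligned_rows: list[list[int]] = [list(encode(first.residues))]
    row_ids = [first.id]
    for k in order[1:]:
        seq = seqs[k]
        rows = np.array(aligned_rows)
        freqs = _profile_counts(rows, std)
        profile_scores = freqs @ sub[:std, :std]
        enc = encode(seq.residues)
        prof_idx, seq_idx = _align_seq_to_profile(
            profile_scores, enc, gap_open, gap_extend
        )
        new_rows: list[list[int]] = [[] for _ in aligned_rows]
        new_seq_row: list[int] = []
        for pi, si in zip(prof_idx, seq_idx):
            for r, row in enumerate(aligned_rows):
                new_rows[r].append(row[pi] if pi >= 0 else -1)
            new_seq_row.append(int(enc[si]) if si >= 0 else -1)
        aligned_rows = new_rows + [new_seq_row]
        row_ids.append(seq.id)
    from .matrices import ALPHABET

    def decode(row: list[int]) -> str:
        return "".join(GAP if v < 0 else ALPHABET[v] for v in row)

    by_id = dict(zip(row_ids, aligned_rows))
    return Alignment([(s.id, decode(by_id[s.id])) for s in seqs])


def mafft_align(
    seqs: list[Sequence],
    options: tuple[str, ...] = ("--globalpair", "--maxiterate", "2"),
) -> Alignment:
    """Align with the MAFFT executable (must be on PATH); row order preserved.

    The default options select the global-pairwise (G-INS-1 style) mode
    with a couple of refinement iterations — the right regime for sets of
    globally homologous domain sequences, and notably more accurate than
    the progressive default when relatives are deeply diverged.
    """
    if not seqs:
        raise UsageError("cannot align an empty sequence list")
    if len(seqs) == 1:
        return Alignment([(seqs[0].id, seqs[0].residues)])
    from .seqio import read_alignment, write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        write_fasta(seqs, infile)
        with open(outfile, "w", encoding="utf-8") as out:
            subprocess.run(
                ["mafft", "--quiet", "--anysymbol", *options, str(infile)],
                stdout=out, stderr=subprocess.DEVNULL, check=True,
            )
        aln = read_alignment(outfile)
    by_id = dict(aln.rows)
    return Alignment([(s.id, by_id[s.id]) for s in seqs])


def default_aligner(seqs: list[Sequence]) -> Alignment:
    """MAFFT when available, else the internal progressive aligner."""
    if shutil.which("mafft"):
        return mafft_align(seqs)
    return progressive_align(seqs)
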