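"""The Functional Coherence index for a parent node of the cluster tree.

A parent node merging two child clusters is functionally coherent when the
evidence of divergence between the children — specificity-determining
positions (SDPs) in the joint alignment, and alignment gappiness indicating
children of different lengths — is weak. The decision combines:

* a DOPS factor D_f: 1 only when both child alignments are informative
  (DOPS > 70), since uninformative alignments produce false SDPs;
* the SDP ratio
  R_sdp = D_f * (N_sdp / (N_c + N_sdp) - 0.2) + (1 - D_f) * (N_sdp / N_c - 1);
* a gap factor f_gap: 1 when gapped columns are at least as numerous as
  non-gapped ones.

The printed decision rule ("as_printed") is FC = 1 iff R_sdp * f_gap <= 0.
Taken literally, a parent with few gaps (f_gap = 0) is always coherent no
matter how many SDPs it contains, which defeats the stated purpose of the
index; the alternative rule "strict_gap" (FC = 1 iff R_sdp <= 0 and
f_gap = 0) treats both SDPs and gaps as vetoes and is what the tree cut
uses by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import conservation, groupsim
from .errors import UsageError
from .seqio import Alignment

DOPS_CUTOFF = 70.0
SDP_RATIO_OFFSET = 0.2
GAP_COLUMN_FRACTION = 0.5

#: FC decision rules; see module docstring.
FC_RULES = ("as_printed", "strict_gap")


@dataclass
class CoherenceDecision:
    """Every quantity entering one parent-node coherence decision."""

    n_sdp: int
    n_c: int
    n_gap: int
    n_nongap: int
    dops_child1: float
    dops_child2: float
    d_f: int
    f_gap: int
    r_sdp: float
    fc: int


def dops_factor(dops1: float, dops2: float, cutoff: float = DOPS_CUTOFF) -> int:
    """1 iff both child alignments have DOPS strictly above ``cutoff``.

    A DOPS of exactly the cutoff yields 0 (the conservative reading of the
    strict inequalities in the rule).
    """
    for d in (dops1, dops2):
        if not 0.0 <= d <= 100.0:
            raise UsageError(f"DOPS value {d} outside [0, 100]")
    return int(dops1 > cutoff and dops2 > cutoff)


def gap_factor(
    aln: Alignment, gap_column_fraction: float = GAP_COLUMN_FRACTION
) -> tuple[int, int, int]:
    """Return (f_gap, n_gap, n_nongap) for a parent alignment.

    A column counts as gapped when its gap fraction is >= the per-column
    threshold. f_gap = 1 when n_nongap <= n_gap (ties included), else 0.
    """
    enc = aln.encoded()
    gap_frac = (enc < 0).mean(axis=0)
    n_gap = int(np.sum(gap_frac >= gap_column_fraction))
    n_nongap = aln.n_columns - n_gap
    return int(n_nongap <= n_gap), n_gap, n_nongap


def sdp_ratio(n_sdp: int, n_c: int, d_f: int) -> float:
    """The SDP ratio R_sdp for a parent node.

    Degenerate denominators: no scored columns at all (N_c + N_sdp = 0) mean
    no divergence evidence, returning -0.2 (merge); with D_f = 0 and N_c = 0
    but SDPs present, the ratio is +inf (never merge).
    """
    if n_sdp < 0 or n_c < 0:
        raise UsageError("counts must be non-negative")
    if d_f not in (0, 1):
        raise UsageError("d_f must be 0 or 1")
    if n_sdp + n_c == 0:
        return -SDP_RATIO_OFFSET
    if d_f == 1:
        return n_sdp / (n_c + n_sdp) - SDP_RATIO_OFFSET
    if n_c == 0:
        return math.inf
    return n_sdp / n_c - 1.0


def functional_coherence(r_sdp: float, f_gap: int, rule: str = "as_printed") -> int:
    """The binary coherence index FC of a parent node."""
    if f_gap not in (0, 1):
        raise UsageError("f_gap must be 0 or 1")
    if rule == "as_printed":
        return int(r_sdp * f_gap <= 0)
    if rule == "strict_gap":
        return int(r_sdp <= 0 and f_gap == 0)
    raise UsageError(f"unknown FC rule {rule!r}; expected one of {FC_RULES}")


def evaluate_parent(
    ga: groupsim.GroupedAlignment,
    matrix: str = "BLOSUM62",
    rule: str = "as_printed",
    dops_cutoff: float = DOPS_CUTOFF,
    gap_column_fraction: float = GAP_COLUMN_FRACTION,
    min_nongap_fraction: float = 0.5,
    weighting: str = "none",
) -> CoherenceDecision:
    """Full coherence decision for a parent node given its grouped alignment.

    Child DOPS values are computed on each child's own sub-alignment
    (all-gap columns dropped); a child with fewer than 2 rows or 2 columns
    gets DOPS 0, forcing D_f = 0.
    """
    m1, m2 = ga.group_masks()
    ids = np.array(ga.aln.ids)
    child_dops = []
    for mask in (m1, m2):
        child_ids = ids[mask].tolist()
        if len(child_ids) < 2:
            child_dops.append(0.0)
            continue
        sub = ga.aln.subalignment(child_ids, drop_all_gap_columns=True)
        if sub.n_columns < 2:
            child_dops.append(0.0)
            continue
        prof = conservation.score_columns(sub, matrix=matrix, weighting=weighting)
        child_dops.append(prof.dops)
    d_f = dops_factor(child_dops[0], child_dops[1], cutoff=dops_cutoff)
    f_gap, n_gap, n_nongap = gap_factor(ga.aln, gap_column_fraction)
    sdp_profile = groupsim.score_sdp(
        ga, matrix=matrix, min_nongap_fraction=min_nongap_fraction
    )
    n_sdp, n_c = groupsim.classify_columns(sdp_profile)
    r = sdp_ratio(n_sdp, n_c, d_f)
    fc = functional_coherence(r, f_gap, rule=rule)
    return CoherenceDecision(
        n_sdp=n_sdp,
        n_c=n_c,
        n_gap=n_gap,
        n_nongap=n_nongap,
        dops_child1=child_dops[0],
        dops_child2=child_dops[1],
        d_f=d_f,
        f_gap=f_gap,
        r_sdp=r,
        fc=fc,
    )
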