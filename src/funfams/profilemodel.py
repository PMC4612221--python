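"""Per-family scoring models and membership assignment.

Each FunFam gets a position-specific scoring model built from its seed
alignment: match columns are those with < 50% gaps, and per-column emission
log-odds (bits) compare observed residue frequencies (with a small
pseudocount) against Robinson-Robinson background frequencies. Sequences
are scored by affine-gap local dynamic programming over the emission
log-odds, yielding a bit score and the aligned interval.

The family's *inclusion threshold* is the lowest score any of its own seed
sequences achieves against the model — so by construction every seed is a
member, and a new sequence is admitted only if it scores at least as high
as the weakest seed. Assignment of a query to a family takes the
highest-scoring model among those whose threshold the query meets.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import ModelError, UsageError
from .matrices import AA_INDEX, AMINO_ACIDS, BACKGROUND
from .seqio import Sequence
from .treecut import FunFam

N_STANDARD = len(AMINO_ACIDS)

GAP_OPEN_BITS = 4.0
GAP_EXTEND_BITS = 0.25
MATCH_GAP_FRACTION = 0.5


@dataclass
class ProfileModel:
    """Emission log-odds (bits) per match column plus an inclusion threshold."""

    family_id: str
    emissions: np.ndarray          # (n_match_columns, 20) bits
    gap_open: float = GAP_OPEN_BITS
    gap_extend: float = GAP_EXTEND_BITS
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    inclusion_threshold: float = 0.0

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != N_STANDARD:
            raise ModelError("emissions must be (n_columns, 20)")
        if not np.isfinite(self.emissions).all():
            raise ModelError("emissions must be finite")

    def __len__(self) -> int:
        return self.emissions.shape[0]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "emissions": self.emissions.tolist(),
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "background": self.background.tolist(),
            "inclusion_threshold": self.inclusion_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileModel":
        return cls(
            family_id=d["family_id"],
            emissions=np.array(d["emissions"]),
            gap_open=d["gap_open"],
            gap_extend=d["gap_extend"],
            background=np.array(d["background"]),
            inclusion_threshold=d["inclusion_threshold"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ProfileModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ScanHit:
    """Result of scoring one sequence against one family model."""

    sequence_id: str
    family_id: str
    bit_score: float
    start: int  # 1-based, inclusive, on the sequence
    end: int    # 1-based, inclusive
    assigned: bool = False


def build_model(
    funfam: FunFam,
    pseudocount: float = 2.0,
    gap_open: float = GAP_OPEN_BITS,
    gap_extend: float = GAP_EXTEND_BITS,
) -> ProfileModel:
    """Build the family model and set its lowest-seed-score threshold.

    ``pseudocount`` is the background prior mass *per observed sequence*
    (the effective prior is ``pseudocount * n_eff``), so smoothing keeps
    pace with the seed count.

    The inclusion threshold is the minimum seed self-scan score, evaluated
    leave-one-out: each seed is scored against emissions estimated from
    the other seeds. A count-based profile gives every seed a preference
    for its own private substitutions, so self-inclusive scans would sit
    systematically above what any genuine new member can reach and the
    lowest-seed threshold would reject true relatives; the leave-one-out
    scan is the unbiased seed score the rule intends.
    """
    enc = funfam.alignment.encoded()
    n_rows, n_cols = enc.shape
    gap_frac = (enc < 0).mean(axis=0)
    match_cols = np.nonzero(gap_frac < MATCH_GAP_FRACTION)[0]
    if len(match_cols) == 0:
        raise ModelError(
            f"family {funfam.family_id}: alignment has no match columns"
        )

    count_matrix = np.zeros((len(match_cols), N_STANDARD))
    for out_i, c in enumerate(match_cols):
        col = enc[:, c]
        col = col[(col >= 0) & (col < N_STANDARD)]  # gaps and X excluded
        count_matrix[out_i] = np.bincount(col, minlength=N_STANDARD)

    def emissions_from(counts: np.ndarray) -> np.ndarray:
        n_eff = counts.sum(axis=1, keepdims=True)
        alpha = pseudocount * np.maximum(n_eff, 1.0)
        probs = (counts + alpha * BACKGROUND) / (n_eff + alpha)
        return np.log2(probs / BACKGROUND)

    model = ProfileModel(
        family_id=funfam.family_id,
        emissions=emissions_from(count_matrix),
        gap_open=gap_open,
        gap_extend=gap_extend,
        inclusion_threshold=-np.inf,
    )

    seeds = funfam.alignment.ungapped()
    loo_scores = []
    if n_rows == 1:
        loo_scores.append(score_sequence(seeds[0], model).bit_score)
    else:
        for row, seed in enumerate(seeds):
            counts = count_matrix.copy()
            row_res = enc[row, match_cols]
            ok = (row_res >= 0) & (row_res < N_STANDARD)
            counts[np.nonzero(ok)[0], row_res[ok]] -= 1.0
            loo_model = ProfileModel(
                family_id=model.family_id,
                emissions=emissions_from(counts),
                gap_open=gap_open,
                gap_extend=gap_extend,
                inclusion_threshold=-np.inf,
            )
            loo_scores.append(score_sequence(seed, loo_model).bit_score)
    model.inclusion_threshold = float(min(loo_scores))
    return model


def score_sequence(seq: Sequence, model: ProfileModel) -> ScanHit:
    """Best local affine-gap alignment score of ``seq`` against the model."""
    if len(seq.residues) == 0:
        raise UsageError("cannot score an empty sequence")
    enc = np.array(
        [AA_INDEX[ch] for ch in seq.residues], dtype=np.int64
    )
    n = len(enc)
    m = len(model)
    # substitution score of sequence position i at model column j
    sub = np.zeros((n, m))
    std_mask = enc < N_STANDARD
    sub[std_mask] = model.emissions[:, enc[std_mask]].T  # X rows stay 0
    go, ge = model.gap_open, model.gap_extend
    NEG = -1e30
    # Smith-Waterman with affine gaps; origin rows propagated for the interval
    prev_m = np.zeros(m + 1)
    prev_y = np.full(m + 1, NEG)
    orig_m = np.zeros(m + 1, dtype=np.int64)
    orig_y = np.zeros(m + 1, dtype=np.int64)
    best = 0.0
    best_end = 0
    best_orig = 0
    for i in range(1, n + 1):
        cur_m = np.zeros(m + 1)
        cur_x = np.full(m + 1, NEG)
        cur_y = np.full(m + 1, NEG)
        cur_om = np.full(m + 1, i, dtype=np.int64)
        cur_ox = np.zeros(m + 1, dtype=np.int64)
        cur_oy = np.zeros(m + 1, dtype=np.int64)
        # Y: gap in model (sequence residue consumed, column stays)
        y_from_m = prev_m - go
        y_from_y = prev_y - ge
        take_m = y_from_m >= y_from_y
        cur_y = np.where(take_m, y_from_m, y_from_y)
        cur_oy = np.where(take_m, orig_m, orig_y)
        # M: diagonal from best previous state
        diag_scores = np.stack([prev_m[:-1], prev_y[:-1]])
        diag_orig = np.stack([orig_m[:-1], orig_y[:-1]])
        # X (gap in sequence) from previous row is folded into prev_m via
        # the in-row scan below, so diagonal competitors are M and Y.
        pick = diag_scores.argmax(axis=0)
        base = diag_scores.max(axis=0)
        borig = np.take_along_axis(diag_orig, pick[None, :], axis=0)[0]
        cand = base + sub[i - 1]
        # local alignment: restart (score 0) when continuing scores < 0
        restart = cand < sub[i - 1]
        cur_m[1:] = np.where(restart, sub[i - 1], cand)
        cur_om[1:] = np.where(restart, i - 1, borig)
        # X: gap in sequence (model column skipped), scan within the row
        run = NEG
        run_orig = 0
        for j in range(1, m + 1):
            open_cand = cur_m[j - 1] - go
            if open_cand >= run - ge:
                run = open_cand
                run_orig = cur_om[j - 1]
            else:
                run = run - ge
            cur_x[j] = run
            cur_ox[j] = run_orig
        # states eligible to end the local alignment: M only (alignments
        # ending in a gap are never optimal with positive penalties)
        row_best_j = int(np.argmax(cur_m))
        if cur_m[row_best_j] > best:
            best = float(cur_m[row_best_j])
            best_end = i
            best_orig = int(cur_om[row_best_j])
        # fold X into the "previous m" track used by the next row's diagonal
        merged = np.maximum(cur_m, cur_x)
        merged_orig = np.where(cur_x > cur_m, cur_ox, cur_om)
        prev_m, orig_m = merged, merged_orig
        prev_y, orig_y = cur_y, cur_oy
    if best <= 0.0:
        return ScanHit(seq.id, model.family_id, 0.0, 1, 1)
    return ScanHit(seq.id, model.family_id, best, best_orig + 1, best_end)


def assign(
    seqs: Iterable[Sequence],
    models: list[ProfileModel],
    mode: Literal["best_hit", "all_above_threshold"] = "best_hit",
) -> list[ScanHit]:
    """Assign sequences to families by model score and inclusion threshold.

    ``best_hit``: one hit per sequence — the highest-scoring model among
    those whose threshold the sequence meets (ties to the smaller family
    id); sequences meeting no threshold are reported with assigned=False
    (carrying their best raw hit, if any). ``all_above_threshold``: every
    model whose threshold is met yields an assigned hit.
    """
    if not models:
        raise UsageError("assign needs at least one model")
    if mode not in ("best_hit", "all_above_threshold"):
        raise UsageError(f"unknown assignment mode {mode!r}")
    out: list[ScanHit] = []
    for seq in seqs:
        hits = [score_sequence(seq, model) for model in models]
        eligible = [
            (h, m) for h, m in zip(hits, models)
            if h.bit_score >= m.inclusion_threshold
        ]
        if mode == "all_above_threshold":
            if eligible:
                out.extend(
                    ScanHit(h.sequence_id, h.family_id, h.bit_score,
                            h.start, h.end, assigned=True)
                    for h, _ in eligible
                )
            else:
                best = max(hits, key=lambda h: h.bit_score)
                out.append(best)
            continue
        if eligible:
            # highest score wins; ties break toward the smaller family id
            top = max(e[0].bit_score for e in eligible)
            tied = sorted(
                (e[0] for e in eligible if e[0].bit_score == top),
                key=lambda x: x.family_id,
            )
            h = tied[0]
            out.append(
                ScanHit(h.sequence_id, h.family_id, h.bit_score,
                        h.start, h.end, assigned=True)
            )
        else:
            best = max(hits, key=lambda h: h.bit_score)
            out.append(best)
    return out


def write_scan_tsv(hits: list[ScanHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# sequence\tfamily\tbit_score\tstart\tend\tassigned\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.family_id}\t{h.bit_score:.2f}\t"
                f"{h.start}\t{h.end}\t{int(h.assigned)}\n"
            )


def save_library(models: list[ProfileModel], directory: str | Path) -> None:
    """One JSON file per model plus an index TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "index.tsv", "w", encoding="utf-8") as fh:
        fh.write("# family\tfile\tn_columns\tinclusion_threshold\n")
        for model in models:
            fname = f"{model.family_id}.json"
            model.save(directory / fname)
            fh.write(
                f"{model.family_id}\t{fname}\t{len(model)}\t"
                f"{model.inclusion_threshold:.4f}\n"
            )


def load_library(directory: str | Path) -> list[ProfileModel]:
    directory = Path(directory)
    models = []
    with open(directory / "index.tsv", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, fname, _, _ = line.rstrip("\n").split("\t")
            models.append(ProfileModel.load(directory / fname))
    return models
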