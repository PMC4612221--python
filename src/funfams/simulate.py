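"""Synthetic superfamilies with planted functional subfamilies.

The generator emulates the alignment structure the classification relies
on: a superfamily of K subfamilies sharing family-wide conserved columns,
each subfamily carrying its own conserved residues at planted SDP columns
(chosen mutually dissimilar between subfamilies), and neutral columns
mutating independently per sequence. Optional subfamily-specific insertions
create length divergence and fragments exercise the fragment filter.
Subfamily-level GO terms (plus shared family-wide terms) and one distinct
EC number per subfamily provide annotation truth.

Sequences within a subfamily are independent draws around the subfamily
consensus (star topology); there is no deeper phylogeny. All outputs are
deterministic under the configured seed.

Truth column indices are 0-based coordinates of the core (ancestor)
alignment; they coincide with master-alignment columns when no indels are
simulated.
"""
from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml

from .errors import UsageError
from .matrices import AMINO_ACIDS, normalized_similarity
from .seqio import (
    AnnotationRecord,
    AnnotationTable,
    GODag,
    Sequence,
    write_fasta,
)

GO_ROOT = "GO:0000001"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic superfamily."""

    seed: int = 0
    k_subfamilies: int = 4
    seqs_per_subfamily: int = 20
    length: int = 200
    frac_conserved: float = 0.15
    frac_sdp: float = 0.30
    frac_neutral: float = 0.55
    mutation_rate_functional: float = 0.04
    mutation_rate_neutral: float = 0.30
    indel_rate: float = 0.0
    fragment_fraction: float = 0.0
    go_terms_per_subfamily: int = 2
    shared_go_fraction: float = 0.5
    neutral_drift: float = 0.30
    annotated_fraction: float = 0.9
    catalytic_fraction: float = 0.3
    sdp_max_similarity: float = 0.35

    def __post_init__(self):
        fracs = (self.frac_conserved, self.frac_sdp, self.frac_neutral,
                 self.indel_rate, self.fragment_fraction,
                 self.shared_go_fraction, self.annotated_fraction,
                 self.catalytic_fraction, self.neutral_drift)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise UsageError("all fractions must lie in [0, 1]")
        if abs(self.frac_conserved + self.frac_sdp + self.frac_neutral - 1.0) > 1e-9:
            raise UsageError("column fractions must sum to 1")
        for name in ("k_subfamilies", "seqs_per_subfamily", "length",
                     "go_terms_per_subfamily"):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be >= 1")


@dataclass
class Truth:
    """Planted ground truth for one simulated superfamily."""

    subfamily_of: dict[str, int]
    sdp_columns: list[int]
    conserved_columns: list[int]
    catalytic_columns: list[int]
    go_terms: dict[int, list[str]]
    ec_numbers: dict[int, str]
    fragments: set[str] = field(default_factory=set)


@lru_cache(maxsize=8)
def _most_dissimilar_set(k: int) -> tuple[tuple[int, ...], float]:
    """The k-residue subset minimizing its worst pairwise similarity.

    Exhaustive over all C(20, k) subsets (cheap for k <= 6); ties broken
    by total pairwise similarity, then lexicographically. Returns the
    subset and its worst pairwise similarity.
    """
    sim = normalized_similarity()
    n = len(AMINO_ACIDS)
    best: tuple[tuple[int, ...], float] | None = None
    best_key = (np.inf, np.inf)
    for combo in itertools.combinations(range(n), k):
        pair_sims = [sim[a, b] for a, b in itertools.combinations(combo, 2)]
        worst = max(pair_sims) if pair_sims else 0.0
        key = (worst, sum(pair_sims))
        if key < best_key:
            best_key = key
            best = (combo, worst)
    assert best is not None
    return best


def _pick_sdp_residues(
    k: int, rng: np.random.Generator, max_similarity: float
) -> list[int]:
    """K residue indices, one per subfamily, as mutually dissimilar as the
    alphabet allows; the per-subfamily assignment is shuffled per call."""
    combo, worst = _most_dissimilar_set(k)
    if worst >= max_similarity:
        raise UsageError(
            f"cannot plant {k} mutually dissimilar residues at similarity "
            f"< {max_similarity} (best achievable worst pair: {worst:.3f}); "
            f"lower k_subfamilies or raise sdp_max_similarity"
        )
    order = rng.permutation(k)
    return [int(combo[i]) for i in order]


@lru_cache(maxsize=1)
def _conservative_neighbors() -> tuple[tuple[int, ...], ...]:
    """For each residue, the most similar other residues (top 4 by
    normalized similarity) — the pool for conservative substitutions."""
    sim = normalized_similarity()
    n = len(AMINO_ACIDS)
    out = []
    for a in range(n):
        order = np.argsort(-sim[a, :n])
        neighbors = tuple(int(b) for b in order if b != a)[:4]
        out.append(neighbors)
    return tuple(out)


def _conservative_substitute(residue: int, rng: np.random.Generator) -> int:
    neighbors = _conservative_neighbors()[residue]
    return neighbors[int(rng.integers(len(neighbors)))]


def simulate_superfamily(config: SimulationConfig) -> tuple[list[Sequence], Truth]:
    """Generate the superfamily's sequences and their planted truth."""
    rng = np.random.default_rng(config.seed)
    L = config.length
    k = config.k_subfamilies
    n_cons = int(round(config.frac_conserved * L))
    n_sdp = int(round(config.frac_sdp * L))
    cols = rng.permutation(L)
    conserved_cols = sorted(int(c) for c in cols[:n_cons])
    sdp_cols = sorted(int(c) for c in cols[n_cons:n_cons + n_sdp])

    ancestor = rng.integers(0, len(AMINO_ACIDS), size=L)
    sdp_residues = {c: _pick_sdp_residues(k, rng, config.sdp_max_similarity)
                    for c in sdp_cols}

    n_cat = int(round(config.catalytic_fraction * len(conserved_cols)))
    catalytic_cols = conserved_cols[:n_cat]

    # site-to-site rate variation: each column draws its own rate around
    # its class mean so conservation scores spread continuously instead of
    # piling onto few values. Conserved columns get a wide spread (their
    # scores may roam the whole high-conservation band), SDP columns a
    # narrow one (their group-specific signal must stay crisp), neutral
    # columns a broad mid-range spread.
    rates = config.mutation_rate_neutral * rng.uniform(0.5, 1.5, size=L)
    functional = np.array(conserved_cols + sdp_cols, dtype=int)
    rates[np.array(conserved_cols, dtype=int)] = (
        config.mutation_rate_functional * rng.uniform(0.1, 4.0, size=len(conserved_cols))
    )
    rates[np.array(sdp_cols, dtype=int)] = (
        config.mutation_rate_functional * rng.uniform(0.5, 1.5, size=len(sdp_cols))
    )

    seqs: list[Sequence] = []
    subfamily_of: dict[str, int] = {}
    fragments: set[str] = set()
    ins_len = int(round(config.indel_rate * L))
    n_aa = len(AMINO_ACIDS)
    neutral_cols = [c for c in range(L)
                    if c not in set(conserved_cols) and c not in set(sdp_cols)]
    for sf in range(k):
        consensus = ancestor.copy()
        for c in sdp_cols:
            consensus[c] = sdp_residues[c][sf]
        # lineage-specific drift: each subfamily's consensus wanders at a
        # fraction of neutral sites, as real subfamilies do; at impure
        # nodes these columns score mid-range (neither conserved nor SDP)
        for c in neutral_cols:
            if rng.random() < config.neutral_drift:
                shift = int(rng.integers(1, n_aa))
                consensus[c] = (consensus[c] + shift) % n_aa
        insert_pos = int(rng.integers(L // 5, 4 * L // 5)) if ins_len else 0
        insert_seg = rng.integers(0, n_aa, size=ins_len)
        block = np.empty((config.seqs_per_subfamily, L), dtype=np.int64)
        # per-lineage divergence: each sequence mutates at its own pace
        seq_mult = rng.uniform(0.8, 1.2, size=config.seqs_per_subfamily)
        is_functional = np.zeros(L, dtype=bool)
        is_functional[functional] = True
        for i in range(config.seqs_per_subfamily):
            mutate = rng.random(L) < np.clip(rates * seq_mult[i], 0.0, 0.95)
            shifts = rng.integers(1, n_aa, size=L)
            random_subs = (consensus + shifts) % n_aa
            block[i] = np.where(mutate, random_subs, consensus)
            # functional sites tolerate only conservative substitutions:
            # the mutant stays similar to the site's consensus residue
            # (and hence dissimilar to other subfamilies' SDP residues)
            for c in np.nonzero(mutate & is_functional)[0]:
                block[i, c] = _conservative_substitute(int(consensus[c]), rng)
        # informative-alignment guarantee: every functional column carries
        # at least one substitution (two for family-conserved columns), so
        # column conservation scores mix several similarity values and
        # stay diverse across the alignment; SDP columns are forced less
        # to keep their within-group conservation — and hence their
        # group-contrast scores — crisp
        sdp_set = set(sdp_cols)
        for c in functional:
            min_subs = min(1 if c in sdp_set else 2,
                           config.seqs_per_subfamily - 1)
            mutated_rows = np.nonzero(block[:, c] != consensus[c])[0]
            missing = min_subs - len(mutated_rows)
            if missing > 0:
                unmutated = np.nonzero(block[:, c] == consensus[c])[0]
                pick = rng.choice(unmutated, size=missing, replace=False)
                for row in pick:
                    block[row, c] = _conservative_substitute(
                        int(consensus[c]), rng
                    )
        for i in range(config.seqs_per_subfamily):
            residues = block[i]
            if ins_len:
                residues = np.concatenate(
                    [residues[:insert_pos], insert_seg, residues[insert_pos:]]
                )
            sid = f"SF{sf:02d}_S{i:03d}"
            text = "".join(AMINO_ACIDS[r] for r in residues)
            seqs.append(Sequence(sid, text))
            subfamily_of[sid] = sf
    # fragments: truncate a deterministic subset of each subfamily's tail
    if config.fragment_fraction > 0:
        n_frag = int(round(config.fragment_fraction * config.seqs_per_subfamily))
        frag_ids = {
            f"SF{sf:02d}_S{i:03d}"
            for sf in range(k)
            for i in range(config.seqs_per_subfamily - n_frag,
                           config.seqs_per_subfamily)
        }
        out = []
        for s in seqs:
            if s.id in frag_ids:
                keep = int(0.6 * len(s.residues))
                out.append(Sequence(s.id, s.residues[:keep], s.description))
                fragments.add(s.id)
            else:
                out.append(s)
        seqs = out

    # conserved/SDP columns are disjoint by construction
    go_terms, ec_numbers = _plant_labels(config)
    truth = Truth(
        subfamily_of=subfamily_of,
        sdp_columns=sdp_cols,
        conserved_columns=conserved_cols,
        catalytic_columns=catalytic_cols,
        go_terms=go_terms,
        ec_numbers=ec_numbers,
        fragments=fragments,
    )
    return seqs, truth


def _plant_labels(config: SimulationConfig) -> tuple[dict[int, list[str]], dict[int, str]]:
    n_shared = int(round(config.shared_go_fraction * config.go_terms_per_subfamily))
    shared = [f"GO:{2 + j:07d}" for j in range(n_shared)]
    go_terms: dict[int, list[str]] = {}
    next_num = 2 + n_shared
    for sf in range(config.k_subfamilies):
        unique = [f"GO:{next_num + j:07d}"
                  for j in range(config.go_terms_per_subfamily)]
        next_num += config.go_terms_per_subfamily
        go_terms[sf] = shared + unique
    ec_numbers = {sf: f"{sf + 1}.1.1.1" for sf in range(config.k_subfamilies)}
    return go_terms, ec_numbers


def simulate_annotations(
    truth: Truth, config: SimulationConfig
) -> tuple[AnnotationTable, AnnotationTable, GODag]:
    """Annotation tables (GO, EC) and the toy DAG linking terms to one root."""
    all_terms = {GO_ROOT} | {
        t for terms in truth.go_terms.values() for t in terms
    }
    parents = {t: ({GO_ROOT} if t != GO_ROOT else set()) for t in all_terms}
    dag = GODag(
        terms=all_terms,
        parents=parents,
        namespace={t: "molecular_function" for t in all_terms},
    )
    go_records: list[AnnotationRecord] = []
    ec_records: list[AnnotationRecord] = []
    per_sf: dict[int, list[str]] = {}
    for sid, sf in truth.subfamily_of.items():
        per_sf.setdefault(sf, []).append(sid)
    for sf, members in per_sf.items():
        members = sorted(members)
        n_annotated = int(round(config.annotated_fraction * len(members)))
        for sid in members[:n_annotated]:
            for term in truth.go_terms[sf]:
                go_records.append(
                    AnnotationRecord(sid, term, "molecular_function",
                                     "high_quality")
                )
            ec_records.append(
                AnnotationRecord(sid, truth.ec_numbers[sf], "EC", "high_quality")
            )
    return AnnotationTable(go_records), AnnotationTable(ec_records), dag


# ---------------------------------------------------------------------------
# Run-directory export
# ---------------------------------------------------------------------------

def write_toy_obo(dag: GODag, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term}\n")
            ns = dag.namespace.get(term, "molecular_function")
            fh.write(f"namespace: {ns}\n")
            for parent in sorted(dag.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! parent\n")
            fh.write("\n")


def write_annotations_tsv(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# accession\tterm\tevidence\tnamespace\n")
        for rec in table:
            evidence = "EXP" if rec.evidence_class == "high_quality" else "IEA"
            fh.write(f"{rec.accession}\t{rec.term}\t{evidence}\t{rec.namespace}\n")


def write_truth_tsv(truth: Truth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# sequence\tsubfamily\tec\tgo_terms\tis_fragment\n")
        for sid in sorted(truth.subfamily_of):
            sf = truth.subfamily_of[sid]
            terms = ",".join(truth.go_terms[sf])
            fh.write(
                f"{sid}\t{sf}\t{truth.ec_numbers[sf]}\t{terms}\t"
                f"{int(sid in truth.fragments)}\n"
            )
        fh.write(f"# sdp_columns\t{','.join(str(c + 1) for c in truth.sdp_columns)}\n")
        fh.write(
            f"# conserved_columns\t"
            f"{','.join(str(c + 1) for c in truth.conserved_columns)}\n"
        )
        fh.write(
            f"# catalytic_columns\t"
            f"{','.join(str(c + 1) for c in truth.catalytic_columns)}\n"
        )


def write_run_dir(config: SimulationConfig, outdir: str | Path) -> Path:
    """Simulate and write FASTA, truth, annotations, toy OBO and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs, truth = simulate_superfamily(config)
    go_table, ec_table, dag = simulate_annotations(truth, config)
    write_fasta(seqs, outdir / "sequences.fasta")
    write_truth_tsv(truth, outdir / "truth.tsv")
    write_annotations_tsv(go_table, outdir / "go_annotations.tsv")
    write_annotations_tsv(ec_table, outdir / "ec_annotations.tsv")
    write_toy_obo(dag, outdir / "ontology.obo")
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return outdir
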