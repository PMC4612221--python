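"""Probabilistic GO-term transfer from matched families to query proteins.

A query assigned to a family inherits each of the family's GO terms with a
confidence equal to the term's annotation frequency among the family's seed
sequences. Confidences are then propagated up the GO DAG (each ancestor
taking the maximum over its predicted descendants), and per-domain
predictions are combined into whole-protein predictions keeping each term's
highest confidence.

Seed counting is DAG-aware by default: a seed counts as annotated with term
t if it carries t or any descendant of t (annotation depth varies between
curators); exact-term counting is available via ``count_descendants=False``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import AnnotationError
from .profilemodel import ProfileModel, ScanHit, score_sequence
from .seqio import AnnotationTable, GODag, Sequence
from .treecut import FunFam

#: Residue overlap two accepted domain hits may share on the query.
DOMAIN_OVERLAP_TOLERANCE = 15


@dataclass(frozen=True)
class Prediction:
    """One (protein, GO term) prediction with its confidence and source."""

    protein_id: str
    term: str
    confidence: float
    family_ids: tuple[str, ...]


def family_term_frequencies(
    funfam: FunFam,
    annotations: AnnotationTable,
    dag: GODag,
    count_descendants: bool = True,
    high_quality_only: bool = True,
) -> dict[str, float]:
    """Per-term confidence = annotated-seed count / total seed count."""
    n_seeds = len(funfam.members)
    closed: list[set[str]] = []
    any_annotated = False
    for member in funfam.members:
        terms = annotations.terms_for(member, high_quality_only=high_quality_only)
        terms = {t for t in terms if t in dag.terms}
        if terms:
            any_annotated = True
        if count_descendants:
            up: set[str] = set()
            for t in terms:
                up |= dag.ancestors(t, include_self=True)
            terms = up
        closed.append(terms)
    if not any_annotated:
        raise AnnotationError(
            f"family {funfam.family_id} has no annotated seed sequences"
        )
    all_terms = set().union(*closed)
    return {
        t: sum(t in seed_terms for seed_terms in closed) / n_seeds
        for t in all_terms
    }


def propagate(
    preds: dict[str, float], dag: GODag, suppress_roots: bool = False
) -> dict[str, float]:
    """Propagate term confidences upward: ancestor = max over descendants.

    Terms absent from the DAG are passed through unchanged with a warning.
    """
    out: dict[str, float] = {}
    for term, conf in preds.items():
        if term not in dag.terms:
            warnings.warn(f"term {term} not in ontology; passed through")
            out[term] = max(out.get(term, 0.0), conf)
            continue
        for t in dag.ancestors(term, include_self=True):
            out[t] = max(out.get(t, 0.0), conf)
    if suppress_roots:
        for root in dag.roots():
            out.pop(root, None)
    return out


def resolve_domains(
    hits: Iterable[ScanHit], overlap_tolerance: int = DOMAIN_OVERLAP_TOLERANCE
) -> list[ScanHit]:
    """Greedy non-overlapping selection of assigned hits by descending score."""
    chosen: list[ScanHit] = []
    for hit in sorted(
        (h for h in hits if h.assigned),
        key=lambda h: (-h.bit_score, h.family_id),
    ):
        ok = True
        for kept in chosen:
            overlap = min(hit.end, kept.end) - max(hit.start, kept.start) + 1
            if overlap > overlap_tolerance:
                ok = False
                break
        if ok:
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def predict_protein(
    protein: Sequence,
    models: list[ProfileModel],
    funfams_by_id: dict[str, FunFam],
    annotations: AnnotationTable,
    dag: GODag,
    overlap_tolerance: int = DOMAIN_OVERLAP_TOLERANCE,
    count_descendants: bool = True,
) -> list[Prediction]:
    """Whole-protein GO predictions via domain resolution and max-union.

    Every model is scanned; hits meeting their family's inclusion threshold
    compete for non-overlapping domain regions (greedy by score). Each
    accepted domain transfers its family's propagated term frequencies; the
    union keeps each term's highest confidence. A protein matching nothing
    yields an empty list.
    """
    raw_hits = []
    for model in models:
        hit = score_sequence(protein, model)
        if hit.bit_score >= model.inclusion_threshold:
            raw_hits.append(
                ScanHit(hit.sequence_id, hit.family_id, hit.bit_score,
                        hit.start, hit.end, assigned=True)
            )
    domains = resolve_domains(raw_hits, overlap_tolerance)
    best: dict[str, tuple[float, set[str]]] = {}
    for hit in domains:
        fam = funfams_by_id[hit.family_id]
        try:
            freqs = family_term_frequencies(
                fam, annotations, dag, count_descendants=count_descendants
            )
        except AnnotationError:
            continue
        for term, conf in propagate(freqs, dag).items():
            prev_conf, prev_fams = best.get(term, (0.0, set()))
            if conf > prev_conf:
                best[term] = (conf, {hit.family_id})
            elif conf == prev_conf:
                best[term] = (conf, prev_fams | {hit.family_id})
    return [
        Prediction(protein.id, term, conf, tuple(sorted(fams)))
        for term, (conf, fams) in sorted(best.items())
    ]


def write_predictions_tsv(preds: list[Prediction], path: str | Path) -> None:
    """CAFA-style columns: protein, term, confidence (3 decimals), families."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein\tterm\tconfidence\tfamilies\n")
        for p in preds:
            fams = ",".join(p.family_ids)
            fh.write(f"{p.protein_id}\t{p.term}\t{p.confidence:.3f}\t{fams}\n")
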