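"""Sequence/alignment data model and readers for every external format used.

Formats: FASTA and aligned FASTA (via Biopython), OBO 1.2 (via obonet),
tab-separated annotation tables with ``#`` comments. All readers accept
gzip-compressed input transparently (by ``.gz`` suffix).

Positions are 0-based internally throughout the package; every user-facing
export (TSV, CLI output) is 1-based.
"""
from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, NamedTuple

import networkx as nx
import numpy as np
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrityError, UsageError
from .matrices import ALPHABET, GAP, encode

_VALID_RESIDUES = set(ALPHABET)
_GO_RE = re.compile(r"^GO:\d{7}$")
_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|n\d+)$")


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sequence:
    """An ungapped protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered multiple sequence alignment with unique row ids.

    Rows are (id, gapped string) pairs; all gapped strings share one length.
    """

    def __init__(self, rows: Iterable[tuple[str, str]]):
        self.rows: list[tuple[str, str]] = [(str(i), str(s)) for i, s in rows]
        if not self.rows:
            raise FormatError("alignment has no rows")
        n = len(self.rows[0][1])
        for rid, row in self.rows:
            if len(row) != n:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {n}"
                )
        if n < 1:
            raise FormatError("alignment has zero columns")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("alignment row ids are not unique")
        # validate residues by round-tripping through Sequence
        for rid, row in self.rows:
            ungapped = row.replace(GAP, "")
            if ungapped:
                Sequence(rid, ungapped)
        self.n_columns = n
        self._encoded: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_rows, n_columns); gaps are -1, X is 20."""
        if self._encoded is None:
            self._encoded = np.vstack([encode(row) for _, row in self.rows])
        return self._encoded

    def ungapped(self) -> list[Sequence]:
        return [Sequence(rid, row.replace(GAP, "")) for rid, row in self.rows]

    def subalignment(
        self, ids: Iterable[str], drop_all_gap_columns: bool = True
    ) -> "Alignment":
        """Restrict to the given row ids (keeping alignment row order)."""
        wanted = set(ids)
        rows = [(rid, row) for rid, row in self.rows if rid in wanted]
        if not rows:
            raise UsageError("subalignment would be empty")
        missing = wanted - {rid for rid, _ in rows}
        if missing:
            raise UsageError(f"ids not in alignment: {sorted(missing)}")
        if drop_all_gap_columns:
            mat = np.array([[c for c in row] for _, row in rows])
            keep = ~(mat == GAP).all(axis=0)
            rows = [(rid, "".join(np.array(list(row))[keep])) for rid, row in rows]
        return Alignment(rows)


class AnnotationRecord(NamedTuple):
    accession: str
    term: str
    namespace: str
    evidence_class: str  # "high_quality" | "other"


class AnnotationTable:
    """Per-sequence function annotations (GO terms or EC numbers)."""

    def __init__(self, records: Iterable[AnnotationRecord]):
        seen: set[tuple[str, str]] = set()
        self.records: list[AnnotationRecord] = []
        for rec in records:
            key = (rec.accession, rec.term)
            if key in seen:
                continue
            seen.add(key)
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def terms_for(
        self,
        accession: str,
        high_quality_only: bool = False,
        namespace: str | None = None,
    ) -> set[str]:
        return {
            r.term
            for r in self.records
            if r.accession == accession
            and (not high_quality_only or r.evidence_class == "high_quality")
            and (namespace is None or r.namespace == namespace)
        }

    def accessions_with_high_quality(self) -> set[str]:
        return {r.accession for r in self.records if r.evidence_class == "high_quality"}

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)


@dataclass
class GODag:
    """A Gene Ontology DAG restricted to its hierarchy edges."""

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, ps in self.parents.items():
            if term not in self.terms:
                raise IntegrityError(f"parent map mentions unknown term {term!r}")
            missing = ps - self.terms
            if missing:
                raise IntegrityError(
                    f"term {term!r} references unknown parents {sorted(missing)}"
                )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term, ps in self.parents.items():
            for p in ps:
                g.add_edge(term, p)
        if not nx.is_directed_acyclic_graph(g):
            raise IntegrityError("ontology contains a cycle")
        self._graph = g

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """All terms reachable upward from ``term`` (excluding it by default)."""
        if term not in self.terms:
            raise UsageError(f"unknown term {term!r}")
        out = nx.descendants(self._graph, term)  # edges point child -> parent
        if include_self:
            out = out | {term}
        return out

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize_residues(raw: str) -> str:
    return raw.upper().replace("*", "").replace(".", GAP)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read an (ungapped) FASTA file, preserving record order.

    Lowercase residues are uppercased and ``*`` stop characters stripped.
    """
    with _open_text(path) as fh:
        text = fh.read()
    _check_fasta_text(text, path)
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = _normalize_residues(str(rec.seq)).replace(GAP, "")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(Sequence(rec.id, residues, rec.description))
    return seqs


def _check_fasta_text(text: str, path) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: expected FASTA header starting with '>'"
            )
        return
    raise FormatError(f"{path}: line 1: empty FASTA file")


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; ``.`` gaps are normalized to ``-``."""
    with _open_text(path) as fh:
        text = fh.read()
    _check_fasta_text(text, path)
    rows = [
        (rec.id, _normalize_residues(str(rec.seq)))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    return Alignment(rows)


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(row), id=rid, description="") for rid, row in aln.rows]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# OBO
# ---------------------------------------------------------------------------

def read_obo(path: str | Path, include_part_of: bool = False) -> GODag:
    """Read an OBO 1.2 ontology into a :class:`GODag`.

    Obsolete terms are excluded. ``is_a`` edges always become parent links;
    ``part_of`` relationships are included when ``include_part_of`` is set.
    """
    with _open_text(path) as fh:
        try:
            graph = obonet.read_obo(fh, ignore_obsolete=True)
        except Exception as exc:  # pragma: no cover - parser detail
            raise FormatError(f"{path}: cannot parse OBO: {exc}") from exc
    terms = set(graph.nodes)
    parents: dict[str, set[str]] = {t: set() for t in terms}
    namespace = {
        t: data.get("namespace", "") for t, data in graph.nodes(data=True)
    }
    wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
    for child, parent, key in graph.edges(keys=True):
        if key in wanted and parent in terms:
            parents[child].add(parent)
    try:
        return GODag(terms=terms, parents=parents, namespace=namespace)
    except IntegrityError:
        raise IntegrityError(f"{path}: ontology contains a cycle") from None


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

#: IEA sub-codes that still count as high quality (EC2GO / Keyword2GO mappings).
HIGH_QUALITY_IEA = frozenset({"IEA:EC2GO", "IEA:KW2GO"})


def classify_evidence(
    code: str, high_quality_iea: frozenset[str] = HIGH_QUALITY_IEA
) -> str:
    """Map a GOA-style evidence code onto {high_quality, other}.

    Default rule: every non-IEA (experimental or curated) code is high
    quality, and so are IEA annotations produced by the EC2GO or Swiss-Prot
    Keyword2GO mappings; all other electronic annotations are "other".
    """
    if code.startswith("IEA"):
        return "high_quality" if code in high_quality_iea else "other"
    return "high_quality"


def read_annotations(
    path: str | Path,
    kind: Literal["go", "ec"],
    high_quality_iea: frozenset[str] = HIGH_QUALITY_IEA,
) -> AnnotationTable:
    """Read a TSV of (accession, term, evidence[, namespace]) rows.

    ``kind="go"`` expects GO:NNNNNNN terms; ``kind="ec"`` expects complete
    four-field EC numbers.
    """
    if kind not in ("go", "ec"):
        raise UsageError(f"unknown annotation kind {kind!r}")
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            accession, term, evidence = parts[0], parts[1], parts[2]
            namespace = parts[3] if len(parts) > 3 else (
                "molecular_function" if kind == "go" else "EC"
            )
            if kind == "go" and not _GO_RE.match(term):
                raise FormatError(
                    f"{path}: line {lineno}: {term!r} is not a GO:NNNNNNN term"
                )
            if kind == "ec" and not _EC_RE.match(term):
                raise FormatError(
                    f"{path}: line {lineno}: {term!r} is not a four-field EC number"
                )
            records.append(
                AnnotationRecord(
                    accession, term, namespace,
                    classify_evidence(evidence, high_quality_iea),
                )
            )
    return AnnotationTable(records)
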