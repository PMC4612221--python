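import pytest

from funfams import annotation, conservation
from funfams.annotation import (
    Prediction,
    family_term_frequencies,
    predict_protein,
    propagate,
    resolve_domains,
)
from funfams.errors import AnnotationError
from funfams.profilemodel import ScanHit
from funfams.seqio import AnnotationRecord, AnnotationTable, GODag
from funfams.treecut import FunFam
from tests.conftest import make_alignment


@pytest.fixture
def toy_dag():
    terms = {"GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004",
             "GO:0000005"}
    # diamond: 5 -> {3, 4} -> 2 -> 1 (root)
    parents = {
        "GO:0000001": set(),
        "GO:0000002": {"GO:0000001"},
        "GO:0000003": {"GO:0000002"},
        "GO:0000004": {"GO:0000002"},
        "GO:0000005": {"GO:0000003", "GO:0000004"},
    }
    return GODag(terms=terms, parents=parents)


def family_of(members, family_id="F1"):
    aln = make_alignment([(m, "ACDEF") for m in members])
    return FunFam(family_id, tuple(members), aln, 0,
                  conservation.score_columns(aln))


def go_table(pairs):
    return AnnotationTable(
        [AnnotationRecord(acc, term, "molecular_function", "high_quality")
         for acc, term in pairs]
    )


class TestFamilyTermFrequencies:
    def test_partial_annotation_frequency(self, toy_dag):
        fam = family_of(["p1", "p2", "p3", "p4", "p5"])
        table = go_table([(f"p{i}", "GO:0000005") for i in range(1, 5)])
        freqs = family_term_frequencies(fam, table, toy_dag)
        assert freqs["GO:0000005"] == pytest.approx(0.8)

    def test_full_annotation_gives_one(self, toy_dag):
        fam = family_of(["p1", "p2"])
        table = go_table([("p1", "GO:0000003"), ("p2", "GO:0000003")])
        assert family_term_frequencies(fam, table, toy_dag)["GO:0000003"] == 1.0

    def test_unannotated_term_absent(self, toy_dag):
        fam = family_of(["p1", "p2"])
        table = go_table([("p1", "GO:0000003"), ("p2", "GO:0000003")])
        assert "GO:0000004" not in family_term_frequencies(fam, table, toy_dag)

    def test_descendant_counting(self, toy_dag):
        # one seed annotated at the leaf, one at its ancestor: the ancestor
        # frequency counts both, the leaf only itself
        fam = family_of(["p1", "p2"])
        table = go_table([("p1", "GO:0000005"), ("p2", "GO:0000003")])
        freqs = family_term_frequencies(fam, table, toy_dag)
        assert freqs["GO:0000003"] == 1.0
        assert freqs["GO:0000005"] == 0.5

    def test_exact_counting_mode(self, toy_dag):
        fam = family_of(["p1", "p2"])
        table = go_table([("p1", "GO:0000005"), ("p2", "GO:0000003")])
        freqs = family_term_frequencies(
            fam, table, toy_dag, count_descendants=False
        )
        assert freqs["GO:0000003"] == 0.5

    def test_no_annotated_seeds_is_error(self, toy_dag):
        fam = family_of(["p1"])
        with pytest.raises(AnnotationError):
            family_term_frequencies(fam, AnnotationTable([]), toy_dag)


class TestPropagate:
    def test_single_child_lifts_parent(self, toy_dag):
        out = propagate({"GO:0000003": 0.8}, toy_dag)
        assert out["GO:0000002"] == 0.8
        assert out["GO:0000001"] == 0.8

    def test_parent_takes_max(self, toy_dag):
        out = propagate(
            {"GO:0000003": 0.8, "GO:0000004": 0.5, "GO:0000002": 0.6}, toy_dag
        )
        assert out["GO:0000002"] == 0.8

    def test_diamond_ancestor_counted_once_at_max(self, toy_dag):
        out = propagate({"GO:0000005": 0.9}, toy_dag)
        assert out["GO:0000002"] == 0.9
        assert len([t for t in out if t == "GO:0000002"]) == 1

    def test_idempotent(self, toy_dag):
        once = propagate({"GO:0000005": 0.7, "GO:0000003": 0.4}, toy_dag)
        assert propagate(once, toy_dag) == once

    def test_monotone_ancestors(self, toy_dag):
        out = propagate({"GO:0000005": 0.6, "GO:0000004": 0.9}, toy_dag)
        for term, conf in out.items():
            for anc in toy_dag.ancestors(term):
                assert out[anc] >= conf - 1e-12

    def test_unknown_term_passes_through_with_warning(self, toy_dag):
        with pytest.warns(UserWarning):
            out = propagate({"GO:9999999": 0.5}, toy_dag)
        assert out["GO:9999999"] == 0.5

    def test_root_suppression(self, toy_dag):
        out = propagate({"GO:0000005": 0.9}, toy_dag, suppress_roots=True)
        assert "GO:0000001" not in out


class TestResolveDomains:
    def test_greedy_keeps_best_of_overlapping(self):
        hits = [
            ScanHit("q", "FA", 80.0, 1, 100, assigned=True),
            ScanHit("q", "FB", 60.0, 50, 150, assigned=True),
        ]
        kept = resolve_domains(hits)
        assert [h.family_id for h in kept] == ["FA"]

    def test_small_overlap_tolerated(self):
        hits = [
            ScanHit("q", "FA", 80.0, 1, 100, assigned=True),
            ScanHit("q", "FB", 60.0, 90, 200, assigned=True),
        ]
        kept = resolve_domains(hits)  # 11-residue overlap <= 15 tolerance
        assert [h.family_id for h in kept] == ["FA", "FB"]

    def test_unassigned_hits_ignored(self):
        hits = [ScanHit("q", "FA", 80.0, 1, 100, assigned=False)]
        assert resolve_domains(hits) == []


class TestPredictProtein:
    def test_end_to_end_prediction(self, default_pipeline, default_sim):
        truth, go, ec, dag, train, test, tree, families, decisions, models = (
            default_pipeline
        )
        fams_by_id = {f.family_id: f for f in families}
        protein = test[0]
        preds = predict_protein(protein, models, fams_by_id, go, dag)
        assert preds, "a held-out member should match its family"
        terms = {p.term: p.confidence for p in preds}
        true_terms = set(truth.go_terms[truth.subfamily_of[protein.id]])
        assert true_terms & set(terms)
        assert all(0 < c <= 1 for c in terms.values())

    def test_unmatched_protein_gives_empty_list(self, default_pipeline):
        from funfams.seqio import Sequence

        truth, go, ec, dag, train, test, tree, families, decisions, models = (
            default_pipeline
        )
        fams_by_id = {f.family_id: f for f in families}
        protein = Sequence("junk", "GPGPGPGPGP" * 5)
        assert predict_protein(protein, models, fams_by_id, go, dag) == []

    def test_max_union_over_domains(self, toy_dag):
        # two domains predicting the same term keep the higher confidence:
        # emulate by two families whose frequencies differ
        fam_hi = family_of(["p1", "p2"], "FH")
        fam_lo = family_of(["q1", "q2", "q3", "q4"], "FL")
        table = go_table(
            [("p1", "GO:0000005"), ("p2", "GO:0000005"), ("q1", "GO:0000005")]
        )
        hi = family_term_frequencies(fam_hi, table, toy_dag)["GO:0000005"]
        lo = family_term_frequencies(fam_lo, table, toy_dag)["GO:0000005"]
        assert hi == 1.0 and lo == 0.25
        merged = {}
        for freqs in (
            propagate(family_term_frequencies(fam_hi, table, toy_dag), toy_dag),
            propagate(family_term_frequencies(fam_lo, table, toy_dag), toy_dag),
        ):
            for t, c in freqs.items():
                merged[t] = max(merged.get(t, 0.0), c)
        assert merged["GO:0000005"] == 1.0
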