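import numpy as np
import pytest

from funfams import conservation, groupsim, simulate, treebuild
from funfams.errors import UsageError
from funfams.seqio import Alignment
from funfams.simulate import SimulationConfig, simulate_annotations, simulate_superfamily


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(UsageError):
            SimulationConfig(frac_conserved=0.5, frac_sdp=0.5, frac_neutral=0.5)

    def test_counts_must_be_positive(self):
        with pytest.raises(UsageError):
            SimulationConfig(k_subfamilies=0)

    def test_infeasible_dissimilarity_is_error(self):
        cfg = SimulationConfig(k_subfamilies=8, seqs_per_subfamily=2)
        with pytest.raises(UsageError, match="dissimilar"):
            simulate_superfamily(cfg)


class TestSuperfamily:
    def test_deterministic_under_seed(self):
        a, _ = simulate_superfamily(SimulationConfig(seed=5))
        b, _ = simulate_superfamily(SimulationConfig(seed=5))
        assert [(s.id, s.residues) for s in a] == [(s.id, s.residues) for s in b]

    def test_different_seeds_differ(self):
        a, _ = simulate_superfamily(SimulationConfig(seed=5))
        b, _ = simulate_superfamily(SimulationConfig(seed=6))
        assert [s.residues for s in a] != [s.residues for s in b]

    def test_counts_match_config(self):
        cfg = SimulationConfig(seed=1, k_subfamilies=4, seqs_per_subfamily=20,
                               length=200, frac_conserved=0.15, frac_sdp=0.30,
                               frac_neutral=0.55)
        seqs, truth = simulate_superfamily(cfg)
        assert len(seqs) == 80
        assert len(truth.sdp_columns) == 60
        assert len(truth.conserved_columns) == 30
        from collections import Counter

        sizes = Counter(truth.subfamily_of.values())
        assert sizes == {0: 20, 1: 20, 2: 20, 3: 20}

    def test_planted_column_sets_disjoint(self):
        _, truth = simulate_superfamily(SimulationConfig(seed=2))
        assert not set(truth.sdp_columns) & set(truth.conserved_columns)

    def test_single_subfamily_valid(self):
        seqs, truth = simulate_superfamily(
            SimulationConfig(seed=1, k_subfamilies=1)
        )
        assert set(truth.subfamily_of.values()) == {0}

    def test_fragments_marked_and_short(self):
        cfg = SimulationConfig(seed=1, fragment_fraction=0.2)
        seqs, truth = simulate_superfamily(cfg)
        assert truth.fragments
        by_id = {s.id: s for s in seqs}
        full = cfg.length
        for sid in truth.fragments:
            assert len(by_id[sid]) < 0.8 * full

    def test_indels_change_lengths(self):
        cfg = SimulationConfig(seed=1, k_subfamilies=2, indel_rate=0.1)
        seqs, _ = simulate_superfamily(cfg)
        assert len({len(s) for s in seqs}) == 1  # every seq gets one insert
        assert len(seqs[0]) == cfg.length + round(0.1 * cfg.length)


class TestPlantedSignal:
    """The generator must actually produce the signals it claims to plant."""

    def test_sdp_columns_score_as_sdps(self):
        cfg = SimulationConfig(seed=1, k_subfamilies=2)
        seqs, truth = simulate_superfamily(cfg)
        aln = Alignment([(s.id, s.residues) for s in seqs])
        ga = groupsim.GroupedAlignment(
            aln, {s.id: truth.subfamily_of[s.id] + 1 for s in seqs}
        )
        gs = groupsim.score_sdp(ga).gs[truth.sdp_columns]
        assert (gs > 0.7).mean() >= 0.95

    def test_conserved_columns_score_conserved(self):
        cfg = SimulationConfig(seed=1)
        seqs, truth = simulate_superfamily(cfg)
        aln = Alignment([(s.id, s.residues) for s in seqs])
        scores = conservation.score_columns(aln).scores[truth.conserved_columns]
        assert (scores >= 0.7).mean() >= 0.95

    def test_subfamily_alignments_are_informative(self):
        cfg = SimulationConfig(seed=1)
        seqs, truth = simulate_superfamily(cfg)
        aln = Alignment([(s.id, s.residues) for s in seqs])
        for sf in range(cfg.k_subfamilies):
            ids = [s.id for s in seqs if truth.subfamily_of[s.id] == sf]
            prof = conservation.score_columns(
                aln.subalignment(ids), weighting="henikoff"
            )
            assert prof.dops > 70


class TestAnnotations:
    def test_shared_terms_when_fraction_one(self):
        cfg = SimulationConfig(seed=1, shared_go_fraction=1.0,
                               go_terms_per_subfamily=2)
        _, truth = simulate_superfamily(cfg)
        term_sets = [set(v) for v in truth.go_terms.values()]
        shared = set.intersection(*term_sets)
        assert len(shared) == 2

    def test_unique_terms_and_dag_structure(self):
        cfg = SimulationConfig(seed=1, k_subfamilies=4, shared_go_fraction=0.0,
                               go_terms_per_subfamily=1)
        seqs, truth = simulate_superfamily(cfg)
        go, ec, dag = simulate_annotations(truth, cfg)
        leaves = {t for terms in truth.go_terms.values() for t in terms}
        assert len(leaves) == 4
        assert dag.roots() == {simulate.GO_ROOT}
        for t in leaves:
            assert dag.parents[t] == {simulate.GO_ROOT}

    def test_distinct_ec_per_subfamily(self):
        cfg = SimulationConfig(seed=1, k_subfamilies=3)
        _, truth = simulate_superfamily(cfg)
        assert len(set(truth.ec_numbers.values())) == 3

    def test_unannotated_fraction_blocks_downstream(self):
        cfg = SimulationConfig(seed=1, k_subfamilies=2, annotated_fraction=0.0)
        seqs, truth = simulate_superfamily(cfg)
        go, ec, dag = simulate_annotations(truth, cfg)
        clusters = treebuild.precluster(seqs)
        assert treebuild.filter_clusters(clusters, go) == []


def test_run_dir_outputs(tmp_path):
    cfg = SimulationConfig(seed=1, k_subfamilies=2, seqs_per_subfamily=4,
                           length=60)
    out = simulate.write_run_dir(cfg, tmp_path / "run")
    for name in ("sequences.fasta", "truth.tsv", "go_annotations.tsv",
                 "ec_annotations.tsv", "ontology.obo", "config.yaml"):
        assert (out / name).exists(), name
    from funfams.seqio import read_annotations, read_fasta, read_obo

    assert len(read_fasta(out / "sequences.fasta")) == 8
    dag = read_obo(out / "ontology.obo")
    assert simulate.GO_ROOT in dag.terms
    table = read_annotations(out / "go_annotations.tsv", kind="go")
    assert len(table) > 0
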