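import numpy as np
import pytest

from funfams import conservation, profilemodel
from funfams.errors import ModelError, UsageError
from funfams.matrices import AA_INDEX, AMINO_ACIDS
from funfams.profilemodel import ProfileModel, assign, build_model, score_sequence
from funfams.seqio import Sequence
from funfams.treecut import FunFam
from tests.conftest import make_alignment, majority_subfamily


def funfam_from_rows(rows, family_id="F1"):
    aln = make_alignment(rows)
    return FunFam(
        family_id=family_id,
        members=tuple(aln.ids),
        alignment=aln,
        source_node=0,
        profile=conservation.score_columns(aln),
    )


class TestBuildModel:
    def test_identical_seeds_share_the_threshold_score(self):
        fam = funfam_from_rows(["ACDEFGHIKLMNPQRSTVWY"] * 5)
        model = build_model(fam)
        scores = {
            score_sequence(s, model).bit_score for s in fam.alignment.ungapped()
        }
        assert len(scores) == 1
        assert model.inclusion_threshold <= scores.pop()

    def test_threshold_is_minimum_seed_score(self):
        rows = ["ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY",
                "ACDEFGHIKLMNPQRSTVWY", "AWDEFGHIKLMNPQRSTVWY"]
        fam = funfam_from_rows(rows)
        model = build_model(fam)
        # the divergent seed bounds the threshold from below; all seeds pass
        for s in fam.alignment.ungapped():
            assert score_sequence(s, model).bit_score >= model.inclusion_threshold

    def test_rare_residue_emissions_exceed_common(self):
        fam_w = funfam_from_rows(["W" * 10] * 5, "FW")
        fam_l = funfam_from_rows(["L" * 10] * 5, "FL")
        e_w = build_model(fam_w).emissions[0, AA_INDEX["W"]]
        e_l = build_model(fam_l).emissions[0, AA_INDEX["L"]]
        assert e_w > e_l  # log-odds vs background favour the rarer residue

    def test_gappy_columns_excluded_from_match_states(self):
        rows = ["ACDEF", "A-DEF", "A-DEF", "A-DEF"]
        fam = funfam_from_rows(rows)
        assert len(build_model(fam)) == 4  # column 2 is 75% gaps

    def test_all_gap_alignment_is_model_error(self):
        rows = ["A----", "-C---", "--D--", "---E-"]
        fam = funfam_from_rows(rows)
        with pytest.raises(ModelError):
            build_model(fam)


class TestScoreSequence:
    def test_empty_sequence_rejected(self):
        fam = funfam_from_rows(["ACDEF"] * 3)
        model = build_model(fam)
        with pytest.raises(Exception):
            score_sequence(Sequence("q", ""), model)

    def test_interval_within_bounds(self):
        fam = funfam_from_rows(["ACDEFGHIKLMNPQRSTVWY"] * 4)
        model = build_model(fam)
        hit = score_sequence(Sequence("q", "MKVACDEFGHIKLMNPQRSTVWYPL"), model)
        assert 1 <= hit.start <= hit.end <= 25

    def test_shuffled_sequences_score_below_threshold(self):
        rng = np.random.default_rng(42)
        base = "".join(rng.choice(list(AMINO_ACIDS), 100))
        fam = funfam_from_rows([base] * 6)
        model = build_model(fam)
        below = 0
        for _ in range(50):
            shuffled = "".join(rng.permutation(list(base)))
            hit = score_sequence(Sequence("q", shuffled), model)
            below += hit.bit_score < model.inclusion_threshold
        assert below >= 49

    def test_argmax_emission_sequence_is_optimal(self):
        # the sequence taking the highest-emission residue at every match
        # column bounds every other sequence's score from above
        rows = ["ACDEFGHIKL", "ACDEFGHIKL", "ACDEFGHIKL", "ACWEFGHIKL"]
        fam = funfam_from_rows(rows)
        model = build_model(fam)
        best = "".join(AMINO_ACIDS[i] for i in model.emissions.argmax(axis=1))
        b_score = score_sequence(Sequence("b", best), model).bit_score
        for s in fam.alignment.ungapped():
            assert b_score >= score_sequence(s, model).bit_score - 1e-9

    def test_greedy_exhaustive_on_short_model(self):
        # every length-4 sequence over {A, W}: the per-column argmax
        # sequence must score highest (no gaps can help at equal length)
        from itertools import product

        fam = funfam_from_rows(["AWAW"] * 5)
        model = build_model(fam)
        scores = {
            "".join(p): score_sequence(Sequence("q", "".join(p)), model).bit_score
            for p in product("AW", repeat=4)
        }
        assert max(scores, key=scores.get) == "AWAW"


class TestAssign:
    @pytest.fixture()
    def two_models(self):
        fam_a = funfam_from_rows(["ACDEFGHIKLACDEFGHIKL"] * 5, "FA")
        fam_b = funfam_from_rows(["WYWYWYWYWYWYWYWYWYWY"] * 5, "FB")
        return [build_model(fam_a), build_model(fam_b)], fam_a, fam_b

    def test_seed_assigned_to_own_family(self, two_models):
        models, fam_a, _ = two_models
        hits = assign(fam_a.alignment.ungapped(), models)
        assert all(h.assigned and h.family_id == "FA" for h in hits)

    def test_unrelated_sequence_unassigned(self, two_models):
        models, *_ = two_models
        hits = assign([Sequence("q", "PPPPPPPPPPGGGGGGGGGG")], models)
        assert len(hits) == 1 and not hits[0].assigned

    def test_all_above_threshold_mode(self, two_models):
        models, fam_a, _ = two_models
        hits = assign(fam_a.alignment.ungapped()[:1], models,
                      mode="all_above_threshold")
        assert all(h.assigned for h in hits)
        assert {h.family_id for h in hits} == {"FA"}

    def test_no_models_is_usage_error(self):
        with pytest.raises(UsageError):
            assign([Sequence("q", "ACDEF")], [])

    def test_heldout_accuracy_on_default_simulation(self, default_pipeline):
        truth, go, ec, dag, train, test, tree, families, decisions, models = (
            default_pipeline
        )
        fam_subfam = {f.family_id: majority_subfamily(f, truth) for f in families}
        hits = assign(test, models)
        correct = sum(
            1 for h in hits
            if h.assigned
            and fam_subfam[h.family_id] == truth.subfamily_of[h.sequence_id]
        )
        assert correct / len(test) >= 0.9


class TestSerialization:
    def test_roundtrip_is_bit_exact(self, tmp_path):
        fam = funfam_from_rows(["ACDEFGHIKL"] * 4)
        model = build_model(fam)
        model.save(tmp_path / "m.json")
        back = ProfileModel.load(tmp_path / "m.json")
        q = Sequence("q", "ACDEFGHIKLWW")
        assert score_sequence(q, back).bit_score == score_sequence(q, model).bit_score
        assert back.inclusion_threshold == model.inclusion_threshold

    def test_library_roundtrip(self, tmp_path):
        fams = [funfam_from_rows(["ACDEFGHIKL"] * 4, "F1"),
                funfam_from_rows(["WYWYWYWYWY"] * 4, "F2")]
        models = [build_model(f) for f in fams]
        profilemodel.save_library(models, tmp_path / "lib")
        back = profilemodel.load_library(tmp_path / "lib")
        assert [m.family_id for m in back] == ["F1", "F2"]
        assert back[0].inclusion_threshold == models[0].inclusion_threshold
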