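"""Profile construction and dynamic-programming scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hoxscan as hs
from hoxscan.profile import _dp_align, load_profiles, save_profiles
from hoxscan.seqio import AA_INDEX

from oracles import brute_force_local, brute_force_semiglobal


def single_seq_profile(residues, matrix, **kwargs):
    aln = hs.Alignment.from_pairs([("train", residues)])
    return hs.build_profile(aln, matrix=matrix, pseudocount_weight=0.0, **kwargs)


class TestExtractMatchColumns:
    def test_gapless_alignment_unchanged(self):
        aln = hs.Alignment.from_pairs([("a", "QTYT"), ("b", "QAYT")])
        out = hs.extract_match_columns(aln, 0.5)
        assert [r.residues for r in out.rows] == ["QTYT", "QAYT"]

    def test_gappy_column_removed(self):
        aln = hs.Alignment.from_pairs(
            [("a", "Q-T"), ("b", "Q-T"), ("c", "Q-T"), ("d", "QAT")]
        )
        out = hs.extract_match_columns(aln, 0.5)
        assert out.width == 2
        assert out.rows[3].residues == "QT"

    def test_threshold_one_keeps_everything(self):
        aln = hs.Alignment.from_pairs([("a", "Q-T"), ("b", "QAT")])
        assert hs.extract_match_columns(aln, 1.0).width == 3

    def test_all_columns_removed_is_error(self):
        aln = hs.Alignment.from_pairs([("a", "--"), ("b", "QT")])
        with pytest.raises(ValueError, match="no match columns"):
            hs.extract_match_columns(aln, 0.4)


class TestBuildProfile:
    def test_single_sequence_identity_matrix_is_one_hot(self, identity_matrix):
        prof = single_seq_profile("ACD", identity_matrix)
        expected = np.zeros((3, 20))
        for i, a in enumerate("ACD"):
            expected[i, AA_INDEX[a]] = 1.0
        assert np.allclose(prof.match_scores, expected)

    def test_mixed_column_weighted_average(self):
        # column observes G and A equally; S(G,G)=6, S(A,A)=4, S(G,A)=0
        s = np.zeros((20, 20))
        s[AA_INDEX["G"], AA_INDEX["G"]] = 6.0
        s[AA_INDEX["A"], AA_INDEX["A"]] = 4.0
        matrix = hs.SubstitutionMatrix(scores=s)
        aln = hs.Alignment.from_pairs([("a", "G"), ("b", "A")])
        prof = hs.build_profile(aln, matrix=matrix, pseudocount_weight=0.0)
        assert prof.match_scores[0, AA_INDEX["G"]] == pytest.approx(3.0)
        assert prof.match_scores[0, AA_INDEX["A"]] == pytest.approx(2.0)

    def test_extrapolation_scores_unseen_residues(self, blosum62):
        """A G-only column still ranks A above W: G→A is less penalised
        than G→W, and every residue gets a finite score."""
        aln = hs.Alignment.from_pairs([("a", "G"), ("b", "G"), ("c", "G")])
        prof = hs.build_profile(aln, matrix=blosum62, pseudocount_weight=0.0)
        row = prof.match_scores[0]
        assert row[AA_INDEX["A"]] > row[AA_INDEX["W"]]
        assert np.all(np.isfinite(row))
        assert blosum62.score("G", "A") > blosum62.score("G", "W")

    def test_pseudocounts_pull_toward_background(self, blosum62):
        background = np.full(20, 0.05)
        aln = hs.Alignment.from_pairs([("a", "GG"), ("b", "GG")])
        sharp = hs.build_profile(aln, matrix=blosum62, pseudocount_weight=0.0,
                                 background=background)
        smooth = hs.build_profile(aln, matrix=blosum62, pseudocount_weight=5.0,
                                  background=background)
        g = AA_INDEX["G"]
        assert smooth.match_scores[0, g] < sharp.match_scores[0, g]

    def test_all_gap_column_is_error(self, identity_matrix):
        aln = hs.Alignment.from_pairs([("a", "Q-"), ("b", "Q-")])
        with pytest.raises(ValueError, match="no match columns|no observed"):
            hs.build_profile(aln, matrix=identity_matrix, max_gap_fraction=1.0)

    def test_json_roundtrip(self, tmp_path, blosum62):
        prof = single_seq_profile("QTYTKW", blosum62, group="ANT")
        path = tmp_path / "profiles.json"
        save_profiles([prof], path)
        (back,) = load_profiles(path)
        assert back.group == "ANT"
        assert np.allclose(back.match_scores, prof.match_scores)
        assert (back.gap_open, back.gap_extend) == (prof.gap_open, prof.gap_extend)


class TestScoreSequence:
    def test_exact_self_match(self, identity_matrix):
        prof = single_seq_profile("QTYT", identity_matrix)
        result = hs.score_sequence(prof, hs.SequenceRecord(id="q", residues="QTYT"))
        assert result.score == pytest.approx(4.0)
        assert (result.start, result.end) == (0, 4)

    def test_no_match_floors_at_zero(self, identity_matrix):
        prof = single_seq_profile("QTYT", identity_matrix)
        result = hs.score_sequence(prof, hs.SequenceRecord(id="q", residues="MMMM"))
        assert result.score == 0.0
        assert result.start == result.end

    def test_embedded_motif_found_locally(self, identity_matrix):
        prof = single_seq_profile("QTYT", identity_matrix)
        result = hs.score_sequence(prof, hs.SequenceRecord(id="q", residues="AAQTYTAA"))
        assert result.score == pytest.approx(4.0)
        assert (result.start, result.end) == (2, 6)

    def test_unknown_residues_score_zero(self, identity_matrix):
        prof = single_seq_profile("QTYT", identity_matrix)
        result = hs.score_sequence(prof, hs.SequenceRecord(id="q", residues="QXYT"))
        assert result.score == pytest.approx(3.0)

    def test_semiglobal_aligns_whole_profile(self, identity_matrix):
        prof = single_seq_profile("QTYT", identity_matrix, gap_open=2.0, gap_extend=1.0)
        rec = hs.SequenceRecord(id="q", residues="AAQTYTAA")
        result = hs.score_sequence(prof, rec, mode="semiglobal")
        assert result.score == pytest.approx(4.0)
        assert (result.start, result.end) == (2, 6)

    def test_unknown_mode_rejected(self, identity_matrix):
        prof = single_seq_profile("QT", identity_matrix)
        with pytest.raises(ValueError, match="mode"):
            hs.score_sequence(prof, hs.SequenceRecord(id="q", residues="QT"), mode="global")

    def test_self_score_is_diagonal_sum_and_maximal(self, blosum62):
        """For a single-sequence, zero-pseudocount profile the training
        sequence scores sum(S[a,a]) and no equal-length sequence beats it."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(hs.AMINO_ACIDS), size=12))
        prof = single_seq_profile(seq, blosum62)
        self_score = hs.score_sequence(prof, hs.SequenceRecord(id="s", residues=seq)).score
        expected = sum(blosum62.score(a, a) for a in seq)
        assert self_score == pytest.approx(expected)
        for k in range(40):
            other = "".join(rng.choice(list(hs.AMINO_ACIDS), size=12))
            sc = hs.score_sequence(prof, hs.SequenceRecord(id=f"o{k}", residues=other)).score
            assert sc <= self_score + 1e-9


class TestDPAgainstBruteForce:
    @staticmethod
    def _gap_penalties(rng):
        # affine convention: opening costs at least one extension
        ge = float(rng.uniform(0.1, 2.0))
        go = float(rng.uniform(ge, 8.0))
        return go, ge

    def test_local_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(120):
            L, m = rng.integers(1, 5), rng.integers(1, 7)
            S = rng.normal(1.0, 3.0, size=(L, m))
            go, ge = self._gap_penalties(rng)
            dp, _, _ = _dp_align(S, go, ge, local=True)
            assert dp == pytest.approx(brute_force_local(S, go, ge), abs=1e-9)

    def test_semiglobal_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(4321)
        for _ in range(120):
            L, m = rng.integers(1, 5), rng.integers(1, 7)
            S = rng.normal(1.0, 3.0, size=(L, m))
            go, ge = self._gap_penalties(rng)
            dp, _, _ = _dp_align(S, go, ge, local=False)
            assert dp == pytest.approx(brute_force_semiglobal(S, go, ge), abs=1e-9)


@given(
    seq=st.text(alphabet=hs.AMINO_ACIDS, min_size=1, max_size=20),
    suffix=st.text(alphabet=hs.AMINO_ACIDS, min_size=1, max_size=10),
)
def test_appending_residues_never_decreases_local_score(seq, suffix):
    matrix = hs.SubstitutionMatrix.blosum62()
    aln = hs.Alignment.from_pairs([("t", "QTYTKWEF")])
    prof = hs.build_profile(aln, matrix=matrix, pseudocount_weight=0.0)
    base = hs.score_sequence(prof, hs.SequenceRecord(id="q", residues=seq)).score
    longer = hs.score_sequence(prof, hs.SequenceRecord(id="q", residues=seq + suffix)).score
    assert longer >= base - 1e-9


class TestScoreTable:
    def test_complete_table_shape(self, identity_matrix):
        profiles = [
            single_seq_profile("QTYT", identity_matrix, group="g1"),
            single_seq_profile("MKVA", identity_matrix, group="g2"),
        ]
        seqs = [hs.SequenceRecord(id=f"s{i}", residues="QTYTMKVA") for i in range(3)]
        table = hs.score_table(profiles, seqs)
        assert table.data.shape == (3, 2)
        assert not table.data.isna().any().any()

    def test_duplicate_group_labels_rejected(self, identity_matrix):
        profiles = [
            single_seq_profile("QTYT", identity_matrix, group="g"),
            single_seq_profile("MKVA", identity_matrix, group="g"),
        ]
        with pytest.raises(ValueError, match="duplicate group"):
            hs.score_table(profiles, [hs.SequenceRecord(id="s", residues="QT")])

    def test_row_order_follows_input_order(self, identity_matrix):
        profiles = [single_seq_profile("QTYT", identity_matrix, group="g")]
        seqs = [
            hs.SequenceRecord(id="b", residues="QTYT"),
            hs.SequenceRecord(id="a", residues="MMMM"),
        ]
        fwd = hs.score_table(profiles, seqs)
        rev = hs.score_table(profiles, seqs[::-1])
        assert fwd.seq_ids == ["b", "a"] and rev.seq_ids == ["a", "b"]
        assert np.allclose(fwd.data.loc[["a", "b"]], rev.data.loc[["a", "b"]])

    def test_training_sequence_attains_column_maximum(self, blosum62):
        """Among random queries of equal length, a profile's own training
        sequence maximises that profile's score column."""
        rng = np.random.default_rng(77)
        train = "".join(rng.choice(list(hs.AMINO_ACIDS), size=15))
        prof = single_seq_profile(train, blosum62, group="g")
        seqs = [hs.SequenceRecord(id="train", residues=train)] + [
            hs.SequenceRecord(
                id=f"r{i}", residues="".join(rng.choice(list(hs.AMINO_ACIDS), size=15))
            )
            for i in range(30)
        ]
        table = hs.score_table([prof], seqs)
        assert table.data["g"].idxmax() == "train"

    def test_tsv_roundtrip(self, tmp_path, identity_matrix):
        profiles = [single_seq_profile("QTYT", identity_matrix, group="g1")]
        seqs = [hs.SequenceRecord(id="s1", residues="QTYT")]
        table = hs.score_table(profiles, seqs)
        path = tmp_path / "scores.tsv"
        table.to_tsv(path)
        back = hs.ScoreTable.from_tsv(path)
        assert np.allclose(back.data, table.data)
        assert back.seq_ids == table.seq_ids and back.groups == table.groups
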