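import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_ccv, naive_kmer_counts, naive_pooled_pi, naive_re
from ccvtyper.ccv import (
    CCVVectorizer,
    FeatureMatrix,
    background_vector,
    build_feature_matrix,
    complete_composition_vector,
    composition_value,
    count_kmers,
    expected_probability,
    probability,
    revised_relative_entropy,
    select_features,
)
from ccvtyper.seqio import DNA_CANONICAL, SequenceRecord

DNA = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestCounting:
    @pytest.mark.parametrize(
        "seq,k,expected,total",
        [
            ("ACGT", 3, {"ACG": 1, "CGT": 1}, 2),
            ("AAAA", 2, {"AA": 3}, 3),
            ("ACNGT", 2, {"AC": 1, "GT": 1}, 4),  # windows CN, NG skipped
        ],
    )
    def test_examples(self, seq, k, expected, total):
        t = count_kmers(seq, k)
        assert t.counts == expected
        assert t.window_total == total

    def test_k_larger_than_length_rejected(self):
        with pytest.raises(ValueError):
            count_kmers("ACG", 4)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=500), st.integers(1, 9))
    def test_matches_naive_oracle(self, seq, k):
        if k > len(seq):
            return
        t = count_kmers(seq, k)
        assert t.counts == naive_kmer_counts(seq, k, DNA_CANONICAL)
        assert t.window_total == len(seq) - k + 1

    @settings(max_examples=100, deadline=None)
    @given(DNA, st.integers(1, 9))
    def test_probabilities_sum_to_one_without_ambiguity(self, seq, k):
        if k > len(seq):
            return
        t = count_kmers(seq, k)
        total = sum(probability(t, a) for a in t.counts)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestProbability:
    def test_examples(self):
        assert probability(count_kmers("ACGT", 3), "ACG") == 0.5
        assert probability(count_kmers("AAAA", 2), "AA") == 1.0
        assert probability(count_kmers("ACGT", 3), "TTT") == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            probability(count_kmers("ACGT", 3), "AC")


class TestExpectedProbability:
    def test_hand_derived_acgt(self):
        t2, t1 = count_kmers("ACGT", 2), count_kmers("ACGT", 1)
        # q(ACG) = p(AC) p(CG) / p(C) = (1/3)(1/3)/(1/4) = 4/9
        assert expected_probability(t2, t1, "ACG") == pytest.approx(4 / 9)
        assert expected_probability(t2, t1, "CGT") == pytest.approx(4 / 9)

    def test_zero_denominator_guard(self):
        t2, t1 = count_kmers("AACC", 2), count_kmers("AACC", 1)
        assert expected_probability(t2, t1, "AGA") == 0.0  # G absent

    def test_short_k_rejected(self):
        t1 = count_kmers("ACGT", 1)
        with pytest.raises(ValueError):
            expected_probability(t1, t1, "AC")


class TestCompositionValue:
    @pytest.mark.parametrize(
        "p,q,expected",
        [(0.5, 4 / 9, 0.125), (0.3, 0.3, 0.0), (0.2, 0.0, 0.0), (0.0, 0.5, -1.0)],
    )
    def test_cases(self, p, q, expected):
        assert composition_value(p, q) == pytest.approx(expected)


class TestCompleteCompositionVector:
    def test_acgt_k3(self):
        cv = complete_composition_vector(SequenceRecord(id="a", residues="ACGT"), 3, 3)
        assert cv.values == pytest.approx({"ACG": 0.125, "CGT": 0.125})

    def test_homopolymer_all_zero(self):
        cv = complete_composition_vector(SequenceRecord(id="a", residues="A" * 12), 3, 9)
        assert all(v == pytest.approx(0.0) for v in cv.values.values())

    def test_key_count_bounded_by_window_count(self):
        rec = SequenceRecord(id="a", residues="ACGTACGGTCAGTTACA")
        cv = complete_composition_vector(rec, 3, 9)
        bound = sum(len(rec) - k + 1 for k in range(3, 10))
        assert 0 < len(cv.values) <= bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="tiny"):
            complete_composition_vector(SequenceRecord(id="tiny", residues="AC"), 3, 9)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=80))
    def test_matches_naive_oracle(self, seq):
        cv = complete_composition_vector(SequenceRecord(id="x", residues=seq), 3, 6)
        expected = naive_ccv(seq, 3, 6)
        assert set(cv.values) == set(expected)
        for a in expected:
            assert cv.values[a] == pytest.approx(expected[a], abs=1e-12)

    def test_duplication_invariance(self):
        # pi is built from ratios, so pooled counts of (X, X) equal CCV(X)
        seq = "ACGTACGGTCAGTTACA"
        single = complete_composition_vector(SequenceRecord(id="x", residues=seq), 3, 6)
        pooled = background_vector(
            [SequenceRecord(id="x1", residues=seq), SequenceRecord(id="x2", residues=seq)],
            3,
            6,
        )
        assert pooled.values == pytest.approx(single.values)


class TestBackground:
    def test_single_sequence_identity(self):
        rec = SequenceRecord(id="a", residues="ACGTACGGTCAGT")
        bg = background_vector([rec], 3, 6)
        cv = complete_composition_vector(rec, 3, 6)
        assert bg.values == pytest.approx(cv.values)

    def test_pooled_counts_oracle(self):
        seqs = ["ACGTACGT", "TTTTACGT"]
        recs = [SequenceRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]
        bg = background_vector(recs, 3, 3)
        for alpha, value in bg.values.items():
            assert value == pytest.approx(naive_pooled_pi(seqs, alpha), abs=1e-12)

    def test_disjoint_usage_pools_evenly(self):
        recs = [
            SequenceRecord(id="a", residues="AAAAA"),
            SequenceRecord(id="c", residues="CCCCC"),
        ]
        bg = background_vector(recs, 3, 3)
        # pooled p(AAA) = 3/6; q(AAA) = (4/8)(4/8)/(5/10) = 0.5 -> pi = 0
        assert bg.values["AAA"] == pytest.approx(0.0)

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            background_vector(
                [
                    SequenceRecord(id="a", residues="ACGTACGT", alphabet="DNA"),
                    SequenceRecord(id="p", residues="MKVLWAAL", alphabet="PROTEIN"),
                ],
                3,
                3,
            )


class TestRevisedRelativeEntropy:
    def test_single_sequence_all_zero(self):
        rec = SequenceRecord(id="a", residues="ACGTACGGTCAGT")
        vecs = [complete_composition_vector(rec, 3, 6)]
        re_map = revised_relative_entropy(vecs, background_vector([rec], 3, 6))
        assert all(abs(v) < 1e-12 for v in re_map.values())

    def test_identical_sequences_all_zero(self):
        recs = [SequenceRecord(id=f"s{i}", residues="ACGTACGGTCAGT") for i in range(4)]
        vecs = [complete_composition_vector(r, 3, 6) for r in recs]
        re_map = revised_relative_entropy(vecs, background_vector(recs, 3, 6))
        assert all(abs(v) < 1e-12 for v in re_map.values())

    def test_two_sequence_toy_matches_brute_force(self, toy_records):
        vecs = [complete_composition_vector(r, 3, 3) for r in toy_records]
        bg = background_vector(toy_records, 3, 3)
        re_map = revised_relative_entropy(vecs, bg)
        expected = naive_re([v.values for v in vecs], bg.values)
        assert set(re_map) == set(expected)
        for a in expected:
            assert re_map[a] == pytest.approx(expected[a], abs=1e-12)

    def test_mismatched_k_range_rejected(self, toy_records):
        vecs = [complete_composition_vector(r, 3, 4) for r in toy_records]
        with pytest.raises(ValueError, match="k range"):
            revised_relative_entropy(vecs, background_vector(toy_records, 3, 3))


class TestSelectFeatures:
    def test_absolute_threshold(self):
        kept = select_features({"AAA": 0.5, "CCC": -1.2, "GGG": 3.0}, 1.0)
        assert kept == ["CCC", "GGG"]

    def test_zero_threshold_keeps_all(self):
        assert select_features({"AAA": 0.0, "TTTT": 0.1}, 0.0) == ["AAA", "TTTT"]

    def test_empty_input(self):
        assert select_features({}, 1.0) == []

    def test_ordering_by_k_then_lexicographic(self):
        kept = select_features({"TTTT": 2.0, "AAA": 2.0, "CCC": 2.0}, 1.0)
        assert kept == ["AAA", "CCC", "TTTT"]


class TestFeatureMatrix:
    def _vectors(self, values_by_id):
        return [
            type(
                "V",
                (),
                {"sequence_id": sid, "values": vals, "k_min": 3, "k_max": 9},
            )
            for sid, vals in values_by_id.items()
        ]

    def test_z_score_example(self):
        vecs = self._vectors({"a": {"AAA": 1.0}, "b": {"AAA": 2.0}, "c": {"AAA": 3.0}})
        fm = build_feature_matrix(vecs, ["AAA"])
        assert fm.matrix[:, 0] == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_constant_column_dropped(self):
        vecs = self._vectors(
            {"a": {"AAA": 5.0, "CCC": 1.0}, "b": {"AAA": 5.0, "CCC": 2.0}}
        )
        fm = build_feature_matrix(vecs, ["AAA", "CCC"])
        assert fm.features == ["CCC"]
        assert fm.dropped == ["AAA"]

    def test_columns_standardized(self, planted_dataset):
        records, _, _ = planted_dataset
        fm = CCVVectorizer(k_max=5).fit(records[:8]).feature_matrix_
        assert np.allclose(fm.matrix.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.matrix.std(axis=0), 1.0, atol=1e-9)

    def test_single_sequence_rejected(self):
        vecs = self._vectors({"a": {"AAA": 1.0}})
        with pytest.raises(ValueError, match="2 sequences"):
            build_feature_matrix(vecs, ["AAA"])

    def test_absent_pi_minus_one_switch(self):
        vecs = self._vectors({"a": {"AAA": 1.0}, "b": {"CCC": 1.0}, "c": {"AAA": 0.5}})
        fm0 = build_feature_matrix(vecs, ["AAA", "CCC"], absent_pi="zero")
        fm1 = build_feature_matrix(vecs, ["AAA", "CCC"], absent_pi="minus-one")
        # raw fills differ, so the standardized columns must differ too
        assert not np.allclose(fm0.matrix, fm1.matrix)

    def test_serialization_round_trip_and_determinism(self, tmp_path, toy_records):
        vec = CCVVectorizer(k_max=4, re_threshold=0.0)
        fm = vec.fit(toy_records).feature_matrix_
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        fm.to_tsv(p1, tmp_path / "a.json")
        CCVVectorizer(k_max=4, re_threshold=0.0).fit(toy_records).feature_matrix_.to_tsv(
            p2, tmp_path / "b.json"
        )
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical rebuild
        back = FeatureMatrix.from_tsv(p1)
        assert back.ids == fm.ids
        assert back.features == fm.features
        assert np.allclose(back.matrix, fm.matrix, atol=1e-9)


class TestCCVVectorizer:
    def test_protein_key_space(self):
        recs = [
            SequenceRecord(id="p1", residues="MKVLWAALLVTFLAGCQA", alphabet="PROTEIN"),
            SequenceRecord(id="p2", residues="MKVLWAALLVQAGCQAKV", alphabet="PROTEIN"),
        ]
        vec = CCVVectorizer(k_max=4, re_threshold=0.0).fit(recs)
        assert vec.features_
        assert all(set(f) <= set("ACDEFGHIKLMNPQRSTVWY") for f in vec.features_)

    def test_transform_matches_fit_rows(self, planted_dataset):
        records, _, _ = planted_dataset
        subset = records[:6]
        vec = CCVVectorizer(k_max=5, re_threshold=0.5).fit(subset)
        again = vec.transform(subset)
        assert np.allclose(again, vec.feature_matrix_.matrix, atol=1e-9)

    def test_get_set_params_round_trip(self):
        vec = CCVVectorizer(k_max=7)
        params = vec.get_params()
        assert params["k_max"] == 7
        vec.set_params(re_threshold=2.0)
        assert vec.re_threshold == 2.0
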