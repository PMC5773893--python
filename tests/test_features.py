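"""Feature encoders: printed dimensions, hand-computed model fits, and
brute-force scoring oracles."""

import itertools
import math

import numpy as np
import pytest

from bpmll import features
from bpmll.features import (
    DINUC_CODES,
    FEATURE_DIMS,
    SCAN_OFFSETS,
    build_feature_matrix,
    encode_dinucleotide,
    encode_markov,
    encode_ppt,
    encode_pwm,
    encode_sparse,
    extract_nonamers,
    fit_markov,
    fit_pwm,
)
from bpmll.seqmodel import DataError, IntronRecord


def _random_seq(rng, n=55):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSparseProfile:
    def test_dimension_is_220(self, rng):
        assert encode_sparse(_random_seq(rng)).shape == (220,)

    def test_poly_a_pattern(self):
        v = encode_sparse("A" * 55)
        assert np.array_equal(v.reshape(55, 4), np.tile([1, 0, 0, 0], (55, 1)))

    def test_leading_acgt_blocks(self):
        v = encode_sparse("ACGT" + "A" * 51)
        assert v[:16].tolist() == [1, 0, 0, 0, 0, 1, 0, 0,
                                   0, 0, 1, 0, 0, 0, 0, 1]

    def test_exactly_55_ones(self, rng):
        v = encode_sparse(_random_seq(rng))
        assert v.sum() == 55 and set(np.unique(v)) <= {0.0, 1.0}

    def test_invalid_character_errors(self):
        with pytest.raises(DataError):
            encode_sparse("N" * 55)


class TestDinucleotideProfile:
    def test_dimension_is_216(self, rng):
        assert encode_dinucleotide(_random_seq(rng)).shape == (216,)

    def test_poly_a_is_all_zero(self):
        assert not encode_dinucleotide("A" * 55).any()

    def test_poly_t_is_all_one(self):
        assert encode_dinucleotide("T" * 55).min() == 1.0

    def test_every_listed_code(self):
        # a sequence starting with each dinucleotide encodes its listed bits
        for dinuc, code in DINUC_CODES.items():
            v = encode_dinucleotide(dinuc + "A" * 53)
            assert v[:4].tolist() == [float(c) for c in code], dinuc


class TestNonamerExtraction:
    def test_counts_per_intron(self):
        rec = IntronRecord("x", "ACGT" * 13 + "TAC", {24})
        pos, neg = extract_nonamers([rec])
        assert len(pos) == 1 and len(neg) == 44
        rec0 = IntronRecord("y", "ACGT" * 13 + "TAC")
        pos0, neg0 = extract_nonamers([rec0])
        assert len(pos0) == 0 and len(neg0) == 45

    def test_nonamer_windows_match_bruteforce_scan(self, rng):
        seq = _random_seq(rng)
        rec = IntronRecord("x", seq, {50, 24, 11})
        pos, neg = extract_nonamers([rec])
        # brute force: 6th base (1-based) of the nonamer at offset o is
        # seq[55-o]; the nonamer spans indices 55-o-5 .. 55-o+3
        expected = {}
        for o in range(50, 5, -1):
            c = 55 - o
            expected[o] = seq[c - 5:c + 4]
        assert pos == [expected[50], expected[24], expected[11]]
        assert neg == [expected[o] for o in range(50, 5, -1)
                       if o not in (50, 24, 11)]
        assert all(len(n) == 9 for n in pos + neg)

    def test_offset50_nonamer_spans_offsets_55_to_47(self, rng):
        seq = _random_seq(rng)
        rec = IntronRecord("x", seq, {50})
        pos, _ = extract_nonamers([rec])
        assert pos == [seq[0:9]]


class TestPWM:
    def test_identical_nonamers_maximize_observed_base(self):
        model = fit_pwm(["TACTAACAC"] * 10)
        for i, base in enumerate("TACTAACAC"):
            col = model.matrix[:, i]
            assert np.argmax(col) == "ACGT".index(base)

    def test_count_symmetry(self):
        model = fit_pwm(["AACTAACAC", "CACTAACAC"])
        assert model.matrix["ACGT".index("A"), 0] == pytest.approx(
            model.matrix["ACGT".index("C"), 0])

    def test_hand_computed_entry(self):
        # 8 nonamers, position 6 (index 5): 6 A and 2 C, pseudocount 1
        nonamers = ["TACTA" + b + "CAC" for b in "AAAAAACC"]
        model = fit_pwm(nonamers)
        expected = math.log2((6 + 1) / (8 + 4) / 0.25)
        assert model.matrix[0, 5] == pytest.approx(expected, abs=1e-12)
        assert model.matrix[1, 5] == pytest.approx(
            math.log2((2 + 1) / 12 / 0.25), abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_pwm([])

    def test_profile_length_and_bruteforce_score(self, rng, fitted_feature_models):
        pwm, _ = fitted_feature_models
        seq = _random_seq(rng)
        profile = encode_pwm(seq, pwm)
        assert profile.shape == (45,)
        # brute-force: score of nonamer j is the sum of its 9 matrix entries
        for j, o in enumerate(SCAN_OFFSETS):
            nonamer = seq[j:j + 9]
            expected = sum(pwm.matrix["ACGT".index(b), i]
                           for i, b in enumerate(nonamer))
            assert profile[j] == pytest.approx(expected, abs=1e-12)

    def test_zero_matrix_gives_zero_profile(self, rng):
        model = features.PWMModel(np.zeros((4, 9)))
        assert not encode_pwm(_random_seq(rng), model).any()

    def test_text_round_trip(self, fitted_feature_models):
        pwm, _ = fitted_feature_models
        back = features.PWMModel.from_text(pwm.to_text())
        assert np.array_equal(back.matrix, pwm.matrix)
        assert np.array_equal(back.background, pwm.background)


class TestMarkov:
    def test_identical_classes_give_zero_scores(self, rng):
        nonamers = ["TACTAACAC", "AAGTAACTT", "CCCTAACGG"]
        model = fit_markov(nonamers, list(nonamers))
        scores = encode_markov(_random_seq(rng), model)
        assert np.abs(scores).max() < 1e-12

    def test_rows_sum_to_one(self, fitted_feature_models):
        _, model = fitted_feature_models
        for trans in (model.pos_trans, model.neg_trans):
            assert np.abs(trans.sum(axis=-1) - 1.0).max() < 1e-12
        assert model.pos_init.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_transition(self):
        model = fit_markov(["AAAAAAAAA"], ["TTTTTTTTT"])
        # P_2(A|A) = (1 + 1) / (1 + 4) with Laplace pseudocount 1
        assert model.pos_trans[0, 0, 0] == pytest.approx(0.4, abs=1e-12)
        assert model.pos_init[0] == pytest.approx(2 / 5, abs=1e-12)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            fit_markov([], ["AAAAAAAAA"])

    def test_profile_matches_bruteforce_chain_product(self, rng,
                                                      fitted_feature_models):
        _, model = fitted_feature_models
        seq = _random_seq(rng)
        profile = encode_markov(seq, model)
        assert profile.shape == (45,)
        for j in (0, 17, 44):
            nonamer = [("ACGT").index(b) for b in seq[j:j + 9]]
            lp = math.log(model.pos_init[nonamer[0]]) \
                - math.log(model.neg_init[nonamer[0]])
            for i in range(1, 9):
                lp += math.log(model.pos_trans[i - 1, nonamer[i - 1], nonamer[i]])
                lp -= math.log(model.neg_trans[i - 1, nonamer[i - 1], nonamer[i]])
            assert profile[j] == pytest.approx(lp, abs=1e-12)

    def test_text_round_trip(self, fitted_feature_models):
        _, model = fitted_feature_models
        back = features.MarkovModel.from_text(model.to_text())
        assert np.array_equal(back.pos_trans, model.pos_trans)
        assert np.array_equal(back.neg_init, model.neg_init)


class TestPPT:
    def test_dimension_is_135(self, rng):
        assert encode_ppt(_random_seq(rng)).shape == (135,)

    def test_all_pyrimidine_sequence(self):
        v = encode_ppt("T" * 55).reshape(45, 3)
        assert np.all(v[:, 0] == 1.0)  # pyrimidine fraction
        assert np.all(v[:, 1] == 0.0)  # inside a tract everywhere

    def test_all_purine_sequence(self):
        v = encode_ppt("A" * 55).reshape(45, 3)
        assert np.all(v[:, 0] == 0.0)
        assert np.all(v[:, 1] == 45.0)  # sentinel distance
        assert np.all(v[:, 2] == 0.0)

    def test_known_tract_geometry(self):
        # tract of 6 pyrimidines (4 C) at offsets 10..5; BP offsets > 10 see it
        seq = "A" * 45 + "CCTCCT" + "AAAA"
        v = encode_ppt(seq).reshape(45, 3)
        scan = list(range(50, 5, -1))
        j = scan.index(20)  # offset 20, upstream of the tract start (offset 10)
        assert v[j, 1] == 20 - 10
        assert v[j, 2] == 6 + 0.5 * 4
        j_in = scan.index(8)  # inside the tract
        assert v[j_in, 1] == 0

    def test_pyrimidine_fraction_bruteforce(self, rng):
        seq = _random_seq(rng)
        v = encode_ppt(seq).reshape(45, 3)
        for j, o in zip((0, 20, 44), (50, 30, 6)):
            window = seq[55 - o + 1:]  # offsets o-1 .. 1
            frac = sum(b in "CT" for b in window) / len(window)
            assert v[j, 0] == pytest.approx(frac, abs=1e-12)


class TestFeatureMatrix:
    @pytest.mark.parametrize("subset,m", [
        ({"SP", "MARKOV"}, 265),
        ({"SP", "DN", "PWM", "MARKOV"}, 526),
        ({"PPT"}, 135),
    ])
    def test_known_subset_dimensions(self, small_records, fitted_feature_models,
                                     subset, m):
        pwm, markov = fitted_feature_models
        fm = build_feature_matrix(small_records[:5], subset, pwm=pwm,
                                  markov=markov)
        assert fm.X.shape == (5, m) and len(fm.feature_names) == m

    def test_all_31_subsets_match_dim_sums(self, small_records,
                                           fitted_feature_models):
        pwm, markov = fitted_feature_models
        kinds = list(FEATURE_DIMS)
        for r in range(1, 6):
            for subset in itertools.combinations(kinds, r):
                fm = build_feature_matrix(small_records[:2], subset,
                                          pwm=pwm, markov=markov)
                assert fm.X.shape[1] == sum(FEATURE_DIMS[k] for k in subset)

    def test_empty_subset_errors(self, small_records):
        with pytest.raises(ValueError):
            build_feature_matrix(small_records[:2], set())

    def test_encoders_deterministic(self, small_records, fitted_feature_models):
        pwm, markov = fitted_feature_models
        a = build_feature_matrix(small_records[:10], {"SP", "PWM", "PPT"},
                                 pwm=pwm, markov=markov)
        b = build_feature_matrix(small_records[:10], {"SP", "PWM", "PPT"},
                                 pwm=pwm, markov=markov)
        assert np.array_equal(a.X, b.X)

    def test_finite_and_binary_blocks(self, small_records, fitted_feature_models):
        pwm, markov = fitted_feature_models
        fm = build_feature_matrix(small_records[:20], set(FEATURE_DIMS),
                                  pwm=pwm, markov=markov)
        assert np.all(np.isfinite(fm.X))
        sp_dn = fm.X[:, :436]  # SP then DN blocks are binary
        assert set(np.unique(sp_dn)) <= {0.0, 1.0}
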