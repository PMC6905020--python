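"""Position frequency/weight matrices, conservation index and the S score."""

import math

import numpy as np
import pytest

from ionseg import AA, FormatError
from ionseg.properties import PropertyAlphabet
from ionseg.pwm import (
    FrequencyMatrix,
    background_probabilities,
    build_frequency_matrix,
    build_weight_matrix,
    conservation_index,
    position_features,
    score_segment,
    train_position_model,
)

from .oracles import (
    oracle_background,
    oracle_conservation,
    oracle_freq_matrix,
    oracle_score,
    oracle_weight_matrix,
)

TOY = PropertyAlphabet("AA", tuple("ABC") + ("X",), lambda r, ss, sa: r)


def toy_alphabet(symbols):
    return PropertyAlphabet("AA", tuple(symbols), lambda r, ss, sa: r)


class TestFrequencyMatrix:
    def test_hand_computed_column(self):
        """Four segments all showing 'A' at one position, 21-symbol alphabet."""
        fm = build_frequency_matrix(["A"] * 4, AA)
        p_a = (4 + 2 / 21) / 6
        assert fm.probs[0, AA.index("A")] == pytest.approx(p_a, abs=1e-9)
        others = np.delete(fm.probs[0], AA.index("A"))
        assert np.allclose(others, (2 / 21) / 6, atol=1e-12)
        assert p_a == pytest.approx(0.682540, abs=1e-6)

    def test_columns_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, L = rng.integers(1, 30), rng.integers(1, 5)
            strings = ["".join(rng.choice(list("ABCX"), L)) for _ in range(n)]
            fm = build_frequency_matrix(strings, TOY)
            assert np.allclose(fm.probs.sum(axis=1), 1.0, atol=1e-12)
            assert (fm.probs > 0).all()
            assert np.array_equal(fm.counts.sum(axis=1), fm.totals)

    def test_ragged_and_empty_inputs(self):
        with pytest.raises(FormatError):
            build_frequency_matrix(["AB", "A"], TOY)
        with pytest.raises(FormatError):
            build_frequency_matrix([], TOY)


class TestBackground:
    def test_add_one_arithmetic(self):
        p0 = background_probabilities(["AB", "AB"], TOY)
        # counts A=2, B=2, C=0, X=0 over 4 symbols, alphabet size 4
        assert np.allclose(p0, [3 / 8, 3 / 8, 1 / 8, 1 / 8])
        assert p0.sum() == pytest.approx(1.0)

    def test_uniform_scheme(self):
        p0 = background_probabilities(["AB"], TOY, scheme="uniform")
        assert np.allclose(p0, 0.25)


class TestWeightMatrix:
    def test_zero_when_matching_background(self):
        fm = FrequencyMatrix("AA", np.ones((2, 4)), np.full(2, 4.0), np.full((2, 4), 0.25))
        wm = build_weight_matrix(fm, np.full(4, 0.25))
        assert np.allclose(wm.m, 0.0)
        assert np.allclose(wm.m_min, 0.0) and np.allclose(wm.m_max, 0.0)

    def test_log_ratio(self):
        fm = FrequencyMatrix("AA", np.ones((1, 2)), np.full(1, 2.0), np.array([[0.5, 0.5]]))
        wm = build_weight_matrix(fm, np.array([0.25, 0.75]))
        assert wm.m[0, 0] == pytest.approx(math.log(2.0))


class TestConservation:
    def test_uniform_column_is_zero(self):
        fm = FrequencyMatrix("AA", np.ones((1, 4)), np.full(1, 4.0), np.full((1, 4), 0.25))
        assert conservation_index(fm)[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_column_is_100(self):
        p = np.array([[1.0, 0.0, 0.0, 0.0]])
        fm = FrequencyMatrix("AA", p * 4, np.full(1, 4.0), p)
        assert conservation_index(fm)[0] == pytest.approx(100.0, abs=1e-12)

    def test_pseudocounted_example_column(self):
        fm = build_frequency_matrix(["A"] * 4, AA)
        c = conservation_index(fm)[0]
        assert c == pytest.approx(oracle_conservation(oracle_freq_matrix(["A"] * 4, AA.symbols))[0])
        assert c == pytest.approx(48.2, abs=0.1)

    def test_log_base_invariance(self):
        freq = oracle_freq_matrix(["AB", "AC", "BC", "AA"], TOY.symbols)
        nat = oracle_conservation(freq, base=math.e)
        two = oracle_conservation(freq, base=2.0)
        assert np.allclose(nat, two, atol=1e-10)


class TestScore:
    def test_argmax_and_argmin_segments(self):
        rng = np.random.default_rng(1)
        strings = ["".join(rng.choice(list("ABC"), 3)) for _ in range(12)]
        model = train_position_model(strings[:6], strings[6:], TOY)
        wm, c = model.pos_weight, model.pos_cons
        best = "".join(TOY.symbols[j] for j in np.argmax(wm.m, axis=1))
        worst = "".join(TOY.symbols[j] for j in np.argmin(wm.m, axis=1))
        assert score_segment(wm, c, best, TOY) == pytest.approx(1.0)
        assert score_segment(wm, c, worst, TOY) == pytest.approx(0.0)

    def test_midpoint_row(self):
        """L=1 toy weight row {+1, 0, -1}: observed middle symbol scores 0.5."""
        wm_row = np.array([[1.0, 0.0, -1.0]])
        from ionseg.pwm import WeightMatrix

        wm = WeightMatrix("AA", wm_row, np.full(3, 1 / 3), wm_row.min(1), wm_row.max(1))
        alpha = toy_alphabet("ABC")
        assert score_segment(wm, np.array([42.0]), "B", alpha) == pytest.approx(0.5)

    def test_degenerate_denominator_scores_zero(self):
        from ionseg.pwm import WeightMatrix

        wm_row = np.zeros((2, 3))
        wm = WeightMatrix("AA", wm_row, np.full(3, 1 / 3), wm_row.min(1), wm_row.max(1))
        alpha = toy_alphabet("ABC")
        assert score_segment(wm, np.zeros(2), "AB", alpha) == 0.0

    def test_score_log_base_invariant(self):
        strings = ["AAB", "ABB", "BBC", "ACC", "AAA", "BCA"]
        p0 = oracle_background(strings, "ABC")
        freq = oracle_freq_matrix(strings, "ABC")
        for base in (math.e, 2.0, 10.0):
            w = oracle_weight_matrix(freq, p0, base=base)
            c = oracle_conservation(freq, base=base)
            s = oracle_score(w, c, "ABC")
            if base == math.e:
                ref = s
            assert s == pytest.approx(ref, abs=1e-10)


class TestPositionFeatures:
    def test_lookup_pairs_and_dimension(self):
        rng = np.random.default_rng(2)
        strings = ["".join(rng.choice(list("ABC"), 4)) for _ in range(10)]
        model = train_position_model(strings[:5], strings[5:], TOY)
        v = position_features(model, strings[0])
        assert v.shape == (8,)
        idx = [TOY.index(c) for c in strings[0]]
        assert np.allclose(v[:4], model.pos_weight.m[np.arange(4), idx])
        assert np.allclose(v[4:], model.neg_weight.m[np.arange(4), idx])

    def test_identical_classes_give_symmetric_halves(self):
        strings = ["AB", "BC", "CA"]
        model = train_position_model(strings, strings, TOY)
        v = position_features(model, "AB")
        assert np.allclose(v[:2], v[2:])


class TestAgainstOracle:
    def test_full_agreement_on_random_tiny_instances(self):
        """p, p0, m, C, S all match the literal-formula oracle to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            A = int(rng.integers(2, 5))
            L = int(rng.integers(1, 5))
            n = int(rng.integers(1, 20))
            symbols = "ABCD"[:A]
            alphabet = toy_alphabet(symbols)
            strings = ["".join(rng.choice(list(symbols), L)) for _ in range(n)]
            fm = build_frequency_matrix(strings, alphabet)
            of = oracle_freq_matrix(strings, symbols)
            for i in range(L):
                for j, sym in enumerate(symbols):
                    assert fm.probs[i, j] == pytest.approx(of[i][sym], abs=1e-10)
            p0 = background_probabilities(strings, alphabet)
            op0 = oracle_background(strings, symbols)
            assert np.allclose(p0, [op0[s] for s in symbols], atol=1e-10)
            wm = build_weight_matrix(fm, p0)
            ow = oracle_weight_matrix(of, op0)
            c = conservation_index(fm)
            oc = oracle_conservation(of)
            assert np.allclose(c, oc, atol=1e-10)
            probe = "".join(rng.choice(list(symbols), L))
            assert score_segment(wm, c, probe, alphabet) == pytest.approx(
                oracle_score(ow, oc, probe), abs=1e-10
            )
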