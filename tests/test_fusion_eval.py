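"""Fusion hierarchy against brute-force recomputation, rule identities,
and the accuracy / rank-sum AUC metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyspnea_hri import fusion_eval as fe
from dyspnea_hri.config import PHONETIZATIONS


def _random_softmax(rng, n=1):
    x = rng.dirichlet(np.ones(4), size=n)
    return x[0] if n == 1 else x


simplex_strategy = st.lists(
    st.floats(0.01, 1.0), min_size=4, max_size=4
).map(lambda v: np.array(v) / np.sum(v))


class TestCombineRule:
    def test_identical_one_hot_fixed_point_for_all_rules(self):
        v = np.array([0.0, 0.0, 1.0, 0.0])
        for rule in fe.FUSION_RULES:
            np.testing.assert_allclose(fe.combine_rule([v, v, v], rule), v)

    def test_product_rule_hand_oracle(self):
        a = np.array([0.7, 0.1, 0.1, 0.1])
        b = np.array([0.4, 0.3, 0.2, 0.1])
        got = fe.combine_rule([a, b], "product")
        raw = a * b
        np.testing.assert_allclose(got, raw / raw.sum(), atol=1e-12)
        np.testing.assert_allclose(got, [0.824, 0.088, 0.059, 0.029], atol=5e-4)

    def test_mean_equals_median_for_two_vectors(self, rng):
        a, b = _random_softmax(rng), _random_softmax(rng)
        np.testing.assert_allclose(
            fe.combine_rule([a, b], "mean"), fe.combine_rule([a, b], "median")
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fe.combine_rule([], "mean")

    def test_unknown_rule_rejected(self, rng):
        with pytest.raises(ValueError):
            fe.combine_rule([_random_softmax(rng)], "vote")

    @given(vs=st.lists(simplex_strategy, min_size=1, max_size=5))
    @settings(max_examples=40, deadline=None)
    def test_outputs_always_on_simplex(self, vs):
        for rule in fe.FUSION_RULES:
            out = fe.combine_rule(vs, rule)
            assert np.all(out >= 0)
            assert out.sum() == pytest.approx(1.0, abs=1e-9)


class TestFiveRuleFuse:
    def test_identical_one_hot_preserved(self):
        v = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(fe.five_rule_fuse([v, v]), v)

    def test_permutation_invariant(self, rng):
        vs = [_random_softmax(rng) for _ in range(4)]
        base = fe.five_rule_fuse(vs)
        for perm in itertools.permutations(range(4)):
            np.testing.assert_allclose(fe.five_rule_fuse([vs[i] for i in perm]), base)

    def test_matches_brute_force_oracle(self, rng):
        a, b = _random_softmax(rng), _random_softmax(rng)
        outs = []
        m = np.stack([a, b])
        for combo in (
            m.mean(0), np.median(m, 0), m.min(0), m.max(0), m.prod(0)
        ):
            outs.append(combo / combo.sum())
        expected = np.mean(outs, axis=0)
        expected /= expected.sum()
        np.testing.assert_allclose(fe.five_rule_fuse([a, b]), expected, atol=1e-12)


class TestSubjectScore:
    @staticmethod
    def _leaves(rng):
        return {
            (phon, kind): [_random_softmax(rng), _random_softmax(rng)]
            for phon in PHONETIZATIONS
            for kind in ("time_dep", "time_indep")
        }

    def test_unanimous_one_hot_class_2(self):
        v = np.array([0.0, 0.0, 1.0, 0.0])
        leaves = {
            (phon, kind): [v.copy(), v.copy()]
            for phon in PHONETIZATIONS
            for kind in ("time_dep", "time_indep")
        }
        pred = fe.subject_score(leaves, "s", 2)
        assert pred.predicted_class == 2
        np.testing.assert_allclose(pred.final_softmax, v)

    def test_matches_brute_force_tree(self, rng):
        leaves = self._leaves(rng)
        pred = fe.subject_score(leaves)
        phon_vecs = []
        for phon in PHONETIZATIONS:
            kind_vecs = [
                fe.five_rule_fuse(leaves[(phon, kind)])
                for kind in ("time_dep", "time_indep")
            ]
            v = np.mean(kind_vecs, axis=0)
            phon_vecs.append(v / v.sum())
        expected = fe.five_rule_fuse(phon_vecs)
        np.testing.assert_allclose(pred.final_softmax, expected, atol=1e-12)

    def test_feature_kind_ablation_skips_level_two(self, rng):
        leaves = self._leaves(rng)
        td_only = {k: v for k, v in leaves.items() if k[1] == "time_dep"}
        pred = fe.subject_score(td_only)
        expected = fe.five_rule_fuse(
            [fe.five_rule_fuse(td_only[(phon, "time_dep")]) for phon in PHONETIZATIONS]
        )
        np.testing.assert_allclose(pred.final_softmax, expected, atol=1e-12)

    def test_missing_repetition_flagged(self, rng):
        leaves = self._leaves(rng)
        leaves[("ae", "time_dep")] = leaves[("ae", "time_dep")][:1]
        pred = fe.subject_score(leaves)
        assert any("single repetition" in f for f in pred.flags)

    def test_phonetization_order_invariant(self, rng):
        leaves = self._leaves(rng)
        shuffled = dict(reversed(list(leaves.items())))
        np.testing.assert_allclose(
            fe.subject_score(leaves).final_softmax,
            fe.subject_score(shuffled).final_softmax,
        )

    def test_no_leaves_rejected(self):
        with pytest.raises(ValueError):
            fe.subject_score({})


class TestMetrics:
    @staticmethod
    def _pred(true, predicted, p0=None):
        final = np.full(4, 0.1)
        final[predicted] = 0.7
        if p0 is not None:
            final = np.array([p0, *(np.ones(3) * (1 - p0) / 3)])
        return fe.SubjectPrediction("s", true, final, int(np.argmax(final)))

    def test_all_correct_is_100(self):
        preds = [self._pred(c, c) for c in range(4)]
        assert fe.accuracy(preds) == 100.0

    def test_three_of_four_is_75(self):
        preds = [self._pred(c, c) for c in range(3)] + [self._pred(3, 0)]
        assert fe.accuracy(preds) == 75.0

    def test_random_predictions_near_chance(self, rng):
        truth = rng.integers(0, 4, 2000)
        guess = rng.integers(0, 4, 2000)
        preds = [self._pred(int(t), int(g)) for t, g in zip(truth, guess)]
        assert fe.accuracy(preds) == pytest.approx(25.0, abs=4.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fe.accuracy([])


class TestBinaryAUC:
    def test_perfect_separation(self):
        sm = [np.array([0.9, 0.1, 0.0, 0.0]), np.array([0.1, 0.5, 0.2, 0.2])]
        assert fe.binary_auc(sm, [0, 2]) == 1.0

    def test_all_ties_is_half(self):
        sm = [np.full(4, 0.25)] * 6
        assert fe.binary_auc(sm, [0, 0, 0, 1, 2, 3]) == 0.5

    def test_matches_exhaustive_pair_counting(self, rng):
        n = 6
        sm = _random_softmax(rng, n)
        truth = [0, 0, 1, 2, 3, 1]
        scores = 1.0 - sm[:, 0]
        pos = scores[np.array(truth) > 0]
        neg = scores[np.array(truth) == 0]
        wins = sum(
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos for q in neg
        )
        expected = wins / (len(pos) * len(neg))
        assert fe.binary_auc(sm, truth) == pytest.approx(expected, abs=1e-12)

    def test_score_definition_equivalence(self, rng):
        # 1 - P(class 0) equals P(1)+P(2)+P(3) on the simplex
        sm = _random_softmax(rng, 10)
        np.testing.assert_allclose(1.0 - sm[:, 0], sm[:, 1:].sum(axis=1), atol=1e-12)

    def test_one_empty_group_rejected(self, rng):
        sm = [_random_softmax(rng) for _ in range(3)]
        with pytest.raises(ValueError):
            fe.binary_auc(sm, [1, 2, 3])
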