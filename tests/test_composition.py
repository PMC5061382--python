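import numpy as np
import pytest

from plauscomp.composition import (
    CompositionModel,
    FullAdditiveRegressor,
    LexicalFunctionRegressor,
    UncomposableItem,
    compose,
    extract_training_pairs,
    fit_full_additive,
    fit_lexical_function,
)
from plauscomp.corpus import TokenizedCorpus
from plauscomp.errors import ConsistencyError, EstimationError, InputError
from plauscomp.space import SemanticSpace


def _corpus_with(pairs_and_counts, filler=("f1", "f2", "f3")):
    """A corpus whose adjacent-bigram frequencies are exactly as planted."""
    sents = []
    for (a, b), n in pairs_and_counts.items():
        for _ in range(n):
            sents.append([filler[0], a, b, filler[1]])
    sents.append(list(filler))
    return TokenizedCorpus(sents)


class TestExtractTrainingPairs:
    def test_pair_frequency_threshold(self):
        corpus = _corpus_with({("moon", "walk"): 25, ("moon", "rock"): 3})
        ts = extract_training_pairs(corpus, {"moon"}, set(), 20, 1)
        assert [tp.head for tp in ts.pairs["moon"]] == ["walk"]
        assert ts.pairs["moon"][0].frequency == 25

    def test_modifier_below_min_pairs_dropped_entirely(self):
        planted = {("m", f"h{i}"): 21 for i in range(49)}
        corpus = _corpus_with(planted)
        ts = extract_training_pairs(corpus, {"m"}, set(), 20, 50)
        assert "m" not in ts.pairs
        assert "m" in ts.excluded_modifiers
        ts2 = extract_training_pairs(corpus, {"m"}, set(), 20, 49)
        assert len(ts2.pairs["m"]) == 49

    def test_item_pairs_withheld(self):
        corpus = _corpus_with({("m", "a"): 30, ("m", "b"): 30})
        ts = extract_training_pairs(corpus, {"m"}, {("m", "a")}, 20, 1)
        assert [tp.head for tp in ts.pairs["m"]] == ["b"]

    def test_invariant_under_sentence_permutation(self, rng):
        corpus = _corpus_with({("m", "a"): 22, ("m", "b"): 25, ("m", "c"): 5})
        sents = list(corpus.sentences)
        rng.shuffle(sents)
        shuffled = TokenizedCorpus(sents)
        a = extract_training_pairs(corpus, {"m"}, set(), 20, 1)
        b = extract_training_pairs(shuffled, {"m"}, set(), 20, 1)
        assert {tp.head: tp.frequency for tp in a.pairs["m"]} == {
            tp.head: tp.frequency for tp in b.pairs["m"]
        }

    def test_missing_bigram_row_is_consistency_error(self):
        corpus = _corpus_with({("m", "a"): 30})
        space = SemanticSpace(np.ones((2, 3)), ["m", "a"])  # no bigram row
        with pytest.raises(ConsistencyError):
            extract_training_pairs(corpus, {"m"}, set(), 20, 1, space=space)

    def test_vectors_attached_from_space(self):
        corpus = _corpus_with({("m", "a"): 30})
        space = SemanticSpace(
            np.array([[1.0, 0], [0, 1], [2, 3]]), ["m", "a", ("m", "a")]
        )
        ts = extract_training_pairs(corpus, {"m"}, set(), 20, 1, space=space)
        np.testing.assert_array_equal(ts.pairs["m"][0].phrase_vector, [2, 3])


class TestLexicalFunction:
    def test_identity_function_recovery(self, rng):
        H = rng.random((10, 3))
        pairs = [(h, h) for h in H]
        fn = fit_lexical_function(pairs, lam=1e-9)
        target = np.hstack([np.eye(3), np.zeros((3, 1))])
        assert np.max(np.abs(fn.matrix_ - target)) < 1e-6

    def test_two_by_two_system_solved_by_hand(self):
        # no intercept: heads e1, e2 map to columns (2,1) and (0,3)
        reg = LexicalFunctionRegressor(alpha=1e-10, fit_intercept=False)
        reg.fit(np.eye(2), np.array([[2.0, 1.0], [0.0, 3.0]]))
        np.testing.assert_allclose(reg.coef_, [[2, 0], [1, 3]], atol=1e-6)

    def test_planted_matrix_recovery(self, rng):
        d = 6
        M_true = rng.random((d, d + 1))
        H = rng.random((5 * d, d))
        P = H @ M_true[:, :-1].T + M_true[:, -1]
        fn = fit_lexical_function(list(zip(H, P)), lam=1e-8)
        rel = np.linalg.norm(fn.matrix_ - M_true) / np.linalg.norm(M_true)
        assert rel < 1e-4

    def test_ridge_at_zero_matches_lstsq_oracle(self, rng):
        H = rng.random((20, 4))
        P = rng.random((20, 4))
        fn = fit_lexical_function(list(zip(H, P)), lam=0.0)
        X = np.hstack([H, np.ones((20, 1))])
        oracle = np.linalg.lstsq(X, P, rcond=None)[0].T
        np.testing.assert_allclose(fn.matrix_, oracle, atol=1e-8)

    def test_composition_linear_in_head_without_intercept(self, rng):
        reg = LexicalFunctionRegressor(alpha=1e-8, fit_intercept=False)
        H = rng.random((12, 4))
        reg.fit(H, H @ rng.random((4, 4)))
        h1, h2 = rng.random(4), rng.random(4)
        lhs = reg.compose(2.0 * h1 + 3.0 * h2)
        rhs = 2.0 * reg.compose(h1) + 3.0 * reg.compose(h2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_gcv_selects_from_grid_and_records_diagnostics(self, rng):
        H = rng.random((30, 4))
        P = H + 0.01 * rng.standard_normal((30, 4))
        fn = fit_lexical_function(list(zip(H, P)))
        assert fn.alpha_ > 0
        assert fn.n_pairs_ == 30
        assert fn.residual_norm_ >= 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(EstimationError):
            fit_lexical_function([])

    def test_recovery_improves_with_training_size(self):
        # average over seeds: more noisy pairs -> smaller recovery error
        d = 4
        errs = {n: [] for n in (8, 80)}
        for seed in range(10):
            r = np.random.default_rng(seed)
            M_true = r.random((d, d + 1))
            for n in errs:
                H = r.random((n, d))
                P = H @ M_true[:, :-1].T + M_true[:, -1]
                P += 0.05 * r.standard_normal(P.shape)
                fn = fit_lexical_function(list(zip(H, P)), lam=1e-8)
                errs[n].append(
                    np.linalg.norm(fn.matrix_ - M_true) / np.linalg.norm(M_true)
                )
        assert np.mean(errs[80]) < np.mean(errs[8])


class TestFullAdditive:
    def test_plain_additive_special_case(self, rng):
        M = rng.random((25, 4))
        H = rng.random((25, 4))
        model = fit_full_additive([(m, h, m + h) for m, h in zip(M, H)], lam=1e-9)
        np.testing.assert_allclose(model.A_, np.eye(4), atol=1e-5)
        np.testing.assert_allclose(model.B_, np.eye(4), atol=1e-5)

    def test_planted_pair_recovery(self, rng):
        d = 5
        A, B = rng.random((d, d)), rng.random((d, d))
        M = rng.random((10 * d, d))
        H = rng.random((10 * d, d))
        P = M @ A.T + H @ B.T
        model = fit_full_additive(list(zip(M, H, P)), lam=1e-8)
        rel = (np.linalg.norm(model.A_ - A) + np.linalg.norm(model.B_ - B)) / (
            np.linalg.norm(A) + np.linalg.norm(B)
        )
        assert rel < 1e-4

    def test_head_only_structure(self, rng):
        # m orthogonal to the generating structure: A stays near zero
        d = 4
        B = rng.random((d, d))
        H = rng.random((40, d))
        M = rng.standard_normal((40, d))  # independent of P
        P = H @ B.T
        model = fit_full_additive(list(zip(M, H, P)), lam=1e-4)
        assert np.linalg.norm(model.A_) < 0.2 * np.linalg.norm(model.B_)


class TestCompose:
    def _space(self):
        return SemanticSpace(np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 3.0]]),
                             ["m", "h", "x"])

    def test_additive(self):
        model = CompositionModel(method="additive")
        np.testing.assert_allclose(
            compose(model, "m", "h", self._space()), [1.0, 1.0]
        )

    def test_multiplicative(self):
        space = SemanticSpace(np.array([[2.0, 3.0], [4.0, 0.0]]), ["m", "h"])
        model = CompositionModel(method="multiplicative")
        np.testing.assert_allclose(compose(model, "m", "h", space), [8.0, 0.0])

    def test_lexical_function_identity_matrix(self):
        fn = LexicalFunctionRegressor(alpha=0.0)
        fn.coef_ = np.hstack([np.eye(2), np.zeros((2, 1))])
        fn.fit_intercept = True
        model = CompositionModel(method="lexical_function",
                                 lexical_functions={"m": fn})
        np.testing.assert_allclose(
            compose(model, "m", "h", self._space()), [0.0, 1.0]
        )

    def test_untrained_modifier_signals_uncomposable(self):
        model = CompositionModel(method="lexical_function", lexical_functions={})
        with pytest.raises(UncomposableItem):
            compose(model, "m", "h", self._space())

    def test_invalid_method_rejected(self):
        with pytest.raises(InputError):
            CompositionModel(method="tensor_product")


class TestModelSerialization:
    def test_lexical_function_roundtrip(self, tmp_path, rng):
        from plauscomp.composition import (
            load_composition_model,
            save_composition_model,
        )

        H = rng.random((12, 3))
        fn = fit_lexical_function(list(zip(H, H @ rng.random((3, 3)))), lam=1e-6)
        model = CompositionModel(method="lexical_function",
                                 lexical_functions={"moon": fn})
        save_composition_model(model, tmp_path / "m")
        back = load_composition_model(tmp_path / "m")
        np.testing.assert_allclose(
            back.lexical_functions["moon"].coef_, fn.coef_, atol=1e-12
        )
        assert back.lexical_functions["moon"].alpha_ == fn.alpha_

    def test_full_additive_roundtrip(self, tmp_path, rng):
        from plauscomp.composition import (
            load_composition_model,
            save_composition_model,
        )

        M, H = rng.random((20, 4)), rng.random((20, 4))
        fa = fit_full_additive([(m, h, m + 2 * h) for m, h in zip(M, H)], lam=1e-6)
        model = CompositionModel(method="full_additive", full_additive_model=fa)
        save_composition_model(model, tmp_path / "m")
        back = load_composition_model(tmp_path / "m")
        np.testing.assert_allclose(back.full_additive_model.A_, fa.A_, atol=1e-12)
        np.testing.assert_allclose(back.full_additive_model.B_, fa.B_, atol=1e-12)
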