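"""Core attention network: oracles, composition, gradients, checkpointing."""

import numpy as np
import pytest

from csg2a.chem import ChemicalCondition, MorganFingerprintEncoder
from csg2a.network import (
    AttentionMatrix,
    attention_scores,
    backward_batch,
    combine_with_prior,
    condition_concat,
    condition_features,
    encode_condition,
    forward_batch,
    forward_perturbation,
    gene_condition_representation,
    init_csg2a_params,
    load_checkpoint,
    predict_perturbed_profile,
    save_checkpoint,
)


def _params(n=10, h=4, m=32, c=16, activation="tanh", dropout=0.0, seed=0, **kw):
    return init_csg2a_params(
        n, n_hidden=h, fp_bits=m, cce_hidden=c,
        activation=activation, dropout=dropout,
        rng=np.random.default_rng(seed), **kw,
    )


class TestGeneConditionRepresentation:
    def test_zero_compound_gives_pure_gene_term(self, rng):
        p = _params()
        g0 = rng.normal(size=10)
        Q = gene_condition_representation(g0, np.zeros(10), p)
        np.testing.assert_allclose(Q, g0[:, None] * p.tensors["W_gene"])

    def test_all_zero_inputs_give_zero(self):
        p = _params()
        np.testing.assert_array_equal(
            gene_condition_representation(np.zeros(10), np.zeros(10), p), 0.0
        )

    def test_matches_per_gene_loop_oracle(self, rng):
        p = _params()
        g0, D = rng.normal(size=10), rng.normal(size=10)
        Q = gene_condition_representation(g0, D, p)
        for i in range(10):  # explicit double loop
            for k in range(4):
                expected = (
                    g0[i] * p.tensors["W_gene"][i, k] + D[i] * p.tensors["W_comp"][i, k]
                )
                assert Q[i, k] == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gene_condition_representation(rng.normal(size=9), np.zeros(10), _params())


class TestAttentionScores:
    def test_orthonormal_rows_give_identity(self):
        np.testing.assert_allclose(attention_scores(np.eye(6)), np.eye(6), atol=1e-12)

    def test_zero_representation_gives_zero(self):
        np.testing.assert_array_equal(attention_scores(np.zeros((5, 3))), 0.0)

    def test_matches_double_loop_oracle(self, rng):
        Q = rng.normal(size=(30, 5))
        A = attention_scores(Q)
        oracle = np.empty((30, 30))
        for i in range(30):
            for j in range(30):
                oracle[i, j] = float(np.dot(Q[i], Q[j]))
        np.testing.assert_allclose(A, oracle, atol=1e-6)

    def test_symmetry_for_any_representation(self, rng):
        for _ in range(5):
            A = attention_scores(rng.normal(size=(20, 8)))
            assert np.max(np.abs(A - A.T)) < 1e-6

    def test_optional_sqrt_h_scaling(self, rng):
        Q = rng.normal(size=(7, 4))
        np.testing.assert_allclose(
            attention_scores(Q, scale=True), attention_scores(Q) / 2.0
        )


class TestCombineWithPrior:
    def test_zero_attention_returns_prior(self, rng):
        prior = (rng.random((6, 6)) < 0.3).astype(float)
        prior = np.triu(prior, 1) + np.triu(prior, 1).T
        np.testing.assert_array_equal(combine_with_prior(np.zeros((6, 6)), prior), prior)

    def test_zero_prior_returns_attention(self, rng):
        A = attention_scores(rng.normal(size=(6, 3)))
        np.testing.assert_array_equal(combine_with_prior(A, np.zeros((6, 6))), A)

    def test_elementwise_sum_and_symmetry(self, rng):
        A = attention_scores(rng.normal(size=(8, 3)))
        P = (rng.random((8, 8)) < 0.4).astype(float)
        P = np.triu(P, 1) + np.triu(P, 1).T
        S = combine_with_prior(A, P)
        np.testing.assert_allclose(S, A + P)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_gene_order_mismatch_rejected(self):
        a = AttentionMatrix(np.zeros((2, 2)), "QC", ["g1", "g2"])
        from csg2a.io import PPIAdjacency

        p = PPIAdjacency(np.zeros((2, 2)), ["g2", "g1"], 900)
        with pytest.raises(ValueError, match="orderings"):
            combine_with_prior(a, p)


class TestForwardPerturbation:
    def test_identity_pipeline_returns_input(self, rng):
        p = _params(activation="identity")
        p.tensors["W_final"] = np.eye(10)
        g0 = rng.normal(size=10)
        np.testing.assert_allclose(forward_perturbation(g0, np.eye(10), p), g0, atol=1e-12)

    def test_zero_attention_with_odd_activation_gives_zero(self, rng):
        p = _params(activation="tanh")
        np.testing.assert_array_equal(
            forward_perturbation(rng.normal(size=10), np.zeros((10, 10)), p), 0.0
        )

    def test_matches_matrix_product_oracle(self, rng):
        p = _params(activation="tanh")
        g0 = rng.normal(size=10)
        A = attention_scores(rng.normal(size=(10, 4)))
        expected = p.tensors["W_final"] @ np.tanh(A @ g0)
        np.testing.assert_allclose(forward_perturbation(g0, A, p), expected, atol=1e-6)

    def test_nonfinite_intermediate_names_stage(self, rng):
        p = _params()
        A = np.full((10, 10), np.inf)
        with pytest.raises(FloatingPointError, match="attention linear"):
            forward_perturbation(rng.normal(size=10), A, p)


class TestConditionEncoder:
    def test_concat_layout_and_dose_linearity(self):
        p = _params(m=32)
        enc = MorganFingerprintEncoder(n_bits=32)
        c1 = ChemicalCondition("CCO", 10.0, 36.0)
        c2 = ChemicalCondition("CCO", 20.0, 36.0)
        x1 = condition_concat(c1, p, enc)
        x2 = condition_concat(c2, p, enc)
        np.testing.assert_array_equal(x1[:32], enc.encode("CCO"))
        np.testing.assert_allclose(x1[32:34], 0.1 * p.tensors["W_dose"])
        np.testing.assert_allclose(x1[34:36], 0.5 * p.tensors["W_time"])
        # doubling dose doubles exactly the two dose-expansion entries
        np.testing.assert_allclose(x2[32:34], 2 * x1[32:34])
        np.testing.assert_array_equal(x2[:32], x1[:32])
        np.testing.assert_array_equal(x2[34:], x1[34:])

    def test_zero_dose_time_weights_make_output_condition_invariant(self):
        p = _params(m=32)
        p.tensors["W_dose"][:] = 0.0
        p.tensors["W_time"][:] = 0.0
        a = encode_condition(ChemicalCondition("CCO", 1.0, 6.0), p)
        b = encode_condition(ChemicalCondition("CCO", 100.0, 72.0), p)
        np.testing.assert_allclose(a, b)
        assert a.shape == (10,)

    def test_zero_projection_gives_zero_vector(self):
        p = _params(m=32)
        p.tensors["W_cce2"][:] = 0.0
        out = encode_condition(ChemicalCondition("CCO", 10.0, 24.0), p)
        np.testing.assert_array_equal(out, 0.0)


class TestComposite:
    def test_deterministic_in_eval_mode(self, rng):
        p = _params(dropout=0.3)
        g0 = rng.normal(size=10)
        cond = ChemicalCondition("CCO", 10.0, 24.0)
        prior = np.zeros((10, 10))
        a, _ = predict_perturbed_profile(g0, cond, prior, p)
        b, _ = predict_perturbed_profile(g0, cond, prior, p)
        np.testing.assert_array_equal(a, b)

    def test_zero_compound_weights_make_output_drug_invariant(self, rng):
        p = _params()
        p.tensors["W_comp"][:] = 0.0
        p.tensors["W_cce2"][:] = 0.0  # D also feeds nothing downstream
        g0 = rng.normal(size=10)
        prior = np.zeros((10, 10))
        a, _ = predict_perturbed_profile(g0, ChemicalCondition("CCO"), prior, p)
        b, _ = predict_perturbed_profile(g0, ChemicalCondition("c1ccccc1"), prior, p)
        np.testing.assert_allclose(a, b)

    def test_composite_equals_manual_chaining(self, rng):
        p = _params(m=32)
        enc = MorganFingerprintEncoder(n_bits=32)
        g0 = rng.normal(size=10)
        cond = ChemicalCondition("CC(=O)O", 25.0, 48.0)
        prior = (rng.random((10, 10)) < 0.3).astype(float)
        prior = np.triu(prior, 1) + np.triu(prior, 1).T
        gc, amat = predict_perturbed_profile(g0, cond, prior, p, encoder=enc)

        D = encode_condition(cond, p, enc)
        Q = gene_condition_representation(g0, D, p)
        A = combine_with_prior(attention_scores(Q), prior)
        expected = forward_perturbation(g0, A, p)
        np.testing.assert_allclose(gc, expected, atol=1e-6)
        np.testing.assert_allclose(amat.A, A, atol=1e-6)

    def test_batched_forward_agrees_with_single_sample_path(self, rng):
        p = _params(m=32)
        enc = MorganFingerprintEncoder(n_bits=32)
        conds = [ChemicalCondition("CCO", 10, 24), ChemicalCondition("CCN", 50, 72)]
        g0 = rng.normal(size=(2, 10))
        prior = np.zeros((10, 10))
        gc_batch, _ = forward_batch(p, g0, condition_features(conds, enc), prior)
        for b in range(2):
            gc_single, _ = predict_perturbed_profile(g0[b], conds[b], prior, p, encoder=enc)
            np.testing.assert_allclose(gc_batch[b], gc_single, atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("activation", ["tanh", "relu"])
    def test_analytic_gradients_match_finite_differences(self, activation):
        rng = np.random.default_rng(7)
        p = _params(n=8, h=3, m=16, c=8, activation=activation, seed=3)
        enc = MorganFingerprintEncoder(n_bits=16)
        conds = [ChemicalCondition(s, 10, 48) for s in ("CCO", "CCN", "CC(=O)O")]
        feats = condition_features(conds, enc)
        g0 = rng.normal(size=(3, 8)) * 0.5
        y = rng.normal(size=(3, 8))
        prior = (rng.random((8, 8)) < 0.3).astype(float)
        prior = np.triu(prior, 1) + np.triu(prior, 1).T

        def loss():
            gc, _ = forward_batch(p, g0, feats, prior)
            return float(np.mean((gc - y) ** 2))

        gc, cache = forward_batch(p, g0, feats, prior)
        grads, dg0 = backward_batch(p, cache, 2 * (gc - y) / gc.size)
        eps = 1e-6
        check_rng = np.random.default_rng(11)
        for name, g in grads.items():
            t = p.tensors[name]
            flat = check_rng.choice(t.size, size=min(10, t.size), replace=False)
            for f in flat:
                ix = np.unravel_index(f, t.shape)
                orig = t[ix]
                t[ix] = orig + eps
                lp = loss()
                t[ix] = orig - eps
                lm = loss()
                t[ix] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(fd) + abs(g[ix]))
                assert abs(fd - g[ix]) / denom < 1e-3, f"{name}[{ix}]"

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        p = _params(n=6, h=3, m=16, c=8, seed=2)
        enc = MorganFingerprintEncoder(n_bits=16)
        feats = condition_features([ChemicalCondition("CCO", 10, 24)], enc)
        g0 = rng.normal(size=(1, 6))
        y = rng.normal(size=(1, 6))

        def loss():
            gc, _ = forward_batch(p, g0, feats, None)
            return float(np.mean((gc - y) ** 2))

        gc, cache = forward_batch(p, g0, feats, None)
        _, dg0 = backward_batch(p, cache, 2 * (gc - y) / gc.size)
        eps = 1e-6
        for j in range(6):
            orig = g0[0, j]
            g0[0, j] = orig + eps
            lp = loss()
            g0[0, j] = orig - eps
            lm = loss()
            g0[0, j] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - dg0[0, j]) / max(1e-8, abs(fd) + abs(dg0[0, j])) < 1e-4


class TestCheckpoint:
    def test_roundtrip_preserves_tensors_config_and_prior(self, tmp_path, rng):
        p = _params(m=32)
        prior = (rng.random((10, 10)) < 0.2).astype(float)
        prior = np.triu(prior, 1) + np.triu(prior, 1).T
        genes = [f"G{i}" for i in range(10)]
        path = tmp_path / "model.npz"
        save_checkpoint(path, p, genes, prior, extra={"note": 1})
        p2, genes2, prior2, extra = load_checkpoint(path)
        assert genes2 == genes
        assert p2.config() == p.config()
        np.testing.assert_array_equal(prior2, prior)
        for k in p.tensors:
            np.testing.assert_array_equal(p2.tensors[k], p.tensors[k])
        assert extra["note"] == 1
        assert p2.checksum() == p.checksum()


class TestAttentionProperties:
    """Hypothesis-driven invariants of the attention construction."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra import numpy as hnp

    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
            elements=st.floats(-5, 5),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scores_symmetric_and_psd_diagonal(self, Q):
        A = attention_scores(Q)
        np.testing.assert_allclose(A, A.T, atol=1e-9)
        assert (np.diagonal(A) >= -1e-12).all()  # self-scores are squared norms

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_prior_fusion_commutes_with_symmetrisation(self, seed):
        rng = np.random.default_rng(seed)
        A = attention_scores(rng.normal(size=(6, 3)))
        P = (rng.random((6, 6)) < 0.4).astype(float)
        P = np.triu(P, 1) + np.triu(P, 1).T
        S = combine_with_prior(A, P)
        np.testing.assert_allclose(S, S.T, atol=1e-9)
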