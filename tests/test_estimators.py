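"""Training stages: optimisation plumbing, freeze contract, composition."""

import numpy as np
import pytest

from csg2a import (
    ChemicalCondition,
    IC50Regressor,
    PerturbationNetwork,
    generate_responses,
    generate_triples,
    generate_world,
    mse_loss,
    pretrain,
)
from csg2a.estimators import response_arrays, finetune
from csg2a.network import condition_features, forward_batch

FAST = dict(n_hidden=16, cce_hidden=64, fp_bits=32)


@pytest.fixture(scope="module")
def small_world():
    return generate_world(n_genes=20, n_drugs=6, n_classes=2, n_cells=8, seed=1)


@pytest.fixture(scope="module")
def small_triples(small_world):
    triples, _ = generate_triples(small_world, 300)
    return triples


@pytest.fixture(scope="module")
def small_adj(small_world):
    return (np.abs(small_world.weights) > 0).astype(float)


@pytest.fixture(scope="module")
def small_responses(small_world):
    records = generate_responses(small_world)
    return response_arrays(records, small_world.basal_matrix())


@pytest.fixture(scope="module")
def small_core(small_triples, small_adj):
    return pretrain(small_triples, ppi=small_adj, max_epochs=120, patience=30, seed=0, **FAST)


class TestMSELoss:
    def test_zero_for_identical_and_constant_offset(self, rng):
        x = rng.normal(size=(4, 6))
        assert mse_loss(x, x) == 0.0
        assert mse_loss(x + 2.0, x) == pytest.approx(4.0)

    def test_matches_two_loop_oracle(self, rng):
        a, b = rng.normal(size=(5, 7)), rng.normal(size=(5, 7))
        total = 0.0
        for i in range(5):
            for j in range(7):
                total += (a[i, j] - b[i, j]) ** 2
        assert mse_loss(a, b) == pytest.approx(total / 35, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros(3), np.zeros(4))


class TestPretraining:
    def test_learns_null_perturbation(self, small_world):
        # with gc = g0 the network must drive val MSE below the target variance
        rng = np.random.default_rng(3)
        g0 = small_world.basal_z[rng.integers(0, 8, size=200)]
        smiles = small_world.drugs[0].smiles
        triples = [(row, row.copy(), ChemicalCondition(smiles)) for row in g0]
        model = pretrain(triples, max_epochs=15, patience=15, seed=0, **FAST)
        assert model.best_val_mse_ < np.var(g0)

    def test_training_loss_decreases_early(self, small_core):
        h = small_core.history_["train_mse"]
        assert h[4] < h[0]

    def test_best_checkpoint_selection(self, small_core):
        assert small_core.best_val_mse_ == pytest.approx(min(small_core.history_["val_mse"]))

    def test_same_seed_reproduces_bitwise(self, small_triples, small_adj):
        cfg = dict(max_epochs=4, patience=4, seed=5, **FAST)
        a = pretrain(small_triples[:150], ppi=small_adj, **cfg)
        b = pretrain(small_triples[:150], ppi=small_adj, **cfg)
        assert a.params_.checksum() == b.params_.checksum()
        assert a.history_ == b.history_

    def test_beats_copy_baseline_on_small_world(self, small_core, small_triples):
        g0 = np.stack([t[0] for t in small_triples])
        gc = np.stack([t[1] for t in small_triples])
        conds = [t[2] for t in small_triples]
        model_mse = mse_loss(small_core.predict((g0, conds)), gc)
        copy_mse = mse_loss(g0, gc)
        assert model_mse < copy_mse

    def test_empty_triples_rejected(self):
        with pytest.raises(ValueError):
            pretrain([])

    def test_ppi_ablation_flag_drops_prior(self, small_triples, small_adj):
        m = pretrain(
            small_triples[:100], ppi=small_adj, use_ppi=False,
            max_epochs=2, patience=2, seed=0, **FAST,
        )
        assert m.ppi_ is None


class TestScalingLayer:
    def _fast_reg(self, core, **kw):
        kw.setdefault("max_epochs", 3)
        kw.setdefault("patience", 3)
        return IC50Regressor(pretrained=core, **kw)

    def test_scale_basal_identity_and_centering(self, small_core, small_responses, rng):
        g0, conds, y = small_responses
        reg = self._fast_reg(small_core).fit((g0, conds), y)
        reg.mu_ = np.zeros(20)
        reg.rho_ = np.full(20, np.log(np.expm1(1.0 - 1e-4)))
        x = rng.normal(size=20)
        np.testing.assert_allclose(reg.scale_basal(x), x, atol=1e-6)
        np.testing.assert_allclose(reg.scale_basal(reg.mu_), 0.0, atol=1e-12)

    def test_scale_basal_elementwise_oracle(self, small_core, small_responses, rng):
        g0, conds, y = small_responses
        reg = self._fast_reg(small_core).fit((g0, conds), y)
        x = rng.normal(size=(3, 20))
        out = reg.scale_basal(x)
        for i in range(3):
            for j in range(20):
                assert out[i, j] == pytest.approx(
                    (x[i, j] - reg.mu_[j]) / reg.sigma_[j], abs=1e-10
                )

    def test_sigma_strictly_positive(self, small_core, small_responses):
        g0, conds, y = small_responses
        reg = self._fast_reg(small_core).fit((g0, conds), y)
        assert (reg.sigma_ > 0).all()


class TestIC50Regressor:
    def test_freeze_keeps_core_bitwise_identical(self, small_core, small_responses):
        g0, conds, y = small_responses
        before = small_core.params_.checksum()
        reg = IC50Regressor(pretrained=small_core, max_epochs=3, patience=3, seed=0)
        reg.fit((g0, conds), y)
        assert reg.core_checksum() == before
        assert small_core.params_.checksum() == before  # source untouched too

    def test_unfrozen_core_tensors_all_change(self, small_core, small_responses):
        g0, conds, y = small_responses
        reg = IC50Regressor(
            pretrained=small_core, freeze_pretrained=False,
            max_epochs=2, patience=2, seed=0,
        )
        reg.fit((g0, conds), y)
        for name, t in reg.core_params_.tensors.items():
            assert not np.array_equal(t, small_core.params_.tensors[name]), name

    def test_prediction_is_deterministic(self, small_core, small_responses):
        g0, conds, y = small_responses
        reg = IC50Regressor(pretrained=small_core, max_epochs=3, patience=3, seed=1)
        reg.fit((g0, conds), y)
        a = reg.predict((g0[:5], conds[:5]))
        b = reg.predict((g0[:5], conds[:5]))
        np.testing.assert_array_equal(a, b)

    def test_same_seed_refit_reproduces_predictions(self, small_core, small_responses):
        g0, conds, y = small_responses
        mk = lambda: IC50Regressor(
            pretrained=small_core, max_epochs=3, patience=3, seed=4
        ).fit((g0, conds), y)
        np.testing.assert_array_equal(mk().predict((g0[:8], conds[:8])),
                                      mk().predict((g0[:8], conds[:8])))

    def test_zero_head_weights_give_zero_output(self, small_core, small_responses):
        g0, conds, y = small_responses
        reg = IC50Regressor(pretrained=small_core, max_epochs=2, patience=2, seed=0)
        reg.fit((g0, conds), y)
        reg.head_tensors_["Wh1"][:] = 0.0
        reg.head_tensors_["Wh2"][:] = 0.0
        np.testing.assert_array_equal(reg.predict((g0[:4], conds[:4])), 0.0)

    def test_prediction_composes_scaling_core_and_head(self, small_core, small_responses):
        g0, conds, y = small_responses
        reg = IC50Regressor(pretrained=small_core, max_epochs=3, patience=3, seed=2)
        reg.fit((g0, conds), y)
        # manual composition of the three stages
        feats = condition_features(conds[:6], reg.encoder_)
        g0p = reg.scale_basal(g0[:6])
        gc, cache = forward_batch(reg.core_params_, g0p, feats, reg.core_ppi_)
        u = np.concatenate([gc, cache["D"], g0p], axis=1)
        expected = (np.tanh(u @ reg.head_tensors_["Wh1"]) @ reg.head_tensors_["Wh2"])[:, 0]
        np.testing.assert_allclose(reg.predict((g0[:6], conds[:6])), expected, atol=1e-10)

    def test_unresolvable_cell_id_listed(self, small_world):
        from csg2a.io import DrugResponseRecord

        records = [DrugResponseRecord("nosuchcell", "d", "CCO", 0.0)]
        with pytest.raises(KeyError, match="nosuchcell"):
            response_arrays(records, small_world.basal_matrix())

    def test_save_load_roundtrip(self, tmp_path, small_core, small_responses):
        g0, conds, y = small_responses
        reg = IC50Regressor(pretrained=small_core, max_epochs=3, patience=3, seed=0)
        reg.fit((g0, conds), y)
        path = tmp_path / "ft.npz"
        reg.save(path)
        back = IC50Regressor.load(path)
        np.testing.assert_array_equal(
            back.predict((g0[:5], conds[:5])), reg.predict((g0[:5], conds[:5]))
        )

    def test_finetune_wrapper_runs_end_to_end(self, small_world, small_core):
        records = generate_responses(small_world)[:60]
        reg = finetune(records, small_world.basal_matrix(), pretrained=small_core,
                       max_epochs=2, patience=2, seed=0)
        assert np.isfinite(reg.best_val_rmse_)


class TestPerturbationNetworkPersistence:
    def test_save_load_roundtrip(self, tmp_path, small_core, small_triples):
        path = tmp_path / "core.npz"
        small_core.save(path)
        back = PerturbationNetwork.load(path)
        g0 = np.stack([t[0] for t in small_triples[:5]])
        conds = [t[2] for t in small_triples[:5]]
        np.testing.assert_array_equal(back.predict((g0, conds)),
                                      small_core.predict((g0, conds)))

    def test_attention_maps_symmetric_with_prior_offset(self, small_core, small_triples, small_adj):
        g0 = np.stack([t[0] for t in small_triples[:3]])
        conds = [t[2] for t in small_triples[:3]]
        maps = small_core.attention_maps((g0, conds))
        # A = QQ^T + prior: still symmetric
        np.testing.assert_allclose(maps, maps.transpose(0, 2, 1), atol=1e-8)

    def test_condition_specificity_of_attention(self, small_core, small_triples):
        # two compounds with different representations give different maps on one g0
        g0 = small_triples[0][0]
        smiles = {t[2].smiles for t in small_triples}
        s1, s2 = sorted(smiles)[:2]
        m1 = small_core.attention_maps((g0[None], [ChemicalCondition(s1)]))[0]
        m2 = small_core.attention_maps((g0[None], [ChemicalCondition(s2)]))[0]
        assert np.abs(m1 - m2).max() > 1e-8
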