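import numpy as np
import pytest

from tapb.autodiff import Tensor
from tapb.features import ResidueFeatureMatrix, ToyTargetEmbedder
from tapb.model import (
    ConfounderDictionary,
    ModelConfig,
    TAPBModel,
    backdoor_predict,
    build_confounder_dictionary,
    pool_target_features,
)

VOCAB = 12


def tiny_config(**kw):
    defaults = dict(
        vocab_size=VOCAB,
        d_model=16,
        d_target=16,
        n_heads=4,
        dict_size=4,
        n_encoder_layers=2,
        n_aggregator_layers=2,
        d_ff=32,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture
def dictionary():
    rng = np.random.default_rng(0)
    centers = rng.standard_normal((4, 16))
    return ConfounderDictionary(centers, np.array([0.4, 0.3, 0.2, 0.1]))


@pytest.fixture
def model(dictionary):
    return TAPBModel(tiny_config(), dictionary=dictionary, seed=0)


def drug_batch(rng, B=3, L=7):
    ids = rng.integers(3, VOCAB, size=(B, L))
    mask = np.ones((B, L), dtype=bool)
    ids[-1, -2:] = 0
    mask[-1, -2:] = False
    return ids, mask


def target_batch(rng, B=3, L=6, d=16):
    feats = rng.standard_normal((B, L, d))
    mask = np.ones((B, L), dtype=bool)
    mask[0, -1] = False
    return feats, mask


class TestConfigInvariants:
    def test_heads_must_equal_dict_size(self):
        with pytest.raises(ValueError, match="dict_size"):
            tiny_config(n_heads=4, dict_size=2)

    def test_width_divisibility(self):
        with pytest.raises(ValueError):
            tiny_config(d_model=18)


class TestConfounderDictionary:
    def test_single_cluster_is_global_mean(self):
        rng = np.random.default_rng(1)
        mats = [
            ResidueFeatureMatrix(rng.standard_normal((5, 8)), np.zeros(5, bool))
            for _ in range(6)
        ]
        d = build_confounder_dictionary(mats, 1, seed=0)
        pooled = np.stack([pool_target_features(m) for m in mats])
        assert d.weights.tolist() == [1.0]
        assert d.centers[0] == pytest.approx(pooled.mean(axis=0))

    def test_two_blob_proportions(self):
        rng = np.random.default_rng(2)
        mats = []
        for i in range(100):
            center = 10.0 if i < 60 else -10.0
            feats = center + 0.1 * rng.standard_normal((4, 8))
            mats.append(ResidueFeatureMatrix(feats, np.zeros(4, bool)))
        d = build_confounder_dictionary(mats, 2, seed=0)
        assert sorted(np.round(d.weights, 6)) == [0.4, 0.6]
        assert d.weights.sum() == pytest.approx(1.0)

    def test_too_few_targets(self):
        mats = [ResidueFeatureMatrix(np.ones((3, 8)), np.zeros(3, bool))]
        with pytest.raises(ValueError):
            build_confounder_dictionary(mats, 2, seed=0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ConfounderDictionary(np.ones((2, 4)), np.array([0.7, 0.7]))


class TestBackdoorAdjustment:
    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            raw = rng.random((5, 2)) + 1e-3
            conditional = raw / raw.sum(axis=1, keepdims=True)
            w = rng.random(5)
            w = w / w.sum()
            expected = np.zeros(2)
            for i in range(5):
                expected += w[i] * conditional[i]
            assert backdoor_predict(conditional, w) == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_reduces_to_conditioning(self):
        row = np.array([[0.3, 0.7]])
        assert backdoor_predict(row, np.array([1.0])).tolist() == [0.3, 0.7]

    def test_identical_rows_for_any_weights(self):
        cond = np.tile([0.25, 0.75], (4, 1))
        out = backdoor_predict(cond, np.array([0.1, 0.2, 0.3, 0.4]))
        assert out == pytest.approx([0.25, 0.75])

    def test_mismatched_weights_rejected(self):
        with pytest.raises(ValueError):
            backdoor_predict(np.ones((3, 2)) / 2, np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            backdoor_predict(np.ones((2, 2)) / 2, np.array([0.5, 0.4]))

    def test_graph_path_matches_numpy_path(self, model, rng):
        ids, dmask = drug_batch(rng)
        feats, tmask = target_batch(rng)
        out = model.forward(ids, dmask, feats, tmask)
        expected = backdoor_predict(
            out["conditional"].data.astype(np.float64), model.dictionary.weights
        )
        assert out["backdoor"].data == pytest.approx(expected, abs=1e-6)

    def test_backdoor_rows_normalized(self, model, rng):
        ids, dmask = drug_batch(rng)
        feats, tmask = target_batch(rng)
        out = model.forward(ids, dmask, feats, tmask)
        assert out["backdoor"].data.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-6)
        assert out["conditional"].data.sum(axis=2) == pytest.approx(
            np.ones((3, 4)), abs=1e-6
        )


class TestPartition:
    def test_concat_inverse_bitwise(self, model, rng):
        F = Tensor(rng.standard_normal((2, 5, 16)).astype(np.float32))
        segments = model.partition_by_confounder(F)
        assert len(segments) == 4
        rebuilt = np.concatenate([s.data for s in segments], axis=-1)
        assert np.array_equal(rebuilt, F.data)

    def test_single_cluster_identity(self):
        rng = np.random.default_rng(0)
        cfg = tiny_config(n_heads=1, dict_size=1)
        d = ConfounderDictionary(rng.standard_normal((1, 16)), np.array([1.0]))
        m = TAPBModel(cfg, dictionary=d, seed=0)
        F = Tensor(rng.standard_normal((2, 5, 16)))
        segs = m.partition_by_confounder(F)
        assert len(segs) == 1 and np.array_equal(segs[0].data, F.data)

    def test_single_cluster_backdoor_equals_conditional(self, rng):
        cfg = tiny_config(n_heads=1, dict_size=1)
        d = ConfounderDictionary(rng.standard_normal((1, 16)), np.array([1.0]))
        m = TAPBModel(cfg, dictionary=d, seed=0)
        ids, dmask = drug_batch(rng)
        feats, tmask = target_batch(rng)
        out = m.forward(ids, dmask, feats, tmask)
        assert np.array_equal(out["backdoor"].data, out["conditional"].data[:, 0, :])


class TestDrugEncoder:
    def test_output_shape_and_determinism(self, model, rng):
        ids, mask = drug_batch(rng)
        a = model.encode_drug(ids, mask)
        b = model.encode_drug(ids, mask)
        assert a.shape == (3, 7, 16)
        assert np.array_equal(a.data, b.data)

    def test_out_of_vocabulary_rejected(self, model):
        ids = np.full((1, 3), VOCAB)
        with pytest.raises(ValueError, match="vocabulary"):
            model.encode_drug(ids, np.ones((1, 3), bool))

    def test_position_sensitivity_from_rotary_encoding(self, model):
        ids = np.array([[3, 4, 5, 6]])
        mask = np.ones((1, 4), bool)
        swapped = np.array([[4, 3, 5, 6]])
        a = model.encode_drug(ids, mask)
        b = model.encode_drug(swapped, mask)
        # same multiset of tokens, different order -> different encoding
        assert not np.allclose(a.data[0, 2], b.data[0, 2])


class TestCAM:
    def test_singleton_head_broadcasts_center_value(self, model, rng):
        # with a singleton key the attention weight is exactly 1, so the
        # pre-residual head output is constant across positions: CAM output
        # differences can only come from the residual E term
        feats, tmask = target_batch(rng)
        E1 = Tensor(feats.astype(np.float32))
        feats2 = feats.copy()
        feats2[:, 2, :] += 1.0  # perturb one position
        E2 = Tensor(feats2.astype(np.float32))
        T1 = model.confounder_align(E1, tmask)
        T2 = model.confounder_align(E2, tmask)
        diff_rows = np.any(np.abs(T1.data - T2.data) > 1e-7, axis=2)
        assert diff_rows[:, 2].all()
        assert not diff_rows[:, [0, 1, 3, 4, 5]].any()

    def test_cam_disabled_uses_plain_projection(self, dictionary, rng):
        cfg = tiny_config(use_cam=False)
        m = TAPBModel(cfg, dictionary=dictionary, seed=0)
        feats, tmask = target_batch(rng)
        E = Tensor(feats.astype(np.float32))
        T = m.confounder_align(E, tmask)
        expected = feats.astype(np.float32) @ m.params["tproj.W"].data + m.params["tproj.b"].data
        assert T.data == pytest.approx(expected, abs=1e-6)

    def test_full_dictionary_variant_runs(self, dictionary, rng):
        cfg = tiny_config(cam_full_dictionary=True)
        m = TAPBModel(cfg, dictionary=dictionary, seed=0)
        feats, tmask = target_batch(rng)
        T = m.confounder_align(Tensor(feats.astype(np.float32)), tmask)
        assert T.shape == (3, 6, 16)

    def test_output_width_is_model_width(self, model, rng):
        feats, tmask = target_batch(rng)
        T = model.confounder_align(Tensor(feats.astype(np.float32)), tmask)
        assert T.shape[-1] == model.config.d_model


class TestAggregator:
    def test_attention_rows_sum_to_one_over_valid_keys(self, model, rng):
        ids, dmask = drug_batch(rng)
        feats, tmask = target_batch(rng)
        out = model.forward(ids, dmask, feats, tmask)
        cross = out["attention"]["cross"]  # [B, H, L_d, L_t]
        sums = cross.sum(axis=-1)
        assert sums == pytest.approx(np.ones_like(sums), abs=1e-5)
        # masked target key receives zero attention
        assert np.all(cross[0, :, :, -1] == 0.0)

    def test_final_layer_head_count(self, model, rng):
        ids, dmask = drug_batch(rng)
        feats, tmask = target_batch(rng)
        out = model.forward(ids, dmask, feats, tmask)
        assert out["attention"]["cross"].shape[1] == model.config.n_heads

    def test_all_padding_pool_rejected(self, model):
        with pytest.raises(ValueError):
            model._masked_pool(Tensor(np.ones((1, 3, 16))), np.zeros((1, 3), bool))


class TestLosses:
    def test_classification_loss_known_values(self):
        probs = Tensor(np.array([[1.0, 0.0]]))
        assert TAPBModel.classification_loss(probs, np.array([0])).data == pytest.approx(0.0, abs=1e-9)
        probs = Tensor(np.array([[0.5, 0.5]]))
        assert TAPBModel.classification_loss(probs, np.array([1])).data == pytest.approx(np.log(2))

    def test_classification_loss_batch_mean_matches_loop(self):
        rng = np.random.default_rng(4)
        raw = rng.random((6, 2)) + 1e-3
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 2, 6)
        loop = -np.mean([np.log(probs[i, labels[i]]) for i in range(6)])
        got = TAPBModel.classification_loss(Tensor(probs), labels)
        assert got.data == pytest.approx(loop)

    def test_mlm_loss_empty_selection_is_zero(self, model, rng):
        hidden = Tensor(rng.standard_normal((2, 5, 16)))
        sel = np.zeros((2, 5), bool)
        ids = np.zeros((2, 5), np.int64)
        assert model.mlm_loss(hidden, sel, ids).data == 0.0

    def test_mlm_loss_matches_loop_oracle(self, model, rng):
        from tapb.autodiff import softmax

        hidden = Tensor(rng.standard_normal((2, 5, 16)).astype(np.float32))
        sel = rng.random((2, 5)) < 0.4
        sel[0, 0] = True
        ids = rng.integers(0, VOCAB, (2, 5))
        got = model.mlm_loss(hidden, sel, ids).data
        logits = hidden.data @ model.params["gm.W"].data + model.params["gm.b"].data
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        probs = e / e.sum(axis=-1, keepdims=True)
        terms = [
            -np.log(probs[b, l, ids[b, l]])
            for b in range(2)
            for l in range(5)
            if sel[b, l]
        ]
        assert got == pytest.approx(np.mean(terms), rel=1e-5)

    def test_total_loss_composition(self, model):
        lb, lm = Tensor(1.5), Tensor(0.25)
        assert TAPBModel.total_loss(lb, lm, model.config).data == pytest.approx(1.75)
        cfg_off = tiny_config(use_mlm=False)
        assert TAPBModel.total_loss(lb, lm, cfg_off).data == pytest.approx(1.5)
        assert TAPBModel.total_loss(lb, None, model.config).data == pytest.approx(1.5)


class TestPersistence:
    def test_save_load_identical_forward(self, model, rng, tmp_path):
        ids, dmask = drug_batch(rng)
        feats, tmask = target_batch(rng)
        before = model.forward(ids, dmask, feats, tmask)["prob"].data
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TAPBModel.load(path)
        after = loaded.forward(ids, dmask, feats, tmask)["prob"].data
        assert np.array_equal(before, after)
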