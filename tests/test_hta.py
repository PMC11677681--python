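"""Segment-masking autoencoder: dynamic convolution, masking, training."""

import numpy as np
import pytest

import psspkit as pk
from psspkit.features import one_hot_encode
from psspkit.hta import (HTA, DyConvBlock, HTAConfig,
                         default_hta_train_config, encode_records, load_hta,
                         mask_segment, save_hta, train_hta)
from psspkit.nn import autograd as ag
from psspkit.nn.autograd import Tensor
from psspkit.nn.layers import Conv1d, MaskedBatchNorm1d
from psspkit.records import ProteinRecord
from psspkit.train import TrainConfig


class TestDyConvBlock:
    def test_attention_weights_sum_to_one(self, rng):
        block = DyConvBlock(5, 4, 3, n_filters=3, rng=rng)
        x = Tensor(rng.normal(size=(4, 5, 9)))
        w = block.attention(x, np.ones((4, 9)))
        assert np.allclose(w.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(w.data >= 0)

    def test_single_filter_equals_ordinary_residual_conv(self, rng):
        """With B = 1 the combined filter is the bank filter itself."""
        block = DyConvBlock(5, 4, 3, n_filters=1, rng=rng)
        block.eval()
        x = Tensor(rng.normal(size=(2, 5, 9)))
        mask = np.ones((2, 9))
        out = block(x, mask)
        # reference: plain conv with the same parameters
        conv = Conv1d(5, 4, 3, rng)
        conv.weight.data = block.bank.data[0].copy()
        conv.bias.data = block.bias.data.copy()
        main = block.bn_main(conv(x), mask)
        res = block.bn_res(block.proj(x), mask)
        ref = ag.leaky_relu(ag.add(main, res), block.leaky_slope)
        assert np.allclose(out.data, ref.data, rtol=0, atol=1e-12)

    def test_identical_filters_make_attention_irrelevant(self, rng):
        block = DyConvBlock(5, 4, 3, n_filters=3, rng=rng)
        block.eval()
        block.bank.data[1] = block.bank.data[0]
        block.bank.data[2] = block.bank.data[0]
        x = Tensor(rng.normal(size=(2, 5, 9)))
        mask = np.ones((2, 9))
        out1 = block(x, mask).data
        block.attn_w.data = rng.normal(size=block.attn_w.data.shape)
        out2 = block(x, mask).data
        assert np.allclose(out1, out2, atol=1e-10)

    def test_different_samples_get_different_combined_filters(self, rng):
        block = DyConvBlock(5, 4, 3, n_filters=3, rng=rng)
        x = Tensor(rng.normal(size=(2, 5, 9)))
        w = block.attention(x, np.ones((2, 9)))
        comb = block.combined_filter(w)
        # hand-computed weighted sum per sample
        expected = np.einsum("nb,bock->nock", w.data, block.bank.data)
        assert np.allclose(comb.data, expected, atol=1e-12)
        assert not np.allclose(comb.data[0], comb.data[1])


class TestMasking:
    def _record(self):
        return ProteinRecord(id="p", sequence="ACDEFGHIKL",
                             ss8="HHHEEETTSS")

    def test_single_segment_always_chosen(self, rng):
        rec = ProteinRecord(id="p", sequence="ACDEF", ss8="HHHHH")
        oh, pos = mask_segment(rec, rng)
        assert pos.all()
        assert np.all(oh.sum(axis=1) == 0)

    def test_masked_rows_zero_and_labels_untouched(self, rng):
        rec = self._record()
        ss8_before = rec.ss8
        oh, pos = mask_segment(rec, rng)
        assert rec.ss8 == ss8_before
        assert np.all(oh[pos].sum(axis=1) == 0)
        assert np.all(oh[~pos].sum(axis=1) == 1)

    def test_token_mode_uses_extra_channel(self, rng):
        oh, pos = mask_segment(self._record(), rng, mask_mode="token")
        assert oh.shape[1] == 22
        assert np.all(oh[pos, 21] == 1.0)
        assert np.all(oh[~pos, 21] == 0.0)

    def test_uniform_choice_over_segments(self):
        rec = ProteinRecord(id="p", sequence="ACDEFGHIKL",
                            ss8="HHHEEEETTT")  # 3 segments
        rng = np.random.default_rng(123)
        counts = {0: 0, 1: 0, 2: 0}
        starts = {0: 0, 3: 1, 7: 2}
        for _ in range(10000):
            _, pos = mask_segment(rec, rng)
            counts[starts[int(np.flatnonzero(pos)[0])]] += 1
        for c in counts.values():
            assert abs(c / 10000 - 1 / 3) < 0.02

    def test_missing_ss8_error(self, rng):
        with pytest.raises(ValueError, match="ss8"):
            mask_segment(ProteinRecord(id="p", sequence="ACD"), rng)


@pytest.fixture(scope="module")
def tiny_model(deterministic_corpus):
    _, records, _ = deterministic_corpus
    tc = default_hta_train_config(seed=42, batch_size=16)
    model, history = train_hta(records[:16], HTAConfig(), tc, n_epochs=2)
    return model, history


class TestModel:
    def test_encoding_shape_and_determinism(self, tiny_model,
                                            deterministic_corpus):
        model, _ = tiny_model
        _, records, _ = deterministic_corpus
        encs1 = encode_records(model, records[:3])
        encs2 = encode_records(model, records[:3])
        for rec, e1, e2 in zip(records[:3], encs1, encs2):
            assert e1.shape == (len(rec), 4)
            assert np.array_equal(e1, e2)

    def test_loss_history_finite_and_decreasing_start(self, tiny_model):
        _, history = tiny_model
        assert all(np.isfinite(history))

    def test_padding_invariance_of_encoder(self, tiny_model, rng):
        model, _ = tiny_model
        model.eval()
        oh = one_hot_encode("ACDEFGHIKLMNPQ")
        x_alone = Tensor(oh.T[None])
        enc_alone = model.encode(x_alone, np.ones((1, 14))).data
        padded = np.zeros((1, 21, 20))
        padded[0, :, :14] = oh.T
        mask = np.zeros((1, 20))
        mask[0, :14] = 1.0
        enc_padded = model.encode(Tensor(padded), mask).data
        assert np.allclose(enc_alone[0], enc_padded[0, :, :14], atol=1e-10)

    def test_training_deterministic_under_fixed_seed(self,
                                                     deterministic_corpus):
        _, records, _ = deterministic_corpus
        tc = TrainConfig(seed=7, batch_size=16)
        _, h1 = train_hta(records[:12], HTAConfig(), tc, n_epochs=2)
        _, h2 = train_hta(records[:12], HTAConfig(), tc, n_epochs=2)
        assert h1 == h2

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path,
                                  deterministic_corpus):
        model, _ = tiny_model
        _, records, _ = deterministic_corpus
        path = tmp_path / "hta.pkl"
        save_hta(model, path)
        back = load_hta(path)
        e1 = encode_records(model, records[:2])
        e2 = encode_records(back, records[:2])
        assert all(np.array_equal(a, b) for a, b in zip(e1, e2))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_hta([], HTAConfig())
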