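"""Multi-task predictor: MMoE gating, towers, forward contracts."""

import numpy as np
import pytest

import psspkit as pk
from psspkit.mtl import (MMoE, MTLConfig, PSSPMTL, TCN, assemble_features,
                         load_mtl, majority_class_q, predict, save_mtl,
                         train_mtl)
from psspkit.nn import autograd as ag
from psspkit.nn.autograd import Tensor
from psspkit.train import TrainConfig


def small_config(**overrides):
    base = dict(features=("one_hot", "physchem"), channels_per_scale=8,
                expert_channels=12, bigru_hidden=6, tcn_blocks=2)
    base.update(overrides)
    return MTLConfig(**base)


class TestMMoE:
    def test_gate_weights_sum_to_one_at_every_position(self, rng):
        cfg = small_config()
        mmoe = MMoE(16, cfg, rng)
        x = Tensor(rng.normal(size=(3, 16, 11)))
        mask = np.ones((3, 11))
        for g in mmoe.gates(x, mask):
            assert g.data.shape == (3, cfg.n_experts, 11)
            assert np.allclose(g.data.sum(axis=1), 1.0, atol=1e-6)

    def test_single_expert_gate_forced_to_one(self, rng):
        cfg = small_config(n_experts=1)
        mmoe = MMoE(16, cfg, rng)
        mmoe.eval()
        x = Tensor(rng.normal(size=(2, 16, 7)))
        mask = np.ones((2, 7))
        fused = mmoe(x, mask)
        # explicit: LeakyReLU(residual + the single expert output)
        for j in range(2):
            res = mmoe.res_bns[j](mmoe.res_convs[j](x), mask)
            ex = mmoe.experts[0](x, mask)
            ref = ag.leaky_relu(ag.add(res, ex), cfg.leaky_slope)
            assert np.allclose(fused[j].data, ref.data, atol=1e-12)

    def test_fused_output_matches_hand_weighted_sum(self, rng):
        cfg = small_config(n_experts=2, expert_channels=3)
        mmoe = MMoE(5, cfg, rng)
        mmoe.eval()
        x = Tensor(rng.normal(size=(1, 5, 4)))
        mask = np.ones((1, 4))
        gates = [g.data for g in mmoe.gates(x, mask)]
        experts = [e(x, mask).data for e in mmoe.experts]
        fused = mmoe(x, mask)
        for j in range(2):
            mix = np.zeros((1, 3, 4))
            for k in range(2):
                # position-wise weight broadcast down the channel rows
                mix += experts[k] * gates[j][:, k:k + 1, :]
            res = mmoe.res_bns[j](mmoe.res_convs[j](x), mask).data
            ref = np.where(res + mix > 0, res + mix,
                           cfg.leaky_slope * (res + mix))
            assert np.allclose(fused[j].data, ref, atol=1e-10)


class TestTCN:
    def test_causality(self, rng):
        cfg = small_config()
        tcn = TCN(8, cfg, rng)
        tcn.eval()
        x = rng.normal(size=(1, 8, 20))
        mask = np.ones((1, 20))
        base = tcn(Tensor(x), mask).data
        x2 = x.copy()
        x2[0, :, 12] += 3.0
        pert = tcn(Tensor(x2), mask).data
        assert np.allclose(base[:, :, :12], pert[:, :, :12], atol=1e-10)
        assert not np.allclose(base[:, :, 12:], pert[:, :, 12:])

    def test_receptive_field_grows_with_dilation(self, rng):
        # kernel 3; block i holds two causal convs of dilation 2**(i-1),
        # each reaching (k-1)*d back, so an impulse at t affects outputs
        # up to t + sum_i 2*(k-1)*2**(i-1) = t + 4 + 8
        cfg = small_config(tcn_blocks=2)
        tcn = TCN(4, cfg, rng)
        tcn.eval()
        L = 30
        base = tcn(Tensor(np.zeros((1, 4, L))), np.ones((1, L))).data
        x = np.zeros((1, 4, L))
        x[0, :, 10] = 1.0
        out = tcn(Tensor(x), np.ones((1, L))).data
        changed = np.flatnonzero(np.abs(out - base).sum(axis=(0, 1)) > 1e-12)
        assert changed.min() == 10
        assert changed.max() == 10 + 4 + 8

    def test_preserves_length(self, rng):
        cfg = small_config()
        tcn = TCN(8, cfg, rng)
        out = tcn(Tensor(rng.normal(size=(2, 8, 13))), np.ones((2, 13)))
        assert out.shape == (2, 8, 13)


class TestForward:
    def test_probability_rows_sum_to_one(self, rng, small_corpus):
        _, records, _ = small_corpus
        cfg = small_config()
        model = PSSPMTL(cfg, rng)
        feats = assemble_features(
            [pk.build_bundle(r) for r in records[:4]], cfg)
        outs = predict(model, feats)
        for rec, o in zip(records[:4], outs):
            assert o.ss_probs.shape == (len(rec), 8)
            assert np.allclose(o.ss_probs.sum(axis=1), 1.0, atol=1e-6)
            assert np.allclose(o.rsa_probs.sum(axis=1), 1.0, atol=1e-6)
            assert len(o.ss_string) == len(rec)

    def test_ablation_changes_channels_and_runs(self, rng, small_corpus):
        _, records, _ = small_corpus
        cfg_full = small_config()
        cfg_oh = small_config(features=("one_hot",))
        assert cfg_full.input_channels == 28
        assert cfg_oh.input_channels == 21
        model = PSSPMTL(cfg_oh, rng)
        feats = assemble_features(
            [pk.build_bundle(r) for r in records[:2]], cfg_oh)
        outs = predict(model, feats)
        assert len(outs) == 2

    def test_wrong_channel_count_rejected(self, rng):
        cfg = small_config()
        model = PSSPMTL(cfg, rng)
        with pytest.raises(ValueError, match="channels"):
            model(Tensor(np.zeros((1, 5, 10))), np.ones((1, 10)))

    def test_embedding_bypasses_convolution_width(self, rng, small_corpus):
        _, records, _ = small_corpus
        cfg = small_config(embedding_dim=6)
        emb_rng = np.random.default_rng(0)
        bundles = [pk.build_bundle(r, embedding=emb_rng.normal(
            size=(len(r), 6))) for r in records[:2]]
        feats = assemble_features(bundles, cfg)
        assert feats[0].shape[1] == cfg.input_channels + 6
        assert cfg.fused_channels == len(cfg.scales) * 8 + 6
        model = PSSPMTL(cfg, rng)
        outs = predict(model, feats)
        assert outs[0].ss_probs.shape[1] == 8

    def test_padding_invariance_in_eval_mode(self, rng, small_corpus):
        _, records, _ = small_corpus
        cfg = small_config()
        model = PSSPMTL(cfg, rng)
        model.eval()
        bundles = [pk.build_bundle(r) for r in records[:6]]
        feats = assemble_features(bundles, cfg)
        alone = predict(model, [feats[0]], batch_size=1)[0]
        batched = predict(model, feats, batch_size=6)[0]
        assert np.allclose(alone.ss_probs, batched.ss_probs, atol=1e-8)
        assert np.allclose(alone.rsa_probs, batched.rsa_probs, atol=1e-8)


class TestTraining:
    def test_both_task_losses_decrease(self, deterministic_corpus):
        _, records, _ = deterministic_corpus
        cfg = small_config(features=("one_hot",))
        feats = assemble_features(
            [pk.build_bundle(r, with_physchem=False) for r in records], cfg)
        tc = TrainConfig(seed=42, batch_size=16)
        model, history = train_mtl(records, feats, cfg, tc, n_epochs=4)
        assert history["loss"][-1] < history["loss"][0]
        assert len(history["loss"]) == 4

    def test_loss_history_reproducible(self, deterministic_corpus):
        _, records, _ = deterministic_corpus
        cfg = small_config(features=("one_hot",))
        feats = assemble_features(
            [pk.build_bundle(r, with_physchem=False) for r in records[:16]],
            cfg)
        tc = TrainConfig(seed=11, batch_size=8)
        _, h1 = train_mtl(records[:16], feats, cfg, tc, n_epochs=2)
        _, h2 = train_mtl(records[:16], feats, cfg, tc, n_epochs=2)
        assert h1["loss"] == h2["loss"]

    def test_gate_normalization_after_training(self, deterministic_corpus,
                                               rng):
        _, records, _ = deterministic_corpus
        cfg = small_config(features=("one_hot",))
        feats = assemble_features(
            [pk.build_bundle(r, with_physchem=False) for r in records[:16]],
            cfg)
        tc = TrainConfig(seed=3, batch_size=8)
        model, _ = train_mtl(records[:16], feats, cfg, tc, n_epochs=2)
        x = Tensor(np.stack([feats[0].T]))
        mask = np.ones((1, feats[0].shape[0]))
        fc = model.msrc(x)
        for g in model.mmoe.gates(fc, mask):
            assert np.allclose(g.data.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_roundtrip(self, tmp_path, deterministic_corpus, rng):
        _, records, _ = deterministic_corpus
        cfg = small_config()
        model = PSSPMTL(cfg, rng)
        feats = assemble_features(
            [pk.build_bundle(r) for r in records[:2]], cfg)
        p1 = predict(model, feats)
        save_mtl(model, tmp_path / "m.pkl")
        back = load_mtl(tmp_path / "m.pkl")
        p2 = predict(back, feats)
        assert np.allclose(p1[0].ss_probs, p2[0].ss_probs)

    def test_majority_baseline_between_0_and_100(self, small_corpus):
        _, records, _ = small_corpus
        q = majority_class_q(records, small_config())
        assert 0 < q < 100
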