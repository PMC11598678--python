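"""U-Net+ResNet18 architecture, BYOL objective, transfer and inference."""

import numpy as np
import pytest

from nirvein import segnet as S
from nirvein.nn import F32


def small_cfg(width=0.1, size=32):
    return S.NetConfig(width_multiplier=width, input_size=size)


class TestArchitecture:
    def test_forward_shape_and_probability_range(self, rng):
        net = S.build_network(small_cfg(), seed=0)
        x = rng.random((2, 1, 32, 32)).astype(F32)
        p = net.forward(x)
        assert p.shape == (2, 1, 32, 32)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_indivisible_input_rejected(self):
        net = S.build_network(small_cfg(), seed=0)
        with pytest.raises(ValueError, match="multiple of 32"):
            net.forward(np.zeros((1, 1, 33, 32), dtype=F32))
        with pytest.raises(ValueError, match="multiple of 32"):
            S.NetConfig(input_size=50)

    def test_parameter_count_monotone_in_width(self):
        counts = [S.build_network(small_cfg(w), seed=0).num_params()
                  for w in (0.125, 0.25, 0.5)]
        assert counts[0] < counts[1] < counts[2]

    def test_deterministic_given_seed(self, rng):
        x = rng.random((1, 1, 32, 32)).astype(F32)
        a = S.build_network(small_cfg(), seed=3).forward(x)
        b = S.build_network(small_cfg(), seed=3).forward(x)
        assert np.array_equal(a, b)
        c = S.build_network(small_cfg(), seed=4).forward(x)
        assert not np.array_equal(a, c)

    def test_zeroed_residual_branch_is_identity(self, rng):
        # with conv weights zeroed and fresh BN (mean 0, var 1) in eval
        # mode, a stride-1 block reduces to relu(x) = x for x >= 0
        net = S.build_network(small_cfg(), seed=0)
        block = net.encoder.layer1[0]
        block.conv1.weight.data[...] = 0.0
        block.conv2.weight.data[...] = 0.0
        block.set_train(False)
        x = rng.random((1, net.encoder.channels[0], 8, 8)).astype(F32)
        assert np.allclose(block.forward(x), x, atol=1e-5)


class TestByol:
    def test_loss_bounds_and_perfect_prediction(self, rng):
        q = rng.normal(size=(8, 16)).astype(F32)
        z = rng.normal(size=(8, 16)).astype(F32)
        loss, _ = S.byol_loss(q, z)
        assert 0.0 <= loss <= 4.0
        assert S.byol_loss(q, q)[0] < 1e-6
        assert np.isclose(S.byol_loss(q, -q)[0], 4.0, atol=1e-5)

    def test_pretrain_smoke_trace_and_determinism(self):
        from nirvein import phantom as PH

        imgs = PH.make_unlabeled_set(6, PH.PhantomSpec(height=32, width=32, seed=1))
        cfg = S.ByolConfig(epochs=2, batch_size=3, seed=5)
        state, trace = S.byol_pretrain(imgs, cfg, small_cfg())
        assert len(trace) == 2
        assert all(np.isfinite(t) and 0 <= t <= 4 for t in trace)
        state2, trace2 = S.byol_pretrain(imgs, cfg, small_cfg())
        assert trace == trace2
        assert all(np.array_equal(state[k], state2[k]) for k in state)

    def test_single_image_collapse_warning(self):
        img = np.random.default_rng(0).random((32, 32))
        with pytest.warns(UserWarning, match="collapse"):
            S.byol_pretrain([img], S.ByolConfig(epochs=0), small_cfg())

    def test_momentum_validation(self):
        with pytest.raises(ValueError, match="momentum"):
            S.ByolConfig(ema_momentum=1.0)


class TestTransfer:
    def test_zero_epoch_keeps_transferred_initialization(self):
        from nirvein import phantom as PH

        imgs = PH.make_unlabeled_set(4, PH.PhantomSpec(height=32, width=32, seed=2))
        enc_state, _ = S.byol_pretrain(imgs, S.ByolConfig(epochs=1, seed=1), small_cfg())
        labeled = [(im, im > im.mean()) for im in imgs]
        cfg = S.FinetuneConfig(epochs=0, seed=9, net=small_cfg())
        net, state = S.transfer_and_finetune(enc_state, labeled, cfg)
        reference = S.UNetResNet18(cfg.net, np.random.default_rng(9))
        reference.encoder.load_state_dict(enc_state)
        for (k, p), (k2, p2) in zip(net.named_params(), reference.named_params()):
            assert k == k2 and np.array_equal(p.data, p2.data), k

    def test_encoder_shape_mismatch_names_layer(self):
        enc_state, _ = S.byol_pretrain(
            [np.zeros((32, 32)), np.ones((32, 32))],
            S.ByolConfig(epochs=0, seed=0), small_cfg(width=0.2))
        labeled = [(np.zeros((32, 32)), np.zeros((32, 32), bool))] * 2
        with pytest.raises(ValueError, match="stem_conv"):
            S.transfer_and_finetune(enc_state, labeled,
                                    S.FinetuneConfig(epochs=0, net=small_cfg(width=0.1)))

    def test_overfits_single_phantom(self):
        from nirvein import phantom as PH

        img, mask, _ = PH.make_vein_phantom(
            PH.PhantomSpec(height=64, width=64, n_vessels=2, seed=6, noise_sigma=0.01))
        cfg = S.FinetuneConfig(epochs=200, batch_size=1, seed=0, lr=5e-3,
                               net=S.NetConfig(width_multiplier=0.25, input_size=64))
        net, state = S.transfer_and_finetune(None, [(img, mask)], cfg)
        assert state.train_bce[-1] < 0.05
        assert len(state.train_bce) == 200


class TestSegment:
    class _StubNet:
        """Fixed-output network standing in for a trained model."""

        def __init__(self, value):
            self.value = value

        def forward(self, x):
            return np.full_like(x, self.value)

        def set_train(self, mode):
            pass

    def test_threshold_conventions(self):
        img = np.zeros((40, 50))  # also exercises padding to 64x64
        prob, mask = S.segment(self._StubNet(0.49), img)
        assert prob.shape == (40, 50) and not mask.any()
        _, mask = S.segment(self._StubNet(0.5), img)
        assert mask.all()  # >= convention: exactly 0.5 is foreground

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = S.build_network(small_cfg(), seed=1)
        x = rng.random((1, 1, 32, 32)).astype(F32)
        net.set_train(False)
        before = net.forward(x)
        path = tmp_path / "ckpt.npz"
        S.save_checkpoint(path, net)
        loaded = S.load_checkpoint(path)
        loaded.set_train(False)
        assert np.array_equal(loaded.forward(x), before)
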