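"""Architecture contracts: shapes, ECA, Patch-GAN, parameter ledger."""

import numpy as np
import pytest

from lispcn.network import (ArchConfig, ClassifierHead, PatchDiscriminator,
                            PerceptualNet, build_bundle, build_encoder,
                            eca_kernel_size, load_bundle, save_bundle)
from lispcn.nn.tensor import Tensor


class TestEncoder:
    def test_latent_shape_64(self, rng):
        enc = build_encoder(seed=0)
        z = enc(Tensor(rng.normal(0, 1, (2, 3, 64, 64)).astype(np.float32)))
        assert z.shape == (2, 8, 8, 8)

    def test_indivisible_size_rejected(self, rng):
        enc = build_encoder(seed=0)
        with pytest.raises(ValueError, match="divisible"):
            enc(Tensor(rng.normal(0, 1, (1, 3, 50, 50)).astype(np.float32)))

    def test_eca_adds_parameters(self):
        with_eca = build_encoder(ArchConfig(use_eca=True), seed=0)
        without = build_encoder(ArchConfig(use_eca=False), seed=0)
        assert with_eca.n_parameters() > without.n_parameters()

    def test_invalid_channel_order_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            build_encoder(ArchConfig(encoder_channels=(4, 4, 8)), seed=0)


class TestEca:
    @pytest.mark.parametrize("channels,expected", [
        (8, 3), (64, 3), (1024, 5), (2, 3), (4, 3),
    ])
    def test_adaptive_kernel_size(self, channels, expected):
        assert eca_kernel_size(channels) == expected

    def test_zero_input_gives_zero_output(self):
        from lispcn.nn.layers import ECA
        eca = ECA(8, rng=np.random.default_rng(0))
        out = eca(Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_zero_conv_gives_half_gate(self):
        from lispcn.nn.layers import ECA
        eca = ECA(8, rng=np.random.default_rng(0))
        eca.weight.data[:] = 0.0
        x = np.full((1, 8, 4, 4), 2.0, dtype=np.float32)
        np.testing.assert_allclose(eca(Tensor(x)).data, x * 0.5, rtol=1e-6)

    def test_gate_spatially_constant_per_channel(self, rng):
        from lispcn.nn.layers import ECA
        eca = ECA(8, rng=np.random.default_rng(0))
        x = rng.normal(0, 1, (2, 8, 4, 4)).astype(np.float32)
        x[np.abs(x) < 0.1] = 0.1  # avoid division blowups
        ratio = eca(Tensor(x)).data / x
        assert np.allclose(ratio, ratio[:, :, :1, :1], atol=1e-5)
        assert (ratio > 0).all() and (ratio < 1).all()


class TestGenerator:
    def test_output_shape_and_range(self, tiny_bundle, rng):
        x = rng.uniform(-1, 1, (2, 3, 32, 32)).astype(np.float32)
        out = tiny_bundle.G(Tensor(x))
        assert out.shape == x.shape
        assert out.data.min() >= -1.0 and out.data.max() <= 1.0

    def test_eval_determinism(self, tiny_bundle, rng):
        x = rng.uniform(-1, 1, (1, 3, 32, 32)).astype(np.float32)
        a = tiny_bundle.G(Tensor(x)).data
        b = tiny_bundle.G(Tensor(x)).data
        np.testing.assert_array_equal(a, b)


class TestDiscriminator:
    def test_patch_score_map_not_global(self, rng):
        disc = PatchDiscriminator(ArchConfig(), np.random.default_rng(0))
        x = rng.uniform(-1, 1, (2, 3, 64, 64)).astype(np.float32)
        scores = disc(Tensor(x))
        assert scores.shape[0] == 2
        assert scores.shape[2] > 1 and scores.shape[3] > 1

    def test_translation_equivariance_interior(self, rng):
        """Shifting the input by the stride product shifts the score map
        one cell; checked away from the zero-padded borders on a
        normalization-free critic (circular shift keeps statistics)."""
        disc = PatchDiscriminator(ArchConfig(), np.random.default_rng(0),
                                  norm=False)
        x = rng.uniform(-1, 1, (1, 3, 128, 128)).astype(np.float32)
        shift = 8  # one full stride product -> one score-map cell
        x_shift = np.roll(x, shift, axis=3)
        a = disc(Tensor(x)).data
        b = disc(Tensor(x_shift)).data
        np.testing.assert_allclose(
            np.roll(a, 1, axis=3)[:, :, 4:-4, 4:-4], b[:, :, 4:-4, 4:-4],
            atol=1e-4)

    def test_constant_weights_give_constant_map(self):
        disc = PatchDiscriminator(ArchConfig(), np.random.default_rng(0))
        for name, p in disc.named_parameters():
            p.data = np.full_like(p.data, 0.01)
        x = np.full((1, 3, 128, 128), 0.3, dtype=np.float32)
        scores = disc(Tensor(x)).data
        interior = scores[:, :, 4:-4, 4:-4]  # borders see zero padding
        assert np.allclose(interior, interior.flat[0], atol=1e-5)


class TestHeadAndPercnet:
    def test_zero_weight_head_gives_half(self, rng):
        head = ClassifierHead(ArchConfig(), np.random.default_rng(0))
        for _, p in head.named_parameters():
            p.data[:] = 0.0
        z = Tensor(rng.normal(0, 1, (3, 8, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(head(z).data, 0.5, atol=1e-7)

    def test_probability_in_open_interval(self, rng):
        head = ClassifierHead(ArchConfig(), np.random.default_rng(0))
        z = Tensor(rng.normal(0, 5, (16, 8, 4, 4)).astype(np.float32))
        p = head(z).data
        assert (p > 0).all() and (p < 1).all()

    def test_spatial_permutation_invariance(self, rng):
        head = ClassifierHead(ArchConfig(), np.random.default_rng(0))
        z = rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32)
        perm = rng.permutation(16)
        z_perm = z.reshape(1, 8, 16)[:, :, perm].reshape(1, 8, 4, 4)
        np.testing.assert_allclose(head(Tensor(z)).data,
                                   head(Tensor(z_perm)).data, rtol=1e-6)

    def test_percnet_deterministic_and_frozen(self, rng):
        a = PerceptualNet(seed=77)
        b = PerceptualNet(seed=77)
        x = Tensor(rng.uniform(-1, 1, (1, 3, 32, 32)).astype(np.float32))
        for fa, fb in zip(a(x), b(x)):
            np.testing.assert_array_equal(fa.data, fb.data)
        assert all(not p.requires_grad for p in a.parameters())

    def test_percnet_identical_inputs_zero_distance(self, rng):
        net = PerceptualNet(seed=1)
        x = rng.uniform(-1, 1, (1, 3, 32, 32)).astype(np.float32)
        fa = net(Tensor(x))
        fb = net(Tensor(x.copy()))
        assert sum(float(np.abs(a.data - b.data).sum())
                   for a, b in zip(fa, fb)) == 0.0


class TestBundle:
    def test_parameter_ledger_sums_components(self):
        bundle = build_bundle(seed=0)
        total = sum(m.n_parameters() for m in bundle.components().values())
        assert bundle.n_parameters() == total

    def test_ablation_reduces_parameter_count(self):
        full = build_bundle(seed=0)
        for variant in ("AS-Dec", "AS-Dis", "AS-GF"):
            assert build_bundle(seed=0, ablation=variant).n_parameters() \
                < full.n_parameters()

    def test_as_pcp_keeps_architecture(self):
        assert build_bundle(seed=0, ablation="AS-Pcp").n_parameters() \
            == build_bundle(seed=0).n_parameters()

    def test_save_load_roundtrip(self, tmp_path, rng):
        bundle = build_bundle(seed=5)
        path = str(tmp_path / "ckpt.pkl")
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        x = rng.uniform(-1, 1, (1, 3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(bundle.synthesize(x),
                                      loaded.synthesize(x))
        np.testing.assert_array_equal(bundle.predict_proba(x),
                                      loaded.predict_proba(x))
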