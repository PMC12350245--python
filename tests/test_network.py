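"""Network building blocks: convolution levels, gated fusion, attention,
spectral sequence encoding, and the assembled forward pass."""

import numpy as np
import pytest

from specseg.autodiff import Tensor
from specseg.errors import ConfigurationError, ShapeError
from specseg.network import (
    AttentionState,
    ConvLevelParams,
    FeaturePyramid,
    NetworkConfig,
    SegmentationModel,
    attention_aggregate,
    bilinear_resize,
    build_pyramid,
    encode_level,
    encode_spectral_sequence,
    gated_fuse,
    init_spectral_params,
    predict,
)


def _identity_params(c=1):
    w = np.zeros((1, 1, c, c))
    for i in range(c):
        w[0, 0, i, i] = 1.0
    return ConvLevelParams(weight=w, bias=np.zeros(c))


class TestEncodeLevel:
    def test_identity_kernel_on_nonnegative_input(self, rng):
        x = np.abs(rng.normal(size=(5, 5, 1)))
        out = encode_level(x, _identity_params())
        assert np.allclose(out.data, x, atol=1e-12)

    def test_relu_zeroes_negative_input(self, rng):
        x = -np.abs(rng.normal(size=(4, 4, 2))) - 0.1
        out = encode_level(x, _identity_params(2))
        assert np.all(out.data == 0.0)

    def test_matches_naive_convolution_oracle(self, rng):
        x = rng.normal(size=(5, 5, 3))
        w = rng.normal(size=(3, 3, 3, 2))
        p = ConvLevelParams(weight=w, bias=np.zeros(2), activation="relu")
        out = encode_level(x, p).data
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        naive = np.zeros((5, 5, 2))
        for i in range(5):
            for j in range(5):
                for c in range(2):
                    naive[i, j, c] = np.sum(xp[i : i + 3, j : j + 3, :] * w[:, :, :, c])
        naive = np.maximum(naive, 0)
        assert np.abs(out - naive).max() < 1e-6

    def test_channel_mismatch(self, rng):
        with pytest.raises(ShapeError):
            encode_level(rng.normal(size=(4, 4, 3)), _identity_params(2))

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            ConvLevelParams(weight=np.zeros((2, 2, 1, 1)), bias=np.zeros(1))


class TestPyramid:
    def test_single_level_equals_encode_level(self, rng):
        cfg = NetworkConfig(n_scales=1, channels=(4,), n_classes=2)
        x = rng.normal(size=(8, 8, 3))
        w = rng.normal(size=(3, 3, 3, 4))
        p = [ConvLevelParams(weight=w, bias=np.zeros(4))]
        pyr = build_pyramid(x, cfg, p)
        assert len(pyr.levels) == 1
        assert np.allclose(pyr.levels[0].data[0], encode_level(x, p[0]).data)

    def test_stride_schedule_halves_each_level(self, rng):
        cfg = NetworkConfig(n_scales=3, channels=(2, 2, 2), n_classes=2)
        x = rng.normal(size=(32, 32, 3))
        params = [
            ConvLevelParams(weight=rng.normal(size=(3, 3, cin, 2)), bias=np.zeros(2))
            for cin in (3, 2, 2)
        ]
        pyr = build_pyramid(x, cfg, params)
        assert [l.shape[1] for l in pyr.levels] == [32, 16, 8]

    def test_zero_scales_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(n_scales=0, channels=(), n_classes=2)

    def test_too_small_image_rejected(self, rng):
        cfg = NetworkConfig(n_scales=4, channels=(2, 2, 2, 2), n_classes=2)
        params = [
            ConvLevelParams(weight=rng.normal(size=(3, 3, cin, 2)), bias=np.zeros(2))
            for cin in (1, 2, 2, 2)
        ]
        with pytest.raises(ShapeError):
            build_pyramid(rng.normal(size=(4, 4, 1)), cfg, params)


class TestGatedFusion:
    def _pyramid(self, levels, gammas):
        tensors = [Tensor(np.asarray(l, dtype=float)) for l in levels]
        return FeaturePyramid(levels=tensors, gate_logits=Tensor(np.asarray(gammas, dtype=float)))

    def test_equal_logits_give_uniform_weights(self):
        lv = [np.ones((1, 4, 4, 2))] * 3
        pyr = self._pyramid(lv, [0.0, 0.0, 0.0])
        gated_fuse(pyr)
        assert np.allclose(pyr.alpha, 1 / 3)

    def test_log_weights_closed_form(self):
        lv = [np.full((1, 4, 4, 1), 1.0), np.full((1, 4, 4, 1), 4.0)]
        pyr = self._pyramid(lv, [np.log(2.0), 0.0])
        fused = gated_fuse(pyr)
        assert np.allclose(fused.data, 2.0, atol=1e-12)

    def test_saturated_gate_selects_one_level(self, rng):
        lv = [rng.normal(size=(1, 4, 4, 2)) for _ in range(3)]
        pyr = self._pyramid(lv, [50.0, 0.0, 0.0])
        fused = gated_fuse(pyr)
        assert np.abs(fused.data - lv[0]).max() < 1e-6

    def test_single_level_passthrough(self, rng):
        lv = [rng.normal(size=(1, 4, 4, 2))]
        pyr = self._pyramid(lv, [3.0])
        fused = gated_fuse(pyr)
        assert np.array_equal(fused.data, lv[0])
        assert np.allclose(pyr.alpha, [1.0])

    def test_gate_weights_live_on_simplex(self, rng):
        for _ in range(10):
            lv = [rng.normal(size=(1, 4, 4, 2)) for _ in range(4)]
            pyr = self._pyramid(lv, rng.normal(size=4) * 5)
            gated_fuse(pyr)
            assert pyr.alpha.sum() == pytest.approx(1.0)
            assert np.all(pyr.alpha > 0)

    def test_coarse_levels_upsampled_to_finest(self, rng):
        lv = [rng.normal(size=(1, 8, 8, 2)), rng.normal(size=(1, 4, 4, 2))]
        pyr = self._pyramid(lv, [0.0, 0.0])
        fused = gated_fuse(pyr)
        assert fused.shape == (1, 8, 8, 2)

    def test_constant_map_survives_resize(self):
        x = Tensor(np.full((1, 4, 4, 2), 3.25))
        out = bilinear_resize(x, (9, 9))
        assert np.allclose(out.data, 3.25)


class TestAttention:
    def _state(self, c, w_val=0.0, b_val=0.0):
        return AttentionState(weight=np.full((1, 1, c, 1), w_val),
                              bias=np.array([b_val]))

    def test_saturated_open_gate_passes_features(self, rng):
        x = rng.normal(size=(4, 4, 3))
        out = attention_aggregate(x, self._state(3, b_val=50.0))
        assert np.abs(out.data - x).max() < 1e-6

    def test_saturated_closed_gate_suppresses(self, rng):
        x = rng.normal(size=(4, 4, 3))
        out = attention_aggregate(x, self._state(3, b_val=-50.0))
        assert np.abs(out.data).max() < 1e-6

    def test_neutral_gate_halves_features(self, rng):
        x = rng.normal(size=(4, 4, 3))
        out = attention_aggregate(x, self._state(3))
        assert np.allclose(out.data, 0.5 * x, atol=1e-12)

    def test_attention_map_strictly_in_unit_interval(self, rng):
        x = rng.normal(size=(4, 4, 3)) * 10
        att = AttentionState(weight=rng.normal(size=(1, 1, 3, 1)),
                             bias=rng.normal(size=(1,)))
        attention_aggregate(x, att)
        assert np.all(att.attention_map > 0) and np.all(att.attention_map < 1)

    def test_grid_mismatch(self, rng):
        with pytest.raises(ShapeError):
            attention_aggregate(rng.normal(size=(4, 4, 3)), self._state(2))


class TestSpectralEncoder:
    def test_none_bypasses(self, rng):
        cfg = NetworkConfig(spectral_encoder="none")
        x = rng.normal(size=(4, 4, 5))
        out = encode_spectral_sequence(x, cfg)
        assert np.array_equal(out.data, x)

    def test_single_band_with_encoder_rejected(self, rng):
        cfg = NetworkConfig(spectral_encoder="lstm")
        with pytest.raises(ConfigurationError, match="none"):
            encode_spectral_sequence(rng.normal(size=(4, 4, 1)), cfg)

    def test_constant_spectrum_gives_constant_map(self):
        cfg = NetworkConfig(spectral_encoder="lstm", spectral_hidden=4)
        x = np.full((6, 6, 5), 0.7)
        params = init_spectral_params(cfg, 5, np.random.default_rng(0))
        out = encode_spectral_sequence(x, cfg, params).data
        assert np.allclose(out, out[0, 0], atol=1e-12)

    @pytest.mark.parametrize("encoder", ["lstm", "transformer"])
    def test_band_order_matters(self, rng, encoder):
        """Sequence encoders read band order; reversal changes the output."""
        cfg = NetworkConfig(spectral_encoder=encoder, spectral_hidden=4,
                            transformer_heads=2, transformer_layers=1)
        x = rng.normal(size=(4, 4, 6))
        params = init_spectral_params(cfg, 6, rng)
        fwd = encode_spectral_sequence(x, cfg, params).data
        rev = encode_spectral_sequence(x[:, :, ::-1].copy(), cfg, params).data
        assert np.abs(fwd - rev).max() > 1e-6

    def test_none_encoder_permutes_with_bands(self, rng):
        cfg = NetworkConfig(spectral_encoder="none")
        x = rng.normal(size=(4, 4, 5))
        perm = rng.permutation(5)
        out = encode_spectral_sequence(x, cfg).data
        out_p = encode_spectral_sequence(x[:, :, perm].copy(), cfg).data
        assert np.array_equal(out[:, :, perm], out_p)


class TestPredict:
    @pytest.fixture
    def model(self):
        return SegmentationModel(
            NetworkConfig(n_classes=3, n_image_classes=2,
                          spectral_encoder="lstm", spectral_hidden=4),
            n_bands=4, seed=0,
        )

    def test_probabilities_normalized(self, rng, model):
        x = rng.normal(size=(8, 8, 4))
        seg, cls = predict(x, model.config, model.params)
        assert np.allclose(seg.sum(axis=2), 1.0, atol=1e-6)
        assert cls.sum() == pytest.approx(1.0, abs=1e-6)
        assert seg.shape == (8, 8, 3)

    def test_uniform_logit_head_gives_uniform_probs(self, rng, model):
        model.params["seg_w"].data[:] = 0.0
        model.params["seg_b"].data[:] = 0.0
        seg, _ = predict(rng.normal(size=(8, 8, 4)), model.config, model.params)
        assert np.allclose(seg, 1.0 / 3.0, atol=1e-12)

    def test_argmax_tie_breaks_to_smallest_index(self):
        probs = np.full((2, 2, 3), 1 / 3)
        assert np.all(np.argmax(probs, axis=2) == 0)

    def test_forward_is_deterministic(self, rng, model):
        x = rng.normal(size=(8, 8, 4))
        a = predict(x, model.config, model.params)
        b = predict(x, model.config, model.params)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_gate_simplex_on_every_forward(self, rng, model):
        for _ in range(3):
            out = model.forward(rng.normal(size=(2, 8, 8, 4)))
            assert out["alpha"].sum() == pytest.approx(1.0)
            assert np.all(out["alpha"] > 0)
            a = out["attention"].attention_map
            assert np.all(a > 0) and np.all(a < 1)
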