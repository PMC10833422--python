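import numpy as np
import pytest

from zernseg import _nn
from zernseg.errors import ConfigurationError, ContractError
from zernseg.models import (
    ModelConfig,
    build_model,
    load_checkpoint,
    predict_slice_probs,
    predict_volume,
    save_checkpoint,
)
from zernseg.volumes import GrayVolume


def n_params(model):
    return sum(p.value.size for p in model.params())


class TestBuildModel:
    def test_unet_shape_contract(self):
        m = build_model(ModelConfig(architecture="unet2d", depth=3, base_channels=8,
                                    patch_size_vox=64, n_classes=4, seed=0))
        x = np.zeros((2, 64, 64, 1), np.float32)
        logits, _ = m.net.forward(x)
        assert logits.shape == (2, 64, 64, 4)

    def test_sensor3d_consumes_context_window(self):
        m = build_model(ModelConfig(architecture="sensor3d", context_slices=3,
                                    patch_size_vox=32, seed=0))
        x = np.zeros((2, 3, 32, 32), np.float32)
        logits, _ = m.net.forward(x)
        assert logits.shape == (2, 32, 32, 4)
        with pytest.raises(ContractError):
            m.net.forward(np.zeros((2, 5, 32, 32), np.float32))

    def test_deterministic_initialization(self):
        cfg = ModelConfig(architecture="sensor3d", patch_size_vox=32, seed=5)
        x = np.random.default_rng(1).random((2, 3, 32, 32)).astype(np.float32)
        l1, _ = build_model(cfg).net.forward(x)
        l2, _ = build_model(cfg).net.forward(x)
        assert np.array_equal(l1, l2)

    def test_invalid_divisibility_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(architecture="unet2d", depth=3, patch_size_vox=36))

    def test_even_context_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(architecture="sensor3d", context_slices=2))

    @pytest.mark.parametrize("arch", ["unet2d", "sensor3d"])
    def test_param_count_grows_with_width_and_depth(self, arch):
        base = n_params(build_model(ModelConfig(architecture=arch, base_channels=4,
                                                depth=2, patch_size_vox=32)))
        wider = n_params(build_model(ModelConfig(architecture=arch, base_channels=8,
                                                 depth=2, patch_size_vox=32)))
        deeper = n_params(build_model(ModelConfig(architecture=arch, base_channels=4,
                                                  depth=3, patch_size_vox=32)))
        assert wider > base
        assert deeper > base


class TestPrediction:
    def _vol(self, shape=(8, 64, 64), seed=2):
        return GrayVolume(np.random.default_rng(seed).random(shape).astype(np.float32), 94.0)

    def test_probabilities_sum_to_one(self):
        m = build_model(ModelConfig(architecture="unet2d", patch_size_vox=32, seed=0))
        probs, _ = predict_volume(m, self._vol())
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_untrained_prediction_deterministic(self):
        m = build_model(ModelConfig(architecture="sensor3d", patch_size_vox=32, seed=0))
        vol = GrayVolume(np.zeros((6, 32, 32), np.float32), 94.0)
        _, l1 = predict_volume(m, vol)
        _, l2 = predict_volume(m, vol)
        assert np.array_equal(l1.data, l2.data)

    def test_labels_argmax_of_probs(self):
        m = build_model(ModelConfig(architecture="unet2d", patch_size_vox=32, seed=1))
        probs, labels = predict_volume(m, self._vol((4, 48, 48)))
        assert np.array_equal(probs.argmax(axis=1).astype(np.uint8), labels.data)

    def test_volume_smaller_than_patch_is_tiling_error(self):
        m = build_model(ModelConfig(architecture="unet2d", patch_size_vox=64, seed=0))
        with pytest.raises(ContractError):
            predict_volume(m, self._vol((4, 32, 32)))

    def test_translation_consistency_away_from_borders(self):
        # a conv-pool net is equivariant to pool-aligned translations except
        # within a receptive-field margin of the borders
        m = build_model(ModelConfig(architecture="unet2d", depth=1, base_channels=8,
                                    patch_size_vox=48, seed=3))
        rng = np.random.default_rng(7)
        big = rng.random((1, 64, 48, 1)).astype(np.float32)
        shift = 4  # multiple of the total pooling stride (2)
        margin = 16  # > receptive-field radius of the depth-1 network
        l1, _ = m.net.forward(big[:, 0:48, :])
        l2, _ = m.net.forward(big[:, shift : 48 + shift, :])
        inner1 = l1[:, shift + margin : 48 - margin, margin:-margin]
        inner2 = l2[:, margin : 48 - shift - margin, margin:-margin]
        assert np.allclose(inner1, inner2, atol=1e-4)


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        m = build_model(ModelConfig(architecture="sensor3d", patch_size_vox=32, seed=4))
        m.trained_epochs = 7
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        assert back.trained_epochs == 7
        assert back.config == m.config
        x = np.random.default_rng(0).random((1, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(m.net.forward(x)[0], back.net.forward(x)[0])


class TestOverfitSanity:
    def test_overfit_single_slice_reaches_high_dice(self, small_phantom):
        # direct optimization on one slice's patches; the model must be able
        # to memorize a single image (capacity + wiring sanity)
        vol, lab = small_phantom.gray, small_phantom.labels
        z = 16
        m = build_model(ModelConfig(architecture="unet2d", patch_size_vox=32,
                                    base_channels=8, depth=2, seed=0))
        g2, l2 = vol.data[z], lab.data[z].astype(np.int64)
        tiles_x, tiles_y = [], []
        for y0 in (0, 16, 32):
            for x0 in (0, 16, 32):
                tiles_x.append(g2[y0 : y0 + 32, x0 : x0 + 32, None])
                tiles_y.append(l2[y0 : y0 + 32, x0 : x0 + 32])
        xb, yb = np.stack(tiles_x), np.stack(tiles_y)
        counts = np.bincount(yb.ravel(), minlength=4).astype(float)
        w = np.minimum(yb.size / (4 * np.maximum(counts, 1)), 50.0)
        opt = _nn.Adadelta(m.params())
        for _ in range(150):
            opt.zero_grad()
            logits, cache = m.net.forward(xb)
            _, dl, _ = _nn.softmax_cross_entropy(logits, yb, w)
            m.net.backward(dl, cache)
            opt.step()
        pred = predict_slice_probs(m, vol.data, z).argmax(axis=0)
        from zernseg.metrics import dice

        _, mean_dice = dice(pred, lab.data[z], n_classes=4)
        assert mean_dice >= 0.95
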