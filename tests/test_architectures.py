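"""Structural conformance of the WIC / WLC / WMC network families."""

import numpy as np
import pytest

from woundmm.architectures import (
    ArchitectureError,
    WICConfig,
    WLCConfig,
    WMCConfig,
    WIC_HEAD_WIDTHS,
    WLC_LSTM_DENSE,
    WLC_LSTM_UNITS,
    WLC_MLP_WIDTHS,
    WMC_POST_FUSION_WIDTHS,
    build_ohv_direct,
    build_wic,
    build_wlc,
    build_wmc,
)
from woundmm.nn import get_weights


def dense_widths(handle):
    return [i.width for i in handle.describe() if i.kind == "dense"]


def lstm_units(handle):
    return [i.width for i in handle.describe() if i.kind == "lstm"]


class TestWIC:
    def test_vgg16_head_is_three_dense_512_with_dropout_then_softmax(self):
        handle = build_wic(WICConfig(n_classes=4, backbone="vgg16"))
        infos = handle.describe()
        # backbone is frozen, head is trainable
        assert all(not i.trainable for i in infos if i.kind == "conv2d")
        trainable_dense = [i for i in infos if i.kind == "dense" and i.trainable]
        assert [i.width for i in trainable_dense] == [512, 512, 512, 4]
        assert trainable_dense[-1].activation == "softmax"
        assert sum(1 for i in infos if i.kind == "dropout") == 3
        assert handle.output_dim == 4

    def test_binary_head_is_single_sigmoid_unit(self):
        handle = build_wic(WICConfig(n_classes=2, backbone="vgg19"))
        last = [i for i in handle.describe() if i.kind == "dense"][-1]
        assert (last.width, last.activation) == (1, "sigmoid")
        assert handle.output_dim == 1

    def test_tinytest_structure_and_output(self):
        handle = build_wic(WICConfig(n_classes=3, backbone="tinytest", input_size=64))
        infos = handle.describe()
        assert all(i.trainable for i in infos if i.kind == "conv2d")  # not frozen
        assert dense_widths(handle) == [512, 512, 512, 3]
        x = np.random.default_rng(0).random((4, 64, 64, 3), dtype=np.float32)
        probs = handle.forward(x)
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_backbone_and_tiny_n_classes_rejected(self):
        with pytest.raises(ArchitectureError, match="unknown backbone"):
            WICConfig(n_classes=4, backbone="mobilenet")
        with pytest.raises(ArchitectureError, match="n_classes"):
            WICConfig(n_classes=1)

    @pytest.mark.parametrize("backbone", ["alexnet", "resnet50", "inceptionv3"])
    def test_other_backbones_build_with_conformant_heads(self, backbone):
        handle = build_wic(WICConfig(n_classes=5, backbone=backbone))
        assert dense_widths(handle) == [512, 512, 512, 5]

    def test_frozen_backbone_weights_untouched_by_training(self):
        from woundmm.training import TrainingConfig, train

        handle = build_wic(
            WICConfig(n_classes=2, backbone="tinytest", input_size=32, freeze_backbone=True)
        )
        backbone = handle.net.layers[0]
        before = get_weights(backbone)
        rng = np.random.default_rng(1)
        x = rng.random((12, 32, 32, 3), dtype=np.float32)
        y = rng.integers(0, 2, 12)
        train(handle, x, y, x[:4], y[:4], TrainingConfig(epochs=2, batch_size=6))
        after = get_weights(backbone)
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        # while the trainable head moved
        head_w = handle.net.layers[1].params["W"]
        assert handle.net.layers[1].trainable

    def test_rebuild_same_seed_gives_identical_weights(self):
        cfg = WICConfig(n_classes=3, backbone="tinytest", seed=11)
        w1 = get_weights(build_wic(cfg).net)
        w2 = get_weights(build_wic(cfg).net)
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)


class TestWLC:
    def test_mlp_widths_match_the_stated_stack(self):
        handle = build_wlc(WLCConfig(input_dim=324, n_classes=4, kind="mlp"))
        assert dense_widths(handle) == list(WLC_MLP_WIDTHS) + [4]
        assert WLC_MLP_WIDTHS == (128, 128, 128, 256, 256, 256, 512, 512, 512)
        relu_dense = [i for i in handle.describe() if i.kind == "dense"][:-1]
        assert all(i.activation == "relu" for i in relu_dense)

    def test_lstm_units_and_final_dense(self):
        handle = build_wlc(WLCConfig(input_dim=324, n_classes=4, kind="lstm"))
        assert lstm_units(handle) == list(WLC_LSTM_UNITS) == [32, 32, 64, 64]
        assert dense_widths(handle) == [WLC_LSTM_DENSE, 4] == [512, 4]

    def test_mlp_parameter_count_matches_closed_form(self):
        d = 37
        handle = build_wlc(WLCConfig(input_dim=d, n_classes=4, kind="mlp"))
        widths = list(WLC_MLP_WIDTHS)
        expected = 0
        fan_in = d
        for w in widths:
            expected += (fan_in + 1) * w
            fan_in = w
        expected += (fan_in + 1) * 4  # softmax head
        assert handle.n_params == expected

    def test_lstm_forward_shapes(self):
        handle = build_wlc(WLCConfig(input_dim=13, n_classes=3, kind="lstm"))
        x = np.eye(13, dtype=np.float32)[:5]
        probs = handle.forward(x)
        assert probs.shape == (5, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_single_step_shaping_builds(self):
        handle = build_wlc(
            WLCConfig(input_dim=13, n_classes=3, kind="lstm", sequence_shaping="single_step")
        )
        assert handle.forward(np.eye(13, dtype=np.float32)[:2]).shape == (2, 3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ArchitectureError, match="unknown WLC kind"):
            WLCConfig(input_dim=10, n_classes=2, kind="transformer")


class TestWMC:
    def test_feature_fusion_concat_width_is_1024_then_512_256(self):
        cfg = WMCConfig(
            wic=WICConfig(n_classes=4, backbone="tinytest", input_size=32),
            wlc=WLCConfig(input_dim=13, n_classes=4),
        )
        handle = build_wmc(cfg)
        infos = handle.describe()
        concat = [i for i in infos if i.kind == "concatenate"]
        assert len(concat) == 1 and concat[0].width == 1024
        post = [i for i in infos[infos.index(concat[0]) :] if i.kind == "dense"]
        assert [i.width for i in post] == list(WMC_POST_FUSION_WIDTHS) + [4]
        assert WMC_POST_FUSION_WIDTHS == (512, 256)

    def test_probability_fusion_concat_width_is_twice_head_width(self):
        cfg = WMCConfig(
            wic=WICConfig(n_classes=4, backbone="tinytest", input_size=32),
            wlc=WLCConfig(input_dim=13, n_classes=4),
            fusion_point="probabilities",
        )
        infos = build_wmc(cfg).describe()
        concat = [i for i in infos if i.kind == "concatenate"][0]
        assert concat.width == 8

    def test_branch_n_classes_mismatch_rejected(self):
        with pytest.raises(ArchitectureError, match="mismatch"):
            WMCConfig(
                wic=WICConfig(n_classes=4, backbone="tinytest"),
                wlc=WLCConfig(input_dim=13, n_classes=2),
            )

    def test_forward_pass_and_softmax_normalization(self):
        handle = build_wmc(
            WMCConfig(
                wic=WICConfig(n_classes=3, backbone="tinytest", input_size=32),
                wlc=WLCConfig(input_dim=7, n_classes=3),
            )
        )
        rng = np.random.default_rng(0)
        x = (rng.random((6, 32, 32, 3), dtype=np.float32), np.eye(7, dtype=np.float32)[:6])
        probs = handle.forward(x)
        assert probs.shape == (6, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestOHVDirect:
    def test_dense_input_width_is_backbone_features_plus_ohv(self):
        handle = build_ohv_direct(
            WICConfig(n_classes=4, backbone="tinytest", input_size=64), location_dim=324
        )
        first_dense = next(
            l for l in handle.net.head.layers if l.describe().kind == "dense"
        )
        assert first_dense.in_dim == 16 * 14 * 14 + 324
        assert dense_widths(handle) == [512, 512, 512, 4]

    def test_no_wlc_stack_present(self):
        handle = build_ohv_direct(
            WICConfig(n_classes=2, backbone="tinytest", input_size=64), location_dim=13
        )
        kinds = {i.kind for i in handle.describe()}
        assert "lstm" not in kinds
        widths = [i.width for i in handle.describe() if i.kind == "dense"]
        assert 128 not in widths and 256 not in widths  # no MLP trunk

    def test_tiny_registry_builds_and_runs(self):
        handle = build_ohv_direct(
            WICConfig(n_classes=2, backbone="tinytest", input_size=32), location_dim=2
        )
        rng = np.random.default_rng(0)
        x = (rng.random((3, 32, 32, 3), dtype=np.float32),
             np.eye(2, dtype=np.float32)[[0, 1, 0]])
        out = handle.forward(x)
        assert out.shape == (3, 1)
        assert np.all((out >= 0) & (out <= 1))


class TestConfigSerialization:
    def test_yaml_roundtrip_and_build(self, tmp_path):
        from woundmm.architectures import (
            build_from_config,
            config_from_yaml,
            config_to_yaml,
        )

        cfg = WMCConfig(
            wic=WICConfig(n_classes=4, backbone="tinytest", input_size=32),
            wlc=WLCConfig(input_dim=13, n_classes=4, kind="lstm"),
        )
        path = tmp_path / "wmc.yaml"
        config_to_yaml(cfg, path)
        back = config_from_yaml(path)
        assert back == cfg
        assert build_from_config(back).n_classes == 4

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("kind: Mystery\nconfig: {}\n")
        from woundmm.architectures import config_from_yaml

        with pytest.raises(ArchitectureError, match="unknown config kind"):
            config_from_yaml(path)
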