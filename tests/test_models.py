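"""Architecture builders, shape chaining, and training behavior."""

import numpy as np
import pandas as pd
import pytest

from trampohar import (
    TrainConfig,
    build,
    build_depth_variant,
    build_ours,
    build_simple_cnn,
    build_vgg16_fc,
    count_params,
    output_shapes,
    train,
    train_rf,
)

# (kind, length, channels) per sequence layer of the GAP network
GAP_NET_EXPECTED = (
    [("conv", 192, 16), ("conv", 192, 16), ("maxpool", 96, 16)]
    + [("conv", 96, 32), ("conv", 96, 32), ("maxpool", 48, 32)]
    + [("conv", 48, 64)] * 3 + [("maxpool", 24, 64)]
    + [("conv", 24, 128)] * 3 + [("maxpool", 12, 128)]
    + [("conv", 12, 128)] * 3 + [("maxpool", 6, 128)]
)


class TestGapNetwork:
    def test_layer_by_layer_shapes(self):
        spec = build_ours()
        got = [
            (l.kind, *s) for l, s in zip(spec.layers, output_shapes(spec))
        ]
        assert got[:-2] == GAP_NET_EXPECTED
        assert got[-2:] == [("gap", 128), ("softmax", 6)]

    def test_thirteen_conv_layers(self):
        assert sum(l.kind == "conv" for l in build_ours().layers) == 13

    def test_sequence_length_halves_at_each_pool(self):
        spec = build_ours()
        lengths = [s[0] for l, s in zip(spec.layers, output_shapes(spec))
                   if l.kind == "maxpool"]
        assert lengths == [96, 48, 24, 12, 6] == [192 // 2**k for k in range(1, 6)]

    def test_gap_head_is_smaller_than_fc_head(self):
        ours, fc = build_ours(), build_vgg16_fc()
        assert count_params(ours) < count_params(fc)
        # feature extractors identical; GAP head adds only the softmax layer
        assert ours.layers[:-2] == fc.layers[:-4]
        assert count_params(ours) == sum(
            3 * cin * cout + cout
            for cin, cout in zip(
                [1, 16, 16, 32, 32, 64, 64, 64, 128, 128, 128, 128, 128],
                [16, 16, 32, 32, 64, 64, 64, 128, 128, 128, 128, 128, 128],
            )
        ) + 128 * 6 + 6

    def test_simple_cnn_reconstruction(self):
        spec = build_simple_cnn()
        assert sum(l.kind == "conv" for l in spec.layers) == 3
        assert count_params(spec) > count_params(build_ours())


class TestDepthVariants:
    @pytest.mark.parametrize(
        "n,channels,pools",
        [
            (1, [16], 0),
            (3, [16, 16, 16], 1),
            (7, [16, 16, 16, 32, 32, 32, 64], 2),
            (19, [16] * 3 + [32] * 3 + [64] * 3 + [128] * 3 + [256] * 3 + [512] * 3 + [1024], 6),
        ],
    )
    def test_hand_derived_layer_lists(self, n, channels, pools):
        spec = build_depth_variant(n)
        assert [l.units for l in spec.layers if l.kind == "conv"] == channels
        assert sum(l.kind == "maxpool" for l in spec.layers) == pools
        assert [l.kind for l in spec.layers[-2:]] == ["gap", "softmax"]

    def test_channel_doubling_rule_all_depths(self):
        for n in range(1, 20):
            convs = [l.units for l in build_depth_variant(n).layers if l.kind == "conv"]
            assert convs == [16 * 2 ** (i // 3) for i in range(n)]

    @pytest.mark.parametrize("n", [0, 20, -3])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            build_depth_variant(n)


def toy_two_class(n=80, rng_seed=0):
    """Linearly separable flattened windows: constant +/-0.4 plus light noise."""
    rng = np.random.default_rng(rng_seed)
    x = rng.normal(0, 0.05, (n, 192, 1)).astype(np.float32)
    y = np.arange(n) % 2
    x += np.where(y[:, None, None] == 0, 0.4, -0.4)
    return x, y


class TestTraining:
    def test_separable_data_is_learned(self):
        x, y = toy_two_class()
        spec = build_depth_variant(1, n_classes=2)
        model = train(spec, (x, y), TrainConfig(epochs=30, seed=1))
        assert (model.predict(x) == y).mean() >= 0.99
        assert model.history[-1] < model.history[0]

    def test_identical_seeds_identical_weights(self):
        x, y = toy_two_class(40)
        spec = build_depth_variant(1, n_classes=2)
        cfg = TrainConfig(epochs=3, seed=7)
        w1 = train(spec, (x, y), cfg).net.get_weights()
        w2 = train(spec, (x, y), cfg).net.get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_probabilities_form_a_simplex(self):
        x, y = toy_two_class(40)
        model = train(build_depth_variant(1, n_classes=2), (x, y), TrainConfig(epochs=2))
        p = model.predict_proba(x)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_refuses_missing_class(self):
        x, y = toy_two_class(40)
        with pytest.raises(ValueError, match="missing class"):
            train(build_depth_variant(1), (x, y), TrainConfig(epochs=1))

    def test_spec_json_round_trip(self):
        from trampohar import ModelSpec

        spec = build("depth:4")
        assert ModelSpec.from_json(spec.to_json()) == spec

    def test_save_load_reproduces_predictions(self, tmp_path):
        from trampohar import FittedModel

        x, y = toy_two_class(40)
        model = train(build_depth_variant(1, n_classes=2), (x, y), TrainConfig(epochs=2))
        model.save(tmp_path / "m")
        back = FittedModel.load(tmp_path / "m")
        np.testing.assert_array_equal(model.predict(x), back.predict(x))


class TestRandomForest:
    def make_table(self, n=60, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        y = np.arange(n) % 2
        x = rng.normal(0, 0.3, (n, 5)) + y[:, None] * 3.0
        return x, y

    def test_separable_table_is_learned(self):
        x, y = self.make_table()
        xt, yt = self.make_table(rng_seed=9)
        forest = train_rf(x, y, seed=0, n_estimators=50)
        assert (forest.predict(xt) == yt).mean() >= 0.95

    def test_duplicated_rows_do_not_change_predictions(self):
        x, y = self.make_table()
        probe, _ = self.make_table(rng_seed=5)
        a = train_rf(x, y, seed=0, n_estimators=50).predict(probe)
        b = train_rf(np.vstack([x, x]), np.concatenate([y, y]), seed=0,
                     n_estimators=50).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        x, _ = self.make_table()
        with pytest.raises(ValueError, match="two classes"):
            train_rf(x, np.zeros(len(x), dtype=int))

    def test_nan_features_rejected_naming_columns(self):
        x, y = self.make_table()
        df = pd.DataFrame(x, columns=[f"c{i}" for i in range(5)])
        df.loc[3, "c2"] = np.nan
        df["label"] = np.where(y == 0, "ST", "TJ")
        with pytest.raises(ValueError, match="c2"):
            train_rf(df)
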