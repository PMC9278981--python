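import numpy as np
import pytest

from brightcell.classifier import (
    ClassifierConfig,
    classify_tiles,
    label_tiles,
    resize_tiles,
    train_classifier,
)
from brightcell.mser import Tile, crop_tiles
from brightcell.nn import SmallCNN, conv_stack_output_side
from brightcell.scenes import MCF7, WBC, SceneSpec, generate_scene

from conftest import disk_mask


def _tiles_by_class(n_scenes=6, seed0=500):
    """Truth-centered labeled tiles from small synthetic scenes."""
    spec = SceneSpec(
        image_size_px=(256, 256), n_mcf7=4, n_wbc=6, n_debris=0,
        interior_margin_px=18,
    )
    out = {MCF7: [], WBC: []}
    for s in range(n_scenes):
        bf, _, _, truth = generate_scene(spec.with_(seed=seed0 + s))
        for t in truth:
            got, _ = crop_tiles(bf, [t.center], 36)
            if got:
                pix = got[0].pixels
                lbl = "MCF7" if t.cell_class == MCF7 else "NON_MCF7"
                out[t.cell_class].append(Tile(pix, f"s{s}", got[0].center, lbl))
    return out


class TestArchitectureGeometry:
    @pytest.mark.parametrize(
        "side,layers,expect", [(36, 3, 1), (36, 2, 6), (15, 2, 1)]
    )
    def test_conv_stack_output_side(self, side, layers, expect):
        assert conv_stack_output_side(side, layers) == expect

    def test_incompatible_stack_raises(self):
        with pytest.raises(ValueError):
            conv_stack_output_side(15, 3)
        with pytest.raises(ValueError):
            SmallCNN(input_side=15, n_conv_layers=3)

    def test_invalid_layer_count(self):
        with pytest.raises(ValueError):
            SmallCNN(n_conv_layers=4)


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        """Backprop through conv/pool/linear agrees with numeric gradients."""
        rng = np.random.default_rng(0)
        model = SmallCNN(
            input_side=14, n_conv_layers=2, channels=(2, 3), seed=1, input_mode="raw"
        )
        x = rng.normal(size=(3, 1, 14, 14))
        y = np.array([0, 1, 0])

        def loss():
            logits = model.forward(x)
            logits = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            return -np.log(probs[np.arange(3), y]).mean(), probs

        _, probs = loss()
        d = probs.copy()
        d[np.arange(3), y] -= 1
        d /= 3
        grad = d
        for lay in reversed(model.layers):
            grad = lay.backward(grad)
            if hasattr(lay, "w") and lay is model.layers[-1]:
                grad = grad.reshape(model._last_conv_shape(x, lay))
        conv = model.layers[0]
        eps = 1e-6
        idx = [(0, 3), (1, 17)]
        for i, j in idx:
            orig = conv.w[i, j]
            conv.w[i, j] = orig + eps
            lp, _ = loss()
            conv.w[i, j] = orig - eps
            lm, _ = loss()
            conv.w[i, j] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(conv.dw[i, j], rel=1e-4, abs=1e-7)


class TestLabelTiles:
    def _tile_at(self, x, y):
        return Tile(np.zeros((36, 36), np.uint8), "img", (x, y))

    def test_label_rules_from_masks(self):
        shape = (256, 256)
        fitc = disk_mask(shape, (60, 60), 10)
        dapi = disk_mask(shape, (60, 60), 5) | disk_mask(shape, (150, 150), 5)
        tiles = label_tiles(
            [self._tile_at(60, 60), self._tile_at(150, 150), self._tile_at(220, 100)],
            fitc,
            dapi,
        )
        assert [t.label for t in tiles] == ["MCF7", "NON_MCF7", "NON_MCF7"]

    def test_signature_outside_central_region_ignored(self):
        shape = (256, 256)
        fitc = disk_mask(shape, (60 + 15, 60), 2)  # inside the tile, outside its core
        dapi = disk_mask(shape, (60, 60), 5)
        (tile,) = label_tiles([self._tile_at(60, 60)], fitc, dapi)
        assert tile.label == "NON_MCF7"

    def test_mask_mismatch_raises(self):
        with pytest.raises(ValueError):
            label_tiles([], np.zeros((64, 64), bool), np.zeros((32, 32), bool))


@pytest.fixture(scope="module")
def tile_sets():
    return _tiles_by_class()


@pytest.fixture(scope="module")
def trained(tile_sets):
    cfg = ClassifierConfig(epochs=12, seed=0)
    tiles = tile_sets[MCF7] + tile_sets[WBC]
    return train_classifier(tiles, cfg), tiles


class TestTrainClassify:
    def test_training_learns_the_two_classes(self, trained, tile_sets):
        (model, report), _ = trained
        assert report.train_accuracy >= 0.95
        assert report.epochs_run == 12

    def test_same_seed_identical_metrics(self, trained, tile_sets):
        cfg = ClassifierConfig(epochs=12, seed=0)
        tiles = tile_sets[MCF7] + tile_sets[WBC]
        (_, report1), _ = trained
        _, report2 = train_classifier(tiles, cfg)
        # wall time is informational; the learned metrics must be identical
        assert report1.train_accuracy == report2.train_accuracy
        assert report1.train_sensitivity == report2.train_sensitivity
        assert report1.train_precision == report2.train_precision

    def test_single_class_raises(self, tile_sets):
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(tile_sets[MCF7], ClassifierConfig(epochs=1))

    def test_score_vectors_are_2d_probabilities(self, trained):
        (model, _), tiles = trained
        results = classify_tiles(model, tiles[:5])
        for lbl, scores in results:
            assert scores.shape == (2,)
            assert scores.sum() == pytest.approx(1.0)
            assert lbl in ("MCF7", "NON_MCF7")

    def test_tile_size_mismatch_raises(self, trained):
        (model, _), _ = trained
        bad = [Tile(np.zeros((15, 15), np.uint8), "x", (0, 0), "MCF7")]
        with pytest.raises(ValueError):
            classify_tiles(model, bad)

    def test_save_load_round_trip(self, trained, tmp_path):
        (model, _), tiles = trained
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SmallCNN.load(path)
        a = model.predict_scores(np.stack([t.pixels for t in tiles[:8]]))
        b = loaded.predict_scores(np.stack([t.pixels for t in tiles[:8]]))
        assert np.array_equal(a, b)


class TestResizeTiles:
    def _tile(self, side=36):
        rng = np.random.default_rng(0)
        return Tile(rng.integers(0, 256, (side, side)).astype(np.uint8), "t", (50, 50))

    def test_enlarge_then_center_crop(self):
        t = self._tile()
        (out,) = resize_tiles([t], 2.0, 36)
        assert out.pixels.shape == (36, 36)

    def test_shrink_to_15(self):
        (out,) = resize_tiles([self._tile()], 0.5, 15)
        assert out.pixels.shape == (15, 15)

    def test_identity(self):
        t = self._tile()
        (out,) = resize_tiles([t], 1.0, 36)
        assert np.array_equal(out.pixels, t.pixels)

    def test_crop_larger_than_scaled_raises(self):
        with pytest.raises(ValueError):
            resize_tiles([self._tile()], 0.5, 36)

    def test_nonpositive_factor_raises(self):
        with pytest.raises(ValueError):
            resize_tiles([self._tile()], 0.0, 36)
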