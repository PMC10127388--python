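"""Tiled inference: canvas resize, partition, count aggregation, heat maps."""

import numpy as np
import pytest

from rapecount.annotations import PointAnnotationSet
from rapecount.density_loss import DensityMap
from rapecount.inference import (
    load_density_csv,
    predict_count,
    predict_count_at_scale,
    render_heatmap,
    resize_to_canvas,
    save_density_csv,
    save_density_png16,
    tile_image,
)
from rapecount.model import build_model, default_rapenet_config


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(default_rapenet_config(width_multiplier=0.1, seed=2))


class TestResize:
    def test_plot_resolution_to_canvas(self, rng):
        img = (rng.random((606, 1105, 3)) * 255).astype(np.uint8)
        out, _ = resize_to_canvas(img)
        assert out.shape == (512, 1024, 3)

    def test_canvas_input_untouched(self, rng):
        img = (rng.random((512, 1024, 3)) * 255).astype(np.uint8)
        out, _ = resize_to_canvas(img)
        np.testing.assert_array_equal(out, img)

    def test_point_count_preserved_and_rescaled(self, rng):
        img = (rng.random((606, 1105, 3)) * 255).astype(np.uint8)
        pts = PointAnnotationSet.from_array(
            "p", rng.random((40, 2)) * [1105, 606]
        )
        _, out_pts = resize_to_canvas(img, pts)
        assert out_pts.n == 40
        arr = out_pts.asarray()
        assert (arr[:, 0] <= 1024).all() and (arr[:, 1] <= 512).all()

    def test_portrait_input_auto_rotated(self, rng):
        img = (rng.random((1105, 606, 3)) * 255).astype(np.uint8)
        out, _ = resize_to_canvas(img)
        assert out.shape == (512, 1024, 3)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            resize_to_canvas(np.empty((0, 0, 3)))


class TestTiling:
    def test_canvas_yields_eight_tiles(self, rng):
        canvas = (rng.random((512, 1024, 3)) * 255).astype(np.uint8)
        ts = tile_image(canvas)
        assert len(ts) == 8
        assert sum(t.shape[0] * t.shape[1] for t, _ in ts.tiles) == 512 * 1024

    def test_partition_roundtrip_bit_exact(self, rng):
        canvas = (rng.random((512, 1024, 3)) * 255).astype(np.uint8)
        ts = tile_image(canvas)
        rebuilt = np.zeros_like(canvas)
        for patch, (x0, y0) in ts.tiles:
            rebuilt[y0:y0 + 256, x0:x0 + 256] = patch
        np.testing.assert_array_equal(rebuilt, canvas)

    def test_every_pixel_in_exactly_one_tile(self, rng):
        canvas = np.zeros((512, 1024), np.uint8)
        ts = tile_image(canvas)
        cover = np.zeros_like(canvas, dtype=int)
        for _, (x0, y0) in ts.tiles:
            cover[y0:y0 + 256, x0:x0 + 256] += 1
        assert (cover == 1).all()

    def test_indivisible_canvas_rejected(self, rng):
        with pytest.raises(ValueError):
            tile_image(np.zeros((500, 1024, 3)))


class TestPredictCount:
    def test_count_equals_sum_of_tile_counts(self, rng, tiny_model):
        img = (rng.random((512, 1024, 3)) * 255).astype(np.uint8)
        count, dm, per_tile = predict_count(img, tiny_model)
        assert len(per_tile) == 8
        assert count == pytest.approx(sum(per_tile), abs=1e-9)
        assert count == pytest.approx(dm.count(), abs=1e-9)

    def test_assembly_conserves_count_over_random_models(self, rng):
        # 20 random (model, input) pairs: assembled-map sum == sum of tiles
        for seed in range(5):
            model = build_model(
                default_rapenet_config(width_multiplier=0.1, seed=seed)
            )
            for _ in range(4):
                img = (rng.random((256, 512, 3)) * 255).astype(np.uint8)
                count, dm, per_tile = predict_count(img, model)
                assert len(per_tile) == 2
                assert count == pytest.approx(sum(per_tile), abs=1e-9)
                assert count == pytest.approx(dm.count(), abs=1e-9)

    def test_single_tile_path_equals_direct_forward(self, rng, tiny_model):
        img = (rng.random((128, 128, 3)) * 255).astype(np.uint8)
        count, dm, per_tile = predict_count(img, tiny_model)
        x = (img.astype(np.float32) / 255).transpose(2, 0, 1)
        direct = tiny_model.predict(x)
        assert len(per_tile) == 1
        np.testing.assert_allclose(dm.values, direct.values, atol=1e-9)

    def test_scale_one_equals_native_prediction(self, rng, tiny_model):
        img = (rng.random((128, 128, 3)) * 255).astype(np.uint8)
        native, _, _ = predict_count(img, tiny_model)
        scaled, _, _ = predict_count_at_scale(img, tiny_model, 1.0)
        assert scaled == pytest.approx(native, abs=1e-9)

    def test_rescale_agrees_between_uint8_and_unit_float_images(
        self, rng, tiny_model
    ):
        # float images in [0, 1] must not be truncated during resampling
        img8 = (rng.random((128, 128, 3)) * 255).astype(np.uint8)
        imgf = img8.astype(np.float32) / 255.0
        c8, _, _ = predict_count_at_scale(img8, tiny_model, 0.8)
        cf, _, _ = predict_count_at_scale(imgf, tiny_model, 0.8)
        assert cf == pytest.approx(c8, rel=1e-4)
        assert c8 > 0

    def test_zeroed_head_gives_zero_count(self, rng):
        model = build_model(default_rapenet_config(width_multiplier=0.1, seed=0))
        for p in model.head.params():
            p.value[...] = 0.0
        img = (rng.random((128, 128, 3)) * 255).astype(np.uint8)
        count, _, _ = predict_count(img, model)
        assert count == 0.0


class TestHeatmapAndExport:
    def test_zero_density_leaves_image_unchanged(self, rng):
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        dm = DensityMap(np.zeros((8, 8)), stride=8)
        out = render_heatmap(img, dm, alpha=0.9)
        np.testing.assert_array_equal(out, img)

    def test_output_shape_matches_input(self, rng):
        img = (rng.random((48, 80, 3)) * 255).astype(np.uint8)
        dm = DensityMap(rng.random((6, 10)), stride=8)
        assert render_heatmap(img, dm, 0.5).shape == img.shape

    def test_density_argmax_is_most_altered_pixel(self, rng):
        img = np.full((32, 32, 3), 120, np.uint8)
        values = np.zeros((4, 4))
        values[1, 2] = 5.0
        out = render_heatmap(img, DensityMap(values, stride=8), alpha=1.0)
        delta = np.abs(out.astype(int) - 120).sum(axis=2)
        hot = np.unravel_index(np.argmax(delta), delta.shape)
        assert abs(hot[0] - (1 * 8 + 4)) <= 4 and abs(hot[1] - (2 * 8 + 4)) <= 4

    def test_alpha_out_of_range_rejected(self, rng):
        dm = DensityMap(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            render_heatmap(np.zeros((32, 32, 3), np.uint8), dm, alpha=1.2)

    def test_density_csv_roundtrip(self, tmp_path, rng):
        dm = DensityMap(rng.random((6, 10)), stride=8)
        path = tmp_path / "d.csv"
        save_density_csv(dm, path)
        back = load_density_csv(path)
        assert back.stride == 8
        np.testing.assert_allclose(back.values, dm.values, rtol=1e-12)

    def test_density_png16_scale(self, tmp_path, rng):
        from PIL import Image

        dm = DensityMap(rng.random((6, 10)) * 3, stride=8)
        path = tmp_path / "d.png"
        scale = save_density_png16(dm, path)
        img = np.asarray(Image.open(path)).astype(float)
        np.testing.assert_allclose(img / scale, dm.values, atol=1.0 / scale)
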