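"""Synthetic scene generator: shape synthesis, rendering, ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from sampdetect import detect, measure, simulate
from sampdetect.classify import rough_classify


def independent_circularity(mask: np.ndarray) -> float:
    """4*pi*A/P^2 computed directly from the traced boundary polygon."""
    from skimage.measure import find_contours
    area = mask.sum()
    contour = max(find_contours(np.pad(mask, 1).astype(float), 0.5), key=len)
    seg = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    perim = np.hypot(seg[:, 0], seg[:, 1]).sum()
    return 4 * np.pi * area / perim ** 2


class TestGrainMask:
    def test_circular_target_yields_disk(self):
        mask = simulate.make_grain_mask(360, 1.0, 1.0, 18.0, seed=3)
        st = measure.shape_stats(mask)
        assert st.size_um == pytest.approx(360, rel=0.15)
        assert st.aspect_ratio == pytest.approx(1.0, abs=0.5)
        assert st.circularity > 0.8

    def test_polypropylene_row_statistics(self):
        # irregular elongated blob at the PP #1 targets
        mask = simulate.make_grain_mask(292.8, 0.62, 2.26, 18.0, seed=1)
        st = measure.shape_stats(mask)
        assert st.size_um == pytest.approx(292.8, rel=0.15)
        assert st.circularity == pytest.approx(0.62, abs=0.15)
        assert st.aspect_ratio == pytest.approx(2.26, abs=0.5)

    def test_masks_connected_and_circularity_valid(self, rng):
        for _ in range(25):
            size = rng.uniform(150, 450)
            circ = rng.uniform(0.45, 0.9)
            asp = rng.uniform(1.0, 3.0)
            try:
                mask = simulate.make_grain_mask(size, circ, asp, 18.0,
                                                seed=int(rng.integers(2**31)))
            except simulate.ShapeSynthesisError:
                continue
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n == 1
            assert independent_circularity(mask) <= 1.15

    def test_unreachable_target_reports_closest(self):
        # a perfect circle at aspect 3 is geometrically impossible
        with pytest.raises(simulate.ShapeSynthesisError) as exc:
            simulate.make_grain_mask(360, 1.0, 3.0, 18.0, seed=0, max_tries=5)
        assert exc.value.achieved is not None

    def test_too_small_size_rejected(self):
        with pytest.raises(ValueError):
            simulate.make_grain_mask(20, 0.6, 1.5, 18.0)


class TestFiberMask:
    def test_straight_fiber_is_bar(self):
        mask = simulate.make_fiber_mask(540, 2, 0.0, 18.0, seed=0)
        st = measure.shape_stats(mask)
        assert mask.shape[0] == 2
        assert st.feret_max_px == pytest.approx(30, abs=1.0)
        assert st.aspect_ratio == pytest.approx(15, rel=0.1)

    def test_high_curvature_shortens_feret(self):
        mask = simulate.make_fiber_mask(540, 2, 0.5, 18.0, seed=5)
        st = measure.shape_stats(mask)
        assert st.feret_max_px < 30 * 0.9

    def test_sampled_fibers_rough_classify_as_fiber(self, rng):
        cfg = simulate.SceneConfig.artificial_mp()
        for _ in range(20):
            mask = simulate.sample_fiber_mask(cfg, rng)
            st = measure.shape_stats(mask)
            assert rough_classify(st) == "fiber"

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            simulate.make_fiber_mask(54, 2, 0.0, 18.0)


class TestRenderVideo:
    def test_empty_scene_constant_background_no_candidates(self):
        cfg = simulate.SceneConfig(n_grains=0, n_fibers=0,
                                   background_noise_sd=0.0, n_frames=5,
                                   frame_width_px=160, frame_height_px=120)
        frames, log = simulate.render_video(cfg)
        assert np.ptp(frames) == 0
        win = log.window
        for t in range(len(frames)):
            assert detect.detect_frame(frames[t], win, frame_index=t) == []

    def test_pure_advection_trajectory(self):
        cfg = simulate.SceneConfig(n_grains=1, n_fibers=0,
                                   background_noise_sd=0.0,
                                   pulsation_duty=1.0, n_frames=20,
                                   flow_velocity_px_per_frame=8.0, seed=2)
        _, log = simulate.render_video(cfg)
        xs = log.particles[0].trajectory[:, 0]
        assert np.allclose(np.diff(xs), 8.0)

    def test_determinism(self):
        cfg = simulate.SceneConfig(n_grains=2, n_fibers=1, n_frames=12,
                                   frame_width_px=200, frame_height_px=150,
                                   seed=9)
        f1, l1 = simulate.render_video(cfg)
        f2, l2 = simulate.render_video(cfg)
        assert np.array_equal(f1, f2)
        for a, b in zip(l1.particles, l2.particles):
            assert np.array_equal(a.trajectory, b.trajectory)
            assert a.true_size_um == b.true_size_um

    def test_window_wider_than_frame_rejected(self):
        cfg = simulate.SceneConfig(window=(0, 0, 1000, 100))
        with pytest.raises(ValueError):
            simulate.render_video(cfg)

    def test_pulsation_pauses_hold_position(self):
        cfg = simulate.SceneConfig(n_grains=1, n_fibers=0, n_frames=20,
                                   pulsation_period_frames=4,
                                   pulsation_duty=0.5,
                                   background_noise_sd=0.0, seed=2)
        _, log = simulate.render_video(cfg)
        dx = np.diff(log.particles[0].trajectory[:, 0])
        assert set(np.round(dx, 6)) == {0.0, 8.0}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate.SceneConfig(pulsation_duty=0.0)
        with pytest.raises(ValueError):
            simulate.SceneConfig(flow_velocity_px_per_frame=-1)


class TestCalibrationRecovery:
    def test_nojima_population_recovered(self):
        """Generating grains from the natural-sediment parameters and
        measuring them back recovers the configured mean size and
        circularity (measured at 6 um/px: fine enough that rasterisation
        does not erase sub-pixel shape detail)."""
        scale = 6.0
        cfg = simulate.SceneConfig(pixel_scale_um=scale)
        rng = np.random.default_rng(0)
        sizes, circs = [], []
        for _ in range(200):
            mask = simulate.sample_grain_mask(cfg, rng)
            st = measure.shape_stats(mask, scale)
            sizes.append(st.size_um)
            circs.append(st.circularity)
        assert np.mean(sizes) == pytest.approx(152.9, rel=0.10)
        assert np.mean(circs) == pytest.approx(0.42, abs=0.10)


class TestCropDataset:
    def test_shapes_labels_and_determinism(self):
        crops, labels = simulate.make_crop_dataset(4, 3, seed=5)
        assert crops.shape == (7, 100, 100)
        assert list(labels) == ["grain"] * 4 + ["fiber"] * 3
        crops2, _ = simulate.make_crop_dataset(4, 3, seed=5)
        assert np.array_equal(crops, crops2)
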