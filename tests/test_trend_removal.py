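"""Trend decomposition, object removal, threshold search and metrics."""

import numpy as np
import pytest

from presscope import (
    PressureFrame,
    SGFilterSpec,
    default_scene_spec,
    extract_lines,
    generate_scene,
    grid_search_threshold,
    mask_energy_fraction,
    psnr,
    remove_external_objects,
    rmse,
)
from presscope.trend import assemble_lines, deviation_grid


class TestExtractLines:
    def test_columns_mode_shapes(self, supine_scene):
        frame, _ = supine_scene
        lines = extract_lines(frame, "columns")
        assert len(lines) == 32
        assert all(len(l) == 64 for l in lines)

    def test_unfolded_mode_single_signal(self, supine_scene):
        frame, _ = supine_scene
        (line,) = extract_lines(frame, "unfolded")
        assert line.shape == (2048,)

    def test_reassembly_is_exact_inverse(self, supine_scene):
        frame, _ = supine_scene
        for axis in ("columns", "unfolded"):
            lines = extract_lines(frame, axis)
            np.testing.assert_array_equal(
                assemble_lines(lines, frame.shape, axis), frame.values
            )


class TestRemoveExternalObjects:
    def test_zero_frame_yields_zero_body_and_empty_mask(self):
        res = remove_external_objects(PressureFrame(np.zeros((64, 32))), th=5.0)
        assert res.body_frame.values.sum() == 0.0
        assert not res.retained_mask.any()

    def test_body_frame_is_raw_on_mask_zero_elsewhere(self, cushion_scene):
        frame, _ = cushion_scene
        res = remove_external_objects(frame)
        np.testing.assert_array_equal(
            res.body_frame.values[res.retained_mask],
            frame.values[res.retained_mask],
        )
        assert (res.body_frame.values[~res.retained_mask] == 0).all()
        assert (res.body_frame.values <= frame.values).all()

    def test_suppressed_plus_body_reconstructs_raw(self, cushion_scene):
        frame, _ = cushion_scene
        res = remove_external_objects(frame)
        np.testing.assert_array_equal(
            res.body_frame.values + res.suppressed_frame.values, frame.values
        )

    def test_mask_monotone_in_threshold(self, cushion_scene):
        frame, _ = cushion_scene
        masks = [
            remove_external_objects(frame, th=th).retained_mask
            for th in (2.0, 8.0, 14.0)
        ]
        assert (masks[1] <= masks[0]).all()
        assert (masks[2] <= masks[1]).all()

    def test_reapplication_never_reintroduces_signal(self, cushion_scene):
        """Cleaning its own output changes nothing on the retained support:
        values agree where both passes retain, and the nonzero support can
        only shrink (zeroed sensels stay zero)."""
        frame, _ = cushion_scene
        first = remove_external_objects(frame, th=12.0)
        second = remove_external_objects(first.body_frame, th=12.0)
        assert (second.body_frame.values <= first.body_frame.values).all()
        support1 = first.body_frame.values > 0
        support2 = second.body_frame.values > 0
        assert (support2 <= support1).all()
        both = first.retained_mask & second.retained_mask
        np.testing.assert_array_equal(
            second.body_frame.values[both], first.body_frame.values[both]
        )

    def test_negative_threshold_rejected(self, supine_scene):
        with pytest.raises(ValueError):
            remove_external_objects(supine_scene[0], th=-1.0)

    def test_window_longer_than_line_rejected(self, supine_scene):
        with pytest.raises(ValueError, match="shorter"):
            remove_external_objects(supine_scene[0], spec=SGFilterSpec(2, 40))

    def test_cushion_suppressed_body_retained(self, cushion_scene):
        frame, truth = cushion_scene
        res = remove_external_objects(frame)
        assert mask_energy_fraction(frame, res.body_frame, truth.body_mask) > 0.85
        assert (
            mask_energy_fraction(frame, res.body_frame, truth.object_only_mask)
            < 0.15
        )


class TestGridSearch:
    def test_single_element_grid_returned(self, cushion_scene):
        assert grid_search_threshold([cushion_scene], th_grid=[7.5]) == 7.5

    def test_perfect_recovery_value_selected(self):
        """A scene whose deviation field separates body and background at a
        known level must select the grid value achieving perfect recovery."""
        v = np.zeros((64, 32))
        v[20:30, 10:20] = 100.0
        frame = PressureFrame(v)
        _, _, dev = deviation_grid(frame)

        class Truth:
            body_mask = None

        truth = Truth()
        # the ideal threshold: masks at it equal the body mask exactly
        for th in (10.0,):
            truth.body_mask = dev > th
        got = grid_search_threshold([(frame, truth)], th_grid=[2.0, 10.0, 30.0])
        assert got == 10.0

    def test_matches_brute_force_f1_argmax(self):
        scenes = [
            generate_scene(default_scene_spec("supine", with_object=True, seed=s))
            for s in range(5)
        ]
        grid = np.arange(0.0, 31.0, 2.0)
        got = grid_search_threshold(scenes, th_grid=grid)

        def f1(mask, ref):
            tp = (mask & ref).sum()
            fp = (mask & ~ref).sum()
            fn = (~mask & ref).sum()
            return 2 * tp / (2 * tp + fp + fn)

        curves = []
        for th in grid:
            scores = []
            for frame, truth in scenes:
                _, _, dev = deviation_grid(frame)
                scores.append(f1(dev > th, truth.body_mask))
            curves.append(np.mean(scores))
        assert got == grid[int(np.argmax(curves))]

    def test_empty_grid_rejected(self, cushion_scene):
        with pytest.raises(ValueError, match="non-empty"):
            grid_search_threshold([cushion_scene], th_grid=[])

    def test_no_scenes_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            grid_search_threshold([])


class TestMetrics:
    def test_rmse_identical_frames_zero(self, supine_scene):
        frame, _ = supine_scene
        assert rmse(frame, frame) == 0.0

    def test_rmse_constant_offset_normalized(self):
        a = PressureFrame(np.full((8, 8), 500.0))
        b = PressureFrame(np.full((8, 8), 400.0))
        assert rmse(a, b, normalize=True) == pytest.approx(0.1)

    def test_rmse_matches_elementwise_recomputation(self, rng):
        a = PressureFrame(rng.uniform(0, 1000, (16, 8)))
        b = PressureFrame(rng.uniform(0, 1000, (16, 8)))
        brute = np.sqrt(((a.values - b.values) ** 2).mean())
        assert rmse(a, b) == pytest.approx(brute, abs=1e-12)

    def test_rmse_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            rmse(PressureFrame(np.zeros((4, 4))), PressureFrame(np.zeros((4, 5))))

    def test_psnr_peak1_rmse_point1_is_20db(self):
        ref = np.zeros((10, 10))
        ref[0, 0] = 1000.0  # normalized peak 1.0
        est = ref + 100.0  # normalized rmse 0.1
        est[0, 0] = 1000.0
        est_rmse = np.sqrt((((ref - est) / 1000.0) ** 2).mean())
        got = psnr(PressureFrame(ref), PressureFrame(np.clip(est, 0, 1000)))
        assert got == pytest.approx(20 * np.log10(1.0 / est_rmse))

    def test_psnr_identical_frames_infinite(self, supine_scene):
        frame, _ = supine_scene
        assert psnr(frame, frame) == np.inf

    def test_psnr_convention_consistent_with_printed_pairing(self):
        """Closed form: peak 0.655 with rmse 0.102 gives 16.15 dB."""
        assert 20 * np.log10(0.655 / 0.102) == pytest.approx(16.15, abs=0.01)
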