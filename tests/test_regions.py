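"""Gradient-field maxima, region growing, labelling and tracking."""

import numpy as np
import pytest

from presscope import (
    Landmark,
    PressureFrame,
    RegionParams,
    SceneSpec,
    default_scene_spec,
    detect_regions,
    filter_regions,
    find_maxima,
    generate_scene,
    generate_sequence,
    gradient_field,
    grow_regions,
    label_regions,
    track_regions,
)
from presscope.regions import tracks_to_table

SUPINE_LABELS = {
    "head",
    "left_shoulder",
    "right_shoulder",
    "sacrum",
    "left_foot",
    "right_foot",
}


def blob(grid, row, col, peak=60.0, sigma=3.0):
    r = np.arange(grid[0])[:, None]
    c = np.arange(grid[1])[None, :]
    return peak * np.exp(-((r - row) ** 2 + (c - col) ** 2) / (2 * sigma**2))


class TestGradientField:
    def test_linear_ramp_has_constant_gradient(self):
        c = np.tile(np.arange(32.0) * 2, (64, 1))
        gf = gradient_field(PressureFrame(c))
        np.testing.assert_allclose(gf.d_col[:, 1:-1], 2.0)
        np.testing.assert_allclose(gf.d_row, 0.0)

    def test_constant_frame_zero_gradient(self):
        gf = gradient_field(PressureFrame(np.full((10, 10), 5.0)))
        assert np.all(gf.d_row == 0) and np.all(gf.d_col == 0)

    def test_gradient_vanishes_at_blob_peak(self, blob_frame):
        gf = gradient_field(blob_frame)
        assert abs(gf.d_row[20, 16]) < 1e-6
        assert abs(gf.d_col[20, 16]) < 1e-6

    def test_tiny_frame_rejected(self):
        with pytest.raises(ValueError):
            gradient_field(PressureFrame(np.zeros((2, 5))))


class TestFindMaxima:
    def test_single_blob_yields_single_peak(self, blob_frame):
        maxima = find_maxima(gradient_field(blob_frame), blob_frame, 20.0)
        assert maxima == [(20, 16)]

    def test_exhaustive_neighborhood_oracle_agrees(self, blob_frame):
        """Every reported maximum must beat its 8-neighbourhood in value."""
        v = blob_frame.values
        for r, c in find_maxima(gradient_field(blob_frame), blob_frame, 10.0):
            patch = v[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            assert v[r, c] == patch.max()

    def test_constant_frame_has_no_maxima(self):
        frame = PressureFrame(np.full((20, 20), 50.0))
        assert find_maxima(gradient_field(frame), frame, 10.0) == []

    def test_supine_phantom_recovers_six_landmarks(self):
        frame, truth = generate_scene(default_scene_spec("supine", seed=5))
        from presscope.enhance import enhance_chain

        sm = enhance_chain(frame)
        maxima = find_maxima(gradient_field(sm), sm, 20.0)
        assert len(maxima) == 6
        for lm in truth.landmarks:
            d = min(
                np.hypot(r - lm.row, c - lm.col) for r, c in maxima
            )
            assert d <= 2.0

    def test_min_height_filters_low_peaks(self, blob_frame):
        assert find_maxima(gradient_field(blob_frame), blob_frame, 80.0) == []


class TestGrowRegions:
    def test_half_max_disc_area_matches_analytic_value(self):
        """rel_level 0.5 on an isotropic Gaussian: area = 2 pi ln(2) sigma^2."""
        sigma = 3.0
        frame = PressureFrame(blob((64, 32), 30, 16, 80.0, sigma))
        (reg,) = grow_regions(frame, [(30, 16)], rel_level=0.5)
        analytic = 2 * np.pi * np.log(2) * sigma**2
        assert abs(reg.area - analytic) / analytic < 0.2

    def test_two_far_blobs_stay_disjoint(self):
        v = blob((64, 32), 10, 8) + blob((64, 32), 50, 24)
        frame = PressureFrame(v)
        regs = grow_regions(frame, [(10, 8), (50, 24)], 0.5)
        assert len(regs) == 2
        assert not (regs[0].mask & regs[1].mask).any()

    def test_regions_shrink_toward_seed_as_level_rises(self, blob_frame):
        areas = [
            grow_regions(blob_frame, [(20, 16)], lvl)[0].area
            for lvl in (0.3, 0.6, 0.9)
        ]
        assert areas[0] > areas[1] > areas[2] >= 1

    def test_overlapping_regions_merge_with_pooled_seeds(self):
        v = blob((64, 32), 20, 14, 60, 4) + blob((64, 32), 20, 18, 60, 4)
        frame = PressureFrame(np.clip(v, 0, 1000))
        regs = grow_regions(frame, [(20, 14), (20, 18)], 0.3)
        assert len(regs) == 1

    def test_seed_outside_grid_rejected(self, blob_frame):
        with pytest.raises(ValueError, match="outside"):
            grow_regions(blob_frame, [(99, 0)], 0.5)

    def test_mean_pressure_is_raw_mean_over_pixels(self, blob_frame):
        noisy = PressureFrame(np.clip(blob_frame.values + 3.0, 0, 1000))
        (reg,) = grow_regions(blob_frame, [(20, 16)], 0.5, value_frame=noisy)
        assert reg.mean_pressure == pytest.approx(
            noisy.values[reg.mask].mean(), abs=1e-12
        )


class TestFilterRegions:
    def test_two_sensel_region_removed(self):
        mask = np.zeros((64, 32), bool)
        mask[10, 10:12] = True
        reg = grow_regions(
            PressureFrame(mask * 50.0), [(10, 10)], 0.5
        )
        assert filter_regions(reg, min_area=4) == []

    def test_large_well_placed_regions_unchanged_in_count(self):
        frame, _ = generate_scene(default_scene_spec("supine", seed=6))
        regs = detect_regions(frame, "supine")
        assert len(filter_regions(regs, min_area=4, posture="supine")) == len(regs)

    def test_hand_decoys_removed_landmarks_kept(self):
        """Small mid-lateral 'hand' blobs are eliminated by opening +
        plausibility bands while the six landmarks survive."""
        spec = default_scene_spec("supine", seed=8)
        spec.support = [
            Landmark("left_hand", 0.48 * 64, 4.0, 40.0, 1.0),
            Landmark("right_hand", 0.48 * 64, 28.0, 40.0, 1.0),
        ]
        frame, truth = generate_scene(spec)
        regs = detect_regions(frame, "supine")
        labels = {r.label for r in regs if r.label != "unlabelled"}
        assert labels == SUPINE_LABELS
        for r in regs:
            # nothing labelled may sit at the decoy positions
            assert not (abs(r.centroid[0] - 30.7) < 2 and r.centroid[1] < 8)


class TestLabelRegions:
    def test_supine_phantom_fully_labelled(self):
        frame, truth = generate_scene(default_scene_spec("supine", seed=3))
        regs = detect_regions(frame, "supine")
        got = {r.label: r.centroid for r in regs if r.label != "unlabelled"}
        assert set(got) == SUPINE_LABELS
        for lm in truth.landmarks:
            r, c = got[lm.name]
            assert np.hypot(r - lm.row, c - lm.col) <= 2.0

    def test_right_lateral_template(self):
        frame, truth = generate_scene(default_scene_spec("right_lateral", seed=3))
        regs = detect_regions(frame, "right_lateral")
        labels = {r.label for r in regs if r.label != "unlabelled"}
        assert labels == {"head", "right_shoulder", "sacrum", "right_foot"}

    def test_single_region_becomes_head(self, blob_frame):
        regs = grow_regions(blob_frame, [(20, 16)], 0.5)
        out = label_regions(regs, "supine")
        assert [r.label for r in out] == ["head"]

    def test_empty_input_gives_empty_output(self):
        assert label_regions([], "supine") == []

    def test_labels_mutually_exclusive_masks(self):
        frame, _ = generate_scene(default_scene_spec("supine", seed=11))
        regs = detect_regions(frame, "supine")
        total = np.zeros(frame.shape, int)
        for r in regs:
            total += r.mask.astype(int)
        assert total.max() <= 1

    def test_detection_equivariant_under_translation(self):
        """Translating the phantom translates the detected centroids
        (checked before posture-band filtering, which is deliberately
        position-dependent)."""
        from presscope.enhance import enhance_chain

        base = np.clip(
            blob((64, 32), 20, 14, 70, 3) + blob((64, 32), 40, 14, 60, 3), 0, 1000
        )
        shifted = np.roll(np.roll(base, 4, axis=0), 3, axis=1)
        cents = []
        for v in (base, shifted):
            sm = enhance_chain(PressureFrame(v))
            maxima = find_maxima(gradient_field(sm), sm, 15.0)
            regs = grow_regions(sm, maxima, 0.65)
            cents.append(sorted(r.centroid for r in regs))
        assert len(cents[0]) == len(cents[1]) == 2
        for (r1, c1), (r2, c2) in zip(*cents):
            assert abs(r2 - r1 - 4) <= 1 and abs(c2 - c1 - 3) <= 1


class TestTracking:
    def test_single_frame_sequence_gives_length_one_tracks(self):
        seq, _ = generate_sequence(default_scene_spec("supine", seed=2), 1)
        tracks = track_regions(seq, "supine")
        assert {t.label for t in tracks} == SUPINE_LABELS
        assert all(len(t) == 1 for t in tracks)

    def test_static_phantom_tracks_are_gap_free(self):
        seq, truth = generate_sequence(default_scene_spec("supine", seed=21), 30)
        tracks = track_regions(seq, "supine")
        assert {t.label for t in tracks} == SUPINE_LABELS
        assert all(len(t.gaps) == 0 and len(t) == 30 for t in tracks)

    def test_ablated_landmark_shows_gaps_over_second_half(self):
        spec = default_scene_spec("supine", seed=4, noise_sd=0.0)
        first, _ = generate_sequence(spec, 5)
        import dataclasses

        ablated_spec = dataclasses.replace(
            spec, landmarks=[l for l in spec.landmarks if l.name != "left_foot"]
        )
        second, _ = generate_sequence(ablated_spec, 5)
        from presscope.frames import sequence_from_arrays

        frames = [f.values for f in first] + [f.values for f in second]
        seq = sequence_from_arrays(frames)
        tracks = {t.label: t for t in track_regions(seq, "supine")}
        lf = tracks["left_foot"]
        assert lf.gaps == [5.0, 6.0, 7.0, 8.0, 9.0]
        assert len(lf) == 5

    def test_tracks_table_layout(self):
        seq, _ = generate_sequence(default_scene_spec("supine", seed=2), 3)
        df = tracks_to_table(track_regions(seq, "supine"))
        assert list(df.columns) == [
            "timestamp_s",
            "label",
            "mean_pressure_mmHg",
            "centroid_row",
            "centroid_col",
        ]
        assert len(df) == 18
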