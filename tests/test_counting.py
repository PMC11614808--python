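import numpy as np
import pytest

import _oracles as oracle
from conftest import full_frame_roi, noiseless
from retinaquant.counting import (
    SegmentationParams,
    binarize_multi_otsu,
    binarize_otsu,
    colocalize,
    combine_masks,
    count_coloc,
    count_single_marker,
    filter_small,
    preprocess,
    score_cells,
    scored_count_record,
    segment_channel,
    threshold_local,
    threshold_multi_otsu,
    threshold_otsu,
)
from retinaquant.errors import (
    DegenerateInputError,
    DimensionError,
    ParameterError,
)
from retinaquant.imaging import ImageStack, RegionOfInterest
from retinaquant.synthetic import SceneConfig, generate_section

IDENTITY = SegmentationParams(
    unsharp_amount=0.0, gaussian_sigma_px=0.0, edge_mode="off"
)


class TestSegmentationParams:
    def test_empty_methods_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationParams(threshold_methods=())

    def test_even_block_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationParams(local_block_px=10)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationParams(min_area_px=-1)

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationParams(threshold_methods=("otsu", "magic"))


class TestPreprocess:
    def test_zero_plane_stays_zero(self):
        params = SegmentationParams(
            unsharp_radius_px=2, unsharp_amount=1.5, gaussian_sigma_px=1.0
        )
        out = preprocess(np.zeros((16, 16)), params)
        np.testing.assert_array_equal(out, 0)

    def test_identity_params(self, rng):
        plane = rng.random((12, 18)) * 100
        out = preprocess(plane, IDENTITY)
        np.testing.assert_array_equal(out, plane)

    def test_impulse_matches_kernel_convolution(self):
        plane = np.zeros((21, 21))
        plane[10, 10] = 1.0
        params = SegmentationParams(gaussian_sigma_px=2.0)
        out = preprocess(plane, params)
        expected = oracle.gaussian_kernel_convolve(plane, 2.0)
        # both clipped to input range [0, 1]
        np.testing.assert_allclose(out, np.clip(expected, 0, 1), atol=1e-6)

    def test_output_clipped_to_input_range(self, rng):
        plane = rng.random((16, 16))
        params = SegmentationParams(unsharp_radius_px=1.5, unsharp_amount=3.0)
        out = preprocess(plane, params)
        assert out.min() >= plane.min() and out.max() <= plane.max()

    def test_negative_sigma_raises(self):
        with pytest.raises(ParameterError):
            SegmentationParams(gaussian_sigma_px=-1)

    def test_nonfinite_rejected(self):
        plane = np.full((4, 4), np.nan)
        with pytest.raises(ParameterError):
            preprocess(plane, IDENTITY)


class TestOtsu:
    def test_bimodal_separates_classes(self):
        plane = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
        t = threshold_otsu(plane)
        assert 10 < t <= 200
        mask = binarize_otsu(plane)
        assert mask.sum() == 50

    def test_matches_bruteforce_8bit(self, rng):
        plane = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        t_ref, mask_ref = oracle.otsu_bruteforce(plane)
        assert threshold_otsu(plane) == pytest.approx(t_ref)
        np.testing.assert_array_equal(binarize_otsu(plane), mask_ref)

    def test_constant_plane_raises(self):
        with pytest.raises(DegenerateInputError):
            threshold_otsu(np.full((8, 8), 3.0))


class TestMultiOtsu:
    def test_two_classes_reproduces_otsu_partition(self, rng):
        plane = rng.integers(0, 256, size=(24, 24)).astype(float)
        np.testing.assert_array_equal(
            binarize_multi_otsu(plane, classes=2), binarize_otsu(plane)
        )

    def test_three_level_plane(self):
        plane = np.repeat([0.0, 100.0, 250.0], 40).reshape(12, 10)
        ts = threshold_multi_otsu(plane, classes=3)
        assert len(ts) == 2
        assert 0 < ts[0] <= 100 < ts[1] <= 250
        mask = binarize_multi_otsu(plane, classes=3)
        assert mask.sum() == 40  # only the 250-level third

    def test_matches_bruteforce_32_bins(self, rng):
        plane = rng.integers(0, 200, size=(20, 20)).astype(float)
        np.testing.assert_array_equal(
            binarize_multi_otsu(plane, classes=3, n_bins=32),
            oracle.multi_otsu_bruteforce(plane, classes=3, n_bins=32),
        )

    def test_too_few_levels_raises(self):
        plane = np.repeat([0.0, 9.0], 8).reshape(4, 4)
        with pytest.raises(DegenerateInputError):
            threshold_multi_otsu(plane, classes=3)


class TestLocalThreshold:
    def test_constant_plane_offsets(self):
        plane = np.full((9, 9), 5.0)
        assert not threshold_local(plane, 3, offset=0.5).any()
        assert threshold_local(plane, 3, offset=-0.5).all()

    def test_single_bright_pixel_matches_naive(self):
        plane = np.zeros((9, 9))
        plane[4, 4] = 10.0
        np.testing.assert_array_equal(
            threshold_local(plane, 3, 0.0), oracle.local_threshold_naive(plane, 3, 0.0)
        )

    def test_random_matches_naive(self, rng):
        plane = rng.random((16, 16))
        np.testing.assert_array_equal(
            threshold_local(plane, 5, 0.1), oracle.local_threshold_naive(plane, 5, 0.1)
        )

    def test_even_block_raises(self):
        with pytest.raises(ParameterError):
            threshold_local(np.zeros((8, 8)), 4)

    def test_oversized_block_raises(self):
        with pytest.raises(ParameterError):
            threshold_local(np.zeros((8, 8)), 9)


class TestCombineMasks:
    def test_identical_masks_any_rule(self, rng):
        m = rng.random((8, 8)) > 0.5
        for rule in ("majority", "intersection", "union"):
            np.testing.assert_array_equal(combine_masks([m, m, m], rule), m)

    def test_a_not_a_full_majority(self, rng):
        a = rng.random((8, 8)) > 0.5
        full = np.ones((8, 8), dtype=bool)
        np.testing.assert_array_equal(combine_masks([a, ~a, full], "majority"), full)

    def test_majority_matches_pixel_vote(self, rng):
        masks = [rng.random((10, 10)) > 0.5 for _ in range(3)]
        np.testing.assert_array_equal(
            combine_masks(masks, "majority"), oracle.majority_vote_naive(masks)
        )

    def test_single_mask_identity_under_any_rule(self, rng):
        m = rng.random((6, 6)) > 0.3
        for rule in ("majority", "intersection", "union"):
            np.testing.assert_array_equal(combine_masks([m], rule), m)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            combine_masks([np.zeros((4, 4), bool), np.zeros((5, 5), bool)])

    def test_empty_list(self):
        with pytest.raises(ParameterError):
            combine_masks([])


class TestFilterSmall:
    def test_artifact_exclusion_15px(self):
        # one 10-px and one 20-px blob; the 10-px one is an artifact
        mask = np.zeros((20, 40), dtype=bool)
        mask[2:4, 2:7] = True  # 10 px
        mask[10:14, 10:15] = True  # 20 px
        filtered, objects = filter_small(mask, 15)
        assert len(objects) == 1
        assert objects.objects[0].area_px == 20

    def test_min_area_zero_keeps_all(self, rng):
        mask = rng.random((16, 16)) > 0.7
        filtered, objects = filter_small(mask, 0)
        np.testing.assert_array_equal(filtered, mask)

    def test_diagonal_chain_is_one_object(self):
        mask = np.zeros((20, 20), dtype=bool)
        for i in range(16):
            mask[i, i] = True  # 8-connected diagonal chain
        filtered, objects = filter_small(mask, 15)
        assert len(objects) == 1
        assert objects.objects[0].area_px == 16
        assert filtered.sum() == 16

    def test_matches_naive_bfs(self, rng):
        mask = rng.random((24, 24)) > 0.6
        for min_area in (0, 3, 15):
            filtered, objects = filter_small(mask, min_area)
            ref_mask, ref_n = oracle.filter_small_naive(mask, min_area)
            np.testing.assert_array_equal(filtered, ref_mask)
            assert len(objects) == ref_n

    def test_survivors_meet_min_area(self, rng):
        mask = rng.random((32, 32)) > 0.6
        _, objects = filter_small(mask, 10)
        assert all(o.area_px >= 10 for o in objects.objects)


class TestColocalize:
    def test_and_with_full_and_empty(self, rng):
        a = rng.random((8, 8)) > 0.5
        np.testing.assert_array_equal(colocalize(a, np.ones_like(a)), a)
        assert not colocalize(a, np.zeros_like(a)).any()

    def test_idempotent(self, rng):
        a = rng.random((8, 8)) > 0.5
        np.testing.assert_array_equal(colocalize(a, a), a)

    def test_matches_coordinate_sets(self, rng):
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        np.testing.assert_array_equal(colocalize(a, b), oracle.and_by_coordinates(a, b))

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            colocalize(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    def test_result_subset_of_inputs(self, rng):
        a = rng.random((10, 10)) > 0.4
        b = rng.random((10, 10)) > 0.4
        both = colocalize(a, b)
        assert not (both & ~a).any() and not (both & ~b).any()


def _blob_stack(centers, radius=4, h=80, w=120, channels=("DAPI", "PCNA"), both=True):
    """Noiseless two-channel stack with disc blobs at given centers."""
    yy, xx = np.mgrid[0:h, 0:w]
    plane = np.zeros((h, w))
    for r, c in centers:
        plane[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = 1.0
    other = plane.copy() if both else np.zeros_like(plane)
    pixels = np.stack([plane[None], other[None]])
    return ImageStack(
        pixels=pixels, channel_names=list(channels), pixel_size_um=1.0, dtype_max=1.0
    )


class TestCountColoc:
    def test_five_nuclei(self):
        centers = [(20, 20), (20, 60), (20, 100), (60, 30), (60, 90)]
        stack = _blob_stack(centers)
        roi = full_frame_roi(80, 120)
        rec = count_coloc(stack, "DAPI", "PCNA", roi)
        assert rec.raw_count == 5
        assert rec.marker_combo == "DAPI∧PCNA"

    def test_all_pcna_negative(self):
        stack = _blob_stack([(20, 20), (60, 90)], both=False)
        rec = count_coloc(stack, "DAPI", "PCNA", full_frame_roi(80, 120))
        assert rec.raw_count == 0

    def test_missing_channel_raises(self):
        stack = _blob_stack([(20, 20)])
        with pytest.raises(KeyError):
            count_coloc(stack, "DAPI", "TUNEL", full_frame_roi(80, 120))

    def test_density_times_normalizer_is_count(self):
        stack = _blob_stack([(20, 20), (60, 90)])
        rec = count_coloc(stack, "DAPI", "PCNA", full_frame_roi(80, 120))
        assert rec.density * rec.normalizer == pytest.approx(rec.raw_count, rel=1e-12)
        assert rec.normalizer_kind == "area_mm2"

    def test_polyline_roi_band_and_length_normalization(self):
        stack = _blob_stack([(20, 20), (20, 100), (80 - 10, 60)])
        band = RegionOfInterest("polyline", [[20.0, 0.0], [20.0, 119.0]])
        params = SegmentationParams(roi_band_halfwidth_px=15)
        rec = count_coloc(stack, "DAPI", "PCNA", band, params)
        assert rec.raw_count == 2  # third blob is 50 px from the band
        assert rec.normalizer_kind == "length_mm"
        assert rec.density == pytest.approx(2 / (119 / 1000))

    def test_seeded_scene_within_10pct(self, frame_roi):
        cfg = SceneConfig(n_nuclei_per_layer=50, pcna_positive_fraction=0.3, seed=4)
        stack, truth = generate_section(cfg)
        rec = count_coloc(stack, "DAPI", "PCNA", frame_roi(*stack.shape_yx))
        true = truth.count("DAPI∧PCNA")
        assert abs(rec.raw_count - true) <= 0.1 * true

    def test_noiseless_scene_exact(self, frame_roi):
        cfg = noiseless(n_nuclei_per_layer=40, pcna_positive_fraction=0.4, seed=8)
        stack, truth = generate_section(cfg)
        rec = count_coloc(stack, "DAPI", "PCNA", frame_roi(*stack.shape_yx))
        assert rec.raw_count == truth.count("DAPI∧PCNA")

    def test_degenerate_channels_zero_count(self, frame_roi):
        pixels = np.zeros((2, 1, 32, 32))
        stack = ImageStack(
            pixels=pixels, channel_names=["DAPI", "PCNA"], pixel_size_um=1.0, dtype_max=1.0
        )
        params = SegmentationParams(local_block_px=15)
        rec = count_coloc(stack, "DAPI", "PCNA", full_frame_roi(32, 32), params)
        assert rec.raw_count == 0

    def test_coloc_leq_single_channel_counts(self, frame_roi):
        cfg = SceneConfig(n_nuclei_per_layer=30, pcna_positive_fraction=0.5, seed=6)
        stack, _ = generate_section(cfg)
        roi = frame_roi(*stack.shape_yx)
        coloc = count_coloc(stack, "DAPI", "PCNA", roi).raw_count
        dapi = count_single_marker(stack, "DAPI", roi).raw_count
        pcna = count_single_marker(stack, "PCNA", roi).raw_count
        assert coloc <= min(dapi, pcna)

    def test_min_area_monotonicity(self, frame_roi):
        cfg = SceneConfig(n_nuclei_per_layer=30, pcna_positive_fraction=0.5, seed=6)
        stack, _ = generate_section(cfg)
        roi = frame_roi(*stack.shape_yx)
        counts = [
            count_coloc(
                stack, "DAPI", "PCNA", roi, SegmentationParams(min_area_px=m)
            ).raw_count
            for m in (0, 15, 60, 200)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_per_plane_counts_sum(self, frame_roi):
        cfg = noiseless(n_nuclei_per_layer=10, pcna_positive_fraction=1.0, n_z=3, seed=12)
        stack, truth = generate_section(cfg)
        rec = count_coloc(stack, "DAPI", "PCNA", frame_roi(*stack.shape_yx))
        assert len(rec.per_plane_counts) == 3
        assert sum(rec.per_plane_counts) == rec.raw_count == truth.count("DAPI∧PCNA")

    def test_max_projection_mode(self, frame_roi):
        cfg = noiseless(n_nuclei_per_layer=10, pcna_positive_fraction=1.0, n_z=3, seed=12)
        stack, truth = generate_section(cfg)
        rec = count_coloc(
            stack, "DAPI", "PCNA", frame_roi(*stack.shape_yx),
            SegmentationParams(z_mode="max_projection"),
        )
        assert len(rec.per_plane_counts) == 1
        assert rec.raw_count == truth.count("DAPI∧PCNA")  # non-touching scene


class TestCountSingleMarker:
    def test_blank_channel_zero(self):
        stack = _blob_stack([], both=False)
        rec = count_single_marker(stack, "PCNA", full_frame_roi(80, 120))
        assert rec.raw_count == 0

    def test_seven_blobs(self):
        centers = [(15, c) for c in (15, 45, 75, 105)] + [(60, c) for c in (20, 60, 100)]
        stack = _blob_stack(centers)
        rec = count_single_marker(stack, "DAPI", full_frame_roi(80, 120))
        assert rec.raw_count == 7

    def test_seeded_tunel_scene(self, frame_roi):
        cfg = SceneConfig(
            n_nuclei_per_layer=40, tunel_positive_fraction=0.3, seed=19
        )
        stack, truth = generate_section(cfg)
        rec = count_single_marker(stack, "TUNEL", frame_roi(*stack.shape_yx))
        true = truth.count("TUNEL")
        assert abs(rec.raw_count - true) <= max(1, 0.1 * true)


class TestScoreCells:
    def _leukocyte_setup(self, pcna_fraction, seed=23):
        cfg = noiseless(
            n_nuclei_per_layer=0,
            n_leukocytes=12,
            leukocyte_nuclear_pcna_fraction=pcna_fraction,
            seed=seed,
        )
        stack, truth = generate_section(cfg)
        body_mask, bodies = filter_small(
            truth.label_maps["Lplastin"][0] > 0, 15, "Lplastin"
        )
        return truth, bodies

    def test_partner_superset_positive(self):
        truth, bodies = self._leukocyte_setup(0.0)
        nuclear = truth.label_maps["DAPI"][0] > 0
        partner = np.ones_like(nuclear)
        scores = score_cells(bodies, nuclear, partner, "nuclear_overlap", 1.0)
        assert all(scores.values())

    def test_empty_partner_negative(self):
        truth, bodies = self._leukocyte_setup(1.0)
        nuclear = truth.label_maps["DAPI"][0] > 0
        scores = score_cells(bodies, nuclear, np.zeros_like(nuclear), "nuclear_overlap")
        assert not any(scores.values())

    def test_programmed_fraction_recovered_exactly_noiseless(self):
        truth, bodies = self._leukocyte_setup(0.5)
        nuclear = truth.label_maps["DAPI"][0] > 0
        partner = truth.label_maps["PCNA"][0] > 0
        scores = score_cells(bodies, nuclear, partner, "nuclear_overlap")
        assert sum(scores.values()) == truth.count(("Lplastin", "PCNA"))

    def test_cell_without_nucleus_scored_negative(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[2:8, 2:8] = 1
        from retinaquant.counting import LabeledObjects, ObjectRecord

        cells = LabeledObjects(
            channel="x",
            z_index=0,
            label_image=labels,
            objects=[ObjectRecord(1, 36, (4.5, 4.5), (2, 2, 8, 8))],
        )
        empty = np.zeros((20, 20), bool)
        scores = score_cells(cells, empty, np.ones((20, 20), bool))
        assert scores == {1: False}

    def test_surround_rule_hucd(self):
        cfg = noiseless(
            n_nuclei_per_layer=10, hucd_positive_fraction=1.0, seed=31
        )
        stack, truth = generate_section(cfg)
        nuclear = truth.label_maps["DAPI"][0] > 0
        partner = truth.label_maps["HuCD"][0] > 0
        _, nuclei = filter_small(nuclear, 15, "DAPI")
        scores = score_cells(nuclei, nuclear, partner, "surround", 0.3)
        assert sum(scores.values()) == len(truth.cells)

    def test_surround_rule_negative_without_ring(self):
        cfg = noiseless(n_nuclei_per_layer=10, seed=31)
        stack, truth = generate_section(cfg)
        nuclear = truth.label_maps["DAPI"][0] > 0
        _, nuclei = filter_small(nuclear, 15, "DAPI")
        scores = score_cells(
            nuclei, nuclear, np.zeros_like(nuclear), "surround", 0.3
        )
        assert not any(scores.values())

    def test_scored_count_record(self, frame_roi):
        truth, bodies = self._leukocyte_setup(0.5)
        nuclear = truth.label_maps["DAPI"][0] > 0
        partner = truth.label_maps["PCNA"][0] > 0
        scores = score_cells(bodies, nuclear, partner, "nuclear_overlap")
        rec = scored_count_record(
            scores, frame_roi(260, 620), 0.5, "Lplastin∧PCNA", sample_id="s1"
        )
        assert rec.raw_count == sum(scores.values())
        assert rec.density * rec.normalizer == pytest.approx(rec.raw_count)

    def test_unknown_rule(self):
        truth, bodies = self._leukocyte_setup(0.0)
        with pytest.raises(ParameterError):
            score_cells(bodies, np.zeros((260, 620), bool), np.zeros((260, 620), bool), "nope")


class TestGeometryInvariance:
    def test_rotation_and_translation(self, frame_roi):
        cfg = noiseless(
            image_height_px=120,
            image_width_px=160,
            layer_bands=[("a", 10, 50), ("b", 60, 110)],
            n_nuclei_per_layer=12,
            pcna_positive_fraction=0.5,
            seed=14,
        )
        stack, _ = generate_section(cfg)
        roi = RegionOfInterest(
            "polygon", [[5.0, 5.0], [5.0, 150.0], [110.0, 150.0], [110.0, 5.0]]
        )
        base = count_coloc(stack, "DAPI", "PCNA", roi)

        # joint 90 deg rotation of image + ROI: (r, c) -> (W-1-c, r)
        w = stack.pixels.shape[3]
        rot_pixels = np.rot90(stack.pixels, axes=(2, 3))
        rot_stack = ImageStack(
            pixels=np.ascontiguousarray(rot_pixels),
            channel_names=stack.channel_names,
            pixel_size_um=stack.pixel_size_um,
            dtype_max=stack.dtype_max,
        )
        rot_roi = RegionOfInterest(
            "polygon",
            np.column_stack([w - 1 - roi.vertices[:, 1], roi.vertices[:, 0]]),
        )
        rotated = count_coloc(rot_stack, "DAPI", "PCNA", rot_roi)
        assert rotated.raw_count == base.raw_count
        assert rotated.density == pytest.approx(base.density)

        # joint translation by padding image and shifting ROI
        pad = 8
        padded = np.pad(
            stack.pixels,
            ((0, 0), (0, 0), (pad, 0), (pad, 0)),
            constant_values=cfg.background_level,
        )
        pad_stack = ImageStack(
            pixels=padded,
            channel_names=stack.channel_names,
            pixel_size_um=stack.pixel_size_um,
            dtype_max=stack.dtype_max,
        )
        pad_roi = RegionOfInterest("polygon", roi.vertices + pad)
        shifted = count_coloc(pad_stack, "DAPI", "PCNA", pad_roi)
        assert shifted.raw_count == base.raw_count
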