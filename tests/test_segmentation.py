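import numpy as np
import pytest
from dataclasses import replace

from cometkit.image_io import IntensityImage
from cometkit.quantification import iou, match_and_evaluate
from cometkit.segmentation import (
    CometSegmentation,
    SegConfig,
    apply_geometric_filters,
    locate_candidates,
    preprocess,
    segment_head,
    segment_image,
    segment_tail,
)
from cometkit.synthetic import SynthConfig, generate_assay_image


def _image(pixels):
    return IntensityImage(np.asarray(pixels, np.uint8), bit_depth=8)


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = _image(np.full((32, 32), 40))
        out = preprocess(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)
        assert out.bit_depth == 8

    def test_removes_isolated_bright_pixels(self):
        rng = np.random.default_rng(0)
        img, _ = generate_assay_image(SynthConfig(seed=1, n_comets=3))
        pixels = img.pixels.copy()
        # salt noise: 50 isolated saturated pixels far from each other
        rows = rng.choice(np.arange(5, 500, 10), 50, replace=False)
        cols = rng.choice(np.arange(5, 500, 10), 50, replace=False)
        pixels[rows, cols] = 255
        out = preprocess(_image(pixels), SegConfig(noise_element_size=3))
        # an isolated single-pixel maximum cannot survive a 3x3 opening
        salt_survivors = int((out.pixels[rows, cols] == 255).sum())
        assert salt_survivors == 0

    def test_nearly_idempotent(self):
        img, _ = generate_assay_image(SynthConfig(seed=2, n_comets=5))
        once = preprocess(img)
        twice = preprocess(once)
        changed = np.mean(once.pixels != twice.pixels)
        assert changed < 0.01

    def test_output_never_exceeds_input_max(self):
        img, _ = generate_assay_image(SynthConfig(seed=3, n_comets=5))
        assert preprocess(img).pixels.max() <= img.pixels.max()

    def test_element_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(_image(np.zeros((4, 4))), SegConfig(noise_element_size=9))


class TestLocateCandidates:
    def test_blank_image_empty_list(self):
        assert locate_candidates(_image(np.full((64, 64), 12))) == []

    def test_finds_all_well_separated_comets(self):
        img, truth = generate_assay_image(SynthConfig(seed=4, n_comets=8))
        regions = locate_candidates(preprocess(img))
        assert len(regions) == 8

    def test_subminimum_speck_dropped(self):
        pixels = np.full((64, 64), 10, np.uint8)
        pixels[10:22, 10:22] = 200  # real candidate, 144 px
        pixels[40, 40] = pixels[40, 41] = pixels[41, 40] = 200  # 3-px speck
        regions = locate_candidates(_image(pixels), SegConfig(min_candidate_area=30))
        assert len(regions) == 1
        assert regions[0].area >= 100

    def test_regions_sorted_row_major(self):
        img, _ = generate_assay_image(SynthConfig(seed=5, n_comets=8))
        regions = locate_candidates(preprocess(img))
        centroids = [r.centroid for r in regions]
        assert centroids == sorted(centroids)

    def test_matches_bruteforce_connected_components_on_small_patches(self):
        """8-connected labeling equals exhaustive pixel-pair union-find."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            pixels = np.full((32, 32), 10, np.uint8)
            for _ in range(3):
                r0, c0 = rng.integers(2, 20, 2)
                pixels[r0 : r0 + rng.integers(3, 9), c0 : c0 + rng.integers(3, 9)] = 200
            cfg = SegConfig(min_candidate_area=1, max_candidate_area=1024)
            regions = locate_candidates(_image(pixels), cfg)

            # brute force: union-find over all 8-neighbour pixel pairs
            binary = pixels > (pixels.min() + pixels.max()) // 2
            parent = {p: p for p in zip(*np.nonzero(binary))}

            def find(p):
                while parent[p] != p:
                    parent[p] = parent[parent[p]]
                    p = parent[p]
                return p

            for (r, c) in list(parent):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        q = (r + dr, c + dc)
                        if q in parent:
                            parent[find((r, c))] = find(q)
            brute = {}
            for p in parent:
                brute.setdefault(find(p), set()).add(p)
            got = {frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(reg.mask))) for reg in regions}
            want = {frozenset((int(r), int(c)) for r, c in s) for s in brute.values()}
            assert got == want


class TestSegmentHead:
    def test_single_synthetic_comet_head_iou(self, single_comet_config):
        img, (gt,) = generate_assay_image(replace(single_comet_config, seed=8))
        pre = preprocess(img)
        (region,) = locate_candidates(pre)
        head = segment_head(pre, region)
        assert head is not None
        assert iou(head, gt.head_mask) >= 0.9

    def test_perfect_disc_accepted_with_expected_shape_scores(self):
        from cometkit.segmentation import _circularity, _convexity

        disc = _disc((64, 64), 32, 32, 16)
        assert 0.85 <= _circularity(disc) <= 1.0
        assert _convexity(disc) >= 0.95
        pixels = np.where(disc, 200, 10).astype(np.uint8)
        regions = locate_candidates(_image(pixels))
        head = segment_head(_image(pixels), regions[0])
        assert head is not None and iou(head, disc) > 0.9

    def test_thin_bar_rejected_on_circularity(self):
        pixels = np.full((64, 64), 10, np.uint8)
        pixels[30:32, 8:56] = 220  # 2-px-wide bright bar
        regions = locate_candidates(_image(pixels), SegConfig(min_candidate_area=20))
        assert len(regions) == 1
        assert segment_head(_image(pixels), regions[0]) is None


class TestSegmentTail:
    def test_head_only_cell_tail_nearly_empty(self, single_comet_config):
        cfg = replace(single_comet_config, seed=9, tail_probability=0.0)
        img, (gt,) = generate_assay_image(cfg)
        pre = preprocess(img)
        (region,) = locate_candidates(pre)
        head = segment_head(pre, region)
        tail = segment_tail(pre, region, head)
        assert tail.sum() <= 0.05 * head.sum()

    def test_tailed_comet_tail_iou(self, single_comet_config):
        cfg = replace(single_comet_config, seed=10, tail_probability=1.0)
        img, (gt,) = generate_assay_image(cfg)
        pre = preprocess(img)
        (region,) = locate_candidates(pre)
        head = segment_head(pre, region)
        tail = segment_tail(pre, region, head)
        assert iou(tail, gt.tail_mask) >= 0.7

    def test_head_and_tail_always_disjoint(self, single_comet_config):
        for seed in range(4):
            cfg = replace(single_comet_config, seed=20 + seed, tail_probability=0.5)
            img, _ = generate_assay_image(cfg)
            pre = preprocess(img)
            for region in locate_candidates(pre):
                head = segment_head(pre, region)
                if head is None:
                    continue
                tail = segment_tail(pre, region, head)
                assert not (head & tail).any()


class TestGeometricFilters:
    def _seg(self, head, tail):
        return CometSegmentation(
            region_id=0, head_mask=head, tail_mask=tail, has_tail=bool(tail.any())
        )

    def test_rotated_tail_discarded_as_orientation(self):
        shape = (96, 96)
        head = _disc(shape, 48, 30, 8)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        # tail at ~40 degrees above the x axis
        along = (xx - 30) * np.cos(np.deg2rad(-40)) - (yy - 48) * np.sin(np.deg2rad(-40))
        perp = (xx - 30) * np.sin(np.deg2rad(-40)) + (yy - 48) * np.cos(np.deg2rad(-40))
        tail = (along > 9) & (along < 50) & (np.abs(perp) < 4)
        out = apply_geometric_filters(self._seg(head, tail), SegConfig(max_angle_deg=15))
        assert not out.accepted and out.discard_reason == "orientation"

    def test_straight_tail_with_sane_ratio_accepted(self):
        shape = (64, 128)
        head = _disc(shape, 32, 20, 8)
        tail = np.zeros(shape, bool)
        tail[28:36, 29:90] = True
        out = apply_geometric_filters(self._seg(head, tail))
        assert out.accepted and out.discard_reason == "none"

    def test_extreme_area_ratio_discarded(self):
        shape = (64, 128)
        head = _disc(shape, 32, 20, 10)
        tail = np.zeros(shape, bool)
        tail[31:33, 31:36] = True  # tiny tail: ratio far above the interval
        out = apply_geometric_filters(self._seg(head, tail), SegConfig(ratio_interval=(0.05, 20)))
        assert not out.accepted and out.discard_reason == "ratio"

    def test_head_only_cell_exempt(self):
        head = _disc((64, 64), 32, 32, 10)
        out = apply_geometric_filters(self._seg(head, np.zeros((64, 64), bool)))
        assert out.accepted


class TestSegmentImage:
    def test_blank_image_empty_result(self, default_model):
        img = _image(np.full((128, 128), 12))
        assert segment_image(img, model=default_model) == []

    def test_seed42_scene_detection(self, scene42, default_model):
        img, truth = scene42
        segs = segment_image(img, model=default_model)
        accepted = [s for s in segs if s.accepted]
        result = match_and_evaluate(accepted, truth)
        assert result.detection_rate >= 90.0

    def test_rerun_is_deterministic(self, scene42, default_model):
        img, _ = scene42
        a = segment_image(img, model=default_model)
        b = segment_image(img, model=default_model)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.head_mask, sb.head_mask)
            np.testing.assert_array_equal(sa.tail_mask, sb.tail_mask)
            assert sa.accepted == sb.accepted

    def test_masks_inside_candidate_bounding_boxes(self, scene42, default_model):
        img, _ = scene42
        pre = preprocess(img)
        regions = locate_candidates(pre)
        boxes = [r.bbox for r in regions]
        for seg in segment_image(img, model=default_model):
            mask = seg.head_mask | seg.tail_mask
            if not mask.any():
                continue
            rows, cols = np.nonzero(mask)
            assert any(
                b[0] <= rows.min() and rows.max() < b[2] and b[1] <= cols.min() and cols.max() < b[3]
                for b in boxes
            )

    def test_noiseless_limit_recovers_noisy_structure(self, default_model):
        """sigma -> 0 changes nothing structural: same comets found."""
        noisy_cfg = SynthConfig(seed=33, n_comets=6)
        clean_cfg = replace(noisy_cfg, noise_sigma=0.0)
        img_noisy, _ = generate_assay_image(noisy_cfg)
        img_clean, _ = generate_assay_image(clean_cfg)
        segs_noisy = segment_image(img_noisy, model=default_model)
        segs_clean = segment_image(img_clean, model=default_model)
        assert len(segs_noisy) == len(segs_clean) == 6
        for sn, sc in zip(segs_noisy, segs_clean):
            assert iou(sn.head_mask, sc.head_mask) > 0.8


class TestSegConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(min_circularity=0.0),
            dict(min_convexity=1.5),
            dict(min_candidate_area=-2),
            dict(min_head_area=100, max_head_area=10),
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegConfig(**kwargs)
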