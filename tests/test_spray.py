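"""Strip decomposition, spray-area proposal, containment and dataset metrics."""

import numpy as np
import pytest

from sprayeval import (
    Annotation,
    ConfigurationError,
    Detection,
    ImageRecord,
    NozzleConfig,
    PixelBox,
    UndefinedMetricError,
    ValidationError,
    area_sprayed,
    evaluate_dataset,
    evaluate_image,
    herbicide_saving,
    is_sprayed,
    propose_spray_areas,
    spray_union,
    strip_decomposition,
    weed_coverage_rate,
)
from sprayeval.errors import AlignmentError

from conftest import oracle_image_metrics, random_scene


def make_image(width=100, height=100, weeds=(), crops=(), dets=(), image_id="img"):
    anns = [Annotation(PixelBox(*b), "weed", id=f"w{i}") for i, b in enumerate(weeds)]
    anns += [Annotation(PixelBox(*b), "crop", id=f"c{i}") for i, b in enumerate(crops)]
    detections = [Detection(PixelBox(*b), cls, conf) for b, cls, conf in dets]
    return ImageRecord(image_id, width, height, anns, detections)


class TestStripDecomposition:
    @pytest.mark.parametrize(
        "height, n, bounds",
        [
            (100, 4, [0, 25, 50, 75, 100]),
            (77, 1, [0, 77]),
            (10, 3, [0, 3, 6, 10]),
        ],
    )
    def test_boundaries(self, height, n, bounds):
        strips = strip_decomposition(height, n)
        assert [s.y_min for s in strips] + [strips[-1].y_max] == bounds

    @pytest.mark.parametrize("height, n", [(100, 0), (100, -1), (10, 11)])
    def test_invalid_configuration(self, height, n):
        with pytest.raises(ConfigurationError):
            strip_decomposition(height, n)

    @pytest.mark.parametrize("height, n", [(360, 7), (1080, 13), (5, 5)])
    def test_partition_exact_and_balanced(self, height, n):
        strips = strip_decomposition(height, n)
        assert strips[0].y_min == 0 and strips[-1].y_max == height
        for a, b in zip(strips, strips[1:]):
            assert a.y_max == b.y_min
        heights = [s.height for s in strips]
        assert max(heights) - min(heights) <= 1


class TestProposeSprayAreas:
    def test_narrow_detection_padded_to_nozzle_width(self):
        img = make_image()
        dets = [Detection(PixelBox(40, 30, 50, 40), "weed", 0.9)]
        boxes = propose_spray_areas(dets, img, NozzleConfig(4))
        assert boxes == [PixelBox(33, 25, 58, 50)]

    def test_wide_detection_spanning_two_strips(self):
        img = make_image()
        dets = [Detection(PixelBox(10, 20, 70, 30), "weed", 0.9)]
        boxes = propose_spray_areas(dets, img, NozzleConfig(4))
        assert sorted(b.as_tuple() for b in boxes) == [(10, 0, 70, 25), (10, 25, 70, 50)]

    def test_crop_detections_propose_nothing(self):
        img = make_image()
        dets = [Detection(PixelBox(40, 30, 50, 40), "crop", 0.99)]
        assert propose_spray_areas(dets, img, NozzleConfig(4)) == []

    def test_empty_detections(self):
        assert propose_spray_areas([], make_image(), NozzleConfig(2)) == []

    def test_every_box_contains_detection_strip_intersection(self, rng):
        for _ in range(30):
            img = random_scene(rng)
            for n in (1, 2, 3, 4):
                dets = img.weed_detections(0.05)
                boxes = propose_spray_areas(dets, img, NozzleConfig(n))
                strips = strip_decomposition(img.height, n)
                expected_pairs = [
                    d.box.intersect(PixelBox(0, s.y_min, img.width, s.y_max))
                    for d in dets
                    for s in strips
                    if s.overlaps(d.box)
                ]
                assert len(boxes) == len(expected_pairs)
                for box, inter in zip(boxes, expected_pairs):
                    assert box.contains_box(inter)


class TestIsSprayed:
    def test_contained(self):
        region = spray_union([PixelBox(0, 0, 10, 10)])
        assert is_sprayed(PixelBox(4, 4, 6, 6), region)

    def test_one_column_outside(self):
        region = spray_union([PixelBox(0, 0, 10, 10)])
        assert not is_sprayed(PixelBox(4, 4, 11, 6), region)

    def test_joint_cover_by_two_boxes(self):
        region = spray_union([PixelBox(0, 0, 6, 10), PixelBox(5, 0, 10, 10)])
        assert is_sprayed(PixelBox(0, 0, 10, 10), region)

    def test_agrees_with_mask_oracle(self, rng):
        for _ in range(40):
            img = random_scene(rng)
            n = int(rng.integers(1, 5))
            result = evaluate_image(img, NozzleConfig(n))
            flags, area = oracle_image_metrics(img, n)
            assert list(result.sprayed_flags) == flags
            assert result.region.area == area


class TestEvaluateImage:
    def test_no_detections_nothing_sprayed(self):
        img = make_image(weeds=[(5, 5, 15, 15), (50, 50, 60, 60), (80, 10, 90, 25)])
        result = evaluate_image(img, NozzleConfig(2))
        assert result.region.area == 0
        assert result.sprayed_flags == (False, False, False)
        assert result.num_gt_weeds == 3

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 7])
    def test_perfect_detections_spray_everything(self, n, rng):
        img = random_scene(rng)
        perfect = img.with_detections(
            [Detection(a.box, "weed", 1.0) for a in img.gt_weeds()]
        )
        result = evaluate_image(perfect, NozzleConfig(n))
        assert all(result.sprayed_flags)

    def test_confidence_threshold_filters(self):
        img = make_image(
            weeds=[(40, 30, 50, 40)],
            dets=[((40, 30, 50, 40), "weed", 0.01)],
        )
        assert evaluate_image(img, NozzleConfig(2), 0.05).region.area == 0
        assert evaluate_image(img, NozzleConfig(2), 0.01).region.area > 0

    def test_n_larger_than_height_rejected(self):
        img = make_image(width=10, height=10)
        with pytest.raises(ConfigurationError):
            evaluate_image(img, NozzleConfig(11))


class TestDatasetMetrics:
    def test_wcr_perfect_and_zero(self, rng):
        imgs = [random_scene(rng) for _ in range(5)]
        perfect = [
            im.with_detections([Detection(a.box, "weed", 1.0) for a in im.gt_weeds()])
            for im in imgs
        ]
        for n in (1, 2, 3, 4):
            m = evaluate_dataset(perfect, NozzleConfig(n))
            assert m.wcr == 100.0
        silent = [im.with_detections([]) for im in imgs]
        m = evaluate_dataset(silent, NozzleConfig(2))
        assert m.wcr == 0.0 and m.area_sprayed == 0.0 and m.herbicide_saving == 100.0

    def test_wcr_undefined_without_weeds(self):
        img = make_image(crops=[(10, 10, 30, 30)])
        with pytest.raises(UndefinedMetricError):
            evaluate_dataset([img], NozzleConfig(1))

    def test_area_sprayed_full_cover(self):
        img = make_image(
            weeds=[(40, 40, 60, 60)],
            dets=[((0, 0, 100, 100), "weed", 0.9)],
        )
        m = evaluate_dataset([img], NozzleConfig(1))
        assert m.area_sprayed == 100.0 and m.herbicide_saving == 0.0

    def test_area_sprayed_alignment_error(self):
        img = make_image(weeds=[(1, 1, 5, 5)])
        result = evaluate_image(img, NozzleConfig(1))
        other = make_image(image_id="other", weeds=[(1, 1, 5, 5)])
        with pytest.raises(AlignmentError):
            area_sprayed([result], [other])

    def test_herbicide_saving_bounds(self):
        assert herbicide_saving(0.0) == 100.0
        assert herbicide_saving(100.0) == 0.0
        assert herbicide_saving(30.0) == 70.0
        with pytest.raises(ValidationError):
            herbicide_saving(120.0)

    def test_order_invariance(self, rng):
        img = random_scene(rng)
        shuffled = ImageRecord(
            img.image_id, img.width, img.height,
            tuple(reversed(img.annotations)), tuple(reversed(img.detections)),
        )
        a = evaluate_image(img, NozzleConfig(3))
        b = evaluate_image(shuffled, NozzleConfig(3))
        assert a.region.area == b.region.area
        assert sorted(a.sprayed_flags) == sorted(b.sprayed_flags)

    def test_crop_irrelevance(self, rng):
        img = random_scene(rng, n_crops=5)
        stripped = ImageRecord(
            img.image_id, img.width, img.height,
            tuple(a for a in img.annotations if a.class_label == "weed"),
            tuple(d for d in img.detections if d.class_label == "weed"),
        )
        for n in (1, 2, 4):
            a = evaluate_dataset([img], NozzleConfig(n))
            b = evaluate_dataset([stripped], NozzleConfig(n))
            assert a.wcr == b.wcr and a.area_sprayed == b.area_sprayed

    def test_nesting_monotonicity_dyadic(self, rng):
        # H=128 divisible by 2n for n in {1,2,4}: finer nozzles spray a subset
        for _ in range(10):
            img = random_scene(rng, width=128, height=128)
            areas = {}
            regions = {}
            for n in (1, 2, 4, 8):
                r = evaluate_image(img, NozzleConfig(n))
                areas[n], regions[n] = r.region.area, r.region
            assert areas[8] <= areas[4] <= areas[2] <= areas[1]
            for coarse, fine in ((1, 2), (2, 4), (4, 8)):
                for rect in regions[fine].rectangles:
                    assert regions[coarse].contains(rect)
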