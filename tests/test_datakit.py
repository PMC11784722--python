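"""Label I/O, splits, augmentation protocol, and the synthetic scene generator."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from imcyolo.datakit import (
    Annotation, DatasetIndex, ImageRecord, SceneParams, adjust_brightness,
    annotations_to_xyxy, expand_with_augmentations, generate_dataset,
    generate_scene, hflip, load_manifest, parse_yolo_labels, read_yolo_labels,
    salt_pepper_noise, split_dataset, write_yolo_labels,
)

boxes = st.builds(
    Annotation,
    class_id=st.integers(0, 3),
    cx=st.floats(0.05, 0.95), cy=st.floats(0.05, 0.95),
    w=st.floats(0.01, 0.1), h=st.floats(0.01, 0.1),
)


class TestLabelIO:
    def test_single_centered_box(self):
        anns = parse_yolo_labels("0 0.5 0.5 0.1 0.1")
        assert anns == [Annotation(0, 0.5, 0.5, 0.1, 0.1)]

    @given(st.lists(boxes, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_write_read_roundtrip_to_six_decimals(self, tmp_path_factory, anns):
        path = tmp_path_factory.mktemp("labels") / "a.txt"
        write_yolo_labels(anns, path)
        back = read_yolo_labels(path)
        assert len(back) == len(anns)
        for a, b in zip(anns, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=5e-7)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    @pytest.mark.parametrize("bad,msg", [
        ("0 0.5 0.5 0.1", "5 fields"),
        ("0 1.5 0.5 0.1 0.1", "outside"),
        ("x 0.5 0.5 0.1 0.1", "line 1"),
    ])
    def test_malformed_lines_report_line_number(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            parse_yolo_labels(bad)

    def test_pixel_conversion(self):
        xyxy = annotations_to_xyxy([Annotation(0, 0.5, 0.5, 0.25, 0.5)], 100, 50)
        assert np.allclose(xyxy, [[37.5, 12.5, 62.5, 37.5]])


class TestSplits:
    def test_exact_arithmetic_for_twenty(self):
        splits = split_dataset(20, seed=0)
        assert [splits.count(s) for s in ("train", "val", "test")] == [14, 3, 3]

    def test_largest_remainder_for_full_corpus_size(self):
        splits = split_dataset(3310, seed=1)
        assert [splits.count(s) for s in ("train", "val", "test")] == [2317, 497, 496]

    @given(st.integers(1, 300), st.integers(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_disjoint_and_exhaustive(self, n, seed):
        splits = split_dataset(n, seed=seed)
        assert len(splits) == n
        assert set(splits) <= {"train", "val", "test"}

    def test_deterministic_under_seed(self):
        assert split_dataset(50, seed=9) == split_dataset(50, seed=9)

    def test_ratios_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(10, ratios=(0.5, 0.2, 0.2))


class TestAugmentations:
    @pytest.mark.parametrize("value,factor,expected", [
        (100, +0.40, 140), (200, +0.40, 255), (100, -0.40, 60)])
    def test_brightness_arithmetic_and_clipping(self, value, factor, expected):
        img = np.full((2, 2, 3), value, dtype=np.uint8)
        assert adjust_brightness(img, factor)[0, 0, 0] == expected

    def test_brightness_factor_bound(self):
        with pytest.raises(ValueError):
            adjust_brightness(np.zeros((2, 2, 3), np.uint8), 1.0)

    def test_saltpepper_zero_intensity_is_identity(self, rng):
        img = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        assert np.array_equal(salt_pepper_noise(img, 0.0, seed=1), img)

    def test_saltpepper_full_intensity_saturates_every_pixel(self, rng):
        img = rng.integers(1, 254, (16, 16, 3), dtype=np.uint8)
        out = salt_pepper_noise(img, 1.0, seed=1)
        assert set(np.unique(out)) <= {0, 255}

    def test_saltpepper_hits_binomial_fraction(self, rng):
        img = np.full((256, 256, 3), 128, dtype=np.uint8)
        out = salt_pepper_noise(img, 0.5, seed=7)
        frac = np.mean(out[:, :, 0] != 128)
        n = 256 * 256
        margin = 3.29 * np.sqrt(0.25 / n)  # 99.9% binomial interval
        assert abs(frac - 0.5) < margin

    def test_hflip_center_mapping_and_fixed_point(self):
        img = np.arange(12, dtype=np.uint8).reshape(2, 2, 3)
        _, anns = hflip(img, [Annotation(0, 0.3, 0.4, 0.1, 0.1),
                              Annotation(0, 0.5, 0.5, 0.2, 0.2)])
        assert anns[0].cx == pytest.approx(0.7)
        assert anns[1].cx == pytest.approx(0.5)

    def test_hflip_is_an_involution(self, rng):
        img = rng.integers(0, 255, (8, 6, 3), dtype=np.uint8)
        anns = [Annotation(0, 0.3, 0.4, 0.1, 0.2)]
        img2, anns2 = hflip(*hflip(img, anns))
        assert np.array_equal(img2, img)
        assert anns2[0].cx == pytest.approx(anns[0].cx)
        assert (anns2[0].cy, anns2[0].w, anns2[0].h) == (anns[0].cy, anns[0].w, anns[0].h)


def _index(n, seed=0):
    splits = split_dataset(n, seed=seed)
    return DatasetIndex(records=[
        ImageRecord(f"img_{i:04d}.png", [Annotation(0, 0.5, 0.5, 0.1, 0.1)], splits[i])
        for i in range(n)])


class TestExpansion:
    def test_one_original_spawns_five_records(self):
        out = expand_with_augmentations(_index(1))
        assert len(out.records) == 5

    def test_full_corpus_expands_to_published_total(self):
        out = expand_with_augmentations(_index(662))
        assert len(out.records) == 3310

    @given(st.integers(1, 60), st.integers(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_no_leakage_pairs_ever(self, n, seed):
        out = expand_with_augmentations(_index(n, seed))
        assert out.leakage_pairs() == []

    def test_double_expansion_rejected(self):
        out = expand_with_augmentations(_index(2))
        with pytest.raises(ValueError, match="already"):
            expand_with_augmentations(out)

    def test_hflip_records_carry_transformed_labels(self):
        idx = DatasetIndex(records=[
            ImageRecord("a.png", [Annotation(0, 0.2, 0.4, 0.1, 0.1)], "train")])
        out = expand_with_augmentations(idx)
        flipped = [r for r in out.records if r.provenance == "hflip"][0]
        assert flipped.annotations[0].cx == pytest.approx(0.8)
        kept = [r for r in out.records if r.provenance == "saltpepper"][0]
        assert kept.annotations[0].cx == pytest.approx(0.2)


class TestSceneGenerator:
    def test_deterministic_under_seed(self):
        p = SceneParams(size=(64, 64), n_burrows=(2, 4), radius=(4, 8), seed=5)
        img1, anns1 = generate_scene(p)
        img2, anns2 = generate_scene(p)
        assert np.array_equal(img1, img2)
        assert anns1 == anns2

    def test_zero_burrows_gives_background_only(self):
        p = SceneParams(size=(64, 64), n_burrows=(0, 0), seed=1)
        img, anns = generate_scene(p)
        assert anns == []
        assert img.shape == (64, 64, 3)

    def test_boxes_contain_their_darkened_pixels(self):
        p = SceneParams(size=(96, 96), n_burrows=(3, 3), radius=(5, 9), seed=2)
        img, anns = generate_scene(p)
        bg, _ = generate_scene(replace(p, n_burrows=(0, 0)))
        dark = (bg.astype(int) - img.astype(int)).sum(axis=2) > 60
        boxes = annotations_to_xyxy(anns, 96, 96)
        inside = np.zeros_like(dark)
        for x1, y1, x2, y2 in boxes:
            inside[int(np.floor(y1)):int(np.ceil(y2)) + 1,
                   int(np.floor(x1)):int(np.ceil(x2)) + 1] = True
        assert not np.any(dark & ~inside)

    def test_default_corpus_sits_in_small_object_regime(self):
        areas = []
        for i in range(12):
            _, anns = generate_scene(SceneParams(seed=100 + i))
            areas.extend(a.w * a.h for a in anns)
        areas = np.asarray(areas)
        assert len(areas) > 30
        assert np.mean(areas < 0.01) >= 0.7
        assert np.median(np.sqrt(areas)) < 0.05

    def test_labels_always_normalized(self):
        for i in range(5):
            _, anns = generate_scene(SceneParams(size=(64, 64), seed=i,
                                                 n_burrows=(3, 6), radius=(3, 7)))
            for a in anns:
                assert 0 <= a.cx - a.w / 2 and a.cx + a.w / 2 <= 1
                assert 0 <= a.cy - a.h / 2 and a.cy + a.h / 2 <= 1


class TestDatasetOnDisk:
    def test_generate_and_reload_manifest(self, tmp_path):
        params = SceneParams(size=(64, 64), n_burrows=(1, 3), radius=(4, 8))
        idx = generate_dataset(tmp_path, 6, params, seed=3)
        assert len(idx.records) == 6
        again = load_manifest(tmp_path)
        assert len(again.records) == 6
        assert [r.split for r in again.records] == [r.split for r in idx.records]
        img = np.asarray(Image.open(idx.records[0].image_path))
        assert img.shape == (64, 64, 3)

    def test_augmented_corpus_writes_five_x_files(self, tmp_path):
        params = SceneParams(size=(48, 48), n_burrows=(1, 2), radius=(4, 6))
        idx = generate_dataset(tmp_path, 4, params, seed=1, augment=True)
        assert len(idx.records) == 20
        assert idx.leakage_pairs() == []
        for r in idx.records:
            assert Image.open(r.image_path).size == (48, 48)

    def test_missing_manifest_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            load_manifest(tmp_path)
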