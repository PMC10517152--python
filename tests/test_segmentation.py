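"""Augmentation, segmenter backends, post-processing, and mask scoring."""

import numpy as np
import pytest

from plantservation import segmentation as seg
from plantservation import synthetic_field as sf
from tests.conftest import make_plant_crop


def small_sources(n=5, size=32, seed=0):
    out = []
    for i in range(n):
        img, mask = make_plant_crop(size=size, radius=8, seed=seed + i)
        out.append(seg.LabeledExample(img, mask))
    return out


class TestAugmentation:
    def test_zero_plan_yields_nothing(self):
        plan = seg.AugmentationPlan(n_geometric=0, n_composited=0)
        assert seg.augment_training_set(small_sources(), plan) == []

    def test_branch_counts_match_plan_exactly(self):
        # the published recipe: 4100 geometric + 3400 composited = 7500
        plan = seg.AugmentationPlan(n_geometric=4100, n_composited=3400,
                                    shift_px=(-4, 4), seed=1)
        bgs = [np.full((32, 32, 3), 120, np.uint8)]
        out = seg.augment_training_set(small_sources(size=32), plan, bgs)
        assert len(out) == 7500
        assert sum(e.provenance == "augmented_geom" for e in out) == 4100
        assert sum(e.provenance == "composited" for e in out) == 3400

    def test_rotation_preserves_mask_area(self):
        img, mask = make_plant_crop(size=64, radius=14, seed=0)
        src = seg.LabeledExample(img, mask)
        plan = seg.AugmentationPlan(n_geometric=20, n_composited=0,
                                    shift_px=(0, 0), scale=(1, 1),
                                    brightness=(1, 1), contrast=(1, 1), seed=2)
        out = seg.augment_training_set([src], plan)
        areas = np.array([e.mask.sum() for e in out])
        assert np.abs(areas / src.mask.sum() - 1).max() < 0.02

    def test_composited_plant_keeps_its_pixels(self):
        src = small_sources(1)[0]
        bg = np.full((32, 32, 3), 200, np.uint8)
        plan = seg.AugmentationPlan(n_geometric=0, n_composited=3,
                                    shift_px=(0, 0), scale=(1, 1),
                                    rotation_deg=(0, 0), brightness=(1, 1),
                                    contrast=(1, 1), seed=0)
        out = seg.augment_training_set([src], plan, [bg])
        for e in out:
            assert np.array_equal(e.image[~e.mask],
                                  np.full(((~e.mask).sum(), 3), 200))

    def test_seed_reproducibility(self):
        plan = seg.AugmentationPlan(n_geometric=10, n_composited=5, seed=7,
                                    shift_px=(-4, 4))
        bgs = [np.full((32, 32, 3), 120, np.uint8)]
        a = seg.augment_training_set(small_sources(), plan, bgs)
        b = seg.augment_training_set(small_sources(), plan, bgs)
        assert all(np.array_equal(x.image, y.image)
                   and np.array_equal(x.mask, y.mask) for x, y in zip(a, b))

    def test_compositing_without_backgrounds(self):
        plan = seg.AugmentationPlan(n_geometric=0, n_composited=1)
        with pytest.raises(ValueError):
            seg.augment_training_set(small_sources(), plan, [])


class TestTraining:
    def test_split_sizes_match_fractions(self):
        examples = small_sources(100, size=16)
        backend, metrics = seg.train_segmenter(seg.ClassicalBackend(), examples,
                                               split=(0.68, 0.12, 0.20), seed=0)
        assert (metrics["n_train"], metrics["n_val"], metrics["n_test"]) == (68, 12, 20)

    def test_classical_backend_passes_through_unfitted(self):
        be = seg.ClassicalBackend()
        out, _ = seg.train_segmenter(be, small_sources(12), seed=0)
        assert out is be

    def test_trainable_backend_overfits_small_set(self):
        examples = []
        for i in range(30):
            img, mask = make_plant_crop(size=48, radius=11, seed=i,
                                        plant_lab=(45, -35, 30))
            examples.append(seg.LabeledExample(img, mask))
        be = seg.TrainableBackend(hidden=(16,), pixels_per_example=600,
                                  max_iter=200)
        be, _ = seg.train_segmenter(be, examples, split=(1.0, 0.0, 0.0), seed=0)
        dices = []
        for ex in examples[:10]:
            pred = seg.postprocess_mask(be.predict(ex.image),
                                        seg.SegPostprocessConfig())
            dices.append(seg.evaluate_masks(pred, ex.mask).dice)
        assert np.mean(dices) > 0.9

    def test_trainable_backend_deterministic_predictions(self):
        examples = small_sources(12, size=32)
        kw = dict(hidden=(8,), pixels_per_example=200, max_iter=60)
        a = seg.TrainableBackend(**kw).fit(examples, seed=3)
        b = seg.TrainableBackend(**kw).fit(examples, seed=3)
        crop = examples[0].image
        assert np.array_equal(a.predict(crop), b.predict(crop))

    def test_too_few_examples(self):
        with pytest.raises(ValueError):
            seg.train_segmenter(seg.ClassicalBackend(), small_sources(3))


class TestSegmentPlant:
    def test_green_plant_on_soil_dice(self):
        img, mask = make_plant_crop(size=96, radius=20, seed=5)
        m, crop = seg.segment_plant(img, (48, 48), seg.ClassicalBackend(),
                                    crop_size=96)
        assert seg.evaluate_masks(m, mask).dice >= 0.8

    def test_bare_background_gives_empty_mask(self):
        img, _ = make_plant_crop(size=96, radius=0, seed=6)
        m, _ = seg.segment_plant(img, (48, 48), seg.ClassicalBackend(),
                                 crop_size=96)
        assert m.sum() == 0

    def test_nothing_outside_circular_crop(self):
        img = np.full((200, 200, 3), 255, np.uint8)  # everything "bright"
        def all_plant(crop):
            return np.ones(crop.shape[:2])
        class Fake:
            backend_id = "fake"
            predict = staticmethod(all_plant)
            def fit(self, *a, **k):
                return self
        m, _ = seg.segment_plant(img, (100, 100), Fake(), crop_size=96)
        assert not np.any(m & ~seg.circular_mask(96))

    def test_border_crop_zero_padded(self):
        img, _ = make_plant_crop(size=64, radius=10)
        m, crop = seg.segment_plant(img, (2, 2), seg.ClassicalBackend(),
                                    crop_size=64)
        assert crop.shape == (64, 64, 3)
        assert np.all(crop[:20, :20] != 255)  # padded region is zeros

    def test_invalid_center(self):
        img, _ = make_plant_crop()
        with pytest.raises(ValueError):
            seg.segment_plant(img, (999, 10), seg.ClassicalBackend())

    def test_backends_are_interchangeable(self):
        img, _ = make_plant_crop(size=48, radius=10, seed=8)
        nn = seg.TrainableBackend(hidden=(8,), pixels_per_example=300,
                                  max_iter=80).fit(small_sources(10, 48), seed=0)
        for backend in (seg.ClassicalBackend(), nn):
            m, crop = seg.segment_plant(img, (24, 24), backend, crop_size=48)
            assert m.dtype == bool and m.shape == (48, 48)
            assert crop.shape == (48, 48, 3)


class TestPostprocess:
    def test_all_ones_survives(self):
        out = seg.postprocess_mask(np.ones((50, 50)))
        assert out.all()

    def test_small_specks_removed_big_blob_kept(self):
        prob = np.zeros((60, 60))
        prob[10:30, 10:20] = 1.0  # 200 px blob
        speck_at = [(2, 2), (2, 56), (56, 2), (56, 56), (30, 45)]
        for y, x in speck_at:
            prob[y:y + 2, x:x + 2] = 1.0  # 4 px specks
        out = seg.postprocess_mask(prob, seg.SegPostprocessConfig(
            gaussian_sigma=0, binary_threshold=0.5, min_object_area=25))
        # brute-force component filter oracle
        from scipy import ndimage as ndi
        lab, n = ndi.label(prob > 0.5)
        keep = np.isin(lab, [i for i in range(1, n + 1)
                             if (lab == i).sum() >= 25])
        assert np.array_equal(out, keep)
        assert out.sum() == 200

    def test_all_zeros(self):
        assert seg.postprocess_mask(np.zeros((20, 20))).sum() == 0

    def test_raising_min_area_never_adds_pixels(self):
        rng = np.random.default_rng(0)
        prob = (rng.random((80, 80)) > 0.6).astype(float)
        prev = None
        for area in (0, 5, 25, 100):
            out = seg.postprocess_mask(prob, seg.SegPostprocessConfig(
                gaussian_sigma=0, min_object_area=area))
            if prev is not None:
                assert np.all(out <= prev)
            prev = out

    def test_invalid_probability_range(self):
        with pytest.raises(ValueError):
            seg.postprocess_mask(np.full((5, 5), 2.0))


class TestEvaluate:
    def test_perfect_prediction(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        r = seg.evaluate_masks(m, m)
        assert (r.dice, r.precision, r.sensitivity) == (1, 1, 1)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool); a[:3] = True
        b = np.zeros((10, 10), bool); b[7:] = True
        r = seg.evaluate_masks(a, b)
        assert r.dice == 0 and r.precision == 0

    def test_half_overlap_closed_form(self):
        # truth and prediction both 50 px, overlapping on 25 px
        truth2 = np.zeros((20, 20), bool); truth2[0:5, 0:10] = True
        pred2 = np.zeros((20, 20), bool); pred2[0:5, 5:15] = True
        r = seg.evaluate_masks(pred2, truth2)
        assert r.dice == pytest.approx(0.5)
        assert r.precision == pytest.approx(0.5)
        assert r.sensitivity == pytest.approx(0.5)

    def test_empty_empty_convention(self):
        e = np.zeros((5, 5), bool)
        r = seg.evaluate_masks(e, e)
        assert r.dice == 1 and r.precision == 1 and r.sensitivity == 1

    def test_dice_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((15, 15)) > 0.5, rng.random((15, 15)) > 0.5
        assert seg.evaluate_masks(a, b).dice == seg.evaluate_masks(b, a).dice

    def test_confusion_counts_partition_pixels(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((15, 15)) > 0.5, rng.random((15, 15)) > 0.5
        r = seg.evaluate_masks(a, b)
        assert r.tp + r.fp + r.fn + r.tn == 225

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg.evaluate_masks(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


def test_labelme_polygon_round_trip(tmp_path):
    import json
    from PIL import Image

    img, mask = make_plant_crop(size=48, radius=10)
    Image.fromarray(img).save(tmp_path / "crop.png")
    doc = {"imageHeight": 48, "imageWidth": 48, "imagePath": "crop.png",
           "shapes": [{"shape_type": "polygon", "label": "plant",
                       "points": [[10, 10], [38, 10], [38, 38], [10, 38]]}]}
    (tmp_path / "crop.json").write_text(json.dumps(doc))
    ex = seg.load_labelme(tmp_path / "crop.json")
    assert ex.image.shape == (48, 48, 3)
    assert ex.mask[24, 24] and not ex.mask[2, 2]
    # rasterized square area (half-open polygon rasterization ~ 28–29 px side)
    assert 27 ** 2 <= ex.mask.sum() <= 29 ** 2
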