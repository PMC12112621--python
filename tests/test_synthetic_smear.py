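"""Smear generator: geometry oracles, determinism, augmentation, dedup."""

import math

import numpy as np
import pytest

from hemamorph.io_formats import Calibration, LabelSchema, box_from_mask
from hemamorph.synthetic_smear import (
    RBC_ARCHETYPES,
    CellSpec,
    GenerationError,
    augment,
    deduplicate,
    dhash,
    generate_dataset,
    normalize_pixels,
    rebalance,
    render_smear,
    render_single_cell,
)


class TestRenderGeometry:
    def test_circle_mask_area_matches_analytic(self, circle_sample):
        """a = b = 3.5 µm at 0.1 µm/px: area within 2% of π·35² px²."""
        mask = circle_sample.instances[0].mask
        expected = math.pi * 35.0**2
        assert abs(mask.sum() - expected) / expected < 0.02

    def test_circle_eccentricity_near_zero(self, circle_sample):
        from skimage.measure import regionprops

        ecc = regionprops(circle_sample.instances[0].mask.astype(int))[0].eccentricity
        assert ecc < 0.1

    def test_empty_specs_background_only(self, cal):
        sample = render_smear([], (64, 64), cal, seed=1)
        assert sample.instances == []
        assert sample.image.shape == (64, 64, 3)

    def test_same_seed_identical_pixels(self, cal):
        spec = CellSpec("rbc", "Normal", (32.0, 32.0), 3.5, 3.5, pallor_ratio=0.4)
        a = render_smear([spec], (64, 64), cal, seed=5)
        b = render_smear([spec], (64, 64), cal, seed=5)
        assert np.array_equal(a.image, b.image)

    def test_overlap_beyond_limit_raises(self, cal):
        s1 = CellSpec("rbc", "Normal", (32.0, 32.0), 3.5, 3.5)
        s2 = CellSpec("rbc", "Normal", (32.0, 36.0), 3.5, 3.5)
        with pytest.raises(GenerationError, match="overlap"):
            render_smear([s1, s2], (64, 72), cal, seed=0)

    def test_annotation_mask_consistency(self, cal):
        sample, _ = render_single_cell("Elliptocyte", cal, seed=3)
        inst = sample.instances[0]
        x, y, w, h = box_from_mask(inst.mask)
        assert (x, y, w, h) == (
            inst.box.x_center,
            inst.box.y_center,
            inst.box.width,
            inst.box.height,
        )

    def test_archetype_only_on_rbc(self):
        with pytest.raises(ValueError):
            CellSpec("lymphocyte", "Target", (0, 0), 4.0, 4.0)


class TestGenerateDataset:
    def test_counts_match_request_exactly(self, cal):
        m = generate_dataset({"rbc": 20, "lymphocyte": 5}, seed=1, calibration=cal)
        assert m.recount() == {"rbc": 20, "lymphocyte": 5}

    def test_all_fifteen_archetypes_present(self, cal):
        mix = {a: 1.0 / 15 for a in RBC_ARCHETYPES}
        m = generate_dataset({"rbc": 45}, archetype_mix=mix, seed=2, calibration=cal)
        archetypes = {
            i.archetype for e in m.entries for i in e.instances if i.archetype
        }
        # with 45 draws every archetype is expected; require a rich majority
        # and verify the requested mix covers exactly the 15 labels
        assert set(mix) == set(RBC_ARCHETYPES)
        assert len(archetypes) >= 12

    def test_fixed_seed_identical_manifest(self, cal):
        kw = dict(class_counts={"rbc": 8, "platelet": 2}, seed=9, calibration=cal)
        assert generate_dataset(**kw).to_json() == generate_dataset(**kw).to_json()

    def test_invalid_mix_rejected(self, cal):
        with pytest.raises(ValueError):
            generate_dataset({"rbc": 2}, archetype_mix={"Normal": 0.5}, seed=0)


@pytest.fixture(scope="module")
def sample(cal):
    spec = CellSpec("rbc", "Normal", (30.0, 40.0), 3.5, 3.5, pallor_ratio=0.4)
    return render_smear([spec], (96, 96), cal, seed=11)


@pytest.fixture(scope="module")
def manifest(cal):
    return generate_dataset({"rbc": 10, "platelet": 2}, seed=3, calibration=cal)


class TestAugment:
    def test_hflip_twice_is_identity(self, sample):
        img1, inst1 = augment(sample.image, sample.instances, "hflip")
        img2, inst2 = augment(img1, inst1, "hflip")
        assert np.array_equal(img2, sample.image)
        assert np.array_equal(inst2[0].mask, sample.instances[0].mask)

    def test_rotate_zero_is_identity(self, sample):
        img, _ = augment(sample.image, sample.instances, "rotate", angle_deg=0.0)
        assert np.max(np.abs(img - sample.image)) < 1e-6

    def test_hflip_box_coordinate_map(self, sample):
        _, insts = augment(sample.image, sample.instances, "hflip")
        orig = sample.instances[0].box
        flipped = insts[0].box
        assert flipped.x_center == pytest.approx(1.0 - orig.x_center, abs=1e-9)
        assert flipped.y_center == orig.y_center
        assert flipped.width == orig.width and flipped.height == orig.height

    def test_out_of_range_parameters_rejected(self, sample):
        with pytest.raises(ValueError):
            augment(sample.image, sample.instances, "rotate", angle_deg=20.0)
        with pytest.raises(ValueError):
            augment(sample.image, sample.instances, "shear", shear_rad=0.3)

    def test_boxes_recomputed_from_rotated_masks(self, sample):
        _, insts = augment(sample.image, sample.instances, "rotate", angle_deg=10.0)
        x, y, w, h = box_from_mask(insts[0].mask)
        assert (x, y, w, h) == (
            insts[0].box.x_center,
            insts[0].box.y_center,
            insts[0].box.width,
            insts[0].box.height,
        )


class TestDeduplicate:
    def test_exact_duplicates_removed_first_kept(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, (32, 32, 3))
        distinct = [rng.uniform(0, 1, (32, 32, 3)) for _ in range(3)]
        images = [base, distinct[0], base, base, distinct[1], base, distinct[2], base]
        assert deduplicate(images) == [0, 1, 4, 6]

    def test_all_distinct_retained(self):
        rng = np.random.default_rng(1)
        images = [rng.uniform(0, 1, (32, 32, 3)) for _ in range(6)]
        assert deduplicate(images) == list(range(6))

    def test_empty_input(self):
        assert deduplicate([]) == []


class TestRebalance:
    def test_minority_oversampled_to_target(self, manifest):
        out = rebalance(manifest, {"rbc": 10, "platelet": 10}, seed=0)
        assert out.recount() == {"rbc": 10, "platelet": 10}

    def test_already_balanced_unchanged(self, manifest):
        out = rebalance(manifest, {"rbc": 10, "platelet": 2}, seed=0)
        assert len(out.entries) == len(manifest.entries)

    def test_target_below_current_rejected(self, manifest):
        with pytest.raises(ValueError):
            rebalance(manifest, {"platelet": 1}, seed=0)

    def test_oversamples_differ_from_sources(self, manifest):
        out = rebalance(manifest, {"platelet": 4}, seed=0)
        new_entries = out.entries[len(manifest.entries):]
        source_hashes = {dhash(e.image) for e in manifest.entries}
        for e in new_entries:
            assert e.instances[0].class_id == LabelSchema.id_of("platelet")
            assert dhash(e.image) not in source_hashes


class TestNormalizePixels:
    def test_closed_form_values(self):
        img = np.array([[[0.0], [128.0]], [[255.0], [128.0]]])[..., 0]
        out = normalize_pixels(img[..., None])
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 1, 0] == pytest.approx(128 / 255, abs=1e-9)

    def test_spanning_input_unchanged(self):
        img = np.zeros((2, 2, 3))
        img[0, 0] = [0, 0, 0]
        img[1, 1] = [1, 1, 1]
        img[0, 1] = [0.25, 0.5, 0.75]
        assert np.allclose(normalize_pixels(img), img)

    def test_constant_channel_raises(self):
        img = np.random.default_rng(0).uniform(0, 1, (4, 4, 3))
        img[..., 2] = 0.5
        with pytest.raises(ValueError, match="constant"):
            normalize_pixels(img)
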