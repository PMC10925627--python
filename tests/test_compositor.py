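"""Lesion placement, overlay, ground truth, dataset assembly and I/O."""

import numpy as np
import pandas as pd
import pytest

import lesionbench as lb
from lesionbench.compositor import LesionMap, ground_truth_set
from lesionbench.errors import (
    DegenerateInputError,
    IntegrityError,
    PlacementExhaustedError,
)
from lesionbench.lesion_forge import IRREGULAR, REGULAR


class TestLesionCount:
    def test_range_and_determinism(self):
        rng = np.random.default_rng(0)
        draws = [lb.sample_lesion_count(rng) for _ in range(100)]
        assert set(draws) <= {3, 4, 5}
        rng2 = np.random.default_rng(0)
        assert draws == [lb.sample_lesion_count(rng2) for _ in range(100)]

    def test_uniform_frequencies(self):
        rng = np.random.default_rng(0)
        draws = np.array([lb.sample_lesion_count(rng) for _ in range(3000)])
        se = np.sqrt((1 / 3) * (2 / 3) / 3000)
        for value in (3, 4, 5):
            assert abs((draws == value).mean() - 1 / 3) < 4 * se


class TestPlacement:
    def test_constraints_hold(self, bank, cohort):
        rng = np.random.default_rng(1)
        lmap = lb.place_lesions(bank, REGULAR, 4, cohort[0], rng)
        assert len(lmap.placements) == 4
        assert lmap.support.sum() > 0
        # entire support inside the brain
        assert cohort[0].brain_mask[lmap.support].all()
        assert lmap.pixels.max() <= 0.5 + 1e-12

    def test_supports_disjoint(self, bank, cohort):
        # pixel value count must equal the sum of individual stamp supports
        rng = np.random.default_rng(2)
        lmap = lb.place_lesions(bank, IRREGULAR, 5, cohort[1], rng)
        total = sum(
            bank.irregular[idx].support.sum() for idx, _ in lmap.placements
        )
        assert lmap.support.sum() == total

    def test_deterministic(self, bank, cohort):
        a = lb.place_lesions(bank, REGULAR, 3, cohort[2], np.random.default_rng(7))
        b = lb.place_lesions(bank, REGULAR, 3, cohort[2], np.random.default_rng(7))
        assert np.array_equal(a.pixels, b.pixels)
        assert a.placements == b.placements

    def test_tiny_mask_exhausts(self, bank):
        tiny = lb.BackgroundSlice(
            pixels=np.full((20, 20), 0.3) * np.pad(np.ones((6, 6)), 7),
            brain_mask=np.pad(np.ones((6, 6), bool), 7),
            subject_id="tiny",
        )
        with pytest.raises(PlacementExhaustedError):
            lb.place_lesions(bank, REGULAR, 3, tiny, np.random.default_rng(0), max_attempts=50)


class TestOverlay:
    def test_identity_outside_lesions(self, bank, cohort):
        rng = np.random.default_rng(3)
        lmap = lb.place_lesions(bank, REGULAR, 3, cohort[0], rng)
        x = lb.overlay(cohort[0], lmap)
        outside = ~lmap.support
        assert np.array_equal(x[outside], cohort[0].pixels[outside])
        inside = lmap.support & (cohort[0].pixels > 0)
        assert np.all(x[inside] >= cohort[0].pixels[inside])

    def test_multiplicative_arithmetic(self):
        bg = lb.BackgroundSlice(
            pixels=np.full((4, 4), 0.6),
            brain_mask=np.ones((4, 4), bool),
            subject_id="s",
        )
        pix = np.zeros((4, 4))
        pix[1, 1] = 0.5
        lmap = LesionMap(pixels=pix, placements=[])
        x = lb.overlay(bg, lmap)
        assert x[1, 1] == pytest.approx(0.9)
        assert x[0, 0] == pytest.approx(0.6)

    def test_black_background_stays_black(self):
        bg = lb.BackgroundSlice(
            pixels=np.pad(np.full((2, 2), 0.5), 1),
            brain_mask=np.pad(np.ones((2, 2), bool), 1),
            subject_id="s",
        )
        pix = np.zeros((4, 4))
        pix[0, 0] = 0.5  # lesion over black exterior
        x = lb.overlay(bg, lmap := LesionMap(pixels=pix, placements=[]))
        assert x[0, 0] == 0.0
        del lmap

    def test_additive_variant(self):
        bg = lb.BackgroundSlice(
            pixels=np.full((2, 2), 0.6),
            brain_mask=np.ones((2, 2), bool),
            subject_id="s",
        )
        pix = np.full((2, 2), 0.5)
        x = lb.overlay(bg, LesionMap(pixels=pix, placements=[]), mode="additive")
        assert np.allclose(x, 1.0)  # 0.6 + 0.5 clipped

    def test_shape_mismatch(self):
        bg = lb.BackgroundSlice(
            pixels=np.full((4, 4), 0.5),
            brain_mask=np.ones((4, 4), bool),
            subject_id="s",
        )
        with pytest.raises(ValueError):
            lb.overlay(bg, LesionMap(pixels=np.zeros((5, 5)), placements=[]))


class TestGroundTruth:
    def test_support_only_dependence(self):
        pix = np.zeros((6, 6))
        pix[2:4, 2:4] = 0.3
        a = lb.ground_truth(LesionMap(pixels=pix, placements=[]))
        b = lb.ground_truth(LesionMap(pixels=pix * 0.5, placements=[]))
        assert np.array_equal(a, b)
        assert a.sum() == 4

    def test_set_and_mask_agree(self):
        rng = np.random.default_rng(4)
        pix = np.where(rng.uniform(size=(8, 8)) > 0.7, 0.4, 0.0)
        lmap = LesionMap(pixels=pix, placements=[])
        mask = lb.ground_truth(lmap)
        pixels = ground_truth_set(lmap)
        assert pixels == {tuple(p) for p in np.argwhere(mask)}

    def test_empty_support_degenerate(self):
        with pytest.raises(DegenerateInputError):
            lb.ground_truth(LesionMap(pixels=np.zeros((4, 4)), placements=[]))


class TestDataset:
    def test_exact_balance_and_lesion_counts(self, dataset):
        labels = [s.label for s in dataset.samples]
        assert labels.count(REGULAR) == labels.count(IRREGULAR) == 30
        for s in dataset.samples:
            assert 3 <= len(s.lesion_map.placements) <= 5
            assert s.n_ground_truth > 0

    def test_image_background_consistency(self, dataset, cohort):
        by_id = {c.subject_id: c for c in cohort}
        for s in dataset.samples[:10]:
            bg = by_id[s.subject_id]
            outside = ~s.ground_truth
            assert np.array_equal(s.image[outside], bg.pixels[outside])

    def test_deterministic(self, cohort, bank):
        a = lb.build_dataset(cohort, bank, 10, seed=5)
        b = lb.build_dataset(cohort, bank, 10, seed=5)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.image, sb.image)
            assert sa.subject_id == sb.subject_id


class TestSplits:
    def test_subject_fractions(self, dataset):
        subj_split = {}
        for s in dataset.samples:
            subj_split.setdefault(s.subject_id, set()).add(
                dataset.splits[s.sample_id]
            )
        # no subject in two splits
        assert all(len(v) == 1 for v in subj_split.values())
        counts = {"train": 0, "val": 0, "test": 0}
        for v in subj_split.values():
            counts[next(iter(v))] += 1
        assert counts == {"train": 7, "val": 2, "test": 3}

    def test_per_split_class_balance(self, dataset):
        for split in ("train", "val", "test"):
            labels = [s.label for s in dataset.subset(split)]
            assert abs(labels.count(REGULAR) - labels.count(IRREGULAR)) <= 1

    def test_deterministic(self, cohort, bank):
        a = lb.split_by_subject(lb.build_dataset(cohort, bank, 12, seed=1), seed=2)
        b = lb.split_by_subject(lb.build_dataset(cohort, bank, 12, seed=1), seed=2)
        assert a.splits == b.splits

    def test_too_few_subjects(self, bank):
        cohort = lb.phantom_cohort(2, seed=0, size=64)
        ds = lb.build_dataset(cohort, bank, 6, seed=0)
        with pytest.raises(ValueError):
            lb.split_by_subject(ds)


class TestDatasetIO:
    def test_round_trip(self, dataset, tmp_path):
        lb.write_dataset(dataset, tmp_path)
        loaded = lb.read_dataset(tmp_path)
        assert len(loaded.samples) == len(dataset.samples)
        assert loaded.splits == dataset.splits
        for a, b in zip(dataset.samples, loaded.samples):
            assert a.label == b.label
            assert np.array_equal(a.ground_truth, b.ground_truth)
            assert np.allclose(a.image, b.image, atol=1e-4)
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert (manifest.n_ground_truth > 0).all()

    def test_tamper_detected(self, dataset, tmp_path):
        lb.write_dataset(dataset, tmp_path)
        victim = next((tmp_path / "masks").iterdir())
        victim.write_bytes(b"corrupted")
        with pytest.raises(IntegrityError):
            lb.read_dataset(tmp_path)

    def test_empty_directory(self, tmp_path):
        with pytest.raises(IntegrityError):
            lb.read_dataset(tmp_path)
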