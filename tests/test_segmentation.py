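"""Segmentation: preprocessing, DICE loss vs brute force, grouped splits,
training mechanics, and the deterministic reference segmenter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipscreen.errors import DegenerateInputError, ValidationError
from hipscreen.phantom import LabelMask, PhantomDataset, make_dataset, render_frame
from hipscreen.segmentation import (
    ModelConfig,
    TrainConfig,
    UNet,
    dice_loss,
    grouped_split,
    load_model,
    preprocess,
    reference_segment,
    save_model,
    segment,
    train,
)
from hipscreen.segmentation.ops import dice_per_class
from conftest import clean_spec


def brute_force_dice_loss(pred, truth_labels, eps=1.0):
    """Independent pixel-count evaluation of the soft DICE loss."""
    dices = []
    for c in (1, 2):
        inter = pred_sum = truth_sum = 0.0
        for i in range(truth_labels.shape[0]):
            for j in range(truth_labels.shape[1]):
                t = 1.0 if truth_labels[i, j] == c else 0.0
                inter += pred[c, i, j] * t
                pred_sum += pred[c, i, j]
                truth_sum += t
        dices.append((2 * inter + eps) / (pred_sum + truth_sum + eps))
    return 1.0 - sum(dices) / len(dices)


def one_hot(labels, n=3):
    return (np.arange(n)[:, None, None] == labels[None]).astype(float)


class TestPreprocess:
    def test_constant_image_normalizes_to_one(self):
        out = preprocess(np.full((100, 80), 0.4), input_size_px=64)
        assert out.shape == (64, 64)
        assert np.allclose(out, 1.0)

    def test_correctly_sized_normalized_image_unchanged(self):
        img = np.random.default_rng(0).random((256, 256))
        img = img / img.mean()
        out = preprocess(img, input_size_px=256)
        assert np.allclose(out, img, atol=1e-6)

    def test_downsampling_preserves_mean(self):
        img = np.random.default_rng(1).random((512, 512))
        out = preprocess(img, input_size_px=256)
        assert out.shape == (256, 256)
        assert abs(out.mean() - 1.0) < 1e-3

    def test_zero_image_raises(self):
        with pytest.raises(DegenerateInputError):
            preprocess(np.zeros((64, 64)))

    def test_idempotent_on_normalized_sized_input(self):
        img = np.random.default_rng(2).random((128, 128)) + 0.5
        once = preprocess(img, input_size_px=128)
        twice = preprocess(once, input_size_px=128)
        assert np.allclose(once, twice, atol=1e-6)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self, clean_frame):
        _, truth = clean_frame
        loss = dice_loss(one_hot(truth.label_mask.labels), truth.label_mask)
        assert loss < 1e-4

    def test_disjoint_foregrounds_near_one(self):
        truth = np.zeros((32, 32), dtype=np.uint8)
        truth[:8, :8] = 1
        truth[:8, 8:16] = 2
        pred_labels = np.zeros((32, 32), dtype=np.uint8)
        pred_labels[24:, :8] = 1
        pred_labels[24:, 8:16] = 2
        loss = dice_loss(one_hot(pred_labels), LabelMask(truth))
        assert loss > 0.97

    def test_half_coverage_rectangle_is_one_third(self):
        """Hard pred covering half a truth rectangle, no false positives:
        per-class DICE = 2*(A/2)/(A/2 + A) = 2/3, so loss = 1/3."""
        truth = np.zeros((64, 64), dtype=np.uint8)
        truth[10:30, 10:50] = 1
        pred_labels = np.zeros_like(truth)
        pred_labels[10:20, 10:50] = 1
        loss = dice_loss(one_hot(pred_labels), LabelMask(truth), classes=(1,), eps=0.0)
        assert loss == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError, match="match"):
            dice_loss(np.zeros((3, 16, 16)), LabelMask(np.zeros((32, 32), dtype=np.uint8)))

    def test_matches_brute_force_on_random_pairs(self, rng):
        """Vectorized loss equals the pixel-count brute force within 1e-6."""
        for _ in range(100):
            truth = rng.integers(0, 3, (32, 32)).astype(np.uint8)
            pred = rng.random((3, 32, 32))
            pred /= pred.sum(axis=0, keepdims=True)
            assert dice_loss(pred, LabelMask(truth)) == pytest.approx(
                brute_force_dice_loss(pred, truth), abs=1e-6)


class TestGroupedSplit:
    def test_ten_subjects_80_20(self):
        ids = [f"S{i}" for i in range(10) for _ in range(3)]
        tr, va = grouped_split(ids, (0.8, 0.2), seed=0)
        assert len(tr) == 8 and len(va) == 2
        assert not set(tr) & set(va)

    def test_deterministic(self):
        ids = [f"S{i}" for i in range(20)]
        assert grouped_split(ids, seed=5) == grouped_split(ids, seed=5)

    def test_unequal_frame_counts_still_subject_disjoint(self):
        ids = ["A"] * 50 + ["B"] * 1 + ["C"] * 7 + ["D"] * 3 + ["E"] * 9
        tr, va = grouped_split(ids, (0.8, 0.2), seed=1)
        assert set(tr) | set(va) == {"A", "B", "C", "D", "E"}
        assert not set(tr) & set(va)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValidationError, match="2 subjects"):
            grouped_split(["A", "A", "A"])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(n_subjects=st.integers(2, 40),
           frames=st.lists(st.integers(1, 5), min_size=2, max_size=40),
           seed=st.integers(0, 1000))
    def test_never_leaks_a_subject(self, n_subjects, frames, seed):
        ids = [f"S{i}" for i in range(n_subjects)
               for _ in range(frames[i % len(frames)])]
        tr, va = grouped_split(ids, (0.8, 0.2), seed=seed)
        assert not set(tr) & set(va)
        assert set(tr) | set(va) == set(ids)
        assert len(va) >= 1 and len(tr) >= 1


def tiny_dataset(n_subjects=8, seed=0):
    return make_dataset(n_subjects, frames_per_subject=2, seed=seed,
                        image_size_px=64, speckle_strength=0.02)


def tiny_configs(epochs=2):
    return (ModelConfig(input_size_px=64, depth=2, base_channels=4),
            TrainConfig(epochs=epochs, batch_size=4, learning_rate=1e-3, seed=0))


class TestTraining:
    def test_report_structure_and_selection(self):
        mc, tc = tiny_configs(epochs=3)
        model, report = train(mc, tc, tiny_dataset())
        assert len(report.epochs) == 3
        dices = [e["val_dice"] for e in report.epochs]
        assert report.selected_epoch == int(np.argmax(dices)) + 1
        assert report.selected_val_dice == max(dices)
        assert model.trained
        assert report.model_checksum == model.checksum()

    def test_single_epoch_selected(self):
        mc, tc = tiny_configs(epochs=1)
        _, report = train(mc, tc, tiny_dataset())
        assert report.selected_epoch == 1

    def test_same_seed_reproducible(self):
        mc, tc = tiny_configs(epochs=2)
        _, r1 = train(mc, tc, tiny_dataset())
        _, r2 = train(mc, tc, tiny_dataset())
        assert r1.epochs == r2.epochs
        assert r1.model_checksum == r2.model_checksum

    def test_training_beats_untrained_model(self):
        mc, tc = tiny_configs(epochs=3)
        ds = tiny_dataset()
        model, report = train(mc, tc, ds)
        assert report.epochs[-1]["train_loss"] < report.epochs[0]["train_loss"]

    def test_missing_foreground_class_aborts(self):
        ds = tiny_dataset()
        gutted = [LabelMask(np.where(m.labels == 2, 0, m.labels)) for m in ds.masks]
        bad = PhantomDataset(images=ds.images, masks=gutted, table=ds.table)
        with pytest.raises(ValidationError, match="foreground class"):
            train(*tiny_configs(), bad)


@pytest.fixture(scope="module")
def trained():
    mc, tc = tiny_configs(epochs=3)
    return train(mc, tc, tiny_dataset())[0]


class TestSegment:
    def test_labels_and_probability_normalization(self, trained):
        img, _ = render_frame(clean_spec(size=64, radius=14.0))
        mask, probs = segment(trained, img)
        assert set(np.unique(mask.labels)) <= {0, 1, 2}
        assert mask.shape == img.shape
        assert np.abs(probs.sum(axis=0) - 1.0).max() < 1e-5

    def test_untrained_model_rejected(self):
        model = UNet(ModelConfig(input_size_px=64, depth=2, base_channels=4))
        with pytest.raises(ValidationError, match="train"):
            segment(model, np.random.default_rng(0).random((64, 64)))

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_model(trained, path)
        restored = load_model(path)
        img, _ = render_frame(clean_spec(size=64, radius=14.0))
        _, p1 = segment(trained, img)
        _, p2 = segment(restored, img)
        assert np.array_equal(p1, p2)
        assert restored.config == trained.config


class TestReferenceSegmenter:
    def test_noise_free_has_both_landmarks(self, clean_frame):
        image, _ = clean_frame
        mask = reference_segment(image)
        assert {1, 2} <= mask.classes_present()

    def test_out_of_plane_frame_incomplete(self):
        image, _ = render_frame(clean_spec(), plane_offset=30.0)
        mask = reference_segment(image)
        assert 2 not in mask.classes_present()

    def test_dice_vs_truth_on_noise_free_phantoms(self, rng):
        for _ in range(20):
            spec = clean_spec(alpha=float(rng.uniform(40, 75)),
                              fhc=float(rng.uniform(0.2, 0.8)),
                              radius=float(rng.uniform(24, 34)))
            image, truth = render_frame(spec)
            scores = dice_per_class(reference_segment(image).labels,
                                    truth.label_mask.labels)
            assert scores[1] >= 0.9 and scores[2] >= 0.9
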