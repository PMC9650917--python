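"""Tests for frame sampling, the video classifier, and the six-metric
evaluation suite (with scikit-learn as the independent oracle)."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from sonovid.aggregator import AttentionConfig, MultiMetaAttention
from sonovid.encoder import Encoder, EncoderConfig
from sonovid.synthio import ClipParams, DatasetIndex, IndexRecord, VideoSequence, generate_clip
from sonovid.trainer import (
    Metrics,
    TrainConfig,
    VideoClassifier,
    compute_metrics,
    predict,
    roc_curve,
    sample_frames,
    train_classifier,
)


class TestSampleFrames:
    def test_evenly_spaced_matches_index_arithmetic(self):
        clip = generate_clip(ClipParams(T=32, H=16, W=16, seed=0))
        sub = sample_frames(clip, T=16)
        expected_idx = [round(k * 31 / 15) for k in range(16)]
        assert np.array_equal(sub.frames, clip.frames[expected_idx])

    def test_short_clip_repeats_every_frame(self):
        clip = generate_clip(ClipParams(T=5, H=16, W=16, seed=1))
        sub = sample_frames(clip, T=16)
        assert len(sub) == 16
        used = {
            next(i for i in range(5) if np.array_equal(f, clip.frames[i]))
            for f in sub.frames
        }
        assert used == {0, 1, 2, 3, 4}

    def test_equal_length_is_identity(self):
        clip = generate_clip(ClipParams(T=16, H=16, W=16, seed=2))
        assert np.array_equal(sample_frames(clip, T=16).frames, clip.frames)

    def test_single_frame_request(self):
        clip = generate_clip(ClipParams(T=7, H=16, W=16, seed=3))
        assert len(sample_frames(clip, T=1)) == 1

    def test_random_jitter_draws_one_frame_per_bin(self):
        clip = generate_clip(ClipParams(T=16, H=16, W=16, seed=4))
        sub = sample_frames(clip, T=4, mode="random_jitter", seed=9)
        idx = [
            next(i for i in range(16) if np.array_equal(f, clip.frames[i]))
            for f in sub.frames
        ]
        bins = [i // 4 for i in idx]
        assert bins == [0, 1, 2, 3]

    def test_invalid_t_rejected(self):
        clip = generate_clip(ClipParams(T=4, H=16, W=16, seed=5))
        with pytest.raises(ValueError, match="T"):
            sample_frames(clip, T=0)


@pytest.fixture(scope="module")
def tiny_model():
    encoder = Encoder(EncoderConfig.tiny(seed=0))
    attention = MultiMetaAttention(AttentionConfig(feature_dim=128, seed=1))
    return VideoClassifier(encoder, attention, seed=2)


class TestPredict:
    def test_score_is_probability(self, tiny_model):
        clip = generate_clip(ClipParams(T=3, H=64, W=64, class_label="malignant", seed=0))
        pred = predict(tiny_model, clip)
        assert 0.0 <= pred.malignant_score <= 1.0
        assert pred.label in ("benign", "malignant")
        assert (pred.label == "malignant") == (pred.malignant_score >= 0.5)

    @pytest.mark.parametrize("t", [1, 64])
    def test_arbitrary_sequence_lengths_accepted(self, tiny_model, t):
        clip = generate_clip(ClipParams(T=t, H=64, W=64, seed=1))
        assert np.isfinite(predict(tiny_model, clip).malignant_score)

    def test_frame_order_shuffle_leaves_prediction_unchanged(self, tiny_model, rng):
        clip = generate_clip(ClipParams(T=8, H=64, W=64, seed=2))
        shuffled = VideoSequence(
            id=clip.id, frames=clip.frames[rng.permutation(8)], label=clip.label
        )
        a, b = predict(tiny_model, clip), predict(tiny_model, shuffled)
        assert a.label == b.label
        assert np.isclose(a.malignant_score, b.malignant_score, atol=1e-5)


def _index_for(clips, test_ids=()):
    records = [IndexRecord(c.id, c.label, len(c), c.id) for c in clips]
    assignment = {c.id: ("test" if c.id in test_ids else "train") for c in clips}
    return DatasetIndex(records=records, split_assignment=assignment)


class TestTrainClassifier:
    def test_single_class_split_rejected(self):
        clips = [generate_clip(ClipParams(T=2, H=32, W=32, class_label="benign", seed=s)) for s in range(2)]
        for i, c in enumerate(clips):
            c.id = f"benign_{i}"
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(clips, _index_for(clips), Encoder(EncoderConfig.tiny(seed=0)), TrainConfig.tiny())

    def test_mean_pooling_degenerate_model_still_trains(self, small_clips):
        # zeroed attention cascade = average pooling; training must proceed
        cfg = TrainConfig(epochs=1, learning_rate=0.01, sample_length=2, batch_size=4, seed=0)
        encoder = Encoder(EncoderConfig.tiny(seed=0))
        index = _index_for(small_clips, test_ids={small_clips[0].id, small_clips[-1].id})
        model, history = train_classifier(small_clips, index, encoder, cfg)
        model.attention.zero_weights()
        pred = predict(model, small_clips[0])
        assert np.isfinite(pred.malignant_score)
        assert len(history) == 1 and np.isfinite(history[0]["train_loss"])


class TestComputeMetrics:
    def test_hand_computed_confusion_matrix(self):
        # TP=9, FN=1, TN=8, FP=2 at threshold 0.5
        scores = [0.9] * 9 + [0.1] + [0.2] * 8 + [0.8] * 2
        labels = [1] * 10 + [0] * 10
        m = compute_metrics(scores, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (9, 1, 8, 2)
        assert np.isclose(m.sensitivity, 0.900)
        assert np.isclose(m.specificity, 0.800)
        assert np.isclose(m.accuracy, 0.850)
        assert np.isclose(m.f1, 2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9), atol=1e-6)

    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.average_precision == 1.0

    def test_tied_scores_give_half_auc(self):
        m = compute_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert np.isclose(m.auc, 0.5)

    def test_single_class_flags_auc_ap_undefined(self):
        m = compute_metrics([0.2, 0.9], [1, 1])
        assert not m.auc_defined and not m.ap_defined
        assert np.isnan(m.auc) and np.isnan(m.average_precision)

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            m = compute_metrics(scores, labels)
            assert np.isclose(m.auc, roc_auc_score(labels, scores), atol=1e-10)
            assert np.isclose(m.average_precision, average_precision_score(labels, scores), atol=1e-10)
            # accuracy consistent with thresholded predictions
            pred = (scores >= 0.5).astype(int)
            assert np.isclose(m.accuracy, (pred == labels).mean())

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        a = compute_metrics(scores, labels).auc
        b = compute_metrics(1 / (1 + np.exp(-7 * scores)), labels).auc
        assert np.isclose(a, b, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.5], [1, 0])


class TestRocCurve:
    def test_endpoints_and_monotonicity(self, rng):
        labels = np.array([1, 1, 0, 0, 1, 0])
        scores = rng.random(6)
        pts = roc_curve(scores, labels)
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_perfect_ranking_passes_through_corner(self):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(np.allclose(p, [0, 1]) for p in pts)

    def test_trapezoid_area_equals_mann_whitney_auc(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)
            pts = roc_curve(scores, labels)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert np.isclose(area, compute_metrics(scores, labels).auc, atol=1e-9)

    def test_reversed_scores_complement_area(self, rng):
        labels = np.array([1, 0, 1, 0, 1, 1, 0])
        scores = rng.random(7)
        a = np.trapezoid(*roc_curve(scores, labels).T[::-1])
        b = np.trapezoid(*roc_curve(-scores, labels).T[::-1])
        assert np.isclose(a, 1 - b, atol=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.9], [1, 1])
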