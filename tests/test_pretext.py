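"""Tests for the contrastive stage: augmentation family, view sampling,
projection, NT-Xent loss and the pretraining loop."""

import dataclasses

import numpy as np
import pytest

from sonovid.nn import Tensor
from sonovid.pretext import (
    AugmentConfig,
    PretrainConfig,
    ProjectionHead,
    augment,
    nt_xent_loss,
    nt_xent_loss_array,
    pretrain,
    project,
    sample_pretext_batch,
)


@pytest.fixture()
def frame(rng):
    return rng.random((48, 48)).astype(np.float32)


def unit_rows(a):
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def pair_involution(k):
    p = np.arange(2 * k)
    p[0::2] += 1
    p[1::2] -= 1
    return p


class TestAugment:
    def test_all_transforms_disabled_is_identity(self, frame):
        out = augment(frame, AugmentConfig.identity(), seed=5)
        assert np.array_equal(out, frame)

    def test_seeded_determinism(self, frame):
        cfg = AugmentConfig()
        assert np.array_equal(augment(frame, cfg, 11), augment(frame, cfg, 11))

    def test_seed_sweep_stays_in_range_and_varies(self, frame):
        cfg = AugmentConfig()
        outs = [augment(frame, cfg, s) for s in range(100)]
        for out in outs:
            assert out.shape == frame.shape
            assert out.min() >= 0.0 and out.max() <= 1.0
        distinct = {out.tobytes() for out in outs}
        assert len(distinct) >= 2

    def test_degenerate_crop_range_rejected(self):
        with pytest.raises(ValueError, match="crop_scale_range"):
            AugmentConfig(crop_scale_range=(0.9, 0.5))

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            AugmentConfig(enabled=("flip", "sharpen"))


class TestSamplePretextBatch:
    def test_view_count_and_pair_structure(self, small_clips):
        views, pair = sample_pretext_batch(small_clips, N=2, M=3, seed=0)
        assert views.shape[0] == 12
        assert np.all(pair[pair] == np.arange(12))  # involution
        assert np.all(pair != np.arange(12))  # no fixed points

    def test_same_seed_reproduces_views(self, small_clips):
        a, _ = sample_pretext_batch(small_clips, N=3, M=2, seed=7)
        b, _ = sample_pretext_batch(small_clips, N=3, M=2, seed=7)
        assert np.array_equal(a, b)

    def test_every_clip_sampled_over_many_draws(self, small_clips):
        # brute-force tally over seeded draws: with N=4 of 8 clips each draw,
        # 200 draws must cover all clips many times over
        counts = np.zeros(len(small_clips))
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ids = rng.choice(len(small_clips), size=4, replace=False)
            counts[ids] += 1
        assert counts.min() > 0
        # and the sampler itself draws without replacement within a batch
        views, _ = sample_pretext_batch(small_clips, N=8, M=1, seed=3)
        assert views.shape[0] == 16

    def test_oversampling_clips_rejected(self, small_clips):
        with pytest.raises(ValueError, match="N=9"):
            sample_pretext_batch(small_clips, N=9, M=1, seed=0)

    def test_same_video_mode_pairs_distinct_frames(self, small_clips):
        views, pair = sample_pretext_batch(
            small_clips, N=4, M=2, seed=1, positive_mode="same_video"
        )
        assert views.shape[0] == 16
        assert np.all(pair[pair] == np.arange(16))


class TestProjection:
    def test_output_is_unit_norm(self, rng):
        head = ProjectionHead(16, 16, 8, seed=0)
        z = project(rng.standard_normal((5, 16)).astype(np.float32), head)
        assert z.shape == (5, 8)
        assert np.allclose(np.linalg.norm(z, axis=1), 1.0, atol=1e-6)

    def test_zero_weights_are_epsilon_guarded(self):
        head = ProjectionHead(4, 4, 4, seed=0)
        for layer in (head.fc1, head.fc2):
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        z = project(np.ones(4, dtype=np.float32), head)
        assert np.isfinite(z).all()  # zero vector maps to zero, not NaN

    def test_configured_output_dimension(self, rng):
        head = ProjectionHead(128, 128, 64, seed=0)
        assert project(rng.standard_normal(128).astype(np.float32), head).shape == (64,)

    def test_dimension_mismatch_raises(self, rng):
        head = ProjectionHead(16, 16, 8, seed=0)
        with pytest.raises(ValueError, match="dim"):
            project(rng.standard_normal(12).astype(np.float32), head)


class TestNTXent:
    def test_identical_embeddings_closed_form(self):
        z = np.tile(unit_rows(np.ones((1, 8))), (4, 1)).astype(np.float32)
        for tau in (0.1, 0.5, 2.0):
            loss = nt_xent_loss_array(z, pair_involution(2), tau)
            assert np.isclose(loss, np.log(3.0), atol=1e-5)

    def test_orthogonal_negatives_closed_form(self):
        z = np.zeros((4, 4), dtype=np.float32)
        z[0, 0] = z[1, 0] = 1.0  # pair 1 identical
        z[2, 1] = z[3, 1] = 1.0  # pair 2 identical, orthogonal to pair 1
        loss = nt_xent_loss_array(z, pair_involution(2), 0.5)
        assert np.isclose(loss, np.log(1 + 2 * np.exp(-2.0)), atol=1e-5)

    def test_matches_double_loop_oracle(self, rng):
        for k in (2, 4, 8):
            z = unit_rows(rng.standard_normal((2 * k, 16))).astype(np.float32)
            pair = pair_involution(k)
            tau = 0.37
            expected = 0.0
            for i in range(2 * k):
                num = np.exp(z[i] @ z[pair[i]] / tau)
                den = sum(np.exp(z[i] @ z[j] / tau) for j in range(2 * k) if j != i)
                expected += -np.log(num / den)
            expected /= 2 * k
            assert np.isclose(nt_xent_loss_array(z, pair, tau), expected, atol=1e-6)

    def test_invariant_under_pair_preserving_permutation(self, rng):
        k = 6
        z = unit_rows(rng.standard_normal((2 * k, 8))).astype(np.float32)
        pair = pair_involution(k)
        base = nt_xent_loss_array(z, pair, 0.5)
        order = np.arange(k)
        rng.shuffle(order)
        perm = np.empty(2 * k, dtype=int)
        perm[0::2], perm[1::2] = 2 * order, 2 * order + 1
        assert np.isclose(nt_xent_loss_array(z[perm], pair, 0.5), base, atol=1e-5)

    def test_lower_bound_for_unit_vectors(self, rng):
        for k in (2, 5, 8):
            z = unit_rows(rng.standard_normal((2 * k, 12))).astype(np.float32)
            tau = 0.5
            bound = np.log(1 + (2 * k - 2) * np.exp(-2.0 / tau))
            assert nt_xent_loss_array(z, pair_involution(k), tau) >= bound - 1e-6

    def test_parameter_validation(self, rng):
        z = unit_rows(rng.standard_normal((4, 4))).astype(np.float32)
        with pytest.raises(ValueError, match="temperature"):
            nt_xent_loss(Tensor(z), pair_involution(2), 0.0)
        with pytest.raises(ValueError, match="involution"):
            nt_xent_loss(Tensor(z), np.array([0, 1, 2, 3]), 0.5)


class TestPretrain:
    def test_smoke_run_reduces_loss(self, small_clips):
        from sonovid.encoder import Encoder, EncoderConfig

        encoder = Encoder(EncoderConfig.tiny(seed=0))
        cfg = dataclasses.replace(PretrainConfig.tiny(seed=0), epochs=5)
        head, history, opt_state = pretrain(small_clips, encoder, cfg)
        assert "velocity" in opt_state
        assert len(history) == 5
        assert history[-1] < history[0]

    def test_fixed_seed_reproduces_history(self, small_clips):
        from sonovid.encoder import Encoder, EncoderConfig

        cfg = dataclasses.replace(PretrainConfig.tiny(seed=0), epochs=2)
        h1 = pretrain(small_clips, Encoder(EncoderConfig.tiny(seed=0)), cfg)[1]
        h2 = pretrain(small_clips, Encoder(EncoderConfig.tiny(seed=0)), cfg)[1]
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        from sonovid.encoder import Encoder, EncoderConfig

        with pytest.raises(ValueError, match="empty"):
            pretrain([], Encoder(EncoderConfig.tiny()), PretrainConfig.tiny())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PretrainConfig(temperature=-1.0)
        with pytest.raises(ValueError):
            PretrainConfig(optimizer="adam")
        with pytest.raises(ValueError):
            PretrainConfig(positive_mode="cluster")
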