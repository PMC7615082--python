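"""BYOL pre-training: augmentations, loss algebra, EMA, gradient isolation."""

import datetime as dt

import numpy as np
import pytest

from hibehrt import nn
from hibehrt.byol import (AugmentationConfig, augment_ehr, augment_segments,
                          build_byol, byol_loss, crop_visits, ema_update,
                          mask_tokens, pretrain, pretrain_step)
from hibehrt.model import small_hier_config
from hibehrt.nn import Tensor
from hibehrt.records import CohortExample, EncodedSequence, Vocabulary


def make_encoded(n=40, max_len=64, n_visits=10, seed=0):
    rng = np.random.default_rng(seed)
    t = np.zeros(max_len, dtype=np.int64)
    t[:n] = rng.integers(4, 30, size=n)
    visits = np.sort(rng.integers(0, n_visits, size=n))
    p = np.zeros(max_len, dtype=np.int64)
    p[:n] = visits
    s = np.zeros(max_len, dtype=np.int64)
    s[:n] = visits % 2
    a = np.zeros(max_len, dtype=np.int64)
    a[:n] = 50
    m = np.zeros(max_len, dtype=np.int64)
    m[:n] = 1
    return EncodedSequence(t, a, s, p, m, n)


class TestAugmentationConfig:
    def test_branch_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AugmentationConfig(zero_prob=0.5, noise_prob=0.4)

    def test_probabilities_in_range(self):
        with pytest.raises(ValueError):
            AugmentationConfig(crop_prob=1.5)


class TestEhrAugmentation:
    def test_identity_when_disabled(self):
        enc = make_encoded()
        out = augment_ehr(enc, AugmentationConfig(crop_prob=0.0,
                                                  token_mask_prob=0.0),
                          np.random.default_rng(0))
        np.testing.assert_array_equal(out.token_ids, enc.token_ids)
        assert out.true_length == enc.true_length

    def test_full_mask_replaces_every_real_token(self):
        enc = make_encoded()
        out = mask_tokens(enc, 1.0, np.random.default_rng(0))
        assert np.all(out.token_ids[:out.true_length] == Vocabulary.MASK)
        assert np.all(out.token_ids[out.true_length:] == Vocabulary.PAD)

    def test_mask_rate_matches_binomial(self):
        """Empirical mask fraction within 3 SE of the nominal 20%."""
        enc = make_encoded(n=60)
        rng = np.random.default_rng(1)
        n_tokens = 60 * 2000
        hits = sum(int((mask_tokens(enc, 0.2, rng).token_ids[:60]
                        == Vocabulary.MASK).sum()) for _ in range(2000))
        frac = hits / n_tokens
        se = np.sqrt(0.2 * 0.8 / n_tokens)
        assert abs(frac - 0.2) < 3 * se

    def test_crop_is_contiguous_visit_interval(self):
        enc = make_encoded(n=50, n_visits=12, seed=3)
        rng = np.random.default_rng(4)
        for _ in range(50):
            out = crop_visits(enc, rng)
            assert out.true_length >= 1
            pos = out.position_ids[:out.true_length]
            assert pos[0] == 0                      # re-based visit index
            assert np.all(np.diff(pos) >= 0)
            np.testing.assert_array_equal(
                out.segment_ids[:out.true_length], pos % 2)

    def test_crop_preserves_ages_of_kept_records(self):
        enc = make_encoded(n=30, seed=5)
        enc.age_ids[:30] = np.arange(30) + 40
        out = crop_visits(enc, np.random.default_rng(6))
        kept = out.true_length
        # the kept ages form a contiguous slice of the original ages
        orig = enc.age_ids[:30]
        sub = out.age_ids[:kept]
        starts = [i for i in range(31 - kept)
                  if np.array_equal(orig[i:i + kept], sub)]
        assert starts


class TestSegmentAugmentation:
    def test_disabled_returns_input(self):
        reps = Tensor(np.random.default_rng(0).normal(size=(2, 5, 8)
                                                      ).astype(np.float32))
        cfg = AugmentationConfig(segment_aug_prob=0.0)
        out, aug = augment_segments(reps, np.ones((2, 5)), cfg,
                                    np.random.default_rng(1))
        assert aug.sum() == 0
        np.testing.assert_array_equal(out.data, reps.data)

    def test_all_zeroed_when_forced(self):
        reps = Tensor(np.ones((2, 5, 8), dtype=np.float32))
        cfg = AugmentationConfig(segment_aug_prob=1.0, zero_prob=1.0,
                                 noise_prob=0.0)
        out, aug = augment_segments(reps, np.ones((2, 5)), cfg,
                                    np.random.default_rng(1))
        assert aug.all()
        np.testing.assert_array_equal(out.data, 0)

    def test_padding_segments_never_augmented(self):
        reps = Tensor(np.ones((1, 4, 8), dtype=np.float32))
        mask = np.array([[1, 1, 0, 0]])
        cfg = AugmentationConfig(segment_aug_prob=1.0)
        _, aug = augment_segments(reps, mask, cfg, np.random.default_rng(2))
        assert not aug[0, 2:].any()

    def test_augmented_count_matches_binomial(self):
        rng = np.random.default_rng(3)
        reps = Tensor(np.ones((1, 20, 4), dtype=np.float32))
        cfg = AugmentationConfig(segment_aug_prob=0.5)
        total = sum(int(augment_segments(reps, np.ones((1, 20)), cfg,
                                         rng)[1].sum())
                    for _ in range(2000))
        n = 20 * 2000
        se = np.sqrt(0.25 / n)
        assert abs(total / n - 0.5) < 3 * se


class TestLossAlgebra:
    def test_identical_vectors_zero_loss(self):
        v = np.random.default_rng(0).normal(size=(1, 3, 8)).astype(np.float32)
        aug = np.ones((1, 3))
        loss = byol_loss(Tensor(v), v, aug)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_antipodal_vectors_loss_four(self):
        v = np.ones((1, 1, 4), dtype=np.float32)
        loss = byol_loss(Tensor(v), -v, np.ones((1, 1)))
        assert float(loss.data) == pytest.approx(4.0, abs=1e-5)

    def test_orthogonal_three_timesteps_loss_six(self):
        on = np.zeros((1, 3, 4), dtype=np.float32)
        tg = np.zeros((1, 3, 4), dtype=np.float32)
        on[0, :, 0] = 1.0
        tg[0, :, 1] = 1.0
        loss = byol_loss(Tensor(on), tg, np.ones((1, 3)))
        assert float(loss.data) == pytest.approx(6.0, abs=1e-5)

    def test_per_timestep_loss_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            on = rng.normal(size=(2, 4, 6)).astype(np.float32)
            tg = rng.normal(size=(2, 4, 6)).astype(np.float32)
            aug = np.zeros((2, 4))
            aug[0, 1] = 1
            loss = float(byol_loss(Tensor(on), tg, aug).data)
            assert 0.0 <= loss <= 4.0 + 1e-5

    def test_zero_norm_rejected(self):
        on = np.zeros((1, 1, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            byol_loss(Tensor(on), np.ones((1, 1, 4), dtype=np.float32),
                      np.ones((1, 1)))

    def test_empty_augmentation_contributes_zero(self):
        v = np.ones((1, 2, 4), dtype=np.float32)
        loss = byol_loss(Tensor(v), v, np.zeros((1, 2)))
        assert float(loss.data) == 0.0


class TestEMA:
    def _state(self, tau):
        cfg = small_hier_config(30, max_len=96)
        return build_byol(cfg, tau=tau, seed=0)

    def test_tau_one_freezes_target(self):
        state = self._state(1.0)
        before = state.target_encoder.state_dict()
        for p in state.online_encoder.parameters():
            p.data += 1.0
        ema_update(state)
        after = state.target_encoder.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_tau_zero_copies_online(self):
        state = self._state(0.0)
        for p in state.online_encoder.parameters():
            p.data += 0.5
        ema_update(state)
        online = state.online_encoder.state_dict()
        target = state.target_encoder.state_dict()
        for k in online:
            np.testing.assert_allclose(online[k], target[k])

    def test_scalar_closed_form(self):
        state = self._state(0.996)
        name, p_target = next(iter(state.target_encoder.named_parameters()))
        p_online = dict(state.online_encoder.named_parameters())[name]
        p_target.data[:] = 0.0
        p_online.data[:] = 1.0
        ema_update(state)
        np.testing.assert_allclose(p_target.data,
                                   np.full_like(p_target.data, 0.004),
                                   rtol=1e-5)

    def test_geometric_convergence_to_frozen_online(self):
        state = self._state(0.996)
        name, p_target = next(iter(state.target_encoder.named_parameters()))
        p_online = dict(state.online_encoder.named_parameters())[name]
        p_target.data[:] = 0.0
        p_online.data[:] = 1.0
        for k in range(10):
            ema_update(state)
        expected = 1.0 - 0.996 ** 10
        np.testing.assert_allclose(p_target.data.ravel()[0], expected,
                                   rtol=1e-4)


def _examples(n, seed=0, max_len=96):
    out = []
    for i in range(n):
        enc = make_encoded(n=40 + (i % 11), max_len=max_len, seed=seed + i)
        out.append(CohortExample(enc, 0, dt.date(2010, 1, 1), 40, f"P{i}"))
    return out


class TestPretrainStep:
    def test_loss_finite_nonnegative_at_init(self):
        cfg = small_hier_config(30, max_len=96)
        state = build_byol(cfg, seed=0)
        opt = nn.SGD(state.online_parameters(), lr=0.01)
        stats = pretrain_step(_examples(6), state, AugmentationConfig(),
                              opt, np.random.default_rng(0))
        assert np.isfinite(stats["loss"])
        assert stats["loss"] >= 0

    def test_target_receives_exactly_zero_gradient(self):
        """Target parameters change the loss but never accumulate gradient."""
        cfg = small_hier_config(30, max_len=96)
        state = build_byol(cfg, tau=1.0, seed=0)
        opt = nn.SGD(state.online_parameters(), lr=0.0)
        rng_state = np.random.default_rng(5)
        examples = _examples(4)
        s1 = pretrain_step(examples, state, AugmentationConfig(), opt,
                           np.random.default_rng(5))
        for _, p in state.target_encoder.named_parameters():
            assert p.grad is None
        for _, p in state.target_projector.named_parameters():
            assert p.grad is None
        # perturbing a target weight changes the loss (same rng stream)
        for p in state.target_encoder.parameters():
            p.data += 0.05
        s2 = pretrain_step(examples, state, AugmentationConfig(), opt,
                           np.random.default_rng(5))
        assert s1["loss"] != pytest.approx(s2["loss"], abs=1e-9)

    def test_short_pretraining_reduces_loss_and_aligns(self):
        """Smoothed BYOL loss falls and cosine alignment rises."""
        cfg = small_hier_config(30, max_len=110)
        state = build_byol(cfg, seed=1)
        log = pretrain(_examples(64, seed=3, max_len=110), state,
                       AugmentationConfig(), steps=120, batch_size=16,
                       lr=0.1, seed=2)
        first = np.mean([r["loss"] for r in log[:10]])
        last = np.mean([r["loss"] for r in log[-10:]])
        assert last < first
        cos_first = np.nanmean([r["mean_cosine"] for r in log[:10]])
        cos_last = np.nanmean([r["mean_cosine"] for r in log[-10:]])
        assert cos_last > cos_first
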