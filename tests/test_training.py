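"""Losses, weighting, augmentation, schedule, EMA, freezing, and fit."""

import math

import numpy as np
import pytest

from feral.chunking import ChunkConfig
from feral.labels import ClassCatalog, FrameLabelTrack
from feral.model import tiny_backbone
from feral.nn import Tensor
from feral.training import (
    ClassStats,
    EmaState,
    TrainConfig,
    apply_freezing,
    bce_pos_weights,
    class_weights,
    clip_augment,
    ema_update,
    fit,
    lr_at,
    mixup_batch,
    smoothed_weighted_ce,
    weighted_bce,
)

RNG = np.random.default_rng(21)


class TestClassWeights:
    def test_balanced_classes_give_unit_weights(self):
        stats = ClassStats(mode="single_label", freq=np.full(4, 0.25))
        assert np.allclose(class_weights(stats), 1.0)

    def test_hand_computed_example(self):
        stats = ClassStats(mode="single_label", freq=np.array([0.04, 0.16, 0.80]))
        # raw sqrt(1/f) = (5, 2.5, 1.1180); mean 2.8727
        assert np.allclose(class_weights(stats), [1.7406, 0.8703, 0.3892], atol=2e-4)

    def test_scale_invariance_in_frame_counts(self):
        cat = ClassCatalog(names=("other", "a"), mode="single_label")
        t1 = FrameLabelTrack("v", 10, 10, np.array([0] * 8 + [1] * 2))
        t2 = FrameLabelTrack("w", 10, 20, np.array([0] * 16 + [1] * 4))
        w1 = class_weights(ClassStats.from_tracks([t1], cat))
        w2 = class_weights(ClassStats.from_tracks([t2], cat))
        assert np.allclose(w1, w2)

    def test_zero_frequency_class_named_in_error(self):
        cat = ClassCatalog(names=("other", "rare"), mode="single_label")
        stats = ClassStats(mode="single_label", freq=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="rare"):
            class_weights(stats, cat)


class TestSmoothedWeightedCE:
    def test_uniform_logits_closed_form(self):
        logits = np.zeros((7, 4))
        targets = RNG.integers(0, 4, size=7)
        loss = smoothed_weighted_ce(logits, targets, smoothing=0.0)
        assert loss.data == pytest.approx(math.log(4), abs=1e-12)

    def test_matches_brute_force_formula(self):
        """Oracle: direct numpy evaluation of the smoothed weighted formula."""
        for trial in range(20):
            rng = np.random.default_rng(trial)
            n, C = 13, 5
            logits = rng.normal(size=(n, C)) * 3
            targets = rng.integers(0, C, size=n)
            w = rng.uniform(0.5, 2.0, size=C)
            s = 0.1
            got = smoothed_weighted_ce(logits, targets, w, smoothing=s).data
            # independent oracle
            p = np.exp(logits - logits.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            y = np.eye(C)[targets]
            q = (1 - s) * y + s / C
            expect = -(w * q * np.log(p)).sum(axis=1).mean()
            assert got == pytest.approx(expect, rel=1e-10)

    def test_zero_smoothing_equals_standard_ce(self):
        logits = RNG.normal(size=(11, 3))
        targets = RNG.integers(0, 3, size=11)
        got = smoothed_weighted_ce(logits, targets, smoothing=0.0).data
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert got == pytest.approx(-np.log(p[np.arange(11), targets]).mean(), rel=1e-10)

    def test_linearity_in_weights(self):
        logits = RNG.normal(size=(5, 3))
        targets = RNG.integers(0, 3, size=5)
        w = np.array([1.0, 2.0, 0.5])
        l1 = smoothed_weighted_ce(logits, targets, w).data
        l2 = smoothed_weighted_ce(logits, targets, 2 * w).data
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_mixed_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            smoothed_weighted_ce(np.zeros((2, 3)), np.array([[0.5, 0.2, 0.2]] * 2))

    def test_non_finite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            smoothed_weighted_ce(np.array([[np.inf, 0.0]]), np.array([0]))


class TestWeightedBCE:
    def test_balanced_counts_reduce_to_unweighted(self):
        stats = ClassStats(mode="multi_label", n_pos=np.array([50, 50]), n_neg=np.array([50, 50]))
        logits = RNG.normal(size=(9, 2))
        y = RNG.integers(0, 2, size=(9, 2)).astype(float)
        got = weighted_bce(logits, y, stats).data
        p = 1 / (1 + np.exp(-logits))
        expect = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert got == pytest.approx(expect, rel=1e-9)

    def test_zero_logits_closed_form(self):
        stats = ClassStats(mode="multi_label", n_pos=np.array([30]), n_neg=np.array([30]))
        y = np.array([[1.0], [0.0]])
        got = weighted_bce(np.zeros((2, 1)), y, stats).data
        assert got == pytest.approx(-math.log(0.5), rel=1e-12)

    def test_rare_class_positives_upweighted_9x(self):
        stats = ClassStats(mode="multi_label", n_pos=np.array([10]), n_neg=np.array([90]))
        logits = np.full((1, 1), 0.3)
        pos = weighted_bce(logits, np.array([[1.0]]), stats).data
        # oracle: positive term is scaled by n_neg/n_pos = 9
        p = 1 / (1 + math.exp(-0.3))
        assert pos == pytest.approx(-9 * math.log(p), rel=1e-9)

    def test_class_without_positives_rejected(self):
        stats = ClassStats(mode="multi_label", n_pos=np.array([0]), n_neg=np.array([100]))
        with pytest.raises(ValueError, match="no positive"):
            weighted_bce(np.zeros((1, 1)), np.zeros((1, 1)), stats)


class TestMixup:
    def test_alpha_one_is_identity(self):
        x = RNG.random((4, 2, 3, 3, 3))
        y = np.eye(3)[RNG.integers(0, 3, size=(4, 2))]
        mx, my, _ = mixup_batch(x, y, 0.2, np.random.default_rng(0), alpha=1.0)
        assert (mx == x).all()
        assert (my == y).all()

    def test_alpha_half_midpoint(self):
        x = np.stack([np.zeros((1, 2, 2, 3)), np.ones((1, 2, 2, 3))])
        y = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        mx, my, draws = mixup_batch(x, y, 0.2, np.random.default_rng(0), alpha=0.5)
        assert np.allclose(mx, 0.5)
        assert np.allclose(my, 0.5)
        assert {d.partner for d in draws} == {0, 1}

    def test_mixed_rows_stay_on_simplex(self):
        x = RNG.random((6, 2, 2, 2, 3))
        y = np.eye(4)[RNG.integers(0, 4, size=(6, 2))]
        _, my, _ = mixup_batch(x, y, 0.4, np.random.default_rng(3))
        assert np.allclose(my.sum(axis=-1), 1.0, atol=1e-12)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            mixup_batch(np.zeros((1, 2, 2, 2, 3)), np.zeros((1, 2, 3)), 0.2, np.random.default_rng(0))


class TestClipAugment:
    def test_identity_op_bit_exact(self):
        video = RNG.random((3, 8, 8, 3))
        out = clip_augment(video, np.random.default_rng(0), ops=("identity",))
        assert (out == video).all()

    def test_fixed_seed_reproducible(self):
        video = RNG.random((3, 8, 8, 3))
        a = clip_augment(video, np.random.default_rng(5))
        b = clip_augment(video, np.random.default_rng(5))
        assert (a == b).all()

    @pytest.mark.parametrize("op", ["brightness", "contrast", "color_jitter"])
    def test_photometric_parameters_constant_across_frames(self, op):
        """Recover the per-frame affine transform; it must be clip-constant.

        Each photometric op acts as v -> a*v + b.  Frames with two distinct
        constant regions let us fit (a, b) per frame; both frames of a clip
        must yield the same parameters.
        """
        video = np.zeros((2, 8, 8, 3))
        video[0, :, :4], video[0, :, 4:] = 0.30, 0.55
        video[1, :, :4], video[1, :, 4:] = 0.40, 0.70
        out = clip_augment(video, np.random.default_rng(11), ops=(op,))
        for c in range(3):
            fitted = []
            for f in range(2):
                lo_in, hi_in = video[f, 0, 0, c], video[f, 0, 7, c]
                lo_out, hi_out = out[f, 0, 0, c], out[f, 0, 7, c]
                a = (hi_out - lo_out) / (hi_in - lo_in)
                b = lo_out - a * lo_in
                fitted.append((a, b))
            assert fitted[0][0] == pytest.approx(fitted[1][0], abs=1e-9)
            assert fitted[0][1] == pytest.approx(fitted[1][1], abs=1e-9)

    def test_geometric_shift_constant_across_frames(self):
        video = np.zeros((2, 16, 16, 3))
        video[0, 4, 4] = 1.0
        video[1, 10, 10] = 1.0
        out = clip_augment(video, np.random.default_rng(2), ops=("translation",))
        # the bright pixel moves by the same offset in both frames
        p0 = np.unravel_index(out[0, ..., 0].argmax(), (16, 16))
        p1 = np.unravel_index(out[1, ..., 0].argmax(), (16, 16))
        assert (p0[0] - 4, p0[1] - 4) == (p1[0] - 10, p1[1] - 10)


class TestSchedule:
    def test_knots_and_endpoints(self):
        peak = 3e-4
        total = 1000
        assert lr_at(0, total, peak) == 0.0
        assert lr_at(200, total, peak) == pytest.approx(peak)  # warmup end
        assert lr_at(total - 1, total, peak) == pytest.approx(0.0, abs=1e-12)
        mid = (200 + total - 1) // 2  # decay midpoint
        assert lr_at(mid, total, peak) == pytest.approx(peak / 2, rel=0.01)

    def test_continuity_at_warmup_knot(self):
        peak, total = 1e-3, 500
        before = lr_at(99, total, peak)
        after = lr_at(100, total, peak)
        assert abs(after - before) < peak / 50

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            lr_at(0, 0, 1e-3)
        with pytest.raises(ValueError):
            lr_at(10, 10, 1e-3)


class TestEma:
    def test_single_step_arithmetic(self):
        state = EmaState(shadow={"w": np.zeros(1)}, beta=0.999)
        ema_update(state, {"w": np.array([2.0])})
        assert state.shadow["w"][0] == pytest.approx(0.002)
        assert state.t == 1

    def test_beta_zero_copies_current_weights(self):
        state = EmaState(shadow={"w": np.array([7.0])}, beta=0.0)
        ema_update(state, {"w": np.array([1.5])})
        assert state.shadow["w"][0] == 1.5

    def test_geometric_convergence_to_constant_weights(self):
        beta = 0.9
        state = EmaState(shadow={"w": np.array([0.0])}, beta=beta)
        theta = np.array([1.0])
        for k in range(1, 41):
            ema_update(state, {"w": theta})
            # closed form: 1 - beta^k
            assert state.shadow["w"][0] == pytest.approx(1 - beta**k, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        state = EmaState(shadow={"w": np.zeros(2)})
        with pytest.raises(ValueError, match="shape"):
            ema_update(state, {"w": np.zeros(3)})


def _tiny_setup(n_frames=40, seed=0):
    cat = ClassCatalog(names=("other", "blob"), mode="single_label")
    targets = np.array(([0] * 10 + [1] * 10) * (n_frames // 20))
    track = FrameLabelTrack("v", 10.0, n_frames, targets)
    rng = np.random.default_rng(seed)
    video = rng.integers(0, 256, size=(n_frames, 16, 16, 3), dtype=np.uint8)
    video[targets == 1, :, :, 0] = 255  # make the classes learnable
    bb = tiny_backbone(seed=seed, input_size=16, chunk_len=8, patch=8, t_patch=2)
    return cat, track, video, bb


class TestFit:
    def _config(self, **kw):
        base = dict(
            epochs=1,
            batch_size=2,
            chunk=ChunkConfig(chunk_len=8, frame_stride=1, overlap=0.5),
            use_augment=False,
            use_mixup=False,
        )
        base.update(kw)
        return TrainConfig(**base)

    def test_full_freeze_leaves_backbone_bitwise_unchanged(self):
        cat, track, video, bb = _tiny_setup()
        before = {n: p.data.copy() for n, p in bb.named_parameters()}
        result = fit([track], {"v": video}, bb, self._config(freeze_frac=1.0), cat)
        after = dict(result.model.backbone.named_parameters())
        for name, old in before.items():
            assert (after[name].data == old).all(), name

    def test_unfrozen_parameters_receive_gradients(self):
        cat, track, video, bb = _tiny_setup()
        before = {n: p.data.copy() for n, p in bb.named_parameters()}
        result = fit([track], {"v": video}, bb, self._config(freeze_frac=0.0), cat)
        changed = sum(
            not (p.data == before[n]).all()
            for n, p in result.model.backbone.named_parameters()
        )
        assert changed == len(before)

    def test_frozen_parameters_have_no_gradient(self):
        _, _, _, bb = _tiny_setup()
        n_frozen = apply_freezing(bb, 0.5)
        groups = bb.layer_groups()
        assert n_frozen == 2
        for g in groups[:2]:
            assert all(not p.requires_grad for p in g)
        for g in groups[2:]:
            assert all(p.requires_grad for p in g)

    def test_identical_seed_identical_final_loss(self):
        results = []
        for _ in range(2):
            cat, track, video, bb = _tiny_setup(seed=0)
            cfg = self._config(use_augment=True, use_mixup=True, seed=3)
            results.append(fit([track], {"v": video}, bb, cfg, cat))
        l1 = [h["loss"] for h in results[0].history]
        l2 = [h["loss"] for h in results[1].history]
        assert l1 == l2

    def test_run_log_is_json_lines(self, tmp_path):
        import json

        cat, track, video, bb = _tiny_setup()
        log = tmp_path / "run.jsonl"
        result = fit([track], {"v": video}, bb, self._config(), cat, log_path=log)
        lines = [json.loads(l) for l in log.read_text().splitlines()]
        assert len(lines) == len(result.history)
        assert {"step", "epoch", "loss", "lr"} <= set(lines[0])

    def test_no_labeled_chunks_rejected(self):
        cat, track, video, bb = _tiny_setup()
        short = FrameLabelTrack("v", 10.0, 4, np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="no labeled chunks"):
            fit([short], {"v": video[:4]}, bb, self._config(), cat)

    def test_ema_tracks_training_weights(self):
        cat, track, video, bb = _tiny_setup()
        cfg = self._config(freeze_frac=0.0)
        result = fit([track], {"v": video}, bb, cfg, cat)
        final = {n: p.data for n, p in result.model.named_parameters()}
        # EMA shadow stays within the range spanned by init and final weights
        for name, shadow in result.ema.shadow.items():
            assert shadow.shape == final[name].shape
        assert result.ema.t == len(result.history)
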