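import numpy as np
import pytest

from fundusseg.network import NetworkConfig, build_msmku
from fundusseg.training import (
    AugmentOp,
    MMLMConfig,
    TrainingPair,
    apply_augment,
    make_augment_ops,
    mixed_loss,
    rank_by_loss,
    schedule_k,
    schedule_n,
    train_alm,
    train_mlm,
    train_mmlm,
)

# working defaults used throughout: n_max=40, n_min=5, k_max=15, k_min=4


def constant_prob_pairs(values, side=16):
    """Pairs whose Dice loss under ChannelProbNet is exactly the requested
    value: image channel 0 constant c, mask all ones -> loss = 1 - 2c/(c^2+1)."""
    pairs = []
    for i, loss in enumerate(values):
        # invert loss = 1 - 2c/(c^2+1) for c in [0, 1]
        s = 1.0 - loss
        c = (1.0 - np.sqrt(1.0 - s * s)) / s if s > 0 else 0.0
        img = np.zeros((side, side, 3))
        img[..., 0] = c
        pairs.append(TrainingPair(image=img, mask=np.ones((side, side), dtype=np.uint8), index=i))
    return pairs


class TestSchedules:
    @pytest.mark.parametrize("t,expected", [(1, 39), (35, 5), (200, 5)])
    def test_hard_example_count(self, t, expected):
        assert schedule_n(t, 40, 5, 100) == expected

    def test_clamped_to_dataset_size(self):
        assert schedule_n(1, 40, 5, 20) == 20

    @pytest.mark.parametrize("t,expected", [(1, 15), (8, 13), (44, 4), (100, 4)])
    def test_augmentation_folds(self, t, expected):
        assert schedule_k(t, 15, 4) == expected

    def test_schedules_non_increasing_with_floors(self):
        ns = [schedule_n(t, 40, 5, 100) for t in range(1, 201)]
        ks = [schedule_k(t, 15, 4) for t in range(1, 201)]
        assert all(a >= b for a, b in zip(ns, ns[1:])) and min(ns) == 5
        assert all(a >= b for a, b in zip(ks, ks[1:])) and min(ks) == 4


class TestRanking:
    def test_descending_order(self, channel_net_factory):
        net = channel_net_factory(16)
        pairs = constant_prob_pairs([0.2, 0.9, 0.5])
        assert rank_by_loss(net, pairs) == [1, 2, 0]

    def test_stable_under_ties(self, channel_net_factory):
        net = channel_net_factory(16)
        pairs = constant_prob_pairs([0.4] * 5)
        assert rank_by_loss(net, pairs) == [0, 1, 2, 3, 4]

    def test_matches_brute_force_sort(self, channel_net_factory):
        rng = np.random.default_rng(0)
        losses = rng.uniform(0.05, 0.95, 50)
        net = channel_net_factory(16)
        pairs = constant_prob_pairs(losses)
        expected = sorted(range(50), key=lambda i: -losses[i])
        got = rank_by_loss(net, pairs)
        # the net reproduces each loss to float precision; compare orders
        assert got == expected

    def test_empty_list_raises(self, channel_net_factory):
        with pytest.raises(ValueError):
            rank_by_loss(channel_net_factory(16), [])


class TestAugmentation:
    def test_ops_reproducible(self):
        cfg = MMLMConfig(seed=5)
        a = make_augment_ops(3, 2, 4, cfg, side=64)
        b = make_augment_ops(3, 2, 4, cfg, side=64)
        assert a == b

    def test_zero_ranges_give_identity(self):
        cfg = MMLMConfig(aug_rotation_deg=0.0, aug_translate_frac=0.0)
        ops = make_augment_ops(1, 2, 3, cfg, side=64)
        assert all(op.is_identity for row in ops for op in row)

    def test_angle_sampler_range_and_mean(self):
        cfg = MMLMConfig(aug_rotation_deg=20.0, seed=1)
        ops = make_augment_ops(1, 1, 1000, cfg, side=64)
        angles = np.array([op.angle for op in ops[0]])
        assert angles.min() >= -20 and angles.max() <= 20
        assert abs(angles.mean()) < 1.0

    def test_identity_returns_inputs_unchanged(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16, 3), dtype=np.uint8)
        msk = (np.random.default_rng(1).random((16, 16)) > 0.5).astype(np.uint8)
        out_img, out_msk = apply_augment(AugmentOp(), img, msk)
        assert np.array_equal(out_img, img) and np.array_equal(out_msk, msk)

    def test_pure_translation_moves_mask_pixel(self):
        msk = np.zeros((24, 24), dtype=np.uint8)
        msk[10, 10] = 1
        img = np.zeros((24, 24, 3), dtype=np.uint8)
        _, out = apply_augment(AugmentOp(shift=(3.0, 0.0)), img, msk)
        assert out[13, 10] == 1 and out.sum() == 1

    def test_rotated_mask_stays_binary(self):
        rng = np.random.default_rng(2)
        msk = (rng.random((20, 20)) > 0.7).astype(np.uint8)
        img = rng.integers(0, 255, (20, 20, 3), dtype=np.uint8)
        _, out = apply_augment(AugmentOp(angle=17.0, shift=(1.5, -2.5)), img, msk)
        assert set(np.unique(out)) <= {0, 1}


class TestMixedLoss:
    def test_hand_evaluated_round_loss(self, channel_net_factory):
        losses = [0.4, 0.1, 0.3, 0.2]
        net = channel_net_factory(16)
        pairs = constant_prob_pairs(losses)
        order = rank_by_loss(net, pairs)
        ops = [[AugmentOp()] * 2]
        total = mixed_loss(net, pairs, order, n_t=2, k_t=1, lambda1=1.0, lambda2=2.0, ops=ops)
        assert total == pytest.approx(1.0 + 2.0 * (0.4 + 0.3), abs=1e-6)

    def test_lambda2_zero_is_weighted_loss_sum(self, channel_net_factory):
        losses = [0.25, 0.6, 0.15]
        net = channel_net_factory(16)
        pairs = constant_prob_pairs(losses)
        order = rank_by_loss(net, pairs)
        total = mixed_loss(net, pairs, order, 2, 1, lambda1=1.5, lambda2=0.0, ops=[[AugmentOp()] * 2])
        assert total == pytest.approx(1.5 * sum(losses), abs=1e-6)

    def test_lambda1_zero_identity_ops_is_top_n_sum(self, channel_net_factory):
        losses = [0.25, 0.6, 0.15, 0.5]
        net = channel_net_factory(16)
        pairs = constant_prob_pairs(losses)
        order = rank_by_loss(net, pairs)
        total = mixed_loss(net, pairs, order, 2, 1, lambda1=0.0, lambda2=1.0, ops=[[AugmentOp()] * 2])
        assert total == pytest.approx(0.6 + 0.5, abs=1e-6)

    def test_linear_in_lambdas(self, channel_net_factory):
        losses = [0.3, 0.7, 0.45]
        net = channel_net_factory(16)
        pairs = constant_prob_pairs(losses)
        order = rank_by_loss(net, pairs)
        ops = [[AugmentOp()] * 2]
        base1 = mixed_loss(net, pairs, order, 2, 1, 1.0, 0.0, ops)
        base2 = mixed_loss(net, pairs, order, 2, 1, 0.0, 1.0, ops)
        for l1, l2 in [(0.5, 2.0), (3.0, 0.25), (1.0, 1.0)]:
            combined = mixed_loss(net, pairs, order, 2, 1, l1, l2, ops)
            assert combined == pytest.approx(l1 * base1 + l2 * base2, abs=1e-6)

    def test_n_t_exceeding_m_raises(self, channel_net_factory):
        net = channel_net_factory(16)
        pairs = constant_prob_pairs([0.3, 0.4])
        with pytest.raises(ValueError):
            mixed_loss(net, pairs, [0, 1], 3, 1, 1.0, 1.0, [[AugmentOp()] * 3])


def tiny_phantom_pairs(n=6, side=32, seed=0):
    from fundusseg.phantom import generate_dataset, od_pairs

    return od_pairs(generate_dataset(n, 0.0, side=side, seed=seed))


TINY_NET = NetworkConfig(input_side=32, base_width=2, seed=1)
TINY_CFG = MMLMConfig(epochs=3, n_max=4, n_min=2, k_max=3, k_min=1, seed=2)


class TestTrainingLoops:
    def test_history_bookkeeping_matches_schedules(self):
        pairs = tiny_phantom_pairs()
        _, hist = train_mmlm(pairs, TINY_NET, TINY_CFG)
        assert len(hist) == TINY_CFG.epochs
        for rec in hist:
            assert rec.n_t == schedule_n(rec.t, TINY_CFG.n_max, TINY_CFG.n_min, len(pairs))
            assert rec.k_t == schedule_k(rec.t, TINY_CFG.k_max, TINY_CFG.k_min)
            assert sorted(rec.sorted_indices) == list(range(len(pairs)))

    def test_round_one_ranking_uses_initial_parameters(self):
        pairs = tiny_phantom_pairs()
        _, hist = train_mmlm(pairs, TINY_NET, TINY_CFG)
        fresh = build_msmku(TINY_NET)
        assert hist[0].sorted_indices == rank_by_loss(fresh, pairs)

    def test_mmlm_with_lambda2_zero_equals_alm(self):
        from dataclasses import replace

        pairs = tiny_phantom_pairs()
        _, h1 = train_mmlm(pairs, TINY_NET, replace(TINY_CFG, lambda2=0.0))
        _, h2 = train_alm(pairs, TINY_NET, TINY_CFG)
        assert [r.mean_loss for r in h1] == [r.mean_loss for r in h2]
        assert [r.min_f for r in h1] == [r.min_f for r in h2]

    def test_mlm_equals_mmlm_with_no_first_term_and_identity_ops(self):
        from dataclasses import replace

        pairs = tiny_phantom_pairs()
        _, h1 = train_mlm(pairs, TINY_NET, TINY_CFG)
        cfg = replace(TINY_CFG, lambda1=0.0, aug_rotation_deg=0.0, aug_translate_frac=0.0, k_max=1, k_min=1)
        _, h2 = train_mmlm(pairs, TINY_NET, cfg)
        assert [r.mean_loss for r in h1] == [r.mean_loss for r in h2]

    def test_equal_seeds_reproduce_bitwise(self):
        pairs = tiny_phantom_pairs()
        net1, h1 = train_mmlm(pairs, TINY_NET, TINY_CFG)
        net2, h2 = train_mmlm(pairs, TINY_NET, TINY_CFG)
        assert [r.mean_loss for r in h1] == [r.mean_loss for r in h2]
        for p1, p2 in zip(net1.params(), net2.params()):
            assert np.array_equal(p1.value, p2.value), p1.name

    def test_training_reduces_loss(self):
        pairs = tiny_phantom_pairs(n=8)
        from dataclasses import replace

        _, hist = train_alm(pairs, TINY_NET, replace(TINY_CFG, epochs=12))
        assert hist[-1].mean_loss < hist[0].mean_loss
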