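"""Training-set constructions, averaging baselines, baseline CNN."""

import numpy as np
import pytest

from sirenstack.motion import (BaselineCnn, BaselineCnnConfig,
                               CorrectionConfig, apply_baseline_cnn,
                               average_repetitions, build_training_set_all,
                               build_training_set_sampled,
                               clean_mask_from_records, train_baseline_cnn)
from sirenstack.stacks import RepetitionSet


def _reps(rng, r=4, shape=(5, 8, 8)):
    return RepetitionSet(rng.random((r, *shape)))


class TestTrainingSets:
    def test_all_size_is_r_times_grid(self, rng):
        reps = _reps(rng, r=4, shape=(5, 8, 8))
        sample = build_training_set_all(reps)
        assert len(sample) == 4 * 5 * 64 == 1280

    def test_all_per_coordinate_target_multiset(self, rng):
        reps = _reps(rng, r=3, shape=(2, 4, 4))
        sample = build_training_set_all(reps)
        n_vox = 2 * 16
        # coordinates repeat identically per repetition block
        coords = sample.coords.reshape(3, n_vox, 3)
        np.testing.assert_array_equal(coords[0], coords[1])
        np.testing.assert_array_equal(coords[0], coords[2])
        targets = sample.targets.reshape(3, n_vox)
        for v in range(n_vox):
            expect = sorted(reps.data.reshape(3, -1)[:, v])
            got = sorted(targets[:, v])
            np.testing.assert_allclose(got, expect, rtol=1e-6)

    def test_sampled_size_and_membership(self, rng):
        reps = _reps(rng, r=4, shape=(5, 8, 8))
        sample = build_training_set_sampled(reps, seed=1)
        assert len(sample) == 5 * 64
        flat = reps.data.reshape(4, -1)
        t = sample.targets.ravel()
        for v in range(flat.shape[1]):
            assert np.min(np.abs(flat[:, v] - t[v])) < 1e-6

    def test_sampled_identical_reps_reproduce_stack(self, rng):
        one = rng.random((3, 6, 6))
        reps = RepetitionSet(np.stack([one] * 4))
        sample = build_training_set_sampled(reps, seed=0)
        np.testing.assert_allclose(sample.targets.ravel(), one.ravel(),
                                   rtol=1e-6)

    def test_sampled_bernoulli_fraction(self):
        # R=2 with values {0,1} everywhere: per-voxel choice is
        # Bernoulli(1/2); check the fraction over 10^4 voxels within 5 sd
        shape = (10, 32, 32)
        reps = RepetitionSet(np.stack([np.zeros(shape), np.ones(shape)]))
        sample = build_training_set_sampled(reps, seed=3)
        frac = sample.targets.mean()
        n = np.prod(shape)
        assert abs(frac - 0.5) < 5 * 0.5 / np.sqrt(n)

    def test_sampled_deterministic_per_seed(self, rng):
        reps = _reps(rng)
        a = build_training_set_sampled(reps, seed=9)
        b = build_training_set_sampled(reps, seed=9)
        np.testing.assert_array_equal(a.targets, b.targets)

    def test_size_ratio_exactly_r(self, rng):
        reps = _reps(rng, r=4)
        assert len(build_training_set_all(reps)) == \
            4 * len(build_training_set_sampled(reps, seed=0))


class TestAveraging:
    def test_identical_reps_average_to_themselves(self, rng):
        one = rng.random((3, 6, 6))
        reps = RepetitionSet(np.stack([one] * 3))
        np.testing.assert_allclose(average_repetitions(reps).data, one)

    def test_two_reps_zero_one_average_half(self):
        shape = (2, 4, 4)
        reps = RepetitionSet(np.stack([np.zeros(shape), np.ones(shape)]))
        np.testing.assert_array_equal(average_repetitions(reps).data, 0.5)

    def test_clean_mask_excludes_corrupted(self, rng):
        reps = _reps(rng, r=4, shape=(3, 4, 4))
        mask = [[1, 2, 3], [0, 1, 2, 3], [0, 1]]
        out = average_repetitions(reps, clean_mask=mask)
        np.testing.assert_allclose(out.data[0], reps.data[1:, 0].mean(axis=0))
        np.testing.assert_allclose(out.data[2], reps.data[:2, 2].mean(axis=0))

    def test_empty_inclusion_rejected(self, rng):
        reps = _reps(rng, r=2, shape=(2, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            average_repetitions(reps, clean_mask=[[0], []])

    def test_clean_mask_from_records(self):
        class Rec:
            def __init__(self, r, z):
                self.repetition_index, self.plane_index = r, z
        mask = clean_mask_from_records([Rec(0, 1), Rec(2, 1)], n_reps=4,
                                       n_planes=3)
        assert mask == [[0, 1, 2, 3], [1, 3], [0, 1, 2, 3]]


class TestCorrectionConfig:
    def test_strategy_aliases(self):
        assert CorrectionConfig(strategy="all_repetitions").canonical_strategy == "all"
        assert CorrectionConfig(strategy="random_sample").canonical_strategy == "sampled"
        with pytest.raises(ValueError):
            CorrectionConfig(strategy="bogus")


class TestBaselineCnn:
    def test_output_shape_matches_input(self, rng):
        model = BaselineCnn(BaselineCnnConfig(seed=0))
        for shape in [(8, 8), (11, 13), (16, 9)]:
            plane = rng.random(shape)
            assert apply_baseline_cnn(model, plane).shape == shape

    def test_identity_training_reduces_error(self, rng):
        # train on clean->clean pairs: the CNN must learn approximately the
        # identity, beating its untrained initialization on held-out planes
        planes = [rng.random((12, 12)) for _ in range(6)]
        pairs = [(p, p) for p in planes[:4]]
        cfg = BaselineCnnConfig(filters=(8, 8, 1), epochs=40, seed=1)
        untrained = BaselineCnn(cfg)
        trained = train_baseline_cnn(pairs, cfg)
        held = planes[4:]
        err_t = np.mean([np.mean((apply_baseline_cnn(trained, p) - p) ** 2)
                         for p in held])
        err_u = np.mean([np.mean((apply_baseline_cnn(untrained, p) - p) ** 2)
                         for p in held])
        assert err_t < err_u
        assert err_t < 0.1  # plain SGD approaches the identity slowly

    def test_loss_trace_decreases(self, rng):
        planes = [rng.random((10, 10)) for _ in range(4)]
        pairs = [(p + rng.normal(0, 0.05, p.shape), p) for p in planes]
        cfg = BaselineCnnConfig(filters=(4, 4, 1), epochs=15, seed=2)
        model = train_baseline_cnn(pairs, cfg)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_baseline_cnn([])

    def test_mismatched_pair_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            train_baseline_cnn([(rng.random((4, 4)), rng.random((5, 5)))],
                               BaselineCnnConfig(filters=(2, 2, 1), epochs=1))
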