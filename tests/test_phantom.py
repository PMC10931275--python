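"""Phantom generation, motion-kernel sampling, degradation and augmentation."""

import numpy as np
import pytest

from motiongrade.phantom import (
    SIGMA_BANDS,
    GradedVolume,
    MotionKernel,
    PhantomConfig,
    augment,
    degrade,
    generate_phantom,
    kernel_array,
    make_graded_dataset,
    mean_gradient_magnitude,
    sample_motion_kernel,
    sample_symmetry,
)
from motiongrade.volume import Volume


class TestPhantom:
    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(shape=(16, 24, 24), seed=11)
        a, b = generate_phantom(cfg), generate_phantom(cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_trabecular_fill_realized(self):
        cfg = PhantomConfig(
            shape=(32, 32, 32), noise_sd=0.0, trabecular_fill=0.3, seed=5
        )
        vol = generate_phantom(cfg)
        # recompute interior mask exactly as the generator defines it
        grids = np.meshgrid(
            *[np.arange(d) - (d - 1) / 2.0 for d in cfg.shape], indexing="ij"
        )
        semi = np.array([0.40 * d for d in cfg.shape]) - cfg.shell_thickness
        interior = np.sqrt(sum((g / a) ** 2 for g, a in zip(grids, semi))) <= 1.0
        frac = np.mean(vol.data[interior] >= cfg.bone_intensity)
        assert abs(frac - 0.3) <= 0.02

    def test_no_shell_means_no_bright_boundary(self):
        cfg = PhantomConfig(
            shape=(32, 32, 32), shell_thickness=0.0, noise_sd=0.0, seed=2
        )
        vol = generate_phantom(cfg)
        grids = np.meshgrid(
            *[np.arange(d) - (d - 1) / 2.0 for d in cfg.shape], indexing="ij"
        )
        semi = np.array([0.40 * d for d in cfg.shape])
        rho = np.sqrt(sum((g / a) ** 2 for g, a in zip(grids, semi)))
        boundary = (rho <= 1.0) & (rho > 0.9)
        interior = rho <= 0.9
        # boundary ring should look statistically like trabecular interior,
        # not like a solid cortical shell
        assert np.mean(vol.data[boundary] == cfg.bone_intensity) < 0.6
        assert (
            abs(np.mean(vol.data[boundary]) - np.mean(vol.data[interior])) < 0.2
        )

    def test_too_small_for_shell_errors(self):
        with pytest.raises(ValueError, match="too small"):
            PhantomConfig(shape=(5, 48, 48), shell_thickness=2.0)

    def test_background_is_empty(self):
        vol = generate_phantom(PhantomConfig(shape=(16, 24, 24), noise_sd=0.0))
        assert vol.data[0, 0, 0] == 0.0


class TestKernel:
    def test_level1_is_identity_any_seed(self):
        for seed in (0, 1, 99):
            k = sample_motion_kernel(1, np.random.default_rng(seed))
            arr = kernel_array(k)
            assert arr.shape == (1, 1, 1) and arr[0, 0, 0] == 1.0

    @pytest.mark.parametrize("level", [2, 3, 4, 5])
    def test_weights_nonnegative_sum_to_one(self, level, rng):
        for _ in range(5):
            k = sample_motion_kernel(level, rng)
            arr = kernel_array(k)
            assert arr.min() >= 0.0
            assert abs(arr.sum() - 1.0) < 1e-9

    def test_invalid_level(self, rng):
        for level in (0, 6, -1):
            with pytest.raises(ValueError, match="level"):
                sample_motion_kernel(level, rng)

    def test_sampler_band_mean(self):
        r = np.random.default_rng(0)
        draws = [sample_motion_kernel(3, r).sigma[0] for _ in range(1000)]
        lo, hi = SIGMA_BANDS[3]
        mid = (lo + hi) / 2
        se = (hi - lo) / np.sqrt(12) / np.sqrt(1000)
        assert abs(np.mean(draws) - mid) <= 3 * se

    def test_severity_bands_strictly_ordered(self):
        uppers = [SIGMA_BANDS[l][1] for l in range(1, 6)]
        lowers = [SIGMA_BANDS[l][0] for l in range(1, 6)]
        assert all(a <= b for a, b in zip(uppers, lowers[1:]))
        assert all(u1 < u2 for u1, u2 in zip(uppers, uppers[1:]))

    def test_max_support_clamp(self, rng):
        k = sample_motion_kernel(5, rng, max_support=15)
        assert k.support <= 15 and k.support % 2 == 1
        assert abs(kernel_array(k).sum() - 1.0) < 1e-9


class TestDegrade:
    def test_identity_kernel_exact(self, small_phantom):
        k = sample_motion_kernel(1, np.random.default_rng(0))
        out = degrade(small_phantom, k)
        np.testing.assert_array_equal(out.data, small_phantom.data)

    def test_constant_volume_conserved(self, rng):
        vol = Volume(np.full((20, 20, 20), 3.5))
        k = sample_motion_kernel(4, rng, max_support=19)
        out = degrade(vol, k)
        np.testing.assert_allclose(out.data, 3.5, atol=1e-6)

    def test_impulse_response_equals_kernel(self):
        k = MotionKernel(level=3, sigma=(2.0, 1.0, 1.0), rotation=np.eye(3), support=13)
        arr = kernel_array(k)
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = degrade(Volume(vol), k)
        expected = np.zeros((15, 15, 15))
        expected[1:14, 1:14, 1:14] = arr
        assert np.max(np.abs(out.data - expected)) < 1e-9

    def test_kernel_larger_than_volume_errors(self, rng):
        k = sample_motion_kernel(5, rng)
        assert k.support > 9
        with pytest.raises(ValueError, match="support"):
            degrade(Volume(np.zeros((9, 9, 9))), k)

    def test_sharpness_decreases_with_sigma(self):
        vol = generate_phantom(PhantomConfig(shape=(24, 24, 24), seed=1))
        sharp = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            k = MotionKernel(
                level=2,
                sigma=(sigma, sigma / 4, sigma / 4),
                rotation=np.eye(3),
                support=min(int(np.ceil(6 * sigma)) | 1, 23),
            )
            sharp.append(mean_gradient_magnitude(degrade(vol, k)))
        assert all(a > b for a, b in zip(sharp, sharp[1:]))


class TestAugment:
    def test_histogram_preserved(self, small_phantom, rng):
        out = augment(small_phantom, rng)
        np.testing.assert_array_equal(
            np.sort(out.data.ravel()), np.sort(small_phantom.data.ravel())
        )

    def test_transform_then_inverse_is_identity(self, rng):
        data = rng.random((6, 6, 6))
        for _ in range(20):
            t = sample_symmetry((6, 6, 6), rng)
            back = t.inverse().apply(t.apply(data))
            np.testing.assert_array_equal(back, data)

    def test_noncubic_transform_inverse(self, rng):
        data = rng.random((4, 8, 8))
        for _ in range(20):
            t = sample_symmetry((4, 8, 8), rng)
            assert t.apply(data).shape == data.shape
            np.testing.assert_array_equal(t.inverse().apply(t.apply(data)), data)

    def test_seeded_determinism(self, small_phantom):
        a = augment(small_phantom, np.random.default_rng(5))
        b = augment(small_phantom, np.random.default_rng(5))
        np.testing.assert_array_equal(a.data, b.data)

    def test_group_sampled_uniformly(self):
        # 48 elements on a cube; each count within 5 SD of uniform
        r = np.random.default_rng(0)
        counts: dict = {}
        n = 10_000
        for _ in range(n):
            t = sample_symmetry((4, 4, 4), r)
            key = (t.perm, t.flips)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 48
        p = 1 / 48
        sd = np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) <= 5 * sd


class TestGradedDataset:
    def test_allocation_bookkeeping(self, rng):
        base = PhantomConfig(shape=(16, 24, 24))
        data = make_graded_dataset([base], {l: 4 for l in range(1, 6)}, rng)
        assert len(data) == 20
        for level in range(1, 6):
            assert sum(g.grade == level for g in data) == 4

    def test_level1_bit_identical_to_phantom(self, rng):
        base = PhantomConfig(shape=(16, 24, 24))
        data = make_graded_dataset([base], {1: 3}, rng)
        for g in data:
            cfg = PhantomConfig(shape=base.shape, seed=int(g.volume.meta["seed"]))
            np.testing.assert_array_equal(g.volume.data, generate_phantom(cfg).data)

    def test_empty_allocation_errors(self, rng):
        with pytest.raises(ValueError):
            make_graded_dataset([PhantomConfig(shape=(16, 24, 24))], {}, rng)

    def test_sharpness_strictly_decreases_with_level(self, rng):
        base = PhantomConfig(shape=(16, 24, 24))
        data = make_graded_dataset([base], {l: 20 for l in range(1, 6)}, rng)
        means = [
            np.mean([mean_gradient_magnitude(g.volume) for g in data if g.grade == l])
            for l in range(1, 6)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_grade_bounds_enforced(self):
        with pytest.raises(ValueError, match="grade"):
            GradedVolume(volume=Volume(np.zeros((2, 2, 2))), grade=6, subject_id="x")
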