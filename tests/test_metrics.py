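"""Quality metrics: quantization rules, PSNR variants, SSIM, perceptual
distance, and the thresholded pixel-difference (IDP) sweep."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldbridge.metrics import (
    DEFAULT_PSI,
    QuantizedPair,
    idp,
    idp_sweep,
    make_pair,
    perceptual_distance,
    psnr,
    quantize,
    ssim,
)

from .oracles import naive_idp, naive_ssim


def _random_pair(seed, size=32, noise=0.05):
    rng = np.random.default_rng(seed)
    a = rng.random((size, size))
    b = np.clip(a + rng.normal(0, noise, a.shape), 0, 1)
    return make_pair(a, b)


class TestQuantize:
    def test_zeros_and_clipping(self):
        assert np.array_equal(quantize(np.zeros((2, 2))), np.zeros((2, 2)))
        assert quantize(np.array([[1.2]]))[0, 0] == 255

    def test_half_rounds_up(self):
        # 0.5 * 255 = 127.5 -> rounds away from zero to 128
        assert quantize(np.array([[0.5]]))[0, 0] == 128

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.array([[np.nan]]))


class TestPSNR:
    def test_identical_images_infinite(self):
        ref = np.arange(16).reshape(4, 4)
        assert psnr(QuantizedPair(ref, ref)) == math.inf

    def test_closed_form_mse_one(self):
        ref = np.zeros((4, 4), dtype=int)
        cand = np.ones((4, 4), dtype=int)  # MSE = 1
        expected = 10 * math.log10(255**2)
        assert psnr(QuantizedPair(ref, cand), "standard") == pytest.approx(
            expected, abs=1e-3
        )
        # the literal 20*log10(Max/MSE) form coincides exactly at MSE = 1
        assert psnr(QuantizedPair(ref, cand), "as_printed") == pytest.approx(
            expected, abs=1e-3
        )

    def test_variants_differ_away_from_mse_one(self):
        pair = _random_pair(1)
        assert psnr(pair, "standard") != pytest.approx(psnr(pair, "as_printed"))

    def test_decreases_with_noise_level(self):
        rng = np.random.default_rng(2)
        a = rng.random((32, 32))
        values = []
        for sigma in (0.01, 0.03, 0.06, 0.12, 0.25):
            b = np.clip(a + rng.normal(0, sigma, a.shape), 0, 1)
            values.append(psnr(make_pair(a, b)))
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            psnr(_random_pair(1), "bogus")


class TestSSIM:
    def test_identical_images_exactly_one(self):
        pair = QuantizedPair(np.arange(256).reshape(16, 16) % 256,
                             np.arange(256).reshape(16, 16) % 256)
        assert ssim(pair, window=11) == 1.0

    def test_constant_images_stabilized(self):
        flat = np.full((16, 16), 128)
        assert ssim(QuantizedPair(flat, flat)) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_sliding_window(self, seed):
        pair = _random_pair(seed)
        assert ssim(pair) == pytest.approx(
            naive_ssim(pair.reference, pair.candidate), abs=1e-7
        )

    def test_symmetric_at_unit_exponents(self):
        pair = _random_pair(3)
        flipped = QuantizedPair(pair.candidate, pair.reference)
        assert ssim(pair) == pytest.approx(ssim(flipped), abs=1e-12)

    def test_bounded_above_by_one(self):
        for seed in range(10):
            assert ssim(_random_pair(seed, noise=0.2)) <= 1.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ssim(_random_pair(1), window=10)

    def test_exponents_change_value(self):
        pair = _random_pair(4, noise=0.1)
        assert ssim(pair, alpha=2.0) != pytest.approx(ssim(pair))


class TestPerceptualDistance:
    def test_identical_is_zero_and_symmetric(self):
        pair = _random_pair(5)
        same = QuantizedPair(pair.reference, pair.reference)
        assert perceptual_distance(same) == 0.0
        flipped = QuantizedPair(pair.candidate, pair.reference)
        assert perceptual_distance(pair) == pytest.approx(
            perceptual_distance(flipped), abs=1e-9
        )

    def test_monotone_in_noise_level(self):
        rng = np.random.default_rng(6)
        a = rng.random((32, 32))
        light = make_pair(a, np.clip(a + rng.normal(0, 0.02, a.shape), 0, 1))
        heavy = make_pair(a, np.clip(a + rng.normal(0, 0.3, a.shape), 0, 1))
        assert perceptual_distance(heavy) > perceptual_distance(light)


class TestIDP:
    def test_hand_worked_two_by_two(self):
        pair = QuantizedPair(np.full((2, 2), 100),
                             np.array([[100, 90], [100, 50]]))
        # relative differences: {0, 0.10, 0, 0.50}; strict > threshold
        assert idp(pair, 0.0).idp == 0.5
        assert idp(pair, 0.10).idp == 0.25
        assert idp(pair, 0.50).idp == 0.0

    def test_identical_zero_at_any_threshold(self):
        ref = np.arange(64).reshape(8, 8)
        for psi in DEFAULT_PSI:
            res = idp(QuantizedPair(ref, ref), psi)
            assert res.idp == 0.0 and res.n_qualifying == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_enumeration(self, seed):
        pair = _random_pair(seed)
        for psi in (0.0, 0.1, 0.25):
            frac, q, n = naive_idp(pair.reference, pair.candidate, psi)
            res = idp(pair, psi)
            assert res.idp == frac and res.n_qualifying == q and res.n_pixels == n

    def test_psi_zero_counts_any_gray_level_difference(self):
        pair = _random_pair(7, noise=0.01)
        expected = np.mean(
            (pair.reference != pair.candidate)
        )
        assert idp(pair, 0.0).idp == pytest.approx(expected)

    def test_zero_policy_background(self):
        ref = np.array([[0, 0], [100, 100]])
        cand = np.array([[0, 5], [100, 100]])
        res = idp(QuantizedPair(ref, cand), 0.75)
        assert res.n_qualifying == 1  # hallucinated signal on empty background
        masked = idp(QuantizedPair(ref, cand), 0.75, "mask_background")
        assert masked.n_pixels == 2 and masked.n_qualifying == 0
        with pytest.raises(ValueError):
            idp(QuantizedPair(ref, cand), 0.1, "bogus")

    def test_invariant_under_joint_pixel_permutation(self, rng):
        pair = _random_pair(8)
        perm = rng.permutation(pair.reference.size)
        shuffled = QuantizedPair(
            pair.reference.ravel()[perm].reshape(pair.reference.shape),
            pair.candidate.ravel()[perm].reshape(pair.candidate.shape),
        )
        for psi in DEFAULT_PSI:
            assert idp(pair, psi).idp == idp(shuffled, psi).idp


class TestIDPSweep:
    def test_default_sweep_thresholds(self):
        assert DEFAULT_PSI == (0.0, 0.10, 0.20, 0.25, 0.50, 0.75)
        results = idp_sweep(_random_pair(1))
        assert [r.psi for r in results] == list(DEFAULT_PSI)

    def test_identical_images_all_zero(self):
        ref = np.arange(64).reshape(8, 8)
        assert all(r.idp == 0.0 for r in idp_sweep(QuantizedPair(ref, ref)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_non_increasing_in_psi(self, seed):
        results = idp_sweep(_random_pair(seed, noise=0.2))
        vals = [r.idp for r in results]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            idp_sweep(_random_pair(1), [0.5, 0.1])


class TestQuantizedPairValidation:
    def test_float_input_rejected(self):
        with pytest.raises(ValueError):
            QuantizedPair(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            QuantizedPair(np.zeros((2, 2), int), np.zeros((3, 3), int))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            QuantizedPair(np.full((2, 2), 300), np.zeros((2, 2), int))
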