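"""Phantom generator: determinism, degradation physics, repeat scans, cohorts."""

import numpy as np
import pytest

from fieldbridge import (
    DegradationParams,
    RigidTransform2D,
    degrade_to_low_field,
    make_cohort,
    make_high_field_subject,
    make_repeat_scan,
)
from fieldbridge.phantom import VENDOR_GAINS

from .oracles import brute_force_shift


class TestHighFieldPhantom:
    def test_deterministic_given_seed(self):
        a = make_high_field_subject("s1", 4, 64, "A", seed=7)
        b = make_high_field_subject("s1", 4, 64, "A", seed=7)
        assert np.array_equal(a.slices, b.slices)
        assert a.slices.shape == (4, 64, 64)

    def test_background_exactly_zero(self):
        stack = make_high_field_subject("s1", 1, 32, "A", seed=7)
        corners = stack.slices[0][[0, 0, -1, -1], [0, -1, 0, -1]]
        assert np.all(corners == 0.0)
        assert np.any(stack.slices[0] == 0.0)

    def test_seed_changes_output(self):
        a = make_high_field_subject("s1", 4, 64, "A", seed=7)
        b = make_high_field_subject("s1", 4, 64, "A", seed=8)
        assert not np.array_equal(a.slices, b.slices)

    def test_intensities_valid(self):
        stack = make_high_field_subject("s2", 3, 48, "B", seed=5)
        assert np.all(np.isfinite(stack.slices))
        assert stack.slices.min() >= 0
        assert stack.slices.max() <= 1

    @pytest.mark.parametrize("n_slices,size", [(0, 64), (4, 16)])
    def test_invalid_dimensions_rejected(self, n_slices, size):
        with pytest.raises(ValueError):
            make_high_field_subject("s1", n_slices, size, "A", seed=1)


class TestDegradation:
    def test_neutral_params_identity(self, phantom64):
        low = degrade_to_low_field(phantom64, DegradationParams.neutral())
        assert np.array_equal(low.slices, phantom64.slices)
        assert low.field_strength == "low"
        assert low.vendor == phantom64.vendor

    def test_noise_mean_absolute_difference(self, phantom64):
        # E|N(0, sigma)| = sigma * sqrt(2/pi); magnitude folding preserves it
        params = DegradationParams.neutral(seed=3).replace(noise_sigma=0.05)
        low = degrade_to_low_field(phantom64, params)
        mad = np.mean(np.abs(low.slices - phantom64.slices))
        assert 0.03 <= mad <= 0.06

    def test_misalignment_recovered_by_shift_search(self, phantom64):
        params = DegradationParams.neutral(seed=3).replace(
            misalign=RigidTransform2D(3, -2, 0)
        )
        low = degrade_to_low_field(phantom64, params)
        shift = brute_force_shift(low.slices[1], phantom64.slices[1])
        assert shift == (3, -2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            DegradationParams(noise_sigma=-0.1)
        with pytest.raises(ValueError):
            DegradationParams(blur_fwhm_px=-1)

    def test_requires_high_field_input(self, phantom64):
        low = degrade_to_low_field(phantom64, DegradationParams.neutral())
        with pytest.raises(ValueError):
            degrade_to_low_field(low, DegradationParams.neutral())

    def test_vendor_gain_preserves_tissue_rank_order(self, phantom64):
        base = DegradationParams.neutral(seed=3)
        low1 = degrade_to_low_field(phantom64, base)
        low2 = degrade_to_low_field(phantom64, base.replace(vendor_gain=1.3))
        s1, s2 = low1.slices[0], low2.slices[0]
        # quartile means keep their ordering under a global gain
        qs = np.quantile(s1[s1 > 0], [0.25, 0.5, 0.75])
        tiers1 = [s1[(s1 > lo) & (s1 <= hi)].mean()
                  for lo, hi in zip([0, *qs], [*qs, np.inf])]
        tiers2 = [s2[(s1 > lo) & (s1 <= hi)].mean()
                  for lo, hi in zip([0, *qs], [*qs, np.inf])]
        assert np.all(np.diff(tiers1) > 0) and np.all(np.diff(tiers2) > 0)


class TestRepeatScans:
    def _low(self, phantom64, sigma):
        params = DegradationParams(
            noise_sigma=sigma, blur_fwhm_px=1.0, bias_amplitude=0.05,
            contrast_scale=0.8, misalign=RigidTransform2D(1.0, -0.5, 1.0),
            seed=21,
        )
        return degrade_to_low_field(phantom64, params), params

    def test_zero_noise_repeat_identical(self, phantom64):
        low, params = self._low(phantom64, 0.0)
        rep = make_repeat_scan(low, params, repeat_seed=99)
        assert np.array_equal(rep.slices, low.slices)
        assert rep.repeat_index == 1

    def test_noisy_repeat_differs_but_deterministic(self, phantom64):
        low, params = self._low(phantom64, 0.03)
        rep1 = make_repeat_scan(low, params, repeat_seed=99)
        rep2 = make_repeat_scan(low, params, repeat_seed=99)
        assert not np.array_equal(rep1.slices, low.slices)
        assert np.array_equal(rep1.slices, rep2.slices)

    def test_same_seed_as_original_rejected(self, phantom64):
        low, params = self._low(phantom64, 0.03)
        with pytest.raises(ValueError):
            make_repeat_scan(low, params, repeat_seed=params.seed)

    def test_repeat_averaging_converges_to_noiseless(self, phantom64):
        """Averaging k repeats approaches the shared noiseless component
        (~1/sqrt(k) shrinkage of the mean deviation)."""
        low, params = self._low(phantom64, 0.05)
        noiseless = degrade_to_low_field(
            phantom64, params.replace(noise_sigma=0.0)
        ).slices
        reps = [make_repeat_scan(low, params, repeat_seed=1000 + k).slices
                for k in range(16)]
        mad4 = np.abs(np.mean(reps[:4], axis=0) - noiseless).mean()
        mad16 = np.abs(np.mean(reps, axis=0) - noiseless).mean()
        assert mad16 < mad4
        assert mad16 < 0.05 / np.sqrt(16) * 1.3


class TestCohort:
    def test_counts_and_vendor_tags(self):
        pairs = make_cohort({"A": 2, "B": 1, "C": 1}, seed=3, n_slices=2,
                            size_px=32)
        assert len(pairs) == 4
        assert [p[0].vendor for p in pairs] == ["A", "A", "B", "C"]
        for high, low in pairs:
            assert high.vendor == low.vendor
            assert low.n_slices == high.n_slices
            assert low.field_strength == "low"

    def test_deterministic(self):
        a = make_cohort({"A": 2}, seed=3, n_slices=2, size_px=32)
        b = make_cohort({"A": 2}, seed=3, n_slices=2, size_px=32)
        for (h1, l1), (h2, l2) in zip(a, b):
            assert np.array_equal(h1.slices, h2.slices)
            assert np.array_equal(l1.slices, l2.slices)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            make_cohort({}, seed=1)
        with pytest.raises(ValueError):
            make_cohort({"A": 0}, seed=1)

    def test_vendor_gains_applied(self):
        assert set(VENDOR_GAINS) == {"A", "B", "C"}
        assert len(set(VENDOR_GAINS.values())) == 3
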