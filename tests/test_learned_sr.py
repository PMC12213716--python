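"""Learned SR models: shapes, determinism, training behavior, architecture
contracts (sub-pixel layout, patch discriminator grid, live transformer
stage)."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from fieldbridge import DegradationParams, degrade_to_low_field, make_high_field_subject
from fieldbridge.learned_sr import (
    ESPCN,
    SRGAN,
    TCGAN,
    SRModelSpec,
    apply_sr,
    build_model,
    pixel_shuffle,
    pixel_unshuffle,
    train,
)
from fieldbridge.nn import Tensor


@pytest.fixture(scope="module")
def tiny_pairs():
    """Ten 32x32 blur+noise degraded slices with their clean counterparts."""
    highs, lows = [], []
    for i in range(10):
        h = make_high_field_subject(f"t{i}", 1, 32, "A", seed=100 + i)
        params = DegradationParams(
            noise_sigma=0.02, blur_fwhm_px=1.5, bias_amplitude=0.0,
            contrast_scale=1.0, seed=200 + i,
        )
        l = degrade_to_low_field(h, params)
        highs.append(h.slices[0])
        lows.append(l.slices[0])
    return np.stack(lows), np.stack(highs)


class TestPixelShuffle:
    def test_identity_at_r_one(self, rng):
        x = rng.normal(size=(4, 3, 3))
        assert np.array_equal(pixel_shuffle(x, 1), x)

    def test_standard_subpixel_layout(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        assert np.array_equal(pixel_shuffle(x, 2)[0], [[1, 2], [3, 4]])

    def test_bijective(self, rng):
        x = rng.normal(size=(2, 8, 5, 5))
        assert np.array_equal(pixel_unshuffle(pixel_shuffle(x, 2), 2), x)

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            pixel_shuffle(rng.normal(size=(3, 2, 2)), 2)


class TestBuildAndShapes:
    def test_espcn_scale_two_shape(self, rng):
        m = ESPCN(scale=2, base_channels=8, epochs=1, seed=0)
        x = rng.random((3, 32, 32))
        y = rng.random((3, 64, 64))
        out = m.fit(x, y).transform(x)
        assert out.shape == (3, 64, 64)

    def test_patch_discriminator_returns_grid(self, rng):
        m = TCGAN(scale=1, base_channels=8, d_model=16, epochs=1,
                  batch_size=4, seed=0)
        x = rng.random((4, 64, 64))
        m.fit(x, x)
        scores = m.discriminator_(Tensor(x[:2][:, None]))
        assert scores.ndim == 4 and scores.shape[2] > 1 and scores.shape[3] > 1

    def test_same_seed_identical_initial_parameters(self):
        a, b = (SRGAN(scale=1, base_channels=8, seed=5) for _ in range(2))
        ra, rb = np.random.default_rng(5), np.random.default_rng(5)
        a._build(ra)
        b._build(rb)
        for pa, pb in zip(a.generator_.state_arrays(), b.generator_.state_arrays()):
            assert np.array_equal(pa, pb)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            SRModelSpec(arch="bogus")

    def test_build_model_dispatch(self):
        for arch, cls in (("espcn", ESPCN), ("srgan", SRGAN), ("tcgan", TCGAN)):
            assert isinstance(build_model(SRModelSpec(arch=arch)), cls)


class TestTraining:
    def test_espcn_loss_decreases(self, tiny_pairs):
        X, y = tiny_pairs
        m = ESPCN(scale=1, base_channels=8, epochs=15, batch_size=5,
                  lr=3e-3, seed=0).fit(X, y)
        assert (m.loss_history_[-1]["generator_loss"]
                < m.loss_history_[0]["generator_loss"])

    def test_identity_fit_sanity(self, tiny_pairs):
        """Scale-1 model on identical input/output pairs approaches the
        identity map."""
        _, X = tiny_pairs
        m = ESPCN(scale=1, base_channels=8, epochs=150, batch_size=5,
                  lr=1e-2, seed=1).fit(X, X)
        mse = float(np.mean((m.transform(X) - X) ** 2))
        assert mse < 1e-3

    def test_training_deterministic(self, tiny_pairs):
        X, y = tiny_pairs
        runs = [
            ESPCN(scale=1, base_channels=8, epochs=5, batch_size=5,
                  seed=3).fit(X, y).loss_history_[-1]["generator_loss"]
            for _ in range(2)
        ]
        assert runs[0] == pytest.approx(runs[1], abs=1e-6)

    @pytest.mark.parametrize("cls", [SRGAN, TCGAN])
    def test_gan_losses_stay_finite(self, cls, tiny_pairs):
        X, y = tiny_pairs
        m = cls(scale=1, base_channels=8, epochs=3, batch_size=5, seed=0)
        m.fit(X, y)
        for rec in m.loss_history_:
            assert np.isfinite(rec["generator_loss"])
            assert np.isfinite(rec["discriminator_loss"])

    def test_misshapen_pairs_rejected(self, rng):
        m = ESPCN(scale=2, epochs=1)
        with pytest.raises(ValueError):
            m.fit(rng.random((3, 16, 16)), rng.random((3, 16, 16)))

    def test_train_wrapper(self, tiny_pairs):
        X, y = tiny_pairs
        model = ESPCN(scale=1, base_channels=8, batch_size=5, seed=0)
        final = train(model, list(zip(X, y)), epochs=3)
        assert "generator_loss" in final and model.n_epochs_ == 3


class TestInference:
    def test_untrained_transform_rejected(self, rng):
        with pytest.raises(NotFittedError):
            ESPCN(scale=1).transform(rng.random((2, 16, 16)))

    def test_output_clipped_and_deterministic(self, tiny_pairs):
        X, y = tiny_pairs
        m = ESPCN(scale=1, base_channels=8, epochs=3, batch_size=5, seed=0)
        m.fit(X, y)
        o1, o2 = m.transform(X), m.transform(X)
        assert np.array_equal(o1, o2)
        assert o1.min() >= 0.0 and o1.max() <= 1.0

    def test_apply_sr_tags_output(self, tiny_pairs):
        X, y = tiny_pairs
        m = ESPCN(scale=1, base_channels=8, epochs=2, batch_size=5, seed=0)
        m.fit(X, y)
        high = make_high_field_subject("s9", 2, 32, "B", seed=9)
        low = degrade_to_low_field(high, DegradationParams(seed=2))
        out = apply_sr(m, low)
        assert out.field_strength == "high"
        assert out.vendor == "B"
        assert out.slices.shape == low.slices.shape

    def test_estimator_cloneable(self):
        m = TCGAN(scale=1, base_channels=8, depth=1, seed=4)
        c = clone(m)
        assert c.get_params() == m.get_params()


class TestTCGANSeriesComposition:
    def test_transformer_stage_is_live(self, tiny_pairs):
        """Ablating the transformer stage changes the output for a fixed
        seed, proving the series composition is exercised."""
        X, y = tiny_pairs
        kw = dict(scale=1, base_channels=8, d_model=16, depth=1, epochs=2,
                  batch_size=5, seed=0)
        with_t = TCGAN(use_transformer=True, **kw).fit(X, y)
        without_t = TCGAN(use_transformer=False, **kw).fit(X, y)
        assert not np.allclose(with_t.transform(X[:2]), without_t.transform(X[:2]))


class TestCheckpointRoundTrip:
    def test_save_load_reproduces_outputs(self, tiny_pairs, tmp_path):
        X, y = tiny_pairs
        m = ESPCN(scale=1, base_channels=8, epochs=3, batch_size=5, seed=0)
        m.fit(X, y)
        ckpt = tmp_path / "espcn.npz"
        m.save(ckpt)
        fresh = ESPCN(scale=1, base_channels=8, epochs=3, batch_size=5, seed=0)
        fresh.load(ckpt)
        assert np.array_equal(fresh.transform(X[:3]), m.transform(X[:3]))

    def test_architecture_mismatch_rejected(self, tiny_pairs, tmp_path):
        X, y = tiny_pairs
        m = ESPCN(scale=1, base_channels=8, epochs=1, batch_size=5, seed=0)
        m.fit(X, y)
        ckpt = tmp_path / "m.npz"
        m.save(ckpt)
        other = SRGAN(scale=1, base_channels=8, seed=0)
        with pytest.raises(ValueError):
            other.load(ckpt)

    def test_unfitted_save_rejected(self, tmp_path):
        with pytest.raises(NotFittedError):
            ESPCN(scale=1).save(tmp_path / "x.npz")
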