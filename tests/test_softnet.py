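"""U-Net construction, loss, SGD update and subtraction."""

import numpy as np
import pytest

from spinebmd import phantom, softnet


def unet_param_count_oracle(depth: int, base: int) -> int:
    """Enumerate convolution shapes independently of the implementation."""
    total = 0

    def conv(c_in, c_out, k):
        return c_out * c_in * k * k + c_out

    c_in = 1
    for lvl in range(depth):
        c_out = base * 2**lvl
        total += conv(c_in, c_out, 3) + conv(c_out, c_out, 3)
        c_in = c_out
    c_bot = base * 2**depth
    total += conv(c_in, c_bot, 3) + conv(c_bot, c_bot, 3)
    c_in = c_bot
    for lvl in reversed(range(depth)):
        c_out = base * 2**lvl
        total += conv(c_in, c_out, 3)       # up-conv
        total += conv(2 * c_out, c_out, 3)  # after skip concat
        total += conv(c_out, c_out, 3)
        c_in = c_out
    total += conv(c_in, 1, 1)
    return total


class TestBuild:
    def test_output_shape_matches_input(self):
        model = softnet.build_unet(softnet.UNetSpec(depth=2, base_channels=4))
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        assert model.forward(x).shape == (1, 1, 64, 64)

    def test_seeded_init_identical(self):
        spec = softnet.UNetSpec(seed=9)
        a, b = softnet.build_unet(spec), softnet.build_unet(spec)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_parameter_count_matches_enumeration(self):
        model = softnet.build_unet(softnet.UNetSpec(depth=3, base_channels=16))
        assert model.n_parameters() == unet_param_count_oracle(3, 16) == 535505

    def test_incompatible_side_rejected(self):
        model = softnet.build_unet(softnet.UNetSpec(depth=3))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 36, 36), dtype=np.float32))

    def test_backward_matches_numeric_gradient(self, rng):
        """Analytic backprop agrees with central finite differences."""
        model = softnet.build_unet(softnet.UNetSpec(depth=2, base_channels=3, seed=0))
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        y = rng.random((2, 1, 16, 16)).astype(np.float32)
        pred, caches = model.forward(x, want_cache=True)
        grads = model.backward((2.0 / pred.size) * (pred - y), caches)
        for name in ("enc0_conv1_W", "bot_conv2_b", "dec1_up_W", "out_W"):
            p = model.params[name]
            idx = tuple(0 for _ in p.shape)
            eps = 1e-3
            orig = p[idx]
            p[idx] = orig + eps
            lp = softnet.mse_loss(y, model.forward(x))
            p[idx] = orig - eps
            lm = softnet.mse_loss(y, model.forward(x))
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, rel=0.05, abs=1e-5)


class TestMseLoss:
    def test_identity_is_zero(self, rng):
        y = rng.random((3, 4))
        assert softnet.mse_loss(y, y) == 0.0

    def test_unit_difference(self):
        assert softnet.mse_loss(np.zeros(2), np.ones(2)) == pytest.approx(1.0)

    def test_matches_scalar_loop_oracle(self, rng):
        y, yhat = rng.random(50), rng.random(50)
        oracle = sum((a - b) ** 2 for a, b in zip(y, yhat)) / 50
        assert softnet.mse_loss(y, yhat) == pytest.approx(oracle)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            softnet.mse_loss(np.zeros(3), np.zeros(4))


class TestSgdStep:
    def test_scalar_update(self):
        out = softnet.sgd_step({"w": np.array([1.0])}, {"w": np.array([0.5])}, 0.1)
        assert out["w"][0] == pytest.approx(0.95)

    def test_zero_gradient_fixed_point(self, rng):
        p = {"w": rng.random(5)}
        out = softnet.sgd_step(p, {"w": np.zeros(5)}, 0.1)
        np.testing.assert_array_equal(out["w"], p["w"])

    def test_quadratic_converges_to_closed_form(self):
        """On J(θ)=θ² with η=0.1, θ_t = 0.8^t — 50 steps reach |θ|<1e-4."""
        theta = {"w": np.array([1.0])}
        for t in range(50):
            grad = {"w": 2.0 * theta["w"]}
            theta = softnet.sgd_step(theta, grad, 0.1)
            assert theta["w"][0] == pytest.approx(0.8 ** (t + 1))
        assert abs(theta["w"][0]) < 1e-4

    def test_nonfinite_gradient_raises(self):
        with pytest.raises(softnet.TrainingError):
            softnet.sgd_step({"w": np.ones(1)}, {"w": np.array([np.nan])}, 0.1)


@pytest.fixture(scope="module")
def trained(small_cohort):
    """Default architecture fitted briefly on 16 phantom pairs."""
    spec = softnet.UNetSpec(epochs=15, seed=0)
    model = softnet.build_unet(spec)
    state = softnet.train_unet(model, small_cohort[:16], spec)
    return model, state


class TestTraining:
    def test_loss_decreases(self, trained):
        _, state = trained
        losses = [tr for tr, _ in state.epoch_losses]
        assert losses[-1] < 0.5 * losses[0]

    def test_training_deterministic(self, small_cohort):
        spec = softnet.UNetSpec(depth=2, base_channels=4, epochs=2, seed=7)
        histories = []
        for _ in range(2):
            model = softnet.build_unet(spec)
            histories.append(softnet.train_unet(model, small_cohort[:8], spec))
        assert histories[0].epoch_losses == histories[1].epoch_losses

    def test_prediction_beats_mean_image_baseline(self, trained, small_cohort):
        model, _ = trained
        held_out = small_cohort[20:30]
        mean_image = np.mean([s.soft_label for s in small_cohort[:16]], axis=0)
        net = np.mean(
            [softnet.mse_loss(s.soft_label,
                              softnet.predict_soft_tissue(model, s.input_image))
             for s in held_out]
        )
        baseline = np.mean(
            [softnet.mse_loss(s.soft_label, mean_image) for s in held_out]
        )
        assert net < baseline

    def test_prediction_shape_and_range(self, trained, small_cohort):
        model, _ = trained
        out = softnet.predict_soft_tissue(model, small_cohort[0].input_image)
        assert out.shape == small_cohort[0].input_image.shape
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestSubtraction:
    def test_soft_equals_original_gives_zero(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(
            softnet.subtract_soft_tissue(img, img), np.zeros_like(img)
        )

    def test_zero_soft_is_identity(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(
            softnet.subtract_soft_tissue(img, np.zeros_like(img)), img
        )

    def test_clamped_at_zero(self):
        out = softnet.subtract_soft_tissue(np.full((4, 4), 0.7), np.full((4, 4), 0.9))
        np.testing.assert_array_equal(out, np.zeros((4, 4)))

    def test_reconstruction_bound_on_phantoms(self, small_cohort):
        """Subtracting the true soft label recovers bone up to clamp + noise."""
        for s in small_cohort[:10]:
            recovered = softnet.subtract_soft_tissue(s.input_image, s.soft_label)
            # noise sd 0.01 -> variance 1e-4; clamping interactions stay below 2x
            assert softnet.mse_loss(s.bone_truth, recovered) < 2e-4 * 2


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        spec = softnet.UNetSpec(depth=2, base_channels=4, seed=3)
        model = softnet.build_unet(spec)
        path = tmp_path / "unet.npz"
        softnet.save_checkpoint(model, path)
        loaded = softnet.load_checkpoint(path)
        assert loaded.spec == spec
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], loaded.params[k])
        x = np.random.default_rng(0).random((1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))
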