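"""Grad-CAM and Integrated Gradients against closed forms and finite
differences."""

import numpy as np
import pytest

from fundusxai.attribution import (
    AdapterConfigurationError,
    IGConfig,
    grad_cam,
    integrated_gradients,
    target_class_policy,
)
from fundusxai.synthetic_data import SceneSpec, generate_scene

from conftest import AffineAdapter, MeanPoolAdapter, SquareAdapter


class TestGradCam:
    def test_mean_pooled_feature_map_closed_form(self):
        # score = mean(A) -> alpha = 1/4, cam = ReLU(A/4)
        adapter = MeanPoolAdapter([[1.0, -1.0], [0.0, 2.0]])
        cam = grad_cam(adapter, image=np.zeros((2, 2, 3)), target_class=0)
        np.testing.assert_allclose(cam.values, [[0.25, 0.0], [0.0, 0.5]])

    def test_negative_contribution_clamps_to_zero(self):
        adapter = MeanPoolAdapter([[-1.0, -2.0], [-3.0, -0.5]])
        cam = grad_cam(adapter, image=np.zeros((2, 2, 3)), target_class=0)
        assert np.all(cam.values == 0.0)

    def test_nonnegative_on_fixture(self, fixture_model, mixed_scene):
        cam = grad_cam(fixture_model, mixed_scene.image, 2)
        assert np.all(cam.values >= 0.0)

    def test_adapter_without_conv_layer_rejected(self):
        with pytest.raises((AdapterConfigurationError, RuntimeError)):
            grad_cam(AffineAdapter(np.ones((2, 2, 3))), np.zeros((2, 2, 3)), 0)

    def test_alphas_match_finite_difference_of_head(self, fixture_model, ma_scene):
        """The adapter's conv-layer gradients must equal a finite-difference
        derivative of the class score with respect to each feature map."""
        cls = 1
        acts, grads = fixture_model.conv_activations_and_gradients(ma_scene.image, cls)
        h, w, k = acts.shape
        f = acts.mean(axis=(0, 1))
        eps = 1e-4
        for channel in range(k):
            bumped = f.copy()
            bumped[channel] += eps / (h * w)  # one pixel of A^k bumped by eps
            fd = (
                fixture_model._logits_from_features(bumped)[cls]
                - fixture_model._logits_from_features(f)[cls]
            ) / eps
            assert fd == pytest.approx(grads[0, 0, channel], rel=1e-3, abs=1e-12)
            # alpha (the spatial mean) equals the constant per-pixel gradient
            assert grads[..., channel].mean() == pytest.approx(fd, rel=1e-3, abs=1e-12)

    def test_invariant_to_shifting_other_logits(self, fixture_model, ma_scene):
        """Pre-softmax scores: adding a constant to non-target logits
        leaves the target-class Grad-CAM unchanged."""
        import copy

        cls = 1
        cam = grad_cam(fixture_model, ma_scene.image, cls)
        shifted = copy.deepcopy(fixture_model)
        shifted.b = shifted.b + 5.0
        shifted.b[cls] -= 5.0  # shift every logit except the target
        cam2 = grad_cam(shifted, ma_scene.image, cls)
        np.testing.assert_allclose(cam.values, cam2.values)


class TestIntegratedGradients:
    @pytest.mark.parametrize("steps", [1, 2, 7, 64])
    @pytest.mark.parametrize("rule", ["left", "trapezoid"])
    def test_exact_on_affine_model(self, steps, rule):
        w = np.array([1.0, 2.0])
        x = np.array([3.0, 4.0])
        adapter = AffineAdapter(w, b=5.0)
        att = integrated_gradients(
            adapter, x, 0, IGConfig(steps=steps, riemann_rule=rule)
        )
        np.testing.assert_allclose(att.values, [3.0, 8.0], rtol=1e-14)
        total = att.values.sum()
        assert total == pytest.approx(
            adapter.class_score(x, 0) - adapter.class_score(np.zeros(2), 0), rel=1e-14
        )

    def test_square_model_left_rule_four_steps(self):
        # F(x)=x^2, x=1: mean gradient 2*(0+.25+.5+.75)/4 = 0.75
        att = integrated_gradients(
            SquareAdapter(), np.array([1.0]), 0, IGConfig(steps=4, riemann_rule="left")
        )
        assert att.values[0] == pytest.approx(0.75)

    def test_completeness_residual_shrinks_with_steps(self, fixture_model):
        scene = generate_scene(SceneSpec(n_ex=3, n_he=2, image_size=128, seed=11))
        x = scene.image
        cls = target_class_policy(fixture_model, x)
        gap = fixture_model.class_score(x, cls) - fixture_model.class_score(
            np.zeros_like(x), cls
        )
        residuals = []
        for steps in (16, 64, 256):
            att = integrated_gradients(fixture_model, x, cls, IGConfig(steps=steps))
            residuals.append(abs(att.values.sum() - gap) / abs(gap))
        assert residuals[0] > residuals[1] > residuals[2]
        assert residuals[2] <= 1e-3

    def test_fast_path_matches_per_step_loop(self, fixture_model):
        """The linearity-based path gradient must equal the generic
        one-gradient-per-step fallback."""
        scene = generate_scene(SceneSpec(n_ma=2, image_size=96, seed=5))
        x = scene.image

        class NoFastPath:
            def __init__(self, inner):
                self._inner = inner

            def predict(self, image):
                return self._inner.predict(image)

            def class_score(self, image, c):
                return self._inner.class_score(image, c)

            def input_gradient(self, image, c):
                return self._inner.input_gradient(image, c)

        for rule in ("left", "trapezoid"):
            cfg = IGConfig(steps=8, riemann_rule=rule)
            fast = integrated_gradients(fixture_model, x, 1, cfg)
            slow = integrated_gradients(NoFastPath(fixture_model), x, 1, cfg)
            np.testing.assert_allclose(fast.values, slow.values, rtol=1e-10, atol=1e-12)

    def test_baseline_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            integrated_gradients(
                AffineAdapter(np.ones(3)),
                np.ones(3),
                0,
                IGConfig(baseline=np.zeros(4)),
            )

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError, match="steps"):
            IGConfig(steps=0)


class TestInputGradientFiniteDifference:
    def test_fixture_input_gradient_matches_finite_difference(self, fixture_model):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 0.8, size=(24, 24, 3))
        cls = 2
        g = fixture_model.input_gradient(x, cls)
        eps = 1e-6
        for _ in range(12):
            i, j, c = rng.integers(0, 24), rng.integers(0, 24), rng.integers(0, 3)
            xp = x.copy()
            xp[i, j, c] += eps
            fd = (
                fixture_model.class_score(xp, cls) - fixture_model.class_score(x, cls)
            ) / eps
            assert g[i, j, c] == pytest.approx(fd, rel=1e-3, abs=1e-9)


class TestTargetClassPolicy:
    def test_argmax_of_probabilities(self, fixture_model):
        class Stub:
            def predict(self, image):
                return np.array([0.1, 0.7, 0.2])

        assert target_class_policy(Stub(), None) == 1

    def test_tie_breaks_to_lowest_index(self):
        class Stub:
            def predict(self, image):
                return np.array([0.5, 0.5])

        assert target_class_policy(Stub(), None) == 0

    def test_pure_ma_scene_predicts_mild_dr(self, fixture_model, ma_scene):
        assert target_class_policy(fixture_model, ma_scene.image) == 1
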