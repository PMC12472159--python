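import numpy as np
import pytest

from fundusxai.synthetic_data import FixtureCNN, SceneSpec, generate_scene


class AffineAdapter:
    """Two-class toy model: class-0 score w.x + b, class-1 score 0."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)

    def predict(self, image):
        s = self.class_score(image, 0)
        e = np.exp([s, 0.0] - max(s, 0.0))
        return e / e.sum()

    def class_score(self, image, class_index):
        return float(np.sum(self.w * image) + self.b) if class_index == 0 else 0.0

    def input_gradient(self, image, class_index):
        return self.w.copy() if class_index == 0 else np.zeros_like(self.w)

    def conv_activations_and_gradients(self, image, class_index):
        raise RuntimeError("affine model has no convolutional layer")


class SquareAdapter:
    """Scalar model F(x) = x**2 on a 1-element image."""

    def predict(self, image):
        return np.array([1.0])

    def class_score(self, image, class_index):
        return float(np.sum(np.asarray(image) ** 2))

    def input_gradient(self, image, class_index):
        return 2.0 * np.asarray(image, dtype=float)


class MeanPoolAdapter:
    """Single-feature-map model whose class score is the spatial mean of
    the feature map: the Grad-CAM closed-form case."""

    def __init__(self, feature_map):
        self.a = np.asarray(feature_map, dtype=float)

    def predict(self, image):
        return np.array([1.0])

    def class_score(self, image, class_index):
        return float(self.a.mean())

    def conv_activations_and_gradients(self, image, class_index):
        grads = np.full_like(self.a, 1.0 / self.a.size)
        return self.a, grads


@pytest.fixture(scope="session")
def fixture_model():
    return FixtureCNN()


@pytest.fixture(scope="session")
def ma_scene():
    return generate_scene(SceneSpec(n_ma=6, seed=3), image_id="ma3")


@pytest.fixture(scope="session")
def mixed_scene():
    return generate_scene(SceneSpec(n_ma=2, n_ex=3, n_he=3, seed=7), image_id="mix7")
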