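"""Gradient-based attribution maps (Grad-CAM and Integrated Gradients).

Both methods answer the same question about a diabetic-retinopathy
classifier: which parts of a fundus image drive the score of a given
severity class?  Grad-CAM works on the last convolutional layer —
feature maps are weighted by the spatial mean of the class-score
gradient and rectified — so its maps are coarse but class-focused.
Integrated Gradients works at pixel level: it averages the input
gradient along a straight-line path from a baseline image to the input
and scales by the input–baseline difference, which makes the
attributions satisfy the completeness axiom (they sum to the difference
in class score between input and baseline).

Classifiers enter through the :class:`ClassifierAdapter` contract so
any autodiff framework (or a hand-differentiated model, like the
bundled reference CNN) can be analysed.  Gradients are taken with
respect to the *pre-softmax* class score; this avoids the saturation of
softmax probabilities and keeps Grad-CAM invariant to shifting the
logits of the other classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Protocol, runtime_checkable

import numpy as np
import tifffile

__all__ = [
    "ClassifierAdapter",
    "IGConfig",
    "RawAttribution",
    "grad_cam",
    "integrated_gradients",
    "target_class_policy",
    "save_attribution",
    "load_attribution",
    "AdapterConfigurationError",
    "AttributionNumericError",
]


class AdapterConfigurationError(RuntimeError):
    """The adapter does not expose what the requested method needs."""


class AttributionNumericError(ArithmeticError):
    """Non-finite values were produced while attributing an image."""


@runtime_checkable
class ClassifierAdapter(Protocol):
    """Contract a classifier must satisfy to be attributable.

    Implementations must provide:

    ``predict(image) -> ndarray``
        Per-class probability vector; non-negative, sums to 1 within
        1e-6.

    ``class_score(image, class_index) -> float``
        Pre-softmax score of one class (the quantity the gradients
        below differentiate).

    ``input_gradient(image, class_index) -> ndarray``
        Gradient of the class score with respect to every input pixel
        and channel; same shape as ``image``.

    ``conv_activations_and_gradients(image, class_index) -> (A, dA)``
        Feature maps ``A`` of the designated last convolutional layer,
        shape (H', W', K), and the gradient ``dA`` of the class score
        with respect to them, same shape.  Adapters without a
        convolutional layer raise :class:`AdapterConfigurationError`.

    Optionally, ``mean_path_gradient(baseline, image, alphas, weights,
    class_index)`` may return the weighted mean of input gradients
    along the straight-line path directly; when present,
    :func:`integrated_gradients` uses it instead of one
    ``input_gradient`` call per path point.
    """

    def predict(self, image: np.ndarray) -> np.ndarray: ...

    def class_score(self, image: np.ndarray, class_index: int) -> float: ...

    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray: ...

    def conv_activations_and_gradients(
        self, image: np.ndarray, class_index: int
    ) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass(frozen=True)
class IGConfig:
    """Integrated-Gradients settings.

    steps : number of Riemann points along the path (>= 1).
    baseline : reference image x'; ``None`` means an all-zero image in
        the model's input space.
    riemann_rule : 'trapezoid' (default; faster convergence of the
        completeness residual) or 'left'.
    channel_reduction : how per-channel attributions collapse to one
        heatmap channel downstream; 'abs_sum' (default) or
        'signed_sum'.  Recorded here, applied by the heatmap pipeline.
    """

    steps: int = 64
    baseline: np.ndarray | None = None
    riemann_rule: Literal["left", "trapezoid"] = "trapezoid"
    channel_reduction: Literal["abs_sum", "signed_sum"] = "abs_sum"

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError(f"steps must be >= 1, got {self.steps}")
        if self.riemann_rule not in ("left", "trapezoid"):
            raise ValueError(f"unknown riemann_rule {self.riemann_rule!r}")
        if self.channel_reduction not in ("abs_sum", "signed_sum"):
            raise ValueError(
                f"unknown channel_reduction {self.channel_reduction!r}"
            )


@dataclass
class RawAttribution:
    """Unnormalized attribution field straight out of a method.

    ``values`` live on the conv-layer grid for Grad-CAM (always
    non-negative, post-ReLU) and per pixel per channel for IG (signed).
    """

    values: np.ndarray
    method: Literal["gradcam", "ig"]
    target_class: int
    channel_reduction: str = "abs_sum"

    def reduced(self) -> np.ndarray:
        """Collapse to a single-channel field on the spatial grid."""
        v = self.values
        if v.ndim == 2:
            return v
        if self.channel_reduction == "abs_sum":
            return np.abs(v).sum(axis=-1)
        return v.sum(axis=-1)


def target_class_policy(adapter: ClassifierAdapter, image: np.ndarray) -> int:
    """Class to attribute: the predicted class, ties to the lowest index.

    Heatmaps explain the decision the classifier actually made, so the
    attribution target is the argmax of the predicted probability
    vector, not the true label.
    """
    probs = np.asarray(adapter.predict(image), dtype=float)
    return int(np.argmax(probs))  # np.argmax returns the first maximum


def grad_cam(
    adapter: ClassifierAdapter, image: np.ndarray, target_class: int
) -> RawAttribution:
    """Grad-CAM map L^c = ReLU(sum_k alpha_k^c A^k) on the conv grid.

    alpha_k^c is the spatial mean of the gradient of the target-class
    score with respect to feature map A^k.  The output is non-negative
    and all-zero when every feature map has non-positive net influence
    on the class score.
    """
    if not hasattr(adapter, "conv_activations_and_gradients"):
        raise AdapterConfigurationError(
            "adapter exposes no convolutional layer for Grad-CAM"
        )
    acts, grads = adapter.conv_activations_and_gradients(image, target_class)
    acts = np.asarray(acts, dtype=float)
    grads = np.asarray(grads, dtype=float)
    if acts.shape != grads.shape:
        raise AdapterConfigurationError(
            f"activation shape {acts.shape} != gradient shape {grads.shape}"
        )
    if not np.all(np.isfinite(grads)):
        raise AttributionNumericError("non-finite conv-layer gradients")
    if acts.ndim == 2:  # single feature map
        acts = acts[..., None]
        grads = grads[..., None]
    alphas = grads.mean(axis=(0, 1))  # (K,)
    cam = np.maximum(np.tensordot(acts, alphas, axes=([-1], [0])), 0.0)
    return RawAttribution(values=cam, method="gradcam", target_class=int(target_class))


def _path_points(rule: str, steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Interpolation coefficients and quadrature weights for the path."""
    if rule == "left":
        alphas = np.arange(steps) / steps
        weights = np.full(steps, 1.0 / steps)
    else:  # trapezoid
        alphas = np.linspace(0.0, 1.0, steps + 1)
        weights = np.full(steps + 1, 1.0 / steps)
        weights[0] = weights[-1] = 0.5 / steps
    return alphas, weights


def integrated_gradients(
    adapter: ClassifierAdapter,
    image: np.ndarray,
    target_class: int,
    cfg: IGConfig | None = None,
) -> RawAttribution:
    """IG attribution (x - x') * mean of input gradients along the path.

    The path is the straight line x' + alpha (x - x'); the mean is a
    Riemann sum with ``cfg.steps`` points under ``cfg.riemann_rule``.
    For an affine model the result is exact for any number of steps;
    for smooth models the completeness residual shrinks as steps grow.
    """
    cfg = cfg or IGConfig()
    image = np.asarray(image, dtype=float)
    baseline = (
        np.zeros_like(image) if cfg.baseline is None else np.asarray(cfg.baseline, float)
    )
    if baseline.shape != image.shape:
        raise ValueError(
            f"baseline shape {baseline.shape} does not match image {image.shape}"
        )
    alphas, weights = _path_points(cfg.riemann_rule, cfg.steps)
    delta = image - baseline

    if hasattr(adapter, "mean_path_gradient"):
        mean_grad = adapter.mean_path_gradient(
            baseline, image, alphas, weights, target_class
        )
    else:
        mean_grad = np.zeros_like(image)
        for a, w in zip(alphas, weights):
            g = adapter.input_gradient(baseline + a * delta, target_class)
            mean_grad += w * np.asarray(g, dtype=float)
    values = delta * mean_grad
    if not np.all(np.isfinite(values)):
        raise AttributionNumericError("non-finite IG attributions")
    return RawAttribution(
        values=values,
        method="ig",
        target_class=int(target_class),
        channel_reduction=cfg.channel_reduction,
    )


def save_attribution(path, raw: RawAttribution) -> None:
    """Write the reduced attribution field as 32-bit float TIFF."""
    tifffile.imwrite(str(path), raw.reduced().astype(np.float32))


def load_attribution(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)
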