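"""Synthetic fundus scenes with pixel-registered lesion masks, plus a
fixed-weight reference CNN classifier with exact analytic gradients.

The generator emulates the geometry a fundus camera produces — a
circular field of view (FOV) on a black frame, a bright optic disc, a
darker macula, vessel arcs — and plants high-contrast lesions of the
types the ICDR grading vocabulary names: microaneurysms (MA, tiny dark
dots), hard exudates (EX, bright yellow blobs), soft exudates (SE,
pale larger blobs), hemorrhages (HE, dark red blobs) and
neovascularization (NV, thin bright vessel tangles).  Every planted
shape is rasterized into both the image and that lesion type's binary
mask with identical coordinates, so overlap ground truth is exact.  An
optional grey "spot" mimics a camera artifact (dust on the lens): it
appears in the image but in no mask, acting as a confounder.

Grades follow the ICDR decision rule: no lesions is grade 0, only
microaneurysms grade 1, any neovascularization grade 4, more than a
threshold of hemorrhages in each of the four quadrants (and no NV)
grade 3, anything else with lesions grade 2.  Venous beading and IRMA
are not rendered, so the severe grade here rests on the hemorrhage
clause alone.

The reference classifier is a small convolutional scorer with fixed,
hand-designed weights: seven zero-mean template kernels (one per
lesion/landmark appearance) -> softplus -> global average pooling ->
linear 5-class head.  Its forward pass and gradients are written out
analytically, which makes it an exact oracle for attribution code:
input gradients, conv-layer gradients and class scores are all
consistent by construction (and checked against finite differences in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .mask_ops import LesionMask

__all__ = [
    "LesionInventory",
    "SpotSpec",
    "SceneSpec",
    "SyntheticSample",
    "grade_rule",
    "generate_scene",
    "FixtureCNN",
    "fixture_classifier",
    "SceneGenerationError",
    "SEVERE_HE_PER_QUADRANT",
]

#: More hemorrhages than this in every quadrant (with no NV) is severe DR.
SEVERE_HE_PER_QUADRANT = 20


class SceneGenerationError(RuntimeError):
    """Lesions could not be placed inside the field of view."""


# --------------------------------------------------------------------------
# grading


@dataclass
class LesionInventory:
    """Counts of planted lesions; hemorrhages are tracked per quadrant."""

    ma: int = 0
    ex: int = 0
    se: int = 0
    nv: int = 0
    he_quadrants: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def he(self) -> int:
        return sum(self.he_quadrants)

    def total(self) -> int:
        return self.ma + self.ex + self.se + self.nv + self.he


def grade_rule(
    inventory: LesionInventory, severe_threshold: int = SEVERE_HE_PER_QUADRANT
) -> int:
    """ICDR grade implied by a lesion inventory.

    0: no lesions.  1: only microaneurysms.  4: any neovascularization.
    3: more than ``severe_threshold`` hemorrhages in each of the four
    quadrants, without NV.  2: anything else with lesions.
    """
    counts = (inventory.ma, inventory.ex, inventory.se, inventory.nv, *inventory.he_quadrants)
    if any(c < 0 for c in counts):
        raise ValueError(f"lesion counts must be non-negative, got {inventory}")
    if inventory.total() == 0:
        return 0
    if inventory.nv > 0:
        return 4
    if all(q > severe_threshold for q in inventory.he_quadrants):
        return 3
    if inventory.ma > 0 and inventory.ex == inventory.se == inventory.he == 0:
        return 1
    return 2


# --------------------------------------------------------------------------
# scene specification


@dataclass(frozen=True)
class SpotSpec:
    """Camera-artifact smudge: centre (fractions of image size), radius px,
    blend strength in (0, 1]."""

    row_frac: float = 0.72
    col_frac: float = 0.45
    radius: int = 7
    intensity: float = 0.5


@dataclass
class SceneSpec:
    """Recipe for one synthetic fundus scene.

    Lesion counts plus per-type radius ranges (px).  All shapes are
    placed uniformly inside the FOV disc, clear of the optic disc and
    each other where feasible.
    """

    image_size: int = 224
    fov_radius_frac: float = 0.48
    n_ma: int = 0
    n_ex: int = 0
    n_se: int = 0
    n_he: int = 0
    n_nv: int = 0
    ma_radius: tuple[int, int] = (3, 4)
    ex_radius: tuple[int, int] = (4, 6)
    se_radius: tuple[int, int] = (6, 8)
    he_radius: tuple[int, int] = (5, 7)
    nv_extent: int = 14  # half-size of the vessel-tangle bounding box
    od_radius_frac: float = 0.10
    mc_radius_frac: float = 0.07
    vessels: bool = True
    artifact_spot: SpotSpec | None = None
    seed: int = 0


@dataclass
class SyntheticSample:
    """A generated scene: image in [0,1], per-type masks, ICDR grade."""

    image: np.ndarray  # (S, S, 3) float64 in [0, 1]
    masks: dict[str, LesionMask]
    grade: int
    inventory: LesionInventory
    spec: SceneSpec
    image_id: str = ""


# --------------------------------------------------------------------------
# rasterization helpers


def _disk_coords(shape: tuple[int, int], center, radius) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    sel = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return np.nonzero(sel)


def _paint(image, coords, color, alpha=1.0) -> None:
    color = np.asarray(color, dtype=float)
    image[coords] = (1 - alpha) * image[coords] + alpha * color


def _place_positions(
    rng: np.random.Generator,
    n: int,
    radius_max: float,
    fov_center: float,
    fov_radius: float,
    forbidden: list[tuple[float, float, float]],
    max_tries: int = 4000,
    balance_quadrants: bool = False,
) -> list[tuple[int, int]]:
    """Uniform positions fully inside the FOV avoiding forbidden discs.

    With ``balance_quadrants``, positions are assigned to the four
    image quadrants round-robin, so n shapes split as evenly as
    possible (used for hemorrhages, whose per-quadrant counts decide
    the severe grade).
    """
    out: list[tuple[int, int]] = []
    tries = 0
    limit = fov_radius - radius_max - 2
    if limit <= 0:
        raise SceneGenerationError(
            f"shape radius {radius_max} too large for FOV radius {fov_radius}"
        )
    while len(out) < n:
        if tries >= max_tries:
            raise SceneGenerationError(
                f"could not place {n} shapes of radius {radius_max} in the FOV"
            )
        tries += 1
        rho = limit * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        r = int(round(fov_center + rho * np.sin(theta)))
        c = int(round(fov_center + rho * np.cos(theta)))
        if any((r - fr) ** 2 + (c - fc) ** 2 < (fd + radius_max) ** 2 for fr, fc, fd in forbidden):
            continue
        if balance_quadrants:
            quadrant = (0 if r < fov_center else 2) + (0 if c < fov_center else 1)
            if quadrant != len(out) % 4:
                continue
        out.append((r, c))
    return out


def _nv_tangle(rng: np.random.Generator, center, extent: int, shape) -> tuple[np.ndarray, np.ndarray]:
    """Thin random-walk vessel tangle as pixel coordinates."""
    r, c = float(center[0]), float(center[1])
    pts = set()
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(6 * extent):
        heading += rng.normal(0, 0.6)
        r += np.sin(heading)
        c += np.cos(heading)
        r = float(np.clip(r, center[0] - extent, center[0] + extent))
        c = float(np.clip(c, center[1] - extent, center[1] + extent))
        ri, ci = int(round(r)), int(round(c))
        for dr in (0, 1):
            for dc in (0, 1):
                rr, cc = ri + dr, ci + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    pts.add((rr, cc))
    rows = np.array([p[0] for p in pts])
    cols = np.array([p[1] for p in pts])
    return rows, cols


def generate_scene(spec: SceneSpec, image_id: str = "") -> SyntheticSample:
    """Render the scene a :class:`SceneSpec` describes, deterministically.

    The same spec (including seed) always yields a bit-identical
    sample.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    center = (size - 1) / 2.0
    fov_radius = spec.fov_radius_frac * size

    image = np.zeros((size, size, 3), dtype=float)
    rr, cc = np.ogrid[:size, :size]
    dist = np.sqrt((rr - center) ** 2 + (cc - center) ** 2)
    fov = dist <= fov_radius

    # fundus background: orange-red with gentle radial falloff and texture
    falloff = 1.0 - 0.25 * (dist / fov_radius) ** 2
    base = np.array([0.75, 0.40, 0.12])
    texture = rng.normal(0, 0.012, size=(size, size))
    for ch in range(3):
        image[..., ch] = np.where(fov, base[ch] * falloff + texture, 0.0)

    # optic disc: bright disc off-centre; macula: dark disc opposite
    od_radius = spec.od_radius_frac * size
    mc_radius = spec.mc_radius_frac * size
    od_center = (int(round(center - 0.10 * size)), int(round(center + 0.28 * size)))
    mc_center = (int(round(center + 0.02 * size)), int(round(center - 0.12 * size)))
    od_coords = _disk_coords((size, size), od_center, od_radius)
    mc_coords = _disk_coords((size, size), mc_center, mc_radius)
    # landmarks get smooth parabolic profiles: real disc/macula boundaries
    # are soft, and sharp synthetic edges would mimic lesion-scale detail
    od_d2 = (rr - od_center[0]) ** 2 + (cc - od_center[1]) ** 2
    od_profile = np.clip(1.0 - od_d2 / od_radius**2, 0.0, 1.0)
    od_color = np.array([0.93, 0.68, 0.45])
    for ch in range(3):
        image[..., ch] += 0.95 * od_profile * (od_color[ch] - image[..., ch])
    mc_d2 = (rr - mc_center[0]) ** 2 + (cc - mc_center[1]) ** 2
    mc_profile = np.clip(1.0 - mc_d2 / mc_radius**2, 0.0, 1.0)
    image *= (1.0 - 0.45 * mc_profile)[..., None]

    masks: dict[str, np.ndarray] = {
        t: np.zeros((size, size), dtype=np.uint8) for t in ("MA", "EX", "SE", "HE", "NV", "OD", "MC")
    }
    masks["OD"][od_coords] = 1
    masks["MC"][mc_coords] = 1

    # vessel arcs from the optic disc (no mask: vasculature is background)
    if spec.vessels:
        for _ in range(3):
            heading = rng.uniform(0, 2 * np.pi)
            r, c = float(od_center[0]), float(od_center[1])
            for _ in range(int(1.2 * fov_radius)):
                heading += rng.normal(0, 0.12)
                r += np.sin(heading)
                c += np.cos(heading)
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < size and 0 <= ci < size) or dist[ri, ci] > fov_radius - 2:
                    break
                # mild contrast: vasculature must not mimic lesions
                image[max(ri - 1, 0) : ri + 1, max(ci - 1, 0) : ci + 1] = (0.64, 0.31, 0.10)

    forbidden = [(*od_center, od_radius + 2), (*mc_center, mc_radius + 2)]

    def plant_disks(kind: str, n: int, radius_range, color, alpha=1.0, balance=False):
        if n == 0:
            return []
        rmax = radius_range[1]
        positions = _place_positions(
            rng, n, rmax, center, fov_radius, forbidden,
            max_tries=200 * n + 4000, balance_quadrants=balance,
        )
        for r0, c0 in positions:
            radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
            coords = _disk_coords((size, size), (r0, c0), radius)
            _paint(image, coords, color, alpha)
            masks[kind][coords] = 1
        return positions

    plant_disks("MA", spec.n_ma, spec.ma_radius, (0.40, 0.04, 0.04))
    plant_disks("EX", spec.n_ex, spec.ex_radius, (0.97, 0.92, 0.35))
    plant_disks("SE", spec.n_se, spec.se_radius, (0.88, 0.82, 0.68))
    he_positions = plant_disks(
        "HE", spec.n_he, spec.he_radius, (0.36, 0.05, 0.03), balance=True
    )
    if spec.n_nv:
        nv_positions = _place_positions(
            rng, spec.n_nv, spec.nv_extent + 2, center, fov_radius, forbidden
        )
        for pos in nv_positions:
            rows, cols = _nv_tangle(rng, pos, spec.nv_extent, (size, size))
            _paint(image, (rows, cols), (0.98, 0.95, 0.60))
            masks["NV"][rows, cols] = 1

    if spec.artifact_spot is not None:
        s = spec.artifact_spot
        coords = _disk_coords(
            (size, size), (int(s.row_frac * size), int(s.col_frac * size)), s.radius
        )
        _paint(image, coords, (0.55, 0.55, 0.55), alpha=s.intensity)

    image = np.clip(image, 0.0, 1.0)

    quad = [0, 0, 0, 0]
    for r0, c0 in he_positions:
        quad[(0 if r0 < center else 2) + (0 if c0 < center else 1)] += 1
    inventory = LesionInventory(
        ma=spec.n_ma, ex=spec.n_ex, se=spec.n_se, nv=spec.n_nv, he_quadrants=tuple(quad)
    )
    lesion_masks = {
        t: LesionMask(m, t, image_id=image_id) for t, m in masks.items()
    }
    return SyntheticSample(
        image=image,
        masks=lesion_masks,
        grade=grade_rule(inventory),
        inventory=inventory,
        spec=spec,
        image_id=image_id,
    )


# --------------------------------------------------------------------------
# fixed-weight reference CNN


def _ring_kernel(r_in: int, r_out: int, sign: int) -> np.ndarray:
    """Zero-mean centre-vs-surround kernel: sign=+1 detects bright
    blobs of radius ~r_in, sign=-1 dark ones."""
    size = 2 * r_out + 1
    rr, cc = np.ogrid[:size, :size]
    d2 = (rr - r_out) ** 2 + (cc - r_out) ** 2
    inner = d2 <= r_in**2
    ring = (d2 > r_in**2) & (d2 <= r_out**2)
    k = np.zeros((size, size))
    k[inner] = 1.0 / inner.sum()
    k[ring] = -1.0 / ring.sum()
    return sign * k


def _build_kernels() -> list[np.ndarray]:
    """Seven template kernels, each (kh, kw, 3), zero-mean per channel.

    Channel order: MA, EX, SE, HE, NV, OD, MC.  Detection channels:
    dark dots and blobs read the green channel (where dark-red lesions
    lose most contrast against the orange background), bright pale
    blobs read blue, the optic disc reads green at coarse scale.
    """
    def on_channel(k2d: np.ndarray, channel: int) -> np.ndarray:
        k = np.zeros((*k2d.shape, 3))
        k[..., channel] = k2d
        return k

    return [
        on_channel(_ring_kernel(3, 6, -1), 1),    # MA: small dark, green
        on_channel(_ring_kernel(4, 8, +1), 1),    # EX: small bright, green
        on_channel(_ring_kernel(6, 10, +1), 2),   # SE: mid bright, blue
        on_channel(_ring_kernel(5, 9, -1), 1),    # HE: mid dark, green
        on_channel(_ring_kernel(1, 3, +1), 1),    # NV: thin bright, green
        on_channel(_ring_kernel(10, 16, +1), 1),  # OD: coarse bright, green
        on_channel(_ring_kernel(8, 13, -1), 1),   # MC: coarse dark, green
    ]


# Per-channel response thresholds: template responses below these are
# background (texture, vessels, landmark edges) and are squashed by the
# softplus; responses above come from the structures the channel is for.
_THETA = np.array([0.16, 0.20, 0.16, 0.15, 0.22, 0.15, 0.08])

# Per-channel softplus gains: sharpen the threshold into a soft gate.
_GAINS = np.array([60.0, 50.0, 50.0, 60.0, 60.0, 40.0, 50.0])

# Linear head: rows = DR grades 0..4, columns = pooled channel features
# [MA, EX, SE, HE, NV, OD, MC].  Values are set in _calibrated_head()
# from the centred feature scales of canonical scenes.
_HEAD_W = np.array(
    [
        #   MA      EX      SE      HE      NV    OD   MC
        [-400.0, -400.0, -400.0, -400.0, -400.0, 0.0, 0.0],  # grade 0: no lesions
        [ 600.0, -400.0, -400.0, -500.0, -400.0, 0.0, 0.0],  # grade 1: MA only
        [  30.0,  250.0,  250.0,  250.0, -400.0, 0.0, 0.0],  # grade 2: EX/SE/HE
        [ 340.0,  150.0,  150.0,  100.0, -200.0, 0.0, 0.0],  # grade 3: massive HE
        [   0.0,    0.0,    0.0,   50.0,  800.0, 0.0, 0.0],  # grade 4: NV
    ]
)
_HEAD_B = np.array([2.0, -0.2, -0.8, -3.4, -1.5])

#: Pooled softplus features of a canonical lesion-free scene; the head
#: operates on features centred at this reference so biases encode
#: grade priors directly.  Frozen constants of the fixture.
_F_REF = np.array([0.0003, 0.0001, 0.0004, 0.0005, 0.0000, 0.0059, 0.0426])


class FixtureCNN:
    """Fixed-weight convolutional DR grader with analytic gradients.

    Architecture: seven template convolutions (zero-padded, stride 1,
    'same') -> softplus with per-channel gain -> global average
    pooling -> linear 5-class head.  ``predict`` applies softmax;
    gradients differentiate the pre-softmax class score.  Implements
    the attribution adapter contract, including the optional
    straight-line-path fast gradient used by Integrated Gradients
    (convolution is linear, so responses along the path interpolate
    linearly between the endpoint responses).
    """

    def __init__(self) -> None:
        self.kernels = _build_kernels()
        self.gains = _GAINS
        self.thresholds = _THETA
        self.W = _HEAD_W
        self.b = _HEAD_B
        self.f_ref = _F_REF
        self.n_classes = 5

    # -- forward pieces ---------------------------------------------------

    def _responses(self, image: np.ndarray) -> np.ndarray:
        """Raw template responses z, shape (H, W, K)."""
        image = np.asarray(image, dtype=float)
        zs = []
        for k in self.kernels:
            # correlation == convolution with the flipped kernel
            flipped = k[::-1, ::-1, :]
            z = np.zeros(image.shape[:2])
            for ch in range(3):
                z += fftconvolve(image[..., ch], flipped[..., ch], mode="same")
            zs.append(z)
        return np.stack(zs, axis=-1)

    def _activations(self, z: np.ndarray) -> np.ndarray:
        # softplus(gain * (z - theta)): a soft gate above the per-channel
        # background threshold
        return np.logaddexp(0.0, self.gains * (z - self.thresholds))

    def _logits_from_features(self, f: np.ndarray) -> np.ndarray:
        return self.W @ (f - self.f_ref) + self.b

    def logits(self, image: np.ndarray) -> np.ndarray:
        a = self._activations(self._responses(image))
        return self._logits_from_features(a.mean(axis=(0, 1)))

    # -- adapter contract -------------------------------------------------

    def predict(self, image: np.ndarray) -> np.ndarray:
        z = self.logits(image)
        z = z - z.max()
        p = np.exp(z)
        return p / p.sum()

    def class_score(self, image: np.ndarray, class_index: int) -> float:
        return float(self.logits(image)[class_index])

    def conv_activations_and_gradients(
        self, image: np.ndarray, class_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        a = self._activations(self._responses(image))
        h, w, _ = a.shape
        grads = np.broadcast_to(self.W[class_index] / (h * w), a.shape).copy()
        return a, grads

    def _backprop_to_input(self, upstream: np.ndarray, shape) -> np.ndarray:
        """Push gradient w.r.t. raw responses z (H, W, K) back through
        the convolutions to the input pixels."""
        dx = np.zeros(shape)
        for k_idx, k in enumerate(self.kernels):
            g = upstream[..., k_idx]
            for ch in range(3):
                dx[..., ch] += fftconvolve(g, k[..., ch], mode="same")
        return dx

    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        z = self._responses(image)
        h, w, _ = z.shape
        # d score / d z_k = W[c,k]/(HW) * gain_k * softplus'(gain_k (z_k - theta_k))
        sig = 1.0 / (1.0 + np.exp(-self.gains * (z - self.thresholds)))
        upstream = (self.W[class_index] * self.gains / (h * w)) * sig
        return self._backprop_to_input(upstream, image.shape)

    def mean_path_gradient(
        self,
        baseline: np.ndarray,
        image: np.ndarray,
        alphas: np.ndarray,
        weights: np.ndarray,
        class_index: int,
    ) -> np.ndarray:
        """Weighted mean of input gradients along the straight-line path.

        Convolution is linear, so z(x' + a(x - x')) = z(x') + a (z(x)
        - z(x')): the path responses need only two convolution passes,
        and the backward convolution distributes over the weighted sum
        of the pointwise softplus derivatives.
        """
        image = np.asarray(image, dtype=float)
        z0 = self._responses(baseline)
        dz = self._responses(image) - z0
        h, w, _ = z0.shape
        acc = np.zeros_like(z0)
        for a, wt in zip(alphas, weights):
            sig = 1.0 / (1.0 + np.exp(-self.gains * (z0 + a * dz - self.thresholds)))
            acc += wt * sig
        upstream = (self.W[class_index] * self.gains / (h * w)) * acc
        return self._backprop_to_input(upstream, image.shape)


def fixture_classifier() -> FixtureCNN:
    """The bundled fixed-weight reference classifier."""
    return FixtureCNN()


# --------------------------------------------------------------------------
# canonical scene recipes


def scene_spec_for_grade(grade: int, seed: int, image_size: int = 224) -> SceneSpec:
    """A clean, high-contrast scene recipe whose inventory implies
    ``grade`` under the ICDR rule."""
    common = dict(image_size=image_size, seed=seed)
    if grade == 0:
        return SceneSpec(**common)
    if grade == 1:
        return SceneSpec(n_ma=6, **common)
    if grade == 2:
        return SceneSpec(n_ma=2, n_ex=5, n_se=2, n_he=4, **common)
    if grade == 3:
        return SceneSpec(n_ma=2, n_ex=3, n_he=88, he_radius=(3, 4), **common)
    if grade == 4:
        return SceneSpec(n_ma=2, n_he=4, n_nv=2, **common)
    raise ValueError(f"grade must be 0..4, got {grade}")
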