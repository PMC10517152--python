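"""Step 3 — training-set augmentation, pluggable segmentation, post-processing.

Per-plant segmentation operates on circular crops (default diameter 384 px)
centered on the localized plant position; the circle excludes neighboring
plants. Two interchangeable backends implement the SegmenterBackend
contract (fit on labeled examples, predict per-pixel plant probability):

* ``ClassicalBackend`` — a zero-training colorimetric rule: a pixel is
  plant-like when its Lab chroma is appreciable and its hue angle falls
  outside the soil/sand/humus hue band (yellow–orange); rosette leaves are
  green (hue ≈ 140°) through red/purple (hue ≈ 10°) and the backgrounds
  cluster near 60°. Deterministic, used for coarse tiling and fast tests.
* ``TrainableBackend`` — a per-pixel multilayer-perceptron classifier on
  color + smoothed-neighborhood features, trainable on CPU in seconds.

Training data are grown from a few manual polygon annotations by geometric/
photometric augmentation and by compositing masked plants onto new
backgrounds. Predicted probability maps are Gaussian-smoothed, thresholded
and cleaned of small objects; masks are scored against ground truth with
Dice, precision, sensitivity and specificity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, morphology
from skimage.transform import AffineTransform, warp

from . import colorimetry

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledExample",
    "AugmentationPlan",
    "SegmenterBackend",
    "ClassicalBackend",
    "TrainableBackend",
    "SegPostprocessConfig",
    "SegMetrics",
    "TrainingDivergedError",
    "circular_mask",
    "load_labelme",
    "augment_training_set",
    "train_segmenter",
    "segment_plant",
    "postprocess_mask",
    "evaluate_masks",
]

CROP_SIZE = 384  # canonical crop diameter in px


class TrainingDivergedError(RuntimeError):
    """Backend failed to reduce the training loss below its initial value."""


@dataclass
class LabeledExample:
    """One training crop: RGB image, binary mask, provenance tag."""

    image: np.ndarray
    mask: np.ndarray
    provenance: str = "manual"  # manual | augmented_geom | composited
    background_kind: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask shapes differ")


@dataclass
class AugmentationPlan:
    """Counts and parameter ranges for the two augmentation branches."""

    n_geometric: int = 4100
    n_composited: int = 3400
    rotation_deg: tuple = (-180.0, 180.0)
    shift_px: tuple = (-30.0, 30.0)
    scale: tuple = (0.8, 1.25)
    brightness: tuple = (0.7, 1.3)
    contrast: tuple = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self):
        if self.n_geometric < 0 or self.n_composited < 0:
            raise ValueError("branch counts must be >= 0")
        for rng in (self.rotation_deg, self.shift_px, self.scale,
                    self.brightness, self.contrast):
            if rng[0] > rng[1]:
                raise ValueError(f"ill-ordered range {rng}")


@dataclass
class SegPostprocessConfig:
    gaussian_sigma: float = 1.0
    binary_threshold: float = 0.5
    min_object_area: int = 25

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 < self.binary_threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")


@dataclass
class SegMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    dice: float
    precision: float
    sensitivity: float
    specificity: float


class SegmenterBackend(Protocol):
    """Contract: fit on labeled examples, predict per-pixel plant probability."""

    backend_id: str

    def fit(self, examples: Sequence[LabeledExample],
            split: tuple = (0.68, 0.12, 0.20), seed: int = 0) -> "SegmenterBackend": ...

    def predict(self, crop: np.ndarray) -> np.ndarray: ...


def circular_mask(size: int) -> np.ndarray:
    """Boolean disk of diameter ``size`` inscribed in a size×size square."""
    rr, cc = draw.disk((size / 2 - 0.5, size / 2 - 0.5), size / 2, shape=(size, size))
    out = np.zeros((size, size), dtype=bool)
    out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# backends


class ClassicalBackend:
    """Colorimetric hue-gate segmenter (no training).

    plant probability = σ((hue distance from background band − margin)/τ_h)
    × σ((chroma − chroma_floor)/τ_c), computed in CIELAB. The background
    band (default 40–85°) covers soil, sand and humus hues; white (marbles,
    snow) has near-zero chroma and is rejected by the chroma gate.
    """

    backend_id = "classical"

    def __init__(self, background_hue_deg: tuple = (40.0, 85.0),
                 hue_margin: float = 8.0, chroma_floor: float = 9.0,
                 lightness_range: tuple = (10.0, 85.0)):
        self.background_hue_deg = background_hue_deg
        self.hue_margin = hue_margin
        self.chroma_floor = chroma_floor
        self.lightness_range = lightness_range
        self.training_log: list = []

    def fit(self, examples=(), split=(0.68, 0.12, 0.20), seed: int = 0):
        return self  # nothing to fit

    def predict(self, crop: np.ndarray) -> np.ndarray:
        lab = colorimetry.srgb_to_lab(np.asarray(crop, dtype=float))
        L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
        chroma = np.hypot(a, b)
        hue = np.degrees(np.arctan2(b, a)) % 360.0
        lo, hi = self.background_hue_deg
        dist = np.where(hue < lo, lo - hue, np.where(hue > hi, hue - hi, 0.0))
        dist = np.minimum(dist, 360.0 - (hi - lo) - dist)  # circular distance
        p_hue = _expit((dist - self.hue_margin) / 4.0)
        p_chroma = _expit((chroma - self.chroma_floor) / 2.0)
        l0, l1 = self.lightness_range
        p_light = _expit((L - l0) / 2.0) * _expit((l1 - L) / 2.0)
        return (p_hue * p_chroma * p_light).astype(float)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class TrainableBackend:
    """Per-pixel MLP classifier on color and smoothed-neighborhood features.

    Features per pixel: R, G, B, L*, a*, b* plus σ=2 Gaussian-smoothed
    L*, a*, b* (local context). A small scikit-learn MLP is trained on a
    subsample of pixels from the training split; prediction is the class-1
    probability reshaped to the crop. Deterministic for a fixed seed.
    """

    backend_id = "nn"

    def __init__(self, hidden=(24, 12), pixels_per_example: int = 1500,
                 max_iter: int = 200):
        self.hidden = tuple(hidden)
        self.pixels_per_example = pixels_per_example
        self.max_iter = max_iter
        self.clf = None
        self.training_log: list = []

    @staticmethod
    def _features(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float) / 255.0
        lab = colorimetry.srgb_to_lab(img * 255.0)
        smooth = np.stack([ndi.gaussian_filter(lab[..., k], 2.0) for k in range(3)],
                          axis=-1)
        feats = np.concatenate([img, lab / 100.0, smooth / 100.0], axis=-1)
        return feats.reshape(-1, feats.shape[-1])

    def fit(self, examples: Sequence[LabeledExample],
            split: tuple = (0.68, 0.12, 0.20), seed: int = 0):
        from sklearn.neural_network import MLPClassifier

        if not examples:
            raise ValueError("no training examples")
        rng = np.random.default_rng(seed)
        Xs, ys = [], []
        for ex in examples:
            F = self._features(ex.image)
            lbl = ex.mask.reshape(-1)
            k = min(self.pixels_per_example, F.shape[0])
            idx = rng.choice(F.shape[0], size=k, replace=False)
            Xs.append(F[idx])
            ys.append(lbl[idx])
        X = np.concatenate(Xs)
        y = np.concatenate(ys).astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingDivergedError("training pixels contain a single class")
        self.clf = MLPClassifier(hidden_layer_sizes=self.hidden,
                                 max_iter=self.max_iter,
                                 random_state=int(seed) % (2 ** 32))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf.fit(X, y)
        loss0 = -np.log(0.5)  # chance-level log loss for a balanced prior
        if self.clf.loss_ > loss0 * 1.5:
            raise TrainingDivergedError(
                f"final loss {self.clf.loss_:.3f} above initial {loss0:.3f}")
        self.training_log.append({"n_pixels": int(len(y)),
                                  "final_loss": float(self.clf.loss_)})
        return self

    def predict(self, crop: np.ndarray) -> np.ndarray:
        if self.clf is None:
            raise RuntimeError("backend not fitted")
        F = self._features(crop)
        prob = self.clf.predict_proba(F)[:, 1]
        return prob.reshape(np.asarray(crop).shape[:2])


def get_backend(name: str, **kwargs) -> SegmenterBackend:
    if name == "classical":
        return ClassicalBackend(**kwargs)
    if name == "nn":
        return TrainableBackend(**kwargs)
    raise KeyError(f"unknown backend {name!r}")


# ---------------------------------------------------------------------------
# annotations and augmentation


def load_labelme(path) -> LabeledExample:
    """Read one labelme-dialect polygon annotation JSON into a LabeledExample.

    Uses the ``imageHeight``/``imageWidth`` fields and rasterizes every
    polygon shape labeled as plant (any label) into one binary mask. The
    image itself is read from ``imagePath`` relative to the JSON file.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
    mask = np.zeros((h, w), dtype=bool)
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            continue
        pts = np.asarray(shape["points"], dtype=float)
        rr, cc = draw.polygon(pts[:, 1], pts[:, 0], shape=(h, w))
        mask[rr, cc] = True
    from PIL import Image

    img_path = path.parent / doc["imagePath"]
    with Image.open(img_path) as im:
        image = np.asarray(im.convert("RGB"))
    return LabeledExample(image=image, mask=mask, provenance="manual")


def _random_geom(ex: LabeledExample, plan: AugmentationPlan, rng) -> LabeledExample:
    h, w = ex.mask.shape
    angle = np.deg2rad(rng.uniform(*plan.rotation_deg))
    scale = rng.uniform(*plan.scale)
    tx, ty = rng.uniform(*plan.shift_px, size=2)
    center = np.array([w / 2, h / 2])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(rotation=angle, scale=scale)
          + AffineTransform(translation=center + (tx, ty)))
    img = warp(ex.image.astype(float), tf.inverse, order=1, mode="constant",
               cval=0.0, preserve_range=True)
    msk = warp(ex.mask.astype(float), tf.inverse, order=0, mode="constant",
               cval=0.0, preserve_range=True) > 0.5
    gain = rng.uniform(*plan.contrast)
    bias = 255.0 * (rng.uniform(*plan.brightness) - 1.0)
    img = np.clip(img * gain + bias, 0, 255).astype(np.uint8)
    return LabeledExample(img, msk, "augmented_geom", ex.background_kind)


def _composite(ex: LabeledExample, background: np.ndarray, rng) -> LabeledExample:
    bg = np.asarray(background)
    if bg.shape[:2] != ex.mask.shape:
        raise ValueError("background and example shapes differ")
    img = bg.copy()
    img[ex.mask] = ex.image[ex.mask]  # plant area cut out of the background
    return LabeledExample(img, ex.mask.copy(), "composited", "composited")


def augment_training_set(labeled: Sequence[LabeledExample],
                         plan: AugmentationPlan,
                         backgrounds: Sequence[np.ndarray] = ()) -> list[LabeledExample]:
    """Grow the labeled set to exactly the branch counts of ``plan``.

    The geometric branch applies one random rotation/shift/scale to image
    and mask jointly plus brightness/contrast to the image only; the
    compositing branch pastes the masked plant onto a randomly chosen
    background from which the plant area is cut out. Seed-reproducible.
    """
    labeled = list(labeled)
    if not labeled:
        raise ValueError("no labeled source examples")
    if any(ex.mask.sum() == 0 for ex in labeled):
        raise ValueError("zero-area label in the source set")
    if plan.n_composited > 0 and not len(backgrounds):
        raise ValueError("compositing branch requires at least one background")
    rng = np.random.default_rng(plan.seed)
    out: list[LabeledExample] = []
    for i in range(plan.n_geometric):
        out.append(_random_geom(labeled[i % len(labeled)], plan, rng))
    for i in range(plan.n_composited):
        src = _random_geom(labeled[i % len(labeled)], plan, rng)
        bg = backgrounds[rng.integers(len(backgrounds))]
        out.append(_composite(src, bg, rng))
    return out


# ---------------------------------------------------------------------------
# training, prediction, evaluation


def train_segmenter(backend: SegmenterBackend,
                    examples: Sequence[LabeledExample],
                    split: tuple = (0.68, 0.12, 0.20), seed: int = 0,
                    post: Optional[SegPostprocessConfig] = None):
    """Split (seeded shuffle), fit the backend, report test-split Dice.

    Returns (backend, metrics dict) with per-split sizes and the mean Dice
    over the held-out test split. The classical backend has no trainable
    state and passes through unchanged (its test Dice is still reported).
    """
    examples = list(examples)
    if len(examples) < 10:
        raise ValueError("need at least 10 examples")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    n_train = int(round(split[0] * len(examples)))
    n_val = int(round(split[1] * len(examples)))
    tr = [examples[i] for i in order[:n_train]]
    va = [examples[i] for i in order[n_train:n_train + n_val]]
    te = [examples[i] for i in order[n_train + n_val:]]
    backend = backend.fit(tr, split=split, seed=seed)
    post = post or SegPostprocessConfig()
    dices = []
    for ex in te or tr:
        pred = postprocess_mask(backend.predict(ex.image), post)
        dices.append(evaluate_masks(pred, ex.mask).dice)
    metrics = {"n_train": len(tr), "n_val": len(va), "n_test": len(te),
               "test_dice": float(np.mean(dices))}
    return backend, metrics


def segment_plant(registered_frame: np.ndarray, center: tuple,
                  backend: SegmenterBackend,
                  post: Optional[SegPostprocessConfig] = None,
                  crop_size: int = CROP_SIZE):
    """Segment one plant in a circular crop around ``center`` = (x, y).

    The crop is zero-padded at frame borders; the inscribed circular region
    (diameter ``crop_size``) masks out neighboring plants before prediction.
    Returns (binary mask, crop) both of shape crop_size².
    """
    frame = np.asarray(registered_frame)
    h, w = frame.shape[:2]
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center {center} outside frame {w}x{h}")
    half = crop_size // 2
    x0, y0 = int(round(cx)) - half, int(round(cy)) - half
    crop = np.zeros((crop_size, crop_size, 3), dtype=np.uint8)
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x0 + crop_size), min(h, y0 + crop_size)
    crop[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = frame[sy0:sy1, sx0:sx1]
    circle = circular_mask(crop_size)
    prob = np.asarray(backend.predict(crop), dtype=float)
    prob[~circle] = 0.0
    mask = postprocess_mask(prob, post or SegPostprocessConfig())
    mask &= circle
    return mask, crop


def postprocess_mask(prob_map: np.ndarray,
                     post: Optional[SegPostprocessConfig] = None) -> np.ndarray:
    """Gaussian smooth → binarize → drop small connected components."""
    post = post or SegPostprocessConfig()
    prob = np.asarray(prob_map, dtype=float)
    if prob.size and (np.nanmin(prob) < -1e-9 or np.nanmax(prob) > 1 + 1e-9):
        raise ValueError("probability map values must lie in [0, 1]")
    if post.gaussian_sigma > 0:
        prob = ndi.gaussian_filter(prob, post.gaussian_sigma)
    mask = prob > post.binary_threshold
    if post.min_object_area > 0:
        lab, n = ndi.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())
            small = np.flatnonzero(sizes < post.min_object_area)
            mask &= ~np.isin(lab, small[small > 0])
    return mask


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixel confusion counts and Dice/precision/sensitivity/specificity.

    Dice = 2|A∩B|/(|A|+|B|). Two empty masks agree perfectly: Dice = 1; a
    ratio with zero denominator and tp = 0 is likewise reported as 1
    (logged), since no disagreeing pixel exists.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))

    def ratio(num, den, name):
        if den == 0:
            logger.debug("undefined %s (0/0) reported as 1", name)
            return 1.0
        return num / den

    dice = ratio(2 * tp, 2 * tp + fp + fn, "dice")
    return SegMetrics(tp, fp, fn, tn, dice,
                      precision=ratio(tp, tp + fp, "precision"),
                      sensitivity=ratio(tp, tp + fn, "sensitivity"),
                      specificity=ratio(tn, tn + fp, "specificity"))
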