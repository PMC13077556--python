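"""Supervised per-pixel segmentation of micrograph structure classes.

One independent binary model per class (bilayer, small_dense, HDL, LDL,
VLDL, ice); overlapping predictions across classes are permitted and
resolved downstream. Two interchangeable detectors are provided:

``PixelClassifier``
    A trainable pixel classifier: a small multilayer perceptron over a
    multiscale filter-bank feature stack (intensity, edge and texture
    channels at several Gaussian scales). Pixel classification over a
    generic feature bank is the classic trainable-segmentation approach
    for electron micrographs; any pixel classifier with the same
    behavioural contract (co-registered masks, class specificity) is
    conformant here.

``RingMatchedFilter``
    A deterministic classical bilayer detector: normalized
    cross-correlation with the double-leaflet ring template over a
    radius sweep, giving downstream Hough/size tests a baseline that
    does not depend on stochastic training.

Both follow scikit-learn estimator conventions (get_params/set_params,
fitted attributes with trailing underscores) and compose with sklearn
model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template, multiscale_basic_features
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPClassifier

from .simulate import ClassSpec, _dip_function
from .types import Micrograph, SegmentationMask

__all__ = [
    "Annotation",
    "AnnotationSet",
    "extract_training_patches",
    "PixelClassifier",
    "RingMatchedFilter",
    "classical_bilayer_detector",
]


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class Annotation:
    """One rectangular ROI with a per-pixel binary label mask."""

    image_id: str
    y0: int
    x0: int
    height: int
    width: int
    labels: np.ndarray  # bool, shape (height, width)
    class_name: str

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != (self.height, self.width):
            raise ValueError(
                f"label mask shape {labels.shape} does not match box "
                f"({self.height}, {self.width})")
        if labels.dtype != bool:
            vals = np.unique(labels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("label masks must be binary")
        object.__setattr__(self, "labels", labels.astype(bool))


@dataclass
class AnnotationSet:
    items: list = field(default_factory=list)

    def area_fraction(self, image_shapes: dict) -> float:
        """Fraction of the total image area covered by ROI boxes —
        the provenance statistic reported alongside trained models."""
        total = sum(h * w for h, w in image_shapes.values())
        boxed = sum(a.height * a.width for a in self.items)
        if total == 0:
            raise ValueError("no image area")
        return boxed / total

    def validate_against(self, image_shapes: dict):
        for a in self.items:
            if a.image_id not in image_shapes:
                raise ValueError(f"annotation references unknown image {a.image_id!r}")
            h, w = image_shapes[a.image_id]
            if a.y0 < 0 or a.x0 < 0 or a.y0 + a.height > h or a.x0 + a.width > w:
                raise ValueError(f"ROI box out of bounds on image {a.image_id!r}")


def extract_training_patches(ann: AnnotationSet, images: dict, patch_size: int = 256,
                             class_name: str = None):
    """Cut (patch, label-mask) pairs out of annotated ROI boxes.

    ROIs larger than ``patch_size`` are tiled into non-overlapping
    ``patch_size`` tiles plus clipped remainder tiles; smaller ROIs give
    one patch of the ROI's own size. Returns (patches, labels, stats)
    where stats reports per-class positive/negative pixel counts.
    Deterministic: ordering follows the annotation list and raster tile
    order.
    """
    if not ann.items:
        raise ValueError("empty annotation set")
    shapes = {k: np.asarray(v.pixels if isinstance(v, Micrograph) else v).shape
              for k, v in images.items()}
    ann.validate_against(shapes)
    patches, labels = [], []
    stats = {}
    for a in ann.items:
        if class_name is not None and a.class_name != class_name:
            raise ValueError(
                f"annotation class {a.class_name!r} does not match requested "
                f"{class_name!r}")
        img = images[a.image_id]
        arr = np.asarray(img.pixels if isinstance(img, Micrograph) else img)
        box = arr[a.y0:a.y0 + a.height, a.x0:a.x0 + a.width]
        for ty in range(0, a.height, patch_size):
            for tx in range(0, a.width, patch_size):
                p = box[ty:ty + patch_size, tx:tx + patch_size]
                l = a.labels[ty:ty + patch_size, tx:tx + patch_size]
                if p.size == 0:
                    continue
                patches.append(np.ascontiguousarray(p))
                labels.append(np.ascontiguousarray(l))
                s = stats.setdefault(a.class_name, {"positive_px": 0, "negative_px": 0,
                                                    "n_patches": 0})
                s["positive_px"] += int(l.sum())
                s["negative_px"] += int(l.size - l.sum())
                s["n_patches"] += 1
    return patches, labels, stats


# ---------------------------------------------------------------------------
# trainable pixel classifier


class TrainingDivergedError(RuntimeError):
    pass


_DIHEDRAL = [
    lambda a: a,
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
    lambda a: a[::-1],
    lambda a: np.rot90(a[::-1], 1),
    lambda a: np.rot90(a[::-1], 2),
    lambda a: np.rot90(a[::-1], 3),
]


class PixelClassifier(BaseEstimator):
    """Binary per-pixel classifier for one structure class.

    Features are `skimage.feature.multiscale_basic_features` (intensity,
    edges, texture over Gaussian scales ``sigma_min``..``sigma_max``);
    the classifier is a small MLP trained on a seeded subsample of
    annotated pixels. ``epochs`` bounds the optimizer iterations and the
    per-epoch loss is kept in ``training_log_``.

    Parameters
    ----------
    class_name : which structure class this model predicts.
    sigma_min, sigma_max : feature-bank scale range in pixels.
    hidden_layer_sizes : MLP architecture.
    epochs, learning_rate, batch_size : optimizer settings.
    max_train_pixels : per-fit cap on sampled training pixels.
    augment : add 8-fold dihedral (flip/rotation) copies of each patch.
    threshold : default probability cutoff for binary masks.
    random_state : seed for pixel subsampling and weight init.
    """

    def __init__(self, class_name: str = "EV_bilayer", sigma_min: float = 1.0,
                 sigma_max: float = 8.0, hidden_layer_sizes: tuple = (32, 16),
                 epochs: int = 50, learning_rate: float = 1e-3,
                 batch_size: int = 256, max_train_pixels: int = 100_000,
                 augment: bool = False, threshold: float = 0.5,
                 random_state: int = 0):
        self.class_name = class_name
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_train_pixels = max_train_pixels
        self.augment = augment
        self.threshold = threshold
        self.random_state = random_state

    # -- features ----------------------------------------------------------

    def _features(self, image: np.ndarray) -> np.ndarray:
        feats = multiscale_basic_features(
            np.asarray(image, dtype=np.float32),
            intensity=True, edges=True, texture=True,
            sigma_min=self.sigma_min, sigma_max=self.sigma_max,
        )
        return feats.reshape(-1, feats.shape[-1])

    # -- fit ---------------------------------------------------------------

    def fit(self, patches, labels):
        """Train on (patch, label-mask) pairs.

        Requires at least one positive and one negative labelled pixel.
        Raises ``TrainingDivergedError`` naming the epoch if the loss
        goes non-finite.
        """
        if len(patches) == 0 or len(patches) != len(labels):
            raise ValueError("need equal, non-empty patch and label lists")
        rng = np.random.default_rng(self.random_state)
        xs, ys = [], []
        for p, l in zip(patches, labels):
            l = np.asarray(l).astype(bool)
            variants = _DIHEDRAL if self.augment else _DIHEDRAL[:1]
            for tf in variants:
                xs.append(self._features(tf(np.asarray(p))))
                ys.append(tf(l).ravel())
        X = np.concatenate(xs, axis=0)
        y = np.concatenate(ys, axis=0)
        if y.sum() == 0 or y.sum() == y.size:
            raise ValueError(
                "training set needs at least one positive and one negative pixel")
        if len(y) > self.max_train_pixels:
            # stratified subsample keeps the minority class represented
            pos = np.nonzero(y)[0]
            neg = np.nonzero(~y)[0]
            n_pos = min(len(pos), max(self.max_train_pixels // 2, 1))
            n_neg = min(len(neg), self.max_train_pixels - n_pos)
            idx = np.concatenate([rng.choice(pos, n_pos, replace=False),
                                  rng.choice(neg, n_neg, replace=False)])
            rng.shuffle(idx)
            X, y = X[idx], y[idx]
        self._scaler_mean_ = X.mean(axis=0)
        self._scaler_std_ = X.std(axis=0) + 1e-8
        Xs = (X - self._scaler_mean_) / self._scaler_std_
        clf = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes, max_iter=self.epochs,
            learning_rate_init=self.learning_rate, batch_size=self.batch_size,
            random_state=self.random_state, solver="adam", tol=0.0,
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter convergence warning
            clf.fit(Xs, y.astype(int))
        for epoch, loss in enumerate(clf.loss_curve_):
            if not math.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        self.model_ = clf
        self.n_features_in_ = X.shape[1]
        self.training_log_ = {
            "per_epoch_loss": [float(v) for v in clf.loss_curve_],
            "n_train_pixels": int(len(y)),
            "positive_fraction": float(y.mean()),
        }
        self.train_accuracy_ = float(clf.score(Xs, y.astype(int)))
        return self

    # -- predict -----------------------------------------------------------

    def predict_probability(self, micrograph, tile: int = 512, overlap: int = 32) -> np.ndarray:
        """Probability map over a full micrograph, tiled with overlap
        blending so tile seams introduce no discontinuity."""
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        img = np.asarray(micrograph.pixels if isinstance(micrograph, Micrograph)
                         else micrograph, dtype=np.float32)
        h, w = img.shape
        if h <= tile and w <= tile:
            return self._predict_patch(img)
        prob = np.zeros((h, w), dtype=np.float64)
        weight = np.zeros((h, w), dtype=np.float64)
        step = tile - 2 * overlap
        taper = _taper_window(tile, overlap)
        for y0 in range(0, h, step):
            for x0 in range(0, w, step):
                y1, x1 = min(y0 + tile, h), min(x0 + tile, w)
                ys, xs = max(y1 - tile, 0), max(x1 - tile, 0)
                patch_prob = self._predict_patch(img[ys:y1, xs:x1])
                wgt = taper[:y1 - ys, :x1 - xs]
                prob[ys:y1, xs:x1] += patch_prob * wgt
                weight[ys:y1, xs:x1] += wgt
                if x1 == w:
                    break
            if y1 == h:
                break
        return prob / np.maximum(weight, 1e-12)

    def _predict_patch(self, patch: np.ndarray) -> np.ndarray:
        X = (self._features(patch) - self._scaler_mean_) / self._scaler_std_
        p = self.model_.predict_proba(X)[:, 1]
        return p.reshape(patch.shape)

    def predict_mask(self, micrograph, threshold: float = None) -> SegmentationMask:
        prob = self.predict_probability(micrograph)
        thr = self.threshold if threshold is None else threshold
        return SegmentationMask(class_name=self.class_name,
                                probability=np.clip(prob, 0, 1), threshold=thr)

    def pixel_accuracy(self, patches, labels) -> float:
        """Mean per-pixel accuracy over held-out (patch, label) pairs."""
        correct = total = 0
        for p, l in zip(patches, labels):
            pred = self._predict_patch(np.asarray(p, dtype=np.float32)) >= self.threshold
            correct += int((pred == np.asarray(l).astype(bool)).sum())
            total += pred.size
        return correct / total


def _taper_window(tile: int, overlap: int) -> np.ndarray:
    ramp = np.ones(tile)
    if overlap > 0:
        edge = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
        ramp[:overlap] = edge
        ramp[-overlap:] = edge[::-1]
    return np.outer(ramp, ramp)


# ---------------------------------------------------------------------------
# classical ring matched filter


class RingMatchedFilter(BaseEstimator):
    """Deterministic bilayer-ring detector by template correlation.

    For each radius in a sweep, the (inverted, locally standardized)
    image is correlated with the zero-mean double-leaflet ring template
    rendered by the simulator's radial profile model; correlation peaks
    above ``threshold`` are kept after non-maximum suppression and
    painted back as annulus footprints, yielding a bilayer segmentation
    mask that mirrors what a trained model would produce.

    Radius sweep bounds are in nm (converted to the micrograph's pixel
    grid at call time). ``threshold`` is a normalized cross-correlation
    coefficient in [0, 1].
    """

    def __init__(self, diameter_min_nm: float = 30.0, diameter_max_nm: float = 150.0,
                 radius_step_px: int = 1, threshold: float = 0.5,
                 leaflet_separation_nm: float = 4.0, leaflet_sigma_nm: float = 1.2,
                 annulus_halfwidth_nm: float = 4.0, lumen_weight: float = 0.5):
        self.diameter_min_nm = diameter_min_nm
        self.diameter_max_nm = diameter_max_nm
        self.radius_step_px = radius_step_px
        self.threshold = threshold
        self.leaflet_separation_nm = leaflet_separation_nm
        self.leaflet_sigma_nm = leaflet_sigma_nm
        self.annulus_halfwidth_nm = annulus_halfwidth_nm
        self.lumen_weight = lumen_weight

    def _template(self, radius_px: float, pixel_size: float) -> np.ndarray:
        """Zero-mean double-leaflet ring with a negative-weight lumen.

        The lumen term is what separates bilayer rings from dense discs:
        a vesicle interior is at background level while a lipoprotein is
        dark throughout, so penalizing interior darkness suppresses
        disc responses without touching true rings.
        """
        spec = ClassSpec(
            class_name="EV_bilayer",
            diameter_distribution={"kind": "fixed", "value": 2 * radius_px * pixel_size},
            density=0.0, contrast=1.0,
            leaflet_separation=self.leaflet_separation_nm,
            leaflet_sigma=self.leaflet_sigma_nm)
        dip = _dip_function(spec, 2 * radius_px * pixel_size)
        ext = int(math.ceil(radius_px + (self.leaflet_separation_nm / 2
                                         + 4 * self.leaflet_sigma_nm) / pixel_size)) + 1
        yy, xx = np.mgrid[-ext:ext + 1, -ext:ext + 1]
        r_nm = np.hypot(yy, xx) * pixel_size
        t = dip(r_nm)
        lumen_edge = (radius_px * pixel_size - self.leaflet_separation_nm / 2
                      - 2 * self.leaflet_sigma_nm)
        if lumen_edge > 0:
            t = t - self.lumen_weight * (r_nm < lumen_edge)
        return t - t.mean()

    def detect(self, micrograph: Micrograph):
        """Candidate (score, r_px, y, x) peaks after NMS."""
        from .detect import _nms  # shared suppression rule

        img = np.asarray(micrograph.pixels, dtype=np.float64)
        px = micrograph.pixel_size
        inv = img.mean() - img  # dark structures -> positive
        sd = inv.std()
        if sd > 0:
            inv = inv / sd
        r_lo = max(int(round(self.diameter_min_nm / 2 / px)), 2)
        r_hi = max(int(round(self.diameter_max_nm / 2 / px)), r_lo + 1)
        candidates = []
        for r in range(r_lo, r_hi + 1, self.radius_step_px):
            tmpl = self._template(r, px)
            if min(img.shape) <= tmpl.shape[0]:
                continue
            resp = match_template(inv, tmpl, pad_input=True)
            peak = resp >= self.threshold
            # local maxima within a small neighbourhood only, to bound NMS input
            if peak.any():
                from scipy import ndimage as ndi
                mx = ndi.maximum_filter(resp, size=5, mode="constant", cval=-1)
                ys, xs = np.nonzero(peak & (resp >= mx))
                for y, x in zip(ys, xs):
                    candidates.append((float(resp[y, x]), int(r), int(y), int(x)))
        return _nms(candidates)

    def predict_mask(self, micrograph: Micrograph) -> SegmentationMask:
        """Bilayer ring footprint mask (union of detected annuli)."""
        peaks = self.detect(micrograph)
        h, w = micrograph.shape
        px = micrograph.pixel_size
        mask = np.zeros((h, w), dtype=bool)
        half = self.annulus_halfwidth_nm / px
        for _, r, y, x in peaks:
            ext = int(math.ceil(r + half)) + 1
            y0, y1 = max(y - ext, 0), min(y + ext + 1, h)
            x0, x1 = max(x - ext, 0), min(x + ext + 1, w)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(yy - y, xx - x)
            mask[y0:y1, x0:x1] |= np.abs(dist - r) <= half
        return SegmentationMask.from_binary("EV_bilayer", mask)


def classical_bilayer_detector(micrograph: Micrograph, params: dict = None) -> SegmentationMask:
    """Functional wrapper over ``RingMatchedFilter`` (see class docs)."""
    det = RingMatchedFilter(**(params or {}))
    return det.predict_mask(micrograph)
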