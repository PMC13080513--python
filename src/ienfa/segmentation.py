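"""Three interchangeable nerve-fibre segmentation backends.

All three operate on the nerve channel of a :class:`~ienfa.image_model.CalibratedImage`
and return a binary mask of candidate fibre pixels:

``ED``
    Sobel edge detection: gradient magnitude, threshold, optional
    morphological close + hole filling.
``CF``
    Custom convolution filtering: a user-supplied (default high-pass) kernel
    applied without flipping — the convention of common image-processing
    tools — followed by the same threshold/morphology chain as ED.
``AA``
    Trainable automated annotation: a seeded random-forest pixel classifier
    over a fixed 20-feature stack (intensity, Gaussian blurs, Sobel
    magnitudes, Hessian eigenvalues, differences of Gaussians), trained from
    sparse scribbles and refinable with correction scribbles.

Thresholds are expressed in normalised [0, 1] intensity units or as
``"otsu"`` for unattended runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk
from sklearn.ensemble import RandomForestClassifier

from .image_model import CalibratedImage

__all__ = [
    "SegmentationError",
    "SegmentationParams",
    "TrainingScribbles",
    "PixelClassifier",
    "DEFAULT_CF_KERNEL",
    "DEFAULT_FEATURE_SIGMAS",
    "sobel_magnitude",
    "segment_ed",
    "segment_cf",
    "build_feature_stack",
    "feature_names",
    "train_classifier",
    "retrain_classifier",
    "segment_aa",
    "read_scribbles_csv",
    "write_scribbles_csv",
    "save_classifier",
    "load_classifier",
]


class SegmentationError(ValueError):
    pass


# Classic 3x3 Sobel kernels, normalised so a unit step edge responds with 1.0.
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64) / 4.0
_SOBEL_Y = _SOBEL_X.T

#: Zero-mean 3x3 high-pass kernel contrasting thin bright fibres against
#: background (centre 8, neighbours -1).
DEFAULT_CF_KERNEL = np.array(
    [[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.float64
)

#: Scales (px) of the Gaussian/edge/curvature features of the AA stack.
DEFAULT_FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0)


@dataclass
class SegmentationParams:
    """Shared parameters of the ED and CF backends.

    threshold
        Normalised cut in [0, 1], or ``"otsu"`` to derive it from the
        transformed image histogram.
    kernel
        CF only; odd-sized square convolution kernel.
    close, fill_holes
        Morphological refinement flags applied after binarisation.
    close_radius
        Disk radius (px) of the closing structuring element.
    """

    algorithm: str = "ED"
    threshold: float | str = "otsu"
    kernel: np.ndarray | None = None
    close: bool = True
    fill_holes: bool = True
    close_radius: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in {"ED", "CF", "AA"}:
            raise SegmentationError(f"unknown algorithm {self.algorithm!r}")
        if isinstance(self.threshold, str):
            if self.threshold != "otsu":
                raise SegmentationError(f"unknown threshold mode {self.threshold!r}")
        elif not 0.0 <= float(self.threshold) <= 1.0:
            raise SegmentationError(
                f"numeric threshold must lie in [0, 1], got {self.threshold}"
            )
        if self.kernel is not None:
            k = np.asarray(self.kernel, dtype=np.float64)
            if k.ndim != 2 or k.shape[0] != k.shape[1]:
                raise SegmentationError("kernel must be square")
            if k.shape[0] % 2 == 0 or k.shape[0] < 3:
                raise SegmentationError("kernel side must be odd and >= 3")
            if not k.any():
                raise SegmentationError("kernel must not be all zeros")
            self.kernel = k


def _check_image(img: CalibratedImage) -> np.ndarray:
    if img.nerve.size == 0:
        raise SegmentationError("empty image")
    return img.nerve


def _resolve_threshold(transformed: np.ndarray, threshold: float | str) -> float:
    if threshold == "otsu":
        if np.ptp(transformed) == 0:
            return np.inf  # flat response: nothing to segment
        return float(threshold_otsu(transformed))
    return float(threshold)


def _binarize_refine(
    response: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    t = _resolve_threshold(response, params.threshold)
    mask = response >= t if np.isfinite(t) else np.zeros(response.shape, bool)
    if params.close:
        mask = ndi.binary_dilation(mask, structure=disk(params.close_radius))
        mask = ndi.binary_erosion(
            mask, structure=disk(params.close_radius), border_value=1
        )
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    return mask


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """√(Gx² + Gy²) with reflected borders, capped at 1 for [0, 1] inputs."""
    gx = ndi.correlate(image, _SOBEL_X, mode="reflect")
    gy = ndi.correlate(image, _SOBEL_Y, mode="reflect")
    return np.minimum(np.hypot(gx, gy), 1.0)


def segment_ed(img: CalibratedImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Sobel edge-detection segmentation of the nerve channel."""
    params = params or SegmentationParams(algorithm="ED")
    nerve = _check_image(img)
    return _binarize_refine(sobel_magnitude(nerve), params)


def segment_cf(img: CalibratedImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Custom-convolution-filter segmentation of the nerve channel.

    The kernel is applied unflipped (image-processing convention), negative
    responses are clipped to zero and the result is capped at 1 before
    thresholding.
    """
    params = params or SegmentationParams(algorithm="CF")
    nerve = _check_image(img)
    kernel = params.kernel if params.kernel is not None else DEFAULT_CF_KERNEL
    # route through SegmentationParams validation when a raw array was passed
    if params.kernel is None:
        SegmentationParams(algorithm="CF", kernel=kernel)
    response = ndi.correlate(nerve, kernel, mode="reflect")
    response = np.clip(response, 0.0, 1.0)
    return _binarize_refine(response, params)


# ---------------------------------------------------------------------------
# Trainable automated annotation (AA)


def feature_names(sigmas: tuple[float, ...] = DEFAULT_FEATURE_SIGMAS) -> list[str]:
    names = ["intensity"]
    names += [f"gaussian_s{s:g}" for s in sigmas]
    names += [f"sobel_s{s:g}" for s in sigmas]
    for s in sigmas:
        names += [f"hessian_eig1_s{s:g}", f"hessian_eig2_s{s:g}"]
    names += [
        f"dog_s{a:g}_s{b:g}" for a, b in zip(sigmas[:-1], sigmas[1:])
    ]
    return names


def build_feature_stack(
    img: CalibratedImage, sigmas: tuple[float, ...] = DEFAULT_FEATURE_SIGMAS
) -> np.ndarray:
    """Per-pixel feature volume of shape (H, W, n_features).

    Default stack (20 features for the 4 default scales): raw intensity,
    Gaussian blurs, Sobel magnitude of each blur, both Hessian eigenvalues
    per scale and differences of Gaussians of adjacent scales.  Deterministic
    given the image.
    """
    if not sigmas:
        raise SegmentationError("feature descriptor list must be non-empty")
    nerve = _check_image(img)
    blurs = [gaussian(nerve, sigma=s, mode="reflect", preserve_range=True) for s in sigmas]
    feats: list[np.ndarray] = [nerve]
    feats += blurs
    feats += [sobel_magnitude(b) for b in blurs]
    for s in sigmas:
        h = hessian_matrix(
            nerve, sigma=s, mode="reflect", use_gaussian_derivatives=True
        )
        e1, e2 = hessian_matrix_eigvals(h)
        feats += [e1, e2]
    feats += [a - b for a, b in zip(blurs[:-1], blurs[1:])]
    return np.stack(feats, axis=-1)


@dataclass
class TrainingScribbles:
    """Sparse pixel labels: ``image_id, x, y, class, round``.

    ``round`` records the correction-loop iteration that produced each label
    so that retraining provenance is preserved.
    """

    table: pd.DataFrame

    REQUIRED = ("image_id", "x", "y", "class", "round")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SegmentationError(f"scribble table lacks columns {missing}")
        if self.table[["x", "y"]].lt(0).any().any():
            raise SegmentationError("scribble coordinates must be non-negative")

    @property
    def classes(self) -> list[str]:
        return sorted(self.table["class"].unique())

    def appended(self, other: "TrainingScribbles") -> "TrainingScribbles":
        return TrainingScribbles(
            pd.concat([self.table, other.table], ignore_index=True)
        )


def read_scribbles_csv(path: str | Path) -> TrainingScribbles:
    return TrainingScribbles(pd.read_csv(path))


def write_scribbles_csv(path: str | Path, scribbles: TrainingScribbles) -> None:
    scribbles.table.to_csv(path, index=False)


@dataclass
class PixelClassifier:
    """Seeded random-forest pixel classifier with a training-label ledger."""

    sigmas: tuple[float, ...]
    classes: tuple[str, ...]
    seed: int
    forest: RandomForestClassifier | None = None
    ledger: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def trained(self) -> bool:
        return self.forest is not None


def _gather_training_matrix(
    images: dict[str, CalibratedImage],
    scribbles: TrainingScribbles,
    sigmas: tuple[float, ...],
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for image_id, group in scribbles.table.groupby("image_id"):
        if image_id not in images:
            raise SegmentationError(
                f"scribbles reference unknown image {image_id!r}"
            )
        img = images[image_id]
        h, w = img.shape
        if (group["x"] >= w).any() or (group["y"] >= h).any():
            raise SegmentationError(
                f"scribble coordinates outside image {image_id!r}"
            )
        stack = build_feature_stack(img, sigmas)
        xs.append(stack[group["y"].to_numpy(), group["x"].to_numpy()])
        ys.append(group["class"].to_numpy())
    return np.concatenate(xs), np.concatenate(ys)


def train_classifier(
    images: dict[str, CalibratedImage],
    scribbles: TrainingScribbles,
    seed: int = 0,
    sigmas: tuple[float, ...] = DEFAULT_FEATURE_SIGMAS,
    n_trees: int = 100,
) -> PixelClassifier:
    """Fit the AA pixel classifier on labelled pixels.

    Deterministic under a fixed seed; requires at least two classes with at
    least one labelled pixel each.  The scribbles become the classifier's
    ledger, which correction rounds extend via :func:`retrain_classifier`.
    """
    classes = scribbles.classes
    if len(classes) < 2:
        raise SegmentationError(
            f"need >= 2 labelled classes, got {classes}"
        )
    x, y = _gather_training_matrix(images, scribbles, sigmas)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    return PixelClassifier(
        sigmas=tuple(sigmas),
        classes=tuple(classes),
        seed=seed,
        forest=forest,
        ledger=scribbles.table.copy(),
    )


def retrain_classifier(
    clf: PixelClassifier,
    images: dict[str, CalibratedImage],
    corrections: TrainingScribbles,
) -> PixelClassifier:
    """Refit with correction scribbles appended to the ledger (same seed)."""
    merged = TrainingScribbles(
        pd.concat([clf.ledger, corrections.table], ignore_index=True)
    )
    return train_classifier(
        images, merged, seed=clf.seed, sigmas=clf.sigmas,
        n_trees=clf.forest.n_estimators if clf.forest is not None else 100,
    )


def segment_aa(
    img: CalibratedImage,
    clf: PixelClassifier,
    prob_threshold: float = 0.5,
    nerve_class: str = "nerve",
) -> np.ndarray:
    """Classify every pixel; nerve-class probability >= threshold -> mask.

    Unlike ED/CF no image transformation is applied: the classifier labels
    the original pixels directly.
    """
    if not clf.trained:
        raise SegmentationError("classifier has not been trained")
    if not 0.0 <= prob_threshold <= 1.0:
        raise SegmentationError(
            f"prob_threshold must lie in [0, 1], got {prob_threshold}"
        )
    if nerve_class not in clf.classes:
        raise SegmentationError(f"classifier has no class {nerve_class!r}")
    stack = build_feature_stack(img, clf.sigmas)
    h, w, f = stack.shape
    proba = clf.forest.predict_proba(stack.reshape(-1, f))
    col = list(clf.forest.classes_).index(nerve_class)
    return (proba[:, col] >= prob_threshold).reshape(h, w)


def save_classifier(path: str | Path, clf: PixelClassifier) -> None:
    """Serialise the classifier state to a single versioned file."""
    joblib.dump({"format_version": 1, "classifier": clf}, path)


def load_classifier(path: str | Path) -> PixelClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise SegmentationError(f"unsupported classifier file version in {path}")
    return payload["classifier"]
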