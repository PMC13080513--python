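"""Calibrated two-channel rasters and epidermis ROI geometry.

Skin-biopsy sections are imaged in two fluorescence channels: a pan-neuronal
marker (PGP9.5) labelling the nerve fibres and an epidermal marker (NKCC1)
outlining the epidermis.  The epidermis is delineated manually as a polygon
whose continuous geometry (shoelace area, summed edge length) provides the
normalisation denominators A (µm²) and P (µm); a rasterised mask of the same
polygon gates the particle analysis.

Conventions: 0-based pixel indices, (x = column, y = row), pixel centres at
integer coordinates.  Intensities are normalised to [0, 1] floats regardless
of source bit depth; the calibration ``scale`` is µm per pixel side.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "ImageFormatError",
    "GeometryError",
    "CalibratedImage",
    "PolygonROI",
    "EpidermisROI",
    "load_image",
    "as_binary_mask",
    "polygon_area_perimeter",
    "rasterize_roi",
    "read_roi_json",
    "write_roi_json",
    "read_imagej_roi",
    "DEFAULT_SCALE_UM_PER_PX",
]

#: Calibration used in the reference acquisition protocol (µm per pixel).
DEFAULT_SCALE_UM_PER_PX = 1.5


class ImageFormatError(ValueError):
    """Raised for unreadable images or channel/calibration contract violations."""


class GeometryError(ValueError):
    """Raised for degenerate or invalid polygon geometry."""


def _normalize_intensities(arr: np.ndarray) -> np.ndarray:
    """Map integer images onto [0, 1] by their dtype range; floats are clipped."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    out = arr.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise ImageFormatError("image contains non-finite intensities")
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class CalibratedImage:
    """Two-channel intensity raster with a physical calibration.

    Parameters
    ----------
    nerve
        Nerve-marker channel, 2-D float array in [0, 1].
    epidermis
        Epidermis-marker channel (same shape), or ``None`` for single-channel
        inputs.
    scale
        Side length of one pixel in µm (> 0).
    """

    nerve: np.ndarray
    epidermis: np.ndarray | None
    scale: float
    channel_names: tuple[str, ...] = ("nerve", "epidermis")

    def __post_init__(self) -> None:
        if self.scale <= 0 or not np.isfinite(self.scale):
            raise ImageFormatError(f"scale must be positive, got {self.scale}")
        if self.nerve.ndim != 2 or self.nerve.size == 0:
            raise ImageFormatError("nerve channel must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.nerve)) or self.nerve.min() < 0:
            raise ImageFormatError("intensities must be finite and non-negative")
        if self.epidermis is not None:
            if self.epidermis.shape != self.nerve.shape:
                raise ImageFormatError(
                    "channel shape mismatch: "
                    f"{self.nerve.shape} vs {self.epidermis.shape}"
                )
            if not np.all(np.isfinite(self.epidermis)) or self.epidermis.min() < 0:
                raise ImageFormatError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nerve.shape

    @property
    def height(self) -> int:
        return self.nerve.shape[0]

    @property
    def width(self) -> int:
        return self.nerve.shape[1]


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            return tifffile.imread(path)
        import imageio.v3 as iio

        return iio.imread(path)
    except (OSError, ValueError) as exc:  # pragma: no cover - passthrough detail
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc


def _split_channels(arr: np.ndarray, n_expected: int) -> list[np.ndarray]:
    if arr.ndim == 2:
        channels = [arr]
    elif arr.ndim == 3:
        # channels-last (H, W, C<=4) vs channels-first (C<=4, H, W)
        if arr.shape[-1] <= 4 and arr.shape[-1] < min(arr.shape[:2]):
            channels = [arr[..., i] for i in range(arr.shape[-1])]
        elif arr.shape[0] <= 4 and arr.shape[0] < min(arr.shape[1:]):
            channels = [arr[i] for i in range(arr.shape[0])]
        else:
            raise ImageFormatError(f"ambiguous channel axis for shape {arr.shape}")
    else:
        raise ImageFormatError(f"expected 2-D or 3-D image, got ndim={arr.ndim}")
    if len(channels) != n_expected:
        raise ImageFormatError(
            f"image has {len(channels)} channel(s) but the configuration "
            f"expects {n_expected}"
        )
    return channels


def load_image(
    path: str | Path,
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX,
    channel_order: tuple[str, ...] = ("nerve", "epidermis"),
) -> CalibratedImage:
    """Load a 1–3 channel TIFF/PNG as a :class:`CalibratedImage`.

    ``channel_order`` maps file channels to semantic names; it must contain
    ``"nerve"`` and may contain ``"epidermis"``.  Intensities are normalised
    to [0, 1] by the source bit depth (a 16-bit image with maximum value
    65535 maps to 1.0).
    """
    if scale_um_per_px <= 0:
        raise ImageFormatError(f"scale must be positive, got {scale_um_per_px}")
    if "nerve" not in channel_order:
        raise ImageFormatError("channel_order must include 'nerve'")
    arr = _read_raster(path)
    channels = _split_channels(arr, len(channel_order))
    by_name = {
        name: _normalize_intensities(ch) for name, ch in zip(channel_order, channels)
    }
    return CalibratedImage(
        nerve=by_name["nerve"],
        epidermis=by_name.get("epidermis"),
        scale=float(scale_um_per_px),
        channel_names=tuple(channel_order),
    )


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce an array of {0, 1} values to a boolean mask."""
    a = np.asarray(arr)
    if a.dtype == bool:
        return a
    uniq = np.unique(a)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be strictly binary (0/1)")
    return a.astype(bool)


@dataclass(frozen=True)
class PolygonROI:
    """Closed simple polygon in pixel coordinates (x = column, y = row).

    Vertices may be sub-pixel; the last vertex implicitly connects to the
    first.  Construction validates that the polygon has at least three
    vertices and does not self-intersect.
    """

    vertices: np.ndarray  # (n, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("polygon is self-intersecting or degenerate")

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class EpidermisROI:
    """Epidermis region: polygon, raster mask and calibrated denominators.

    ``area_um2`` and ``perimeter_um`` come from the continuous polygon (the
    values the delineation tool reports), not from the raster; the mask is
    used only to gate particles.
    """

    polygon: PolygonROI
    mask: np.ndarray  # bool, image-shaped
    area_um2: float
    perimeter_um: float
    scale: float


def polygon_area_perimeter(
    polygon: PolygonROI, scale: float
) -> tuple[float, float]:
    """Shoelace area (µm², scale²-weighted) and edge length (µm) of a polygon."""
    if scale <= 0:
        raise GeometryError(f"scale must be positive, got {scale}")
    poly = polygon.to_shapely()
    return poly.area * scale**2, poly.length * scale


def rasterize_roi(
    polygon: PolygonROI, shape: tuple[int, int], scale: float
) -> EpidermisROI:
    """Rasterize a polygon by pixel-centre inclusion (boundary centres count).

    The polygon must lie within the pixel-centre grid ``[0, W-1] × [0, H-1]``.
    Area and perimeter are taken from the continuous polygon.
    """
    h, w = shape
    v = polygon.vertices
    if (
        v[:, 0].min() < 0
        or v[:, 0].max() > w - 1
        or v[:, 1].min() < 0
        or v[:, 1].max() > h - 1
    ):
        raise GeometryError("polygon extends outside the image bounds")
    poly = polygon.to_shapely()
    x0, y0, x1, y1 = poly.bounds
    cx0, cx1 = int(np.floor(x0)), int(np.ceil(x1))
    cy0, cy1 = int(np.floor(y0)), int(np.ceil(y1))
    xs = np.arange(cx0, cx1 + 1)
    ys = np.arange(cy0, cy1 + 1)
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[cy0 : cy1 + 1, cx0 : cx1 + 1] = inside
    area, perim = polygon_area_perimeter(polygon, scale)
    return EpidermisROI(
        polygon=polygon, mask=mask, area_um2=area, perimeter_um=perim, scale=scale
    )


# ---------------------------------------------------------------------------
# ROI serialisation


def write_roi_json(path: str | Path, polygon: PolygonROI, scale: float) -> None:
    payload = {
        "scale_um_per_px": float(scale),
        "vertices": [[float(x), float(y)] for x, y in polygon.vertices],
    }
    Path(path).write_text(json.dumps(payload))


def read_roi_json(path: str | Path) -> tuple[PolygonROI, float]:
    """Read ``{"scale_um_per_px": s, "vertices": [[x, y], ...]}``."""
    payload = json.loads(Path(path).read_text())
    try:
        scale = float(payload["scale_um_per_px"])
        vertices = np.asarray(payload["vertices"], dtype=np.float64)
    except (KeyError, TypeError, ValueError) as exc:
        raise GeometryError(f"malformed ROI JSON {path}: {exc}") from exc
    return PolygonROI(vertices), scale


def read_imagej_roi(path: str | Path) -> PolygonROI:
    """Read a polygon record from an ImageJ ``.roi`` file (type=polygon only).

    Only the legacy binary polygon layout is supported: magic ``Iout``,
    bounding box, vertex count, then 16-bit x and y offsets relative to the
    bounding box corner.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 64 or raw[:4] != b"Iout":
        raise GeometryError(f"{path} is not an ImageJ ROI file")
    roi_type = raw[6]
    if roi_type != 0:  # 0 = polygon
        raise GeometryError(f"unsupported ImageJ ROI type {roi_type} (want polygon)")
    top, left, _bottom, _right, n = struct.unpack(">hhhhH", raw[8:18])
    coords = struct.unpack(f">{2 * n}h", raw[64 : 64 + 4 * n])
    xs = np.asarray(coords[:n], dtype=np.float64) + left
    ys = np.asarray(coords[n:], dtype=np.float64) + top
    return PolygonROI(np.column_stack([xs, ys]))
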