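"""Image containers, unit conversion and histogram-based auto-thresholds.

All images carry a physical pixel size in nanometres. The coordinate
convention used throughout the package is:

* pixel indices are 0-based ``(row, col)``;
* the physical coordinate of pixel ``(i, j)`` is its centre,
  ``x = (j + 0.5) * pixel_size_nm``, ``y = (i + 0.5) * pixel_size_nm``;
* all distances are reported in nm.

Auto-thresholds (Triangle, Intermodes) are computed on a 256-bin histogram
spanning the observed intensity range, which reproduces the behaviour of
8-bit-style auto-thresholding regardless of the input bit depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "PixelImage",
    "ImageStack",
    "DegenerateHistogramError",
    "HistogramNotBimodalError",
    "to_pixels",
    "max_project",
    "histogram_256",
    "triangle_threshold",
    "intermodes_threshold",
    "read_tiff",
    "write_tiff",
    "read_roi_labels",
]

N_HISTOGRAM_BINS = 256
INTERMODES_MAX_ITER = 10_000


class DegenerateHistogramError(ValueError):
    """Raised when an auto-threshold is requested for a constant image."""


class HistogramNotBimodalError(ValueError):
    """Raised when iterative smoothing fails to produce a bimodal histogram."""


@dataclass
class PixelImage:
    """A single 2D intensity plane with a physical pixel size.

    Parameters
    ----------
    values
        2D array of intensities (any integer or float dtype; stored as float64).
    pixel_size_nm
        Physical edge length of one pixel in nanometres (> 0).
    channel_name
        Free-text channel label (e.g. ``"syph"``, ``"basp1"``).
    """

    values: np.ndarray
    pixel_size_nm: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("PixelImage requires a 2D array")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ImageStack:
    """An ordered list of planes (z and/or channel axis) sharing a grid."""

    planes: list[PixelImage]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("ImageStack requires at least one plane")
        shape = self.planes[0].shape
        px = self.planes[0].pixel_size_nm
        for p in self.planes:
            if p.shape != shape or p.pixel_size_nm != px:
                raise ValueError("all planes must share shape and pixel size")

    @property
    def pixel_size_nm(self) -> float:
        return self.planes[0].pixel_size_nm

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    def __len__(self) -> int:
        return len(self.planes)

    def channel(self, name: str) -> PixelImage:
        for p in self.planes:
            if p.channel_name == name:
                return p
        raise KeyError(f"no plane named {name!r}")

    def as_array(self) -> np.ndarray:
        return np.stack([p.values for p in self.planes])


def to_pixels(length_nm: float, pixel_size_nm: float) -> float:
    """Convert a physical length to (real-valued) pixels; no rounding here."""
    if not length_nm > 0 or not pixel_size_nm > 0:
        raise ValueError("length_nm and pixel_size_nm must be > 0")
    return length_nm / pixel_size_nm


def max_project(stack: ImageStack) -> PixelImage:
    """Per-pixel maximum-intensity projection across all planes."""
    arr = stack.as_array()
    return PixelImage(
        arr.max(axis=0),
        pixel_size_nm=stack.pixel_size_nm,
        channel_name=stack.planes[0].channel_name,
    )


# ---------------------------------------------------------------------------
# Histogram auto-thresholds
# ---------------------------------------------------------------------------


def histogram_256(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram between the observed min and max.

    Returns ``(counts, vmin, bin_width)``; the centre of bin ``b`` on the
    intensity scale is ``vmin + (b + 0.5) * bin_width``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    vmin = float(v.min())
    vmax = float(v.max())
    if vmax == vmin:
        raise DegenerateHistogramError("degenerate histogram: constant image")
    counts, _ = np.histogram(v, bins=N_HISTOGRAM_BINS, range=(vmin, vmax))
    return counts.astype(np.float64), vmin, (vmax - vmin) / N_HISTOGRAM_BINS


def _bin_center(b: int, vmin: float, width: float) -> float:
    return vmin + (b + 0.5) * width


def triangle_threshold(img: np.ndarray | PixelImage) -> float:
    """Triangle auto-threshold on the intensity scale.

    A chord is drawn in (bin index, count) coordinates from the histogram
    peak to the non-empty bin farthest from it; the threshold is the bin that
    maximizes the perpendicular distance between the histogram curve and this
    chord (ties broken toward the lower bin).
    """
    values = img.values if isinstance(img, PixelImage) else img
    counts, vmin, width = histogram_256(values)

    peak = int(np.argmax(counts))
    nonempty = np.flatnonzero(counts)
    # farthest occupied bin from the peak, on either side
    far = int(nonempty[np.argmax(np.abs(nonempty - peak))])
    if far == peak:
        raise DegenerateHistogramError("degenerate histogram: single occupied bin")

    lo, hi = (peak, far) if peak < far else (far, peak)
    b = np.arange(lo, hi + 1)
    # perpendicular distance of (b, h[b]) from the line through
    # (peak, h[peak]) and (far, h[far])
    x1, y1 = peak, counts[peak]
    x2, y2 = far, counts[far]
    d = np.abs((y2 - y1) * b - (x2 - x1) * counts[lo : hi + 1] + x2 * y1 - y2 * x1)
    best = int(b[np.argmax(d)])
    return _bin_center(best, vmin, width)


def _smooth3(h: np.ndarray) -> np.ndarray:
    """One pass of 3-bin mean smoothing with replicate edge padding."""
    padded = np.concatenate(([h[0]], h, [h[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(h: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima, ends padded with -inf."""
    padded = np.concatenate(([-np.inf], h, [-np.inf]))
    return np.flatnonzero((padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:]))


def intermodes_threshold(img: np.ndarray | PixelImage) -> float:
    """Intermodes auto-threshold on the intensity scale.

    The 256-bin histogram is repeatedly smoothed with a 3-bin running mean
    until exactly two local maxima survive; the threshold is the midpoint of
    the two modes mapped back to intensities. Histograms that reach fewer
    than two maxima, or do not reach two within ``INTERMODES_MAX_ITER``
    passes, raise :class:`HistogramNotBimodalError`.
    """
    values = img.values if isinstance(img, PixelImage) else img
    counts, vmin, width = histogram_256(values)

    h = counts.copy()
    for _ in range(INTERMODES_MAX_ITER):
        maxima = _local_maxima(h)
        if len(maxima) == 2:
            mid = (maxima[0] + maxima[1]) / 2.0
            return vmin + (mid + 0.5) * width
        if len(maxima) < 2:
            raise HistogramNotBimodalError("histogram not bimodal")
        h = _smooth3(h)
    raise HistogramNotBimodalError("histogram not bimodal (iteration cap)")


# ---------------------------------------------------------------------------
# TIFF / ROI I/O
# ---------------------------------------------------------------------------


def write_tiff(stack: ImageStack, path) -> None:
    """Write a multi-page TIFF, one page per plane; pixel size and channel
    names are stored as JSON in the image description."""
    desc = json.dumps(
        {
            "pixel_size_nm": stack.pixel_size_nm,
            "channel_names": [p.channel_name for p in stack.planes],
        }
    )
    tifffile.imwrite(path, stack.as_array(), description=desc, photometric="minisblack")


def read_tiff(path, pixel_size_nm: float | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Pixel size is recovered from the JSON image description written by
    :func:`write_tiff`; for foreign files it must be supplied explicitly.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: dict = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    px = meta.get("pixel_size_nm", pixel_size_nm)
    if px is None:
        raise ValueError("unknown pixel size: no metadata and no --pixel-size-nm")
    if arr.ndim == 2:
        arr = arr[None]
    names = meta.get("channel_names", [""] * len(arr))
    planes = [
        PixelImage(plane, pixel_size_nm=float(px), channel_name=names[k])
        for k, plane in enumerate(arr)
    ]
    return ImageStack(planes, metadata=meta)


def read_roi_labels(path, pixel_size_nm: float | None = None) -> np.ndarray:
    """Read an ROI label map (integer TIFF page) as an int array."""
    stack = read_tiff(path, pixel_size_nm=pixel_size_nm or 1.0)
    return stack.planes[0].values.astype(np.int64)
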