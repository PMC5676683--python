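"""Segmentation of animal bodies and per-blob feature extraction.

Animals appear as dark blobs on a bright, roughly constant background.  Each
frame is thresholded, 8-connected components are filtered by pixel count, and
every surviving blob is summarised by the feature bundle used downstream for
identity linking:

* sub-pixel centre of mass (unweighted mean of pixel centres),
* size (pixel count),
* an intensity histogram of the contrast-normalised rectangular ROI
  enclosing the blob, and
* the seven Hu moment invariants of the masked, normalised intensities.

Coordinate convention (used throughout the package): 0-based indices,
``x`` = column, ``y`` = row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure


class DegenerateBlobError(ValueError):
    """Raised when a blob carries no usable intensity signal."""


@dataclass(frozen=True)
class GrayFrame:
    """A single 8-bit grayscale video frame.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities in ``[0, 255]``.
    index : int
        Frame number, ``>= 0``.  The detection time is ``index / fps``.
    """

    pixels: np.ndarray
    index: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("frame must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BlobMask:
    """Pixel support of one connected blob.

    ``rows``/``cols`` hold the coordinates of the member pixels; ``bbox`` is
    the tight inclusive bounding box ``(row_min, col_min, row_max, col_max)``.
    """

    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.intp)
        cols = np.asarray(self.cols, dtype=np.intp)
        if rows.size == 0 or rows.shape != cols.shape:
            raise ValueError("blob mask must contain at least one pixel")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)

    @property
    def size(self) -> int:
        return int(self.rows.size)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (
            int(self.rows.min()),
            int(self.cols.min()),
            int(self.rows.max()),
            int(self.cols.max()),
        )

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass(frozen=True)
class Detection:
    """Feature bundle of one blob in one frame."""

    cm: tuple[float, float]          # (x, y) sub-pixel centre of mass
    size: int                        # pixel count of the blob
    hist: np.ndarray                 # length-kn integer ROI histogram
    hu: np.ndarray                   # 7 Hu moment invariants
    t: float                         # seconds, frame / fps
    frame: int
    bbox: tuple[int, int, int, int]  # inclusive (row_min, col_min, row_max, col_max)


@dataclass
class DetectionConfig:
    """User-facing segmentation / feature parameters.

    ``threshold`` separates animal from background; with the default polarity
    pixels *below* the threshold are foreground (dark animals on a bright
    background) — set ``invert=True`` for bright animals on a dark background.
    ``kn`` is the number of histogram bins of the normalised ROI.
    """

    threshold: float = 100.0
    min_size: int = 20
    max_size: int = 1_000_000
    fps: float = 25.0
    kn: int = 32
    invert: bool = False
    binary_hu: bool = False       # Hu moments of the silhouette instead of intensities
    mask_histogram: bool = False  # histogram blob pixels only instead of the whole ROI

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        if not 0 < self.min_size <= self.max_size:
            raise ValueError("need 0 < min_size <= max_size")
        if self.kn < 2:
            raise ValueError("kn must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def segment_frame(
    frame: GrayFrame,
    intensity_threshold: float,
    min_size: int,
    max_size: int,
    invert: bool = False,
) -> list[BlobMask]:
    """Extract 8-connected foreground components, filtered by pixel count.

    Components are returned in deterministic order: by row-major position of
    each component's first pixel.
    """
    if not 0 <= intensity_threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if not 0 < min_size <= max_size:
        raise ValueError("need 0 < min_size <= max_size")
    px = frame.pixels
    fg = px > intensity_threshold if invert else px < intensity_threshold
    if not fg.any():
        return []
    labels = measure.label(fg, connectivity=2)
    blobs: list[tuple[int, BlobMask]] = []
    width = px.shape[1]
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        if not min_size <= rows.size <= max_size:
            continue
        first = int((rows * width + cols).min())
        blobs.append((first, BlobMask(rows, cols)))
    blobs.sort(key=lambda item: item[0])
    return [b for _, b in blobs]


def normalize_roi(frame: GrayFrame, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Min-max contrast stretch of the bbox rectangle onto ``[0, 255]``.

    A constant ROI (min == max) maps to all zeros.
    """
    r0, c0, r1, c1 = bbox
    h, w = frame.shape
    if not (0 <= r0 <= r1 < h and 0 <= c0 <= c1 < w):
        raise ValueError(f"bbox {bbox} outside frame bounds {frame.shape}")
    roi = frame.pixels[r0 : r1 + 1, c0 : c1 + 1].astype(np.float64)
    lo, hi = roi.min(), roi.max()
    if hi == lo:
        return np.zeros_like(roi)
    return np.clip((roi - lo) * 255.0 / (hi - lo), 0.0, 255.0)


def roi_histogram(norm_roi: np.ndarray, kn: int) -> np.ndarray:
    """Histogram of ROI intensities over ``kn`` equal bins spanning [0, 255].

    Bin ``k`` counts values in ``[255 k / kn, 255 (k+1) / kn)``; the value 255
    exactly goes to the last bin so that the bins conserve the pixel count.
    """
    if kn < 2:
        raise ValueError("kn must be >= 2")
    values = np.asarray(norm_roi, dtype=np.float64).ravel()
    if values.size and (values.min() < 0 or values.max() > 255):
        raise ValueError("ROI values must lie in [0, 255]")
    bins = np.floor(values * kn / 255.0).astype(np.intp)
    np.clip(bins, 0, kn - 1, out=bins)
    return np.bincount(bins, minlength=kn).astype(np.int64)


def hu_moments(norm_roi: np.ndarray, mask: BlobMask, binary: bool = False) -> np.ndarray:
    """Seven Hu invariants of the blob's (masked) normalised intensity image.

    ROI pixels outside the blob are set to zero before moment computation, so
    background texture does not leak into the shape descriptor.  With
    ``binary=True`` the silhouette (1 inside, 0 outside) is used instead of
    the intensities.
    """
    r0, c0, _, _ = mask.bbox
    img = np.zeros_like(np.asarray(norm_roi, dtype=np.float64))
    rr = mask.rows - r0
    cc = mask.cols - c0
    img[rr, cc] = 1.0 if binary else np.asarray(norm_roi, dtype=np.float64)[rr, cc]
    if not img.any():
        raise DegenerateBlobError("blob has no intensity signal (all-zero masked ROI)")
    mu = measure.moments_central(img)
    nu = measure.moments_normalized(mu)
    hu = measure.moments_hu(nu)
    if not np.all(np.isfinite(hu)):
        raise DegenerateBlobError("non-finite Hu invariants")
    return hu


def extract_detection(
    frame: GrayFrame,
    blob: BlobMask,
    fps: float,
    kn: int,
    binary_hu: bool = False,
    mask_histogram: bool = False,
) -> Detection:
    """Assemble the per-blob feature bundle for one frame."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    bbox = blob.bbox
    roi = normalize_roi(frame, bbox)
    if mask_histogram:
        rr = blob.rows - bbox[0]
        cc = blob.cols - bbox[1]
        hist = roi_histogram(roi[rr, cc], kn)
    else:
        hist = roi_histogram(roi, kn)
    try:
        hu = hu_moments(roi, blob, binary=binary_hu)
    except DegenerateBlobError:
        # a zero-contrast blob (uniform intensity filling its own bbox)
        # still has a shape: fall back to silhouette moments
        hu = hu_moments(roi, blob, binary=True)
    cm = (float(blob.cols.mean()), float(blob.rows.mean()))
    return Detection(
        cm=cm,
        size=blob.size,
        hist=hist,
        hu=hu,
        t=frame.index / fps,
        frame=frame.index,
        bbox=bbox,
    )


def detect_frame(frame: GrayFrame, cfg: DetectionConfig) -> list[Detection]:
    """Segment one frame and extract all detections under ``cfg``."""
    blobs = segment_frame(frame, cfg.threshold, cfg.min_size, cfg.max_size, invert=cfg.invert)
    return [
        extract_detection(
            frame,
            b,
            fps=cfg.fps,
            kn=cfg.kn,
            binary_hu=cfg.binary_hu,
            mask_histogram=cfg.mask_histogram,
        )
        for b in blobs
    ]
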