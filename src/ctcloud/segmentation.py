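"""Grey-window selection and per-slice edge detection.

The Roberts cross operator is the primary detector: it uses a pair of 2x2
diagonal-difference kernels and is implemented here directly (it is the
core primitive of the segmentation route).  Prewitt, Sobel,
Laplacian-of-Gaussian, zero-cross and Canny variants are provided for
side-by-side comparison.

Border policy: positions without a complete kernel window output 0, so the
field-of-view boundary never produces phantom edges.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack_io import SliceImage

__all__ = [
    "GreyWindow",
    "EdgeMap",
    "DETECTORS",
    "window_mask",
    "roberts_edges",
    "detect_edges",
    "compare_edge_detectors",
]

DETECTORS = (
    "roberts",
    "prewitt",
    "sobel",
    "log",
    "zerocross",
    "canny",
    "approx_canny",
)


@dataclasses.dataclass(frozen=True)
class GreyWindow:
    """Inclusive grey-value interval on the 8-bit scale."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 255):
            raise ValueError(f"invalid grey window [{self.lo}, {self.hi}]; need 0 <= lo <= hi <= 255")

    @classmethod
    def parse(cls, text: str) -> "GreyWindow":
        """Parse a ``LO:HI`` string."""
        lo, _, hi = text.partition(":")
        return cls(int(lo), int(hi))


@dataclasses.dataclass
class EdgeMap:
    """Binary edge mask with the detector name and threshold that made it."""

    mask: np.ndarray
    detector: str
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("edge mask must be 2D")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def _as_pixels(image: SliceImage | np.ndarray) -> np.ndarray:
    if isinstance(image, SliceImage):
        return image.pixels
    return np.asarray(image)


def window_mask(slice_: SliceImage | np.ndarray, window: GreyWindow) -> np.ndarray:
    """Binary mask of pixels with grey value inside the window (inclusive)."""
    a = _as_pixels(slice_)
    return (a >= window.lo) & (a <= window.hi)


def _auto_threshold(magnitude: np.ndarray) -> float:
    """Otsu threshold of a gradient-magnitude image; 0 for flat images."""
    vals = magnitude[magnitude > 0]
    if vals.size == 0 or vals.min() == vals.max():
        return 0.0
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(vals))


def roberts_edges(image: np.ndarray, threshold: float | None = None) -> EdgeMap:
    """Roberts cross edge detection with 2x2 diagonal-difference kernels.

    For each pixel (i, j) owning a complete 2x2 neighbourhood,
    ``Gx = p(i,j) - p(i+1,j+1)`` and ``Gy = p(i,j+1) - p(i+1,j)``; the mask
    is 1 where ``sqrt(Gx^2 + Gy^2)`` exceeds the threshold.  The last row
    and column have no complete window and stay 0.  When ``threshold`` is
    None, Otsu's threshold of the non-zero magnitudes is used.
    """
    a = np.asarray(_as_pixels(image), dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("image must be at least 2x2 for Roberts edge detection")
    gx = a[:-1, :-1] - a[1:, 1:]
    gy = a[:-1, 1:] - a[1:, :-1]
    magnitude = np.zeros_like(a)
    magnitude[:-1, :-1] = np.hypot(gx, gy)
    if threshold is None:
        threshold = _auto_threshold(magnitude)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return EdgeMap(mask=magnitude > threshold, detector="roberts", threshold=float(threshold))


_PREWITT_GX = np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [1.0, 0.0, -1.0]])
_SOBEL_GX = np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]])


def _first_difference_edges(a: np.ndarray, kernel_gx: np.ndarray, detector: str, threshold: float | None) -> EdgeMap:
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3 for {detector}")
    gx = ndi.convolve(a, kernel_gx, mode="constant")
    gy = ndi.convolve(a, kernel_gx.T, mode="constant")
    magnitude = np.hypot(gx, gy)
    magnitude[0, :] = magnitude[-1, :] = 0.0
    magnitude[:, 0] = magnitude[:, -1] = 0.0
    if threshold is None:
        threshold = _auto_threshold(magnitude)
    return EdgeMap(mask=magnitude > threshold, detector=detector, threshold=float(threshold))


def _zero_cross_edges(a: np.ndarray, sigma: float, detector: str, threshold: float | None) -> EdgeMap:
    if sigma > 0:
        lap = ndi.gaussian_laplace(a, sigma=sigma)
    else:
        lap = ndi.laplace(a)
    if threshold is None:
        mean_abs = float(np.mean(np.abs(lap)))
        threshold = 0.75 * mean_abs
    mask = np.zeros(a.shape, dtype=bool)
    # A zero crossing is a sign change against the right or lower neighbour
    # whose jump exceeds the threshold; marked on the pixel nearer zero.
    for axis in (0, 1):
        here = lap
        there = np.roll(lap, -1, axis=axis)
        sign_change = (here * there) < 0
        jump = np.abs(here - there) > threshold
        nearer = np.abs(here) <= np.abs(there)
        hit = sign_change & jump
        if axis == 0:
            hit[-1, :] = False
        else:
            hit[:, -1] = False
        mask |= hit & nearer
        shifted = np.zeros_like(mask)
        if axis == 0:
            shifted[1:, :] = (hit & ~nearer)[:-1, :]
        else:
            shifted[:, 1:] = (hit & ~nearer)[:, :-1]
        mask |= shifted
    border = max(1, int(np.ceil(2 * sigma))) if sigma > 0 else 1
    mask[:border, :] = mask[-border:, :] = False
    mask[:, :border] = mask[:, -border:] = False
    return EdgeMap(mask=mask, detector=detector, threshold=float(threshold))


def _canny_edges(a: np.ndarray, sigma: float, detector: str,
                 low: float | None, high: float | None) -> EdgeMap:
    from skimage.feature import canny

    mask = canny(a, sigma=sigma, low_threshold=low, high_threshold=high)
    return EdgeMap(mask=mask, detector=detector, threshold=float(low if low is not None else 0.0))


def detect_edges(
    image: SliceImage | np.ndarray,
    detector: str = "roberts",
    threshold: float | None = None,
    sigma: float = 2.0,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
) -> EdgeMap:
    """Dispatch to a named edge detector.

    ``threshold`` is a gradient-magnitude cutoff (Roberts/Prewitt/Sobel) or
    a zero-crossing jump cutoff (log/zerocross); Canny uses the hysteresis
    pair ``low_threshold``/``high_threshold`` and smoothing ``sigma``.
    """
    a = np.asarray(_as_pixels(image), dtype=np.float64)
    if detector == "roberts":
        return roberts_edges(a, threshold)
    if detector == "prewitt":
        return _first_difference_edges(a, _PREWITT_GX, "prewitt", threshold)
    if detector == "sobel":
        return _first_difference_edges(a, _SOBEL_GX, "sobel", threshold)
    if detector == "log":
        return _zero_cross_edges(a, sigma, "log", threshold)
    if detector == "zerocross":
        return _zero_cross_edges(a, 0.0, "zerocross", threshold)
    if detector == "canny":
        return _canny_edges(a, min(sigma, 1.0), "canny", low_threshold, high_threshold)
    if detector == "approx_canny":
        # coarser smoothing, cheaper approximation of the full operator
        return _canny_edges(a, max(sigma, 2.0), "approx_canny", low_threshold, high_threshold)
    raise ValueError(f"unknown edge detector {detector!r}; valid: {', '.join(DETECTORS)}")


def compare_edge_detectors(slice_: SliceImage | np.ndarray, **params) -> pd.DataFrame:
    """Run all seven detector configurations on one slice.

    Returns a DataFrame with one row per detector: name, edge-pixel count
    and the binary mask, for side-by-side rendering.
    """
    rows = []
    for det in DETECTORS:
        em = detect_edges(slice_, detector=det, **params)
        rows.append({"detector": det, "edge_pixels": em.count, "mask": em.mask})
    return pd.DataFrame(rows, columns=["detector", "edge_pixels", "mask"])
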