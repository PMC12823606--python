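"""Body-vs-background segmentation and repeat selection.

Imaged limbs rest on a dark surface, so tissue pixels carry high water
(TWI) and oxygenation (StO2) signals while background pixels do not.
Segmentation fuses the two index images:

1. compute the per-pixel TWI and StO2 images (display scale, [0, 100]);
2. Gaussian-filter each with a (5, 5)-pixel kernel to reduce noise;
3. divide each by its own maximum and sum them — the fused map lies in
   [0, 2], low where both indices are low, high where both are high.

When the histogram of fused values is bimodal (background peak vs body
peak) the threshold is found with Otsu's method; otherwise a fixed
threshold of 1 is used, which also handles frames with no body part or
with the body filling the whole frame. Of the three repeat acquisitions
per site, the one whose mask best covers the central analysis region is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks

from .hypercube import Hypercube
from .indices import DEFAULT_SCALING, IndexScaling, index_image

__all__ = [
    "BodyMask",
    "fused_index_image",
    "otsu_threshold",
    "is_bimodal",
    "body_mask",
    "select_best_repeat",
]

#: Fixed fallback threshold on the fused [0, 2] map.
FIXED_THRESHOLD = 1.0

#: Otsu histogram: 256 uniform bins over the fused range [0, 2].
OTSU_BINS = 256
FUSED_RANGE = (0.0, 2.0)

#: Bimodality test: 64-bin histogram, moving-average smoothing window,
#: and minimum peak prominence as a fraction of the tallest bin.
BIMODAL_BINS = 64
BIMODAL_SMOOTH_WINDOW = 5
BIMODAL_MIN_PROMINENCE = 0.05


@dataclass
class BodyMask:
    """Boolean tissue mask with segmentation provenance."""

    mask: np.ndarray
    threshold: float
    method: str  # "otsu" | "fixed"
    coverage_central: float = float("nan")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.threshold <= 2.0:
            raise ValueError("fused-map threshold must lie in [0, 2]")
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "fixed" and self.threshold != FIXED_THRESHOLD:
            raise ValueError("fixed method implies threshold 1.0")


def fused_index_image(
    cube: Hypercube,
    scaling: IndexScaling = DEFAULT_SCALING,
    kernel_sigma: float = 1.0,
) -> np.ndarray:
    """Max-normalized, Gaussian-smoothed TWI + StO2 map in [0, 2].

    ``kernel_sigma`` is the width (px) of the Gaussian whose support is
    the nominal 5 x 5 kernel; the filter itself is separable.
    """
    fused = np.zeros(cube.spatial_shape, dtype=float)
    for name in ("TWI", "STO2"):
        img = index_image(cube, name, scaling=scaling, scaled=True)
        img = np.nan_to_num(img, nan=0.0)
        img = gaussian_filter(img, sigma=kernel_sigma, truncate=2.0)  # 5x5 support
        peak = img.max()
        if peak <= 0:
            raise ValueError(f"all-zero {name} image: cannot max-normalize")
        fused += img / peak
    return fused


def otsu_threshold(
    values: np.ndarray,
    bins: int = OTSU_BINS,
    value_range: tuple[float, float] = FUSED_RANGE,
) -> float:
    """Histogram threshold maximizing between-class variance.

    Deterministic for the fixed binning (256 uniform bins over [0, 2]
    by default). Cuts through an empty histogram valley all maximize the
    criterion; the midpoint of that tied plateau is returned so the
    threshold sits centrally between the two modes.
    """
    v = np.asarray(values, dtype=float).ravel()
    if np.unique(v).size < 2:
        raise ValueError("Otsu threshold needs at least two distinct values")
    counts, edges = np.histogram(v, bins=bins, range=value_range)
    counts = counts.astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)  # class-0 weight for cut after bin i
    w1 = total - w0
    centers = 0.5 * (edges[:-1] + edges[1:])
    moments = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = moments / w0
        mu1 = (moments[-1] - moments) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    between = between[:-1]  # cut must leave both classes non-empty
    tied = np.nonzero(between == between.max())[0]
    best = int(round(tied.mean()))  # midpoint of the tied plateau
    return float(edges[best + 1])


def is_bimodal(
    values: np.ndarray,
    bins: int = BIMODAL_BINS,
    smooth_window: int = BIMODAL_SMOOTH_WINDOW,
    min_prominence_frac: float = BIMODAL_MIN_PROMINENCE,
) -> bool:
    """True iff the smoothed value histogram shows two separated modes.

    The histogram (64 bins over the data range) is smoothed with a short
    moving average; the test passes when at least two local maxima of
    non-trivial prominence are separated by a local minimum, which is
    what :func:`scipy.signal.find_peaks` counts.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 10 or np.unique(v).size < 2:
        return False
    counts, _ = np.histogram(v, bins=bins)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    # zero-pad so modes sitting in the first/last bin count as peaks
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence_frac * smoothed.max())
    return len(peaks) >= 2


def body_mask(
    cube: Hypercube,
    scaling: IndexScaling = DEFAULT_SCALING,
    central_region: np.ndarray | None = None,
) -> BodyMask:
    """Segment tissue pixels of one acquisition.

    Otsu's threshold is used when the fused-map histogram is bimodal,
    otherwise the fixed threshold 1.0. The mask is the set of pixels
    strictly above the threshold. If ``central_region`` (boolean image)
    is given, the fraction of it covered by the mask is recorded for
    repeat selection.
    """
    fused = fused_index_image(cube, scaling=scaling)
    if is_bimodal(fused):
        thr = otsu_threshold(fused)
        method = "otsu"
    else:
        thr = FIXED_THRESHOLD
        method = "fixed"
    mask = fused > thr
    coverage = float("nan")
    if central_region is not None:
        region = np.asarray(central_region, dtype=bool)
        coverage = float(mask[region].mean()) if region.any() else float("nan")
    return BodyMask(mask=mask, threshold=thr, method=method, coverage_central=coverage)


def select_best_repeat(masks: list[BodyMask], central_region: np.ndarray) -> int:
    """Index of the repeat whose mask best covers the central region.

    Exactly three repeats are expected (fewer are tolerated when a
    repeat is missing); ties break toward the lowest repeat index.
    """
    if not masks:
        raise ValueError("no repeats to select from")
    region = np.asarray(central_region, dtype=bool)
    shape = masks[0].mask.shape
    coverages = []
    for bm in masks:
        if bm.mask.shape != shape or region.shape != shape:
            raise ValueError("mask / central-region shape mismatch")
        coverages.append(float(bm.mask[region].mean()))
    return int(np.argmax(coverages))  # argmax takes the first max: lowest index wins
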