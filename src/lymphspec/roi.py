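"""Central-ROI spectra and affected-vs-unaffected delta metrics.

The analysis region of every acquisition is a circular patch at the
image center, 100 px in diameter (about 4.6 cm of skin at the fixed
50 cm capture distance). Each tissue pixel inside the patch is
L1-normalized — divided by its summed intensity — and the normalized
spectra are averaged into one representative spectrum per measurement.
Indices are computed *from that averaged spectrum* (index of the
average, not average of per-pixel indices), separately per body side,
so global lighting differences between acquisitions cancel. Side
differences are then simple subtractions affected - unaffected on raw
index values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .hypercube import Hypercube, Spectrum
from .indices import IndexSet

__all__ = [
    "MissingMeasurementError",
    "SiteMeasurement",
    "DeltaMetrics",
    "central_roi_mask",
    "representative_spectrum",
    "delta_metrics",
]

SITES = ("hand", "forearm", "upper_arm")
SIDES = ("affected", "unaffected")

#: Default ROI diameter in pixels (~4.6 cm at 50 cm capture distance).
ROI_DIAMETER_PX = 100


class MissingMeasurementError(ValueError):
    """The ROI contains no tissue pixels; the measurement is flagged missing."""


@dataclass
class SiteMeasurement:
    """Indices of one anatomical site on one side of one patient."""

    patient: str
    side: str
    site: str
    spectrum: Spectrum
    indices: IndexSet
    repeat: int = 0
    meta: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")


@dataclass(frozen=True)
class DeltaMetrics:
    """Signed affected-minus-unaffected index differences (raw scale)."""

    d_lwr: float
    d_twi: float
    d_tli: float


def central_roi_mask(
    image_shape: tuple[int, int], diameter_px: int = ROI_DIAMETER_PX
) -> np.ndarray:
    """Boolean disk of the given diameter centered on the image.

    The image center is at pixel coordinates ((H-1)/2, (W-1)/2)
    (640 x 480 frames -> (239.5, 319.5)); a pixel belongs to the disk
    when its center lies strictly within ``diameter_px / 2`` of it, so
    the disk is symmetric under reflection about the center.
    """
    h, w = image_shape
    if diameter_px > min(h, w):
        raise ValueError(f"ROI diameter {diameter_px} exceeds image dims {image_shape}")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 < (diameter_px / 2.0) ** 2


def representative_spectrum(
    cube: Hypercube, body: np.ndarray, roi: np.ndarray
) -> Spectrum:
    """L1-normalize each body pixel inside the ROI, then average.

    The result sums to 1 (a mean of unit-sum vectors). An empty
    body-ROI intersection raises :class:`MissingMeasurementError` rather
    than returning a zero spectrum.
    """
    select = np.asarray(body, dtype=bool) & np.asarray(roi, dtype=bool)
    if select.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube spatial shape")
    if not select.any():
        raise MissingMeasurementError("no tissue pixels inside the central ROI")
    pix = cube.data[select].astype(float)  # (n_pixels, n_bands)
    sums = pix.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("ROI contains pixels with non-positive total intensity")
    mean = (pix / sums).mean(axis=0)
    mean = mean / mean.sum()  # exact unit sum despite float rounding
    return Spectrum(mean, cube.grid, normalized=True)


def delta_metrics(affected: IndexSet, unaffected: IndexSet) -> DeltaMetrics:
    """Componentwise affected - unaffected on raw index values."""
    return DeltaMetrics(
        d_lwr=affected.lwr - unaffected.lwr,
        d_twi=affected.twi_raw - unaffected.twi_raw,
        d_tli=affected.tli_raw - unaffected.tli_raw,
    )
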