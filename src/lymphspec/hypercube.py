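"""Hyperspectral data model and low-level spectral operators.

A hyperspectral measurement is a reflectance *hypercube*: a
``(height, width, n_bands)`` array of non-negative reflectance
intensities with an attached wavelength grid. The default grid matches
a visible/NIR push-broom tissue camera: 100 band centers from 500 to
995 nm in uniform 5 nm steps, giving 640 x 480 x 100 cubes.

Every tissue index in :mod:`lymphspec.indices` is built from two
primitives defined here: the mean reflectance over a wavelength band
(inclusive at both ends) and the mean central-difference second
derivative over a band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "WavelengthGrid",
    "WavelengthBand",
    "Hypercube",
    "Spectrum",
    "make_default_grid",
    "band_mean",
    "band_mean_image",
    "second_derivative_mean",
    "second_derivative_mean_image",
]

#: Default grid parameters: 100 bands, 500-995 nm inclusive, 5 nm steps.
DEFAULT_START_NM = 500.0
DEFAULT_STOP_NM = 995.0
DEFAULT_STEP_NM = 5.0
DEFAULT_N_BANDS = 100

#: Default spatial resolution (height, width) of an acquisition.
DEFAULT_SHAPE = (480, 640)


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nm, strictly increasing and uniform."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid needs at least two wavelengths")
        d = np.diff(wl)
        if np.any(d <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(d, d[0]):
            raise ValueError("wavelength spacing must be uniform")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def step(self) -> float:
        """Grid spacing in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def band_indices(self, band: "WavelengthBand") -> np.ndarray:
        """Indices of grid points with ``band.lo <= wavelength <= band.hi``."""
        wl = self.wavelengths
        idx = np.nonzero((wl >= band.lo - 1e-9) & (wl <= band.hi + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(
                f"band {band.lo}-{band.hi} nm contains no grid point "
                f"(grid spans {wl[0]}-{wl[-1]} nm)"
            )
        return idx

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass(frozen=True)
class WavelengthBand:
    """Closed wavelength interval [lo, hi] in nm; both ends inclusive."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValueError(f"band lo must be <= hi, got {self.lo} > {self.hi}")


def make_default_grid() -> WavelengthGrid:
    """The camera's default grid: 100 band centers, 500, 505, ..., 995 nm."""
    wl = DEFAULT_START_NM + DEFAULT_STEP_NM * np.arange(DEFAULT_N_BANDS)
    return WavelengthGrid(wl)


@dataclass
class Hypercube:
    """Reflectance cube of shape (height, width, n_bands) on a wavelength grid.

    Parameters
    ----------
    data:
        Non-negative finite reflectance intensities.
    grid:
        Band-center wavelengths; length must equal ``data.shape[2]``.
    meta:
        Free-form acquisition metadata (patient id, side, site, repeat
        index, capture distance ...).
    """

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"{self.data.shape[2]} bands in data but {len(self.grid)} grid points"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("hypercube contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("hypercube contains negative reflectance")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixel_spectrum(self, row: int, col: int) -> "Spectrum":
        return Spectrum(self.data[row, col].astype(float), self.grid)


@dataclass
class Spectrum:
    """1-D reflectance vector aligned to a wavelength grid.

    ``normalized`` marks L1 normalization: values sum to 1 (within 1e-9).
    """

    values: np.ndarray
    grid: WavelengthGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise ValueError("spectrum length must equal grid length")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1")

    def l1_normalize(self) -> "Spectrum":
        """Divide by the summed intensity so the result sums to 1."""
        s = self.values.sum()
        if s <= 0:
            raise ValueError("cannot L1-normalize a spectrum with non-positive sum")
        return Spectrum(self.values / s, self.grid, normalized=True)


# ---------------------------------------------------------------------------
# band operators


def band_mean(spectrum: Spectrum, band: WavelengthBand) -> float:
    """Arithmetic mean of reflectance at all grid points inside ``band``.

    Band ends are inclusive: the 925-935 nm band on the default grid
    covers the three grid points {925, 930, 935}.
    """
    idx = spectrum.grid.band_indices(band)
    return float(spectrum.values[idx].mean())


def band_mean_image(cube: Hypercube, band: WavelengthBand) -> np.ndarray:
    """Per-pixel :func:`band_mean` over a hypercube; shape (H, W)."""
    idx = cube.grid.band_indices(band)
    return cube.data[:, :, idx].mean(axis=2).astype(float)


def _second_derivative(values: np.ndarray, step: float, smooth_sigma: float) -> np.ndarray:
    """Central-difference second derivative along the last axis, nm^-2.

    Endpoints are invalid (returned as NaN); callers restrict to interior
    bands. ``smooth_sigma`` is an optional Gaussian pre-smoothing width in
    grid-step units (0 disables it).
    """
    v = np.asarray(values, dtype=float)
    if smooth_sigma > 0:
        v = gaussian_filter1d(v, sigma=smooth_sigma, axis=-1, mode="nearest")
    d2 = np.full_like(v, np.nan)
    d2[..., 1:-1] = (v[..., :-2] - 2.0 * v[..., 1:-1] + v[..., 2:]) / step**2
    return d2


def second_derivative_mean(
    spectrum: Spectrum, band: WavelengthBand, smooth_sigma: float = 1.0
) -> float:
    """Mean central-difference second derivative over ``band``, in nm^-2.

    The spectrum is optionally pre-smoothed with a 1-D Gaussian of width
    ``smooth_sigma`` grid steps (default one band). Every band point needs
    a neighbour on each side, so the band must be interior to the grid.
    """
    idx = spectrum.grid.band_indices(band)
    n = len(spectrum.grid)
    if idx[0] == 0 or idx[-1] == n - 1:
        raise ValueError("band touches the grid boundary; second derivative undefined")
    d2 = _second_derivative(spectrum.values, spectrum.grid.step, smooth_sigma)
    return float(d2[idx].mean())


def second_derivative_mean_image(
    cube: Hypercube, band: WavelengthBand, smooth_sigma: float = 1.0
) -> np.ndarray:
    """Per-pixel :func:`second_derivative_mean`; shape (H, W)."""
    idx = cube.grid.band_indices(band)
    n = len(cube.grid)
    if idx[0] == 0 or idx[-1] == n - 1:
        raise ValueError("band touches the grid boundary; second derivative undefined")
    lo, hi = idx[0], idx[-1]
    # compute only the slab needed (with margin for smoothing + differencing)
    margin = int(np.ceil(4 * smooth_sigma)) + 1 if smooth_sigma > 0 else 1
    a, b = max(0, lo - margin), min(n, hi + margin + 1)
    d2 = _second_derivative(cube.data[:, :, a:b].astype(float), cube.grid.step, smooth_sigma)
    return d2[:, :, (lo - a) : (hi - a + 1)].mean(axis=2)
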