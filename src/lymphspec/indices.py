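"""Spectral tissue indices: LWR, TWI, TLI, StO2.

All indices are defined on fixed near-infrared / visible wavelength
bands where tissue chromophores absorb:

* **LWR** (lipid-to-water ratio) — ratio of the mean reflectance in the
  lipid absorption band (925-935 nm) to the water absorption band
  (965-985 nm). Fluid accumulation deepens the water band and lowers LWR.
* **TWI** (tissue water index) — ratio of mean reflectance 875-895 nm over
  950-975 nm; rises with tissue water content.
* **TLI** (tissue lipid index) — mean spectral second derivative over the
  lipid band 925-935 nm; a lipid absorption dip curves the reflectance
  upward there, so TLI rises with lipid content.
* **StO2** (tissue oxygenation) — ratio of second-derivative means over
  the hemoglobin band 575-590 nm and the deoxyhemoglobin band 740-780 nm.

The commercial camera displays each index affinely rescaled and clamped
to [0, 100]; the vendor's scaling constants are unpublished, so this
package maps a documented physiological raw range linearly onto [0, 100]
instead (:class:`IndexScaling`, overridable). Every scientific output of
the pipeline (deltas, staging) is computed from the *raw*, unscaled
values, so no conclusion depends on the scaling choice.

Raw ratio indices (LWR, TWI, StO2) are invariant to global rescaling of
the spectrum; TLI raw is not (it is linear in the spectrum), which is why
representative spectra are L1-normalized before indices are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import (
    Hypercube,
    Spectrum,
    WavelengthBand,
    band_mean,
    band_mean_image,
    second_derivative_mean,
    second_derivative_mean_image,
)

__all__ = [
    "BANDS",
    "IndexScaling",
    "IndexSet",
    "lwr",
    "twi_raw",
    "twi",
    "tli_raw",
    "tli",
    "sto2_raw",
    "sto2",
    "side_indices",
    "index_image",
]

#: Published band definitions (nm), inclusive at both ends.
BANDS: dict[str, WavelengthBand] = {
    "lwr_lipid": WavelengthBand(925.0, 935.0),
    "lwr_water": WavelengthBand(965.0, 985.0),
    "twi_num": WavelengthBand(875.0, 895.0),
    "twi_den": WavelengthBand(950.0, 975.0),
    "tli": WavelengthBand(925.0, 935.0),
    "sto2_num": WavelengthBand(575.0, 590.0),
    "sto2_den": WavelengthBand(740.0, 780.0),
}

INDEX_NAMES = ("LWR", "TWI", "TLI", "STO2")


@dataclass(frozen=True)
class IndexScaling:
    """Affine maps from raw index values onto the display scale [0, 100].

    Each pair ``(lo, hi)`` is the raw range mapped linearly to 0..100;
    values outside are clamped. Defaults cover the raw ranges produced by
    physiological reflectance spectra and are deliberately documented,
    not vendor constants.
    """

    twi_range: tuple[float, float] = (0.5, 1.5)
    tli_range: tuple[float, float] = (0.0, 5e-4)  # nm^-2
    sto2_range: tuple[float, float] = (0.0, 50.0)

    @staticmethod
    def _scale(raw, rng):
        lo, hi = rng
        scaled = (np.asarray(raw, dtype=float) - lo) / (hi - lo) * 100.0
        return np.clip(scaled, 0.0, 100.0)


DEFAULT_SCALING = IndexScaling()


@dataclass
class IndexSet:
    """Raw and display-scaled index values for one spectrum."""

    lwr: float
    twi_raw: float
    tli_raw: float
    sto2_raw: float
    twi: float = field(default=np.nan)
    tli: float = field(default=np.nan)
    sto2: float = field(default=np.nan)


def _ratio(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise ValueError(f"non-positive denominator band mean in {what}")
    return num / den


def lwr(spectrum: Spectrum) -> float:
    """Lipid-to-water ratio: band_mean(925-935) / band_mean(965-985)."""
    return _ratio(
        band_mean(spectrum, BANDS["lwr_lipid"]),
        band_mean(spectrum, BANDS["lwr_water"]),
        "LWR",
    )


def twi_raw(spectrum: Spectrum) -> float:
    """Raw tissue water index: band_mean(875-895) / band_mean(950-975).

    Water absorbs near 970 nm, so deeper water absorption lowers the
    denominator and raises the index — TWI increases with water content.
    """
    return _ratio(
        band_mean(spectrum, BANDS["twi_num"]),
        band_mean(spectrum, BANDS["twi_den"]),
        "TWI",
    )


def twi(spectrum: Spectrum, scaling: IndexScaling = DEFAULT_SCALING) -> float:
    return float(scaling._scale(twi_raw(spectrum), scaling.twi_range))


def tli_raw(spectrum: Spectrum, smooth_sigma: float = 1.0) -> float:
    """Raw tissue lipid index: mean second derivative over 925-935 nm (nm^-2)."""
    return second_derivative_mean(spectrum, BANDS["tli"], smooth_sigma=smooth_sigma)


def tli(spectrum: Spectrum, scaling: IndexScaling = DEFAULT_SCALING) -> float:
    return float(scaling._scale(tli_raw(spectrum), scaling.tli_range))


def sto2_raw(spectrum: Spectrum, smooth_sigma: float = 1.0) -> float:
    """Raw oxygenation index: second-derivative-mean ratio 575-590 / 740-780.

    Returns NaN when the denominator second-derivative mean is zero
    (e.g. an exactly linear spectrum) — an explicitly undefined value,
    never silently 0.
    """
    num = second_derivative_mean(spectrum, BANDS["sto2_num"], smooth_sigma=smooth_sigma)
    den = second_derivative_mean(spectrum, BANDS["sto2_den"], smooth_sigma=smooth_sigma)
    # physiological curvatures are ~1e-5 nm^-2; below 1e-12 the band is
    # numerically flat and the ratio undefined
    if abs(den) < 1e-12:
        return float("nan")
    return num / den


def sto2(spectrum: Spectrum, scaling: IndexScaling = DEFAULT_SCALING) -> float:
    raw = sto2_raw(spectrum)
    if np.isnan(raw):
        return float("nan")
    return float(scaling._scale(raw, scaling.sto2_range))


def side_indices(
    spectrum: Spectrum, scaling: IndexScaling = DEFAULT_SCALING
) -> IndexSet:
    """All indices of one representative (L1-normalized) spectrum.

    The contract is index-of-average: indices are computed from the
    averaged ROI spectrum, not averaged over per-pixel indices.
    """
    lw = lwr(spectrum)
    tw = twi_raw(spectrum)
    tl = tli_raw(spectrum)
    so = sto2_raw(spectrum)
    return IndexSet(
        lwr=lw,
        twi_raw=tw,
        tli_raw=tl,
        sto2_raw=so,
        twi=float(scaling._scale(tw, scaling.twi_range)),
        tli=float(scaling._scale(tl, scaling.tli_range)),
        sto2=float(scaling._scale(so, scaling.sto2_range)) if np.isfinite(so) else float("nan"),
    )


def index_image(
    cube: Hypercube,
    index_name: str,
    scaling: IndexScaling = DEFAULT_SCALING,
    scaled: bool = True,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Per-pixel index map of a hypercube; same spatial shape as the cube.

    ``index_name`` is one of ``"LWR"``, ``"TWI"``, ``"TLI"``, ``"STO2"``.
    For TWI/TLI/STO2, ``scaled=True`` returns the [0, 100] display scale.
    LWR has no display scaling and is always returned raw.
    """
    name = index_name.upper()
    if name == "LWR":
        num = band_mean_image(cube, BANDS["lwr_lipid"])
        den = band_mean_image(cube, BANDS["lwr_water"])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)
    if name == "TWI":
        num = band_mean_image(cube, BANDS["twi_num"])
        den = band_mean_image(cube, BANDS["twi_den"])
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(den > 0, num / den, np.nan)
        return scaling._scale(raw, scaling.twi_range) if scaled else raw
    if name == "TLI":
        raw = second_derivative_mean_image(cube, BANDS["tli"], smooth_sigma)
        return scaling._scale(raw, scaling.tli_range) if scaled else raw
    if name == "STO2":
        num = second_derivative_mean_image(cube, BANDS["sto2_num"], smooth_sigma)
        den = second_derivative_mean_image(cube, BANDS["sto2_den"], smooth_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(den != 0, num / den, np.nan)
        return scaling._scale(raw, scaling.sto2_range) if scaled else raw
    raise ValueError(f"unknown index name {index_name!r}; expected one of {INDEX_NAMES}")
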