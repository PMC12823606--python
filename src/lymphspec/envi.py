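"""Minimal ENVI raster I/O for hypercubes.

Cubes are stored in the de facto hyperspectral interchange layout: a
plain-text ``.hdr`` header next to a raw binary payload, band-sequential
(BSQ), 32-bit little-endian floats, with the wavelength list embedded in
the header. Only the subset of the ENVI dialect needed for round-tripping
:class:`~lymphspec.hypercube.Hypercube` objects is implemented.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .hypercube import Hypercube, WavelengthGrid

__all__ = ["read_envi", "write_envi"]

_REQUIRED_KEYS = ("samples", "lines", "bands", "data type", "interleave")

# ENVI data type codes we accept -> numpy dtype
_DTYPES = {4: np.float32, 5: np.float64}


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read a BSQ ENVI raster (``.hdr`` + sibling payload) as a Hypercube."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise ValueError(f"ENVI header missing required field '{key}'")
    samples = int(fields["samples"])  # columns
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if fields["interleave"].lower() != "bsq":
        raise ValueError(f"unsupported interleave '{fields['interleave']}' (only bsq)")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(w) for w in wl_text.split(",") if w.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    payload_path = header_path.with_suffix(".raw")
    if not payload_path.exists():
        raise FileNotFoundError(f"payload {payload_path} not found")
    dtype = np.dtype(_DTYPES[dtype_code]).newbyteorder("<")
    raw = np.fromfile(payload_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"payload holds {raw.size} values but header declares {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )
    # BSQ: band-major on disk -> (rows, cols, bands) in memory
    data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    meta = {
        k: v for k, v in fields.items() if k not in _REQUIRED_KEYS + ("wavelength",)
    }
    return Hypercube(data=data, grid=WavelengthGrid(wavelengths), meta=meta)


def write_envi(cube: Hypercube, header_path: str | Path) -> Path:
    """Write a Hypercube as a BSQ float32 ENVI raster; returns the header path."""
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    payload_path = header_path.with_suffix(".raw")
    rows, cols, bands = cube.data.shape
    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths)
    lines = [
        "ENVI",
        "description = {lymphspec hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        f"wavelength units = nm",
        f"wavelength = {{{wl}}}",
    ]
    for key, val in cube.meta.items():
        if isinstance(val, (str, int, float)):
            lines.append(f"{key} = {val}")
    header_path.write_text("\n".join(lines) + "\n")
    cube.data.astype("<f4").transpose(2, 0, 1).tofile(payload_path)
    return header_path
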