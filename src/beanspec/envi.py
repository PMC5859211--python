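"""Minimal ENVI header/raw reader and writer.

Supports the dialect produced by line-scan SWIR cameras: an ASCII ``.hdr``
with ``samples``, ``lines``, ``bands``, ``data type``, ``interleave`` and a
``wavelength = { ... }`` block, next to a headerless little-endian raw
file in BIL, BSQ or BIP band order. Counts are stored as 16-bit unsigned
integers, calibrated data as 32-bit float.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .hypercube import Hypercube

__all__ = [
    "read_envi",
    "write_envi",
    "EnviError",
    "EnviHeaderError",
    "EnviDimensionError",
    "EnviInterleaveError",
]


class EnviError(Exception):
    """Base class for ENVI I/O failures."""


class EnviHeaderError(EnviError):
    """Header missing or malformed (e.g. no wavelength block)."""


class EnviDimensionError(EnviError):
    """Raw file size inconsistent with header dimensions."""


class EnviInterleaveError(EnviError):
    """Interleave is not one of BIL, BSQ, BIP."""


# ENVI data type codes -> numpy dtypes (little-endian)
_DTYPES = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2", 13: "<u4"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bil", "bsq", "bip")


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviHeaderError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    # brace blocks may span lines; collapse them first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | os.PathLike) -> Hypercube:
    """Load a hypercube from an ENVI header + raw pair.

    The raw file is the header path with its ``.hdr`` suffix removed (or
    ``.raw`` appended if the header has no suffix). Raises distinct
    errors for a missing wavelength block, a raw/header size mismatch
    and an unknown interleave.
    """
    header_path = os.fspath(header_path)
    with open(header_path, "r") as fh:
        fields = _parse_header(fh.read())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise EnviHeaderError(f"header missing required field {exc}") from exc
    interleave = fields.get("interleave", "").lower()
    if interleave not in _INTERLEAVES:
        raise EnviInterleaveError(f"unknown interleave {interleave!r}")
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _DTYPES:
        raise EnviHeaderError(f"unsupported data type code {dtype_code}")
    dtype = np.dtype(_DTYPES[dtype_code])

    if "wavelength" not in fields:
        raise EnviHeaderError("header has no wavelength block")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(v) for v in wl_text.replace(",", " ").split()])
    if wavelengths.size != bands:
        raise EnviHeaderError(
            f"wavelength block has {wavelengths.size} entries for {bands} bands"
        )

    raw_path = header_path[:-4] if header_path.endswith(".hdr") else header_path + ".raw"
    data = np.fromfile(raw_path, dtype=dtype)
    expected = lines * samples * bands
    if data.size != expected:
        raise EnviDimensionError(
            f"raw file holds {data.size} values, header implies {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )

    if interleave == "bsq":  # (bands, lines, samples)
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        cube = data.reshape(lines, samples, bands)

    signal = fields.get("signal", "counts").strip().lower()
    if signal not in ("counts", "reflectance", "absorbance"):
        signal = "counts"
    meta = {"interleave": interleave, "source": header_path}
    if "description" in fields:
        meta["description"] = fields["description"].strip("{} ")
    return Hypercube(np.ascontiguousarray(cube), wavelengths, signal=signal, metadata=meta)


def write_envi(
    cube: Hypercube,
    header_path: str | os.PathLike,
    interleave: str = "bil",
    dtype: str | np.dtype | None = None,
) -> str:
    """Write a hypercube as an ENVI header + raw pair; returns the raw path.

    ``dtype`` defaults to uint16 for counts cubes and float32 otherwise;
    counts are rounded and clipped into the uint16 range when quantized.
    """
    header_path = os.fspath(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviInterleaveError(f"unknown interleave {interleave!r}")
    if dtype is None:
        dtype = np.uint16 if cube.signal == "counts" else np.float32
    dtype = np.dtype(dtype).newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        raise EnviHeaderError(f"unsupported dtype {dtype}")

    data = np.asarray(cube.cube)
    if dtype.kind == "u":
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max)
    data = data.astype(dtype)

    lines, samples, bands = data.shape
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        flat = data

    raw_path = header_path[:-4] if header_path.endswith(".hdr") else header_path + ".raw"
    flat.tofile(raw_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{{cube.metadata.get('description', 'beanspec scene')}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"signal = {cube.signal}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    return raw_path
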