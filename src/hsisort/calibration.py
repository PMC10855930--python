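"""ENVI cube I/O and flat-field reflectance calibration.

Raw sensor counts are converted to relative reflectance with the standard
dark/white flat-field normalisation

    Rc = (R - D) / (W - D)

applied per pixel and per band, where D is the dark frame (shutter closed,
0% reflectance) and W the white-reference frame. Cubes travel on disk in
the ENVI format: a plain-text header describing dimensions, interleave and
wavelengths next to a raw binary payload.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .containers import HyperCube, ReferenceFrames

log = logging.getLogger(__name__)

#: ENVI numeric data-type codes supported by this reader.
ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5,
              np.dtype(np.uint16): 12}

_INTERLEAVES = ("bsq", "bil", "bip")


class EnviFormatError(ValueError):
    """Malformed or internally inconsistent ENVI header/payload."""


class UnsupportedEnviError(EnviFormatError):
    """Header is valid ENVI but uses a dialect outside the supported set."""


@dataclass
class EnviHeader:
    samples: int  # columns
    lines: int    # rows
    bands: int
    interleave: str
    data_type: int
    byte_order: int  # 0 little, 1 big
    wavelengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if min(self.samples, self.lines, self.bands) <= 0:
            raise EnviFormatError("dimensions must be positive")
        if self.interleave not in _INTERLEAVES:
            raise UnsupportedEnviError(f"interleave {self.interleave!r}")
        if self.data_type not in ENVI_DTYPES:
            raise UnsupportedEnviError(f"ENVI data type code {self.data_type}")
        if self.byte_order not in (0, 1):
            raise EnviFormatError(f"byte order {self.byte_order}")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.size != self.bands:
                raise EnviFormatError(
                    f"header declares {self.bands} bands but lists "
                    f"{self.wavelengths.size} wavelengths"
                )


def _parse_header_text(text: str) -> dict:
    """Parse ENVI 'key = value' lines, including {...} multi-line blocks."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    fields: dict = {}
    body = text.lstrip()[4:]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise EnviFormatError(f"unterminated block for key {key!r}")
            fields[key] = rest[1:close].strip()
            pos = offset + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            fields[key] = rest[:nl].strip()
            pos = offset + nl + 1
    return fields


def read_envi_header(header_path) -> EnviHeader:
    text = Path(header_path).read_text()
    fields = _parse_header_text(text)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields.get("interleave", "bsq").lower()
        data_type = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    byte_order = int(fields.get("byte order", 0))
    wl = None
    if "wavelength" in fields:
        wl = np.array([float(tok) for tok in fields["wavelength"].split(",") if tok.strip()])
    return EnviHeader(samples=samples, lines=lines, bands=bands,
                      interleave=interleave, data_type=data_type,
                      byte_order=byte_order, wavelengths=wl)


def read_envi(header_path, data_path=None) -> HyperCube:
    """Read an ENVI cube into rows x cols x bands order, any interleave.

    ``data_path`` defaults to the header path with its suffix dropped (or
    replaced by ``.img`` if that file exists).
    """
    header_path = Path(header_path)
    if data_path is None:
        stem = header_path.with_suffix("")
        data_path = stem if stem.exists() else stem.with_suffix(".img")
    hdr = read_envi_header(header_path)
    dtype = np.dtype(ENVI_DTYPES[hdr.data_type])
    dtype = dtype.newbyteorder("<" if hdr.byte_order == 0 else ">")
    payload = np.fromfile(data_path, dtype=dtype)
    expected = hdr.samples * hdr.lines * hdr.bands
    if payload.size != expected:
        raise EnviFormatError(
            f"payload holds {payload.size} values, header declares {expected}"
        )
    if hdr.interleave == "bsq":      # (bands, lines, samples)
        cube = payload.reshape(hdr.bands, hdr.lines, hdr.samples).transpose(1, 2, 0)
    elif hdr.interleave == "bil":    # (lines, bands, samples)
        cube = payload.reshape(hdr.lines, hdr.bands, hdr.samples).transpose(0, 2, 1)
    else:                            # bip: (lines, samples, bands)
        cube = payload.reshape(hdr.lines, hdr.samples, hdr.bands)
    wl = hdr.wavelengths
    if wl is None:
        wl = np.arange(hdr.bands, dtype=float)
    return HyperCube(data=cube.astype(float), wavelengths=wl, kind="raw")


def write_envi(cube: HyperCube, header_path, data_path=None, *,
               interleave: str = "bsq", dtype=np.float32) -> None:
    """Write a cube as an ENVI header + raw little-endian binary payload."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise UnsupportedEnviError(f"interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in ENVI_CODES:
        raise UnsupportedEnviError(f"dtype {dtype}")
    rows, cols, bands = cube.data.shape
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data
    arr.astype(dtype.newbyteorder("<")).tofile(data_path)
    wl_text = ", ".join(f"{w:.1f}" for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl_text} }}\n"
    )


def _broadcast_reference(ref: np.ndarray, shape: tuple) -> np.ndarray:
    """Accept full-frame or single-line references; broadcast over rows."""
    if ref.shape == shape:
        return ref
    if ref.shape[0] == 1 and ref.shape[1:] == shape[1:]:
        return np.broadcast_to(ref, shape)
    raise ValueError(f"reference shape {ref.shape} incompatible with cube {shape}")


def calibrate(raw: HyperCube, refs: ReferenceFrames, *,
              clip: bool = False, eps: float = 1e-12) -> HyperCube:
    """Flat-field reflectance calibration Rc = (R - D)/(W - D).

    Pixels/bands where the white-dark span is <= ``eps`` (dead reference
    pixels) are set to 0 and counted in ``meta['bad_reference_pixels']``;
    negative reflectance (R < D) is kept unless ``clip`` is set, in which
    case the output is clipped to [0, 1].
    """
    dark = _broadcast_reference(refs.dark.data, raw.data.shape)
    white = _broadcast_reference(refs.white.data, raw.data.shape)
    span = white - dark
    bad = span <= eps
    n_bad = int(bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - dark) / np.where(bad, 1.0, span)
    refl = np.where(bad, 0.0, refl)
    if n_bad:
        log.warning("calibration: %d pixel/band cells had white-dark span <= %g; "
                    "set to 0", n_bad, eps)
    n_negative = int((refl < 0).sum())
    if clip:
        refl = np.clip(refl, 0.0, 1.0)
    return HyperCube(
        data=refl,
        wavelengths=raw.wavelengths,
        kind="reflectance",
        meta={"bad_reference_pixels": n_bad, "negative_reflectance_pixels": n_negative},
    )
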