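"""Hyperspectral cube container, black/white reflectance correction, ENVI I/O.

A cube is stored in memory as ``(lines, samples, bands)`` float64 with a
wavelength axis.  On disk it is an ENVI-style pair: a text ``.hdr`` with the
core key set (samples/lines/bands/data type/interleave/byte order/wavelength)
and a raw binary ``.img`` in BSQ, BIL or BIP order.

Reflectance correction follows the usual dark-current / white-reference
normalisation: ``R = (I0 - Ib) / (Iw - Ib)`` per pixel per band, where ``Iw``
is the white (PTFE plate) frame and ``Ib`` the lens-capped dark frame.  R is
deliberately not clipped to [0, 1] — specular glare legitimately exceeds the
white reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .synthetic import AcquisitionMode

INTERLEAVES = ("bsq", "bil", "bip")

# numpy dtype <-> ENVI "data type" codes (core subset)
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """(lines, samples, bands) reflectance/intensity array with wavelengths."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    interleave: str = "bsq"
    mode: Optional[AcquisitionMode] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all cube dimensions must be >= 1")
        if self.wavelengths_nm.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {self.wavelengths_nm.size} != "
                f"bands {self.data.shape[2]}")
        if self.interleave not in INTERLEAVES:
            raise ValueError(f"interleave must be one of {INTERLEAVES}")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CorrectionFrames:
    """Raw frame plus its white-reference and dark calibration frames."""

    I0: Hypercube
    Iw: Hypercube
    Ib: Hypercube

    def __post_init__(self):
        shape = self.I0.data.shape
        for name, cube in (("Iw", self.Iw), ("Ib", self.Ib)):
            if cube.data.shape != shape:
                raise ValueError(
                    f"{name} shape {cube.data.shape} != I0 shape {shape}")
            if not np.array_equal(cube.wavelengths_nm, self.I0.wavelengths_nm):
                raise ValueError(f"{name} wavelength axis differs from I0")


def black_white_correct(frames: CorrectionFrames) -> Hypercube:
    """Per-pixel reflectance: ``R = (I0 - Ib) / (Iw - Ib)``.

    A pixel/band where the white and dark frames coincide has no dynamic
    range and indicates a corrupted calibration; it raises with the offending
    pixel named rather than propagating NaN/inf.
    """
    denom = frames.Iw.data - frames.Ib.data
    bad = denom == 0.0
    if bad.any():
        line, sample, band = (int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            "white and dark frames are equal at pixel "
            f"(line={line}, sample={sample}, band={band}); cannot correct")
    r = (frames.I0.data - frames.Ib.data) / denom
    return Hypercube(r, frames.I0.wavelengths_nm.copy(),
                     interleave=frames.I0.interleave, mode=frames.I0.mode)


# ---------------------------------------------------------------------------
# ENVI-dialect reader/writer (text header + raw binary)
# ---------------------------------------------------------------------------

def _to_disk_order(data: np.ndarray, interleave: str) -> np.ndarray:
    # memory order is (lines, samples, bands)
    if interleave == "bsq":      # (bands, lines, samples)
        return np.ascontiguousarray(np.transpose(data, (2, 0, 1)))
    if interleave == "bil":      # (lines, bands, samples)
        return np.ascontiguousarray(np.transpose(data, (0, 2, 1)))
    return np.ascontiguousarray(data)  # bip: (lines, samples, bands)


def _from_disk_order(flat: np.ndarray, lines: int, samples: int, bands: int,
                     interleave: str) -> np.ndarray:
    if interleave == "bsq":
        return np.transpose(flat.reshape(bands, lines, samples), (1, 2, 0))
    if interleave == "bil":
        return np.transpose(flat.reshape(lines, bands, samples), (0, 2, 1))
    return flat.reshape(lines, samples, bands)


def _paths(path) -> tuple[Path, Path]:
    """Resolve (header, data) paths from a stem, .hdr or .img path."""
    p = Path(path)
    if p.suffix == ".hdr":
        stem = p.with_suffix("")
    elif p.suffix == ".img":
        stem = p.with_suffix("")
    else:
        stem = p
    return stem.with_suffix(".hdr"), stem.with_suffix(".img")


def write_envi(cube: Hypercube, path) -> None:
    """Write ``<stem>.hdr`` + ``<stem>.img`` (float64, little endian)."""
    hdr_path, img_path = _paths(path)
    data = _to_disk_order(cube.data, cube.interleave).astype("<f8")
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype('float64')]}",
        f"interleave = {cube.interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = { " + wl + " }",
    ]
    if cube.mode is not None:
        lines.append(f"acquisition kind = {cube.mode.kind}")
        if cube.mode.angle_deg is not None:
            lines.append(f"incident angle = {cube.mode.angle_deg}")
    hdr_path.write_text("\n".join(lines) + "\n")
    data.tofile(img_path)


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is not None:                   # inside a { } block
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                key, buf = None, []
            continue
        if "=" not in line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        if "{" in v and "}" not in v:
            key, buf = k.lower(), [v]
        else:
            fields[k.lower()] = v
    return fields


def read_envi(path) -> Hypercube:
    """Read an ENVI header/binary pair written by :func:`write_envi`.

    Raises on missing core keys, unsupported data types, or a wavelength
    list whose length disagrees with the band count.
    """
    hdr_path, img_path = _paths(path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    if not img_path.exists():
        raise FileNotFoundError(f"missing ENVI binary {img_path}")
    fields = _parse_header(hdr_path.read_text())
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required field {req!r}")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    interleave = fields["interleave"].lower()
    if interleave not in INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(_ENVI_DTYPES[code]).newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" in fields:
        inner = fields["wavelength"].split("{", 1)[1].rsplit("}", 1)[0]
        wavelengths = np.array(
            [float(tok) for tok in inner.replace(",", " ").split()])
        if wavelengths.size != bands:
            raise ValueError(
                f"header has {wavelengths.size} wavelengths for {bands} bands")
    else:
        wavelengths = np.arange(bands, dtype=float)

    offset = int(fields.get("header offset", "0"))
    flat = np.fromfile(img_path, dtype=dtype, offset=offset)
    if flat.size != lines * samples * bands:
        raise ValueError(
            f"binary payload has {flat.size} values, header implies "
            f"{lines * samples * bands}")
    data = _from_disk_order(flat.astype(float), lines, samples, bands, interleave)

    mode = None
    if "acquisition kind" in fields:
        angle = fields.get("incident angle")
        mode = AcquisitionMode(fields["acquisition kind"],
                               int(angle) if angle is not None else None)
    return Hypercube(data, wavelengths, interleave=interleave, mode=mode)
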