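"""Hyperspectral cube I/O and reflectance calibration.

Cubes are stored in canonical ``rows x cols x bands`` order in memory and
exchanged on disk either as an ENVI header/binary pair (the instrument-adjacent
standard: a plain-text ``.hdr`` plus a raw interleaved binary) or as a NumPy
``.npz`` container (convenient for fixtures and caching).

Reflectance calibration follows the standard two-point scheme

    R = (I_raw - I_dark) / (I_white - I_dark)

using white-reference and dark-current cubes acquired alongside the sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Hypercube",
    "default_wavelength_grid",
    "read_cube",
    "write_cube",
    "read_npz",
    "write_npz",
    "calibrate_reflectance",
    "CalibrationResult",
]

#: ENVI numeric data-type codes -> numpy dtypes (subset used in practice)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


def default_wavelength_grid(n_bands: int = 428, lo: float = 382.0, hi: float = 1004.0) -> np.ndarray:
    """Evenly spaced wavelength grid in nm; the default covers 382-1004 nm in
    428 consecutive bands, matching the VIS-NIR imager configuration."""
    return np.linspace(lo, hi, n_bands)


@dataclass
class Hypercube:
    """A reflectance cube bound to its wavelength grid.

    Parameters
    ----------
    data
        ``rows x cols x bands`` array of reflectance (dimensionless,
        nominally in [0, 1] after calibration).
    wavelengths
        Strictly increasing band centres in nm; length must equal the
        number of bands.
    """

    data: np.ndarray
    wavelengths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data contains non-finite values")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# ENVI header/binary pair
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([a-zA-Z][a-zA-Z0-9 _]*?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_cube(header_path: str | Path, data_path: str | Path | None = None) -> Hypercube:
    """Read an ENVI header/binary pair into canonical row-major order.

    The header must declare ``samples``, ``lines``, ``bands``, ``data type``,
    ``interleave`` (bil/bip/bsq) and a ``wavelength = {...}`` list whose
    length equals the band count. ``data_path`` defaults to the header path
    with its suffix replaced by ``.raw``.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    fields = _parse_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field '{key}'")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave '{interleave}' (expected one of {_INTERLEAVES})")

    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    wl_text = fields["wavelength"].strip("{} \n")
    wavelengths = np.array([float(v) for v in wl_text.replace("\n", " ").split(",") if v.strip()])
    if wavelengths.size != bands:
        raise ValueError(f"header lists {wavelengths.size} wavelengths but declares {bands} bands")

    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))
    flat = np.fromfile(Path(data_path), dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if flat.size != expected:
        raise ValueError(f"binary holds {flat.size} values, expected {expected} for {rows}x{cols}x{bands}")

    if interleave == "bsq":  # (bands, rows, cols)
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":  # (rows, bands, cols)
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip: (rows, cols, bands)
        data = flat.reshape(rows, cols, bands)
    return Hypercube(np.ascontiguousarray(data), wavelengths)


def write_cube(cube: Hypercube, header_path: str | Path, interleave: str = "bsq") -> tuple[Path, Path]:
    """Write ``cube`` as an ENVI pair; returns (header path, binary path)."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave '{interleave}'")
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".raw")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code; cast to float32/float64 first")

    if interleave == "bsq":
        arranged = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arranged = cube.data.transpose(0, 2, 1)
    else:
        arranged = cube.data

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {starchspec export}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(arranged).tofile(data_path)
    return header_path, data_path


# ---------------------------------------------------------------------------
# NPZ container
# ---------------------------------------------------------------------------

def write_npz(cube: Hypercube, path: str | Path) -> Path:
    path = Path(path)
    np.savez(path, data=cube.data, wavelengths=cube.wavelengths)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_npz(path: str | Path) -> Hypercube:
    with np.load(Path(path)) as npz:
        if "data" not in npz or "wavelengths" not in npz:
            raise ValueError("NPZ cube container must hold 'data' and 'wavelengths'")
        return Hypercube(npz["data"], npz["wavelengths"])


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Calibrated cube plus the mask of elements where white == dark
    (dead reference pixels), which were zeroed rather than divided."""

    cube: Hypercube
    invalid_mask: np.ndarray

    @property
    def n_invalid(self) -> int:
        return int(self.invalid_mask.sum())


def calibrate_reflectance(raw: Hypercube, white: Hypercube, dark: Hypercube) -> CalibrationResult:
    """Two-point reflectance correction R = (raw - dark) / (white - dark).

    Elements where the white and dark references coincide carry no radiometric
    information; they are set to 0 and reported through ``invalid_mask``
    instead of raising, since real reference cubes have dead pixels.
    """
    if raw.data.shape != white.data.shape or raw.data.shape != dark.data.shape:
        raise ValueError(
            f"shape mismatch: raw {raw.data.shape}, white {white.data.shape}, dark {dark.data.shape}"
        )
    denom = white.data.astype(np.float64) - dark.data.astype(np.float64)
    invalid = denom == 0
    numer = raw.data.astype(np.float64) - dark.data.astype(np.float64)
    out = np.zeros_like(numer)
    np.divide(numer, denom, out=out, where=~invalid)
    return CalibrationResult(Hypercube(out, raw.wavelengths), invalid)
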