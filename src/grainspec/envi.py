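"""Minimal ENVI image I/O.

Reads and writes the classic ENVI pair: a plain-text ``.hdr`` describing the
cube (samples/lines/bands, data type, interleave, wavelength list) next to a
flat binary file. Only the fields this pipeline needs are supported: BSQ, BIL
and BIP interleaves, little/big endian, and the numeric data types below.

Cubes are exchanged with the rest of the package as ``(rows, cols, bands)``
arrays regardless of the on-disk interleave.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

# ENVI "data type" codes -> numpy dtypes
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a {lowercased key: str or list} dict."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    # fold multi-line { ... } blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            items = val.strip("{}").split(",")
            fields[key] = [s.strip() for s in items if s.strip()]
        else:
            fields[key] = val
    return fields


def read_envi(header_path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI cube.

    Parameters
    ----------
    header_path
        Path to the ``.hdr`` file; the binary is found by dropping the
        extension (or from the ``.dat``/``.img`` sibling).

    Returns
    -------
    cube : ndarray, shape (rows, cols, bands)
    wavelengths : ndarray or None
        Band centers in nm if the header carries a wavelength block.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()

    stem = header_path.with_suffix("")
    for candidate in (stem, stem.with_suffix(".dat"), stem.with_suffix(".img")):
        if candidate.exists() and candidate != header_path:
            data_path = candidate
            break
    else:
        raise FileNotFoundError(f"no binary next to {header_path}")

    raw = np.fromfile(data_path, dtype=dtype)
    offset = int(fields.get("header offset", 0)) // dtype.itemsize
    raw = raw[offset:]
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array([float(w) for w in fields["wavelength"]])
    return np.ascontiguousarray(cube.astype(dtype.newbyteorder("="))), wavelengths


def write_envi(
    header_path: str | Path,
    cube: np.ndarray,
    wavelengths: np.ndarray | None = None,
    interleave: str = "bsq",
) -> Path:
    """Write a (rows, cols, bands) cube as an ENVI ``.hdr`` + ``.dat`` pair.

    Returns the path of the binary file written.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be 3-D (rows, cols, bands)")
    rows, cols, bands = cube.shape
    if cube.dtype not in _CODES:
        cube = cube.astype(np.float64)
    interleave = interleave.lower()
    if interleave == "bsq":
        ordered = cube.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = cube.transpose(0, 2, 1)
    elif interleave == "bip":
        ordered = cube
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[cube.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:g}" for w in np.asarray(wavelengths))
        lines.append("wavelength units = Nanometers")
        lines.append("wavelength = { " + wl + " }")
    header_path.write_text("\n".join(lines) + "\n")

    data_path = header_path.with_suffix(".dat")
    np.ascontiguousarray(ordered).tofile(data_path)
    return data_path
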