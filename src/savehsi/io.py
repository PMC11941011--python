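"""File I/O: images (PNG/TIFF, sRGB decoded once at ingest), spectral cubes
(ENVI BSQ with wavelengths in the header, or NPZ), spectra CSV tables and
calibration bundles (JSON).

Images are converted to linear light exactly once, at read time; writers
encode back to sRGB unless asked for raw output.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import CalibrationResults, SpectralCube
from .colorimetry import ContractError, SpectralGrid, linear_to_srgb, srgb_to_linear

__all__ = [
    "read_image",
    "write_image",
    "read_cube",
    "write_cube",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_bundle",
    "write_bundle",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed file content; message names the file and offending field."""


def read_image(path: str, linearize: bool = True) -> np.ndarray:
    """Read an 8/16-bit image; returns float in [0, 1], sRGB-decoded to
    linear light unless ``linearize=False``."""
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = 1.0
    v = arr.astype(float) / scale
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        v = v[:, :, :3]
    if linearize:
        v = srgb_to_linear(v * 255.0)
    return v


def write_image(path: str, image: np.ndarray, bit_depth: int = 8, encode_srgb: bool = True) -> None:
    """Write a float image in [0, 1] (linear if ``encode_srgb``) or an
    integer array verbatim."""
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        iio.imwrite(path, img)
        return
    if encode_srgb:
        v = linear_to_srgb(img) / 255.0
    else:
        v = np.clip(img, 0.0, 1.0)
    if bit_depth == 8:
        iio.imwrite(path, np.round(v * 255.0).astype(np.uint8))
    elif bit_depth == 16:
        # 16-bit colour output goes through tifffile (PNG back ends are 8-bit)
        import tifffile

        if not path.endswith((".tif", ".tiff")):
            raise ContractError("16-bit images must be written as TIFF")
        tifffile.imwrite(path, np.round(v * 65535.0).astype(np.uint16))
    else:
        raise ContractError("bit_depth must be 8 or 16")


# -- spectral cubes ---------------------------------------------------------


def write_cube(path: str, cube: SpectralCube, fmt: str | None = None) -> None:
    """Write a cube as ENVI BSQ (.hdr + raw float32) or NPZ archive.

    Format inferred from the extension when ``fmt`` is None ('.npz' -> npz,
    anything else -> ENVI).
    """
    fmt = fmt or ("npz" if path.endswith(".npz") else "envi")
    if fmt == "npz":
        np.savez_compressed(
            path,
            values=cube.values.astype(np.float32),
            wavelengths=cube.grid.wavelengths,
            grid=np.array([cube.grid.start_nm, cube.grid.stop_nm, cube.grid.step_nm]),
        )
        return
    base = path[:-4] if path.endswith(".hdr") else path
    h, w, b = cube.values.shape
    wl = ", ".join(f"{x:.1f}" for x in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {savehsi reflectance cube}\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(base + ".hdr", "w") as fh:
        fh.write(header)
    # BSQ: band-sequential
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0).astype("<f4")).tofile(base + ".img")


def _parse_envi_header(path: str) -> dict:
    fields: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    if not text.startswith("ENVI"):
        raise ParseError(f"{path}: missing ENVI magic line")
    # join brace-delimited multi-line values
    body = text[4:]
    key = None
    buf = ""
    for raw in body.splitlines():
        line = raw.strip()
        if not line:
            continue
        if key is None:
            if "=" not in line:
                raise ParseError(f"{path}: malformed header line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            buf = val
        else:
            buf += " " + line
        if buf.count("{") > buf.count("}"):
            continue
        fields[key.lower()] = buf.strip()
        key, buf = None, ""
    return fields


def read_cube(path: str) -> SpectralCube:
    """Read an ENVI BSQ (.hdr/.img) or NPZ cube."""
    if path.endswith(".npz"):
        with np.load(path) as z:
            start, stop, step = z["grid"]
            return SpectralCube(SpectralGrid(start, stop, step), z["values"].astype(float))
    base = path[:-4] if path.endswith((".hdr", ".img")) else path
    fields = _parse_envi_header(base + ".hdr")
    try:
        h, w, b = (int(fields[k]) for k in ("lines", "samples", "bands"))
        wl_text = fields["wavelength"].strip("{} ")
        wl = np.array([float(x) for x in wl_text.split(",")])
    except (KeyError, ValueError) as e:
        raise ParseError(f"{base}.hdr: bad or missing field ({e})") from e
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ParseError(f"{base}.hdr: only BSQ interleave is supported")
    data = np.fromfile(base + ".img", dtype="<f4")
    if data.size != h * w * b:
        raise ParseError(f"{base}.img: size {data.size} does not match {h}x{w}x{b}")
    values = np.moveaxis(data.reshape(b, h, w), 0, 2).astype(float)
    step = float(np.round(np.diff(wl).mean(), 9)) if b > 1 else 1.0
    return SpectralCube(SpectralGrid(float(wl[0]), float(wl[-1]), step), values)


# -- spectra CSV ------------------------------------------------------------


def write_spectra_csv(path: str, grid: SpectralGrid, spectra: np.ndarray, names: list[str]) -> None:
    """CSV dialect: header row, wavelength column, one column per sample."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    df = pd.DataFrame({"wavelength_nm": grid.wavelengths})
    for name, col in zip(names, X):
        df[name] = col
    df.to_csv(path, index=False, float_format="%.6g")


def read_spectra_csv(path: str) -> tuple[SpectralGrid, np.ndarray, list[str]]:
    """Read the spectra CSV dialect -> (grid, (n_samples, n_bands), names)."""
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"{path}: cannot parse CSV ({e})") from e
    if "wavelength_nm" not in df.columns:
        raise ParseError(f"{path}: missing 'wavelength_nm' column")
    if df.isnull().any().any():
        row = int(df.isnull().any(axis=1).idxmax())
        raise ParseError(f"{path}: missing value at data row {row}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    steps = np.diff(wl)
    if wl.size < 2 or np.any(steps <= 0) or np.ptp(steps) > 1e-6:
        raise ParseError(f"{path}: wavelength column must be uniform and increasing")
    grid = SpectralGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    names = [c for c in df.columns if c != "wavelength_nm"]
    return grid, df[names].to_numpy(dtype=float).T, names


# -- calibration bundles ----------------------------------------------------


def write_bundle(path: str, results: CalibrationResults) -> None:
    results.save(path)


def read_bundle(path: str) -> CalibrationResults:
    try:
        return CalibrationResults.load(path)
    except (json.JSONDecodeError, KeyError) as e:
        raise ParseError(f"{path}: not a valid calibration bundle ({e})") from e


def sha256_of(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
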