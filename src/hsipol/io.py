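"""File formats: ENVI cubes, ROI sidecars, spectra tables.

ENVI cubes are written as an ASCII ``.hdr`` (samples/lines/bands plus the
wavelength list) next to a band-sequential (BSQ) raw binary of
little-endian 32-bit floats.  A single-file compressed ``.npz`` container
with an embedded wavelength vector is also provided for fixtures.

ROI sidecars are CSV with columns ``x_px, y_px, diameter_px, label,
donor`` (0-based pixel coordinates of the disk center).
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .core import CellROI, HyperspectralCube, SpectraTable

_ENVI_DTYPE = {4: np.dtype("<f4")}  # ENVI code 4 = 32-bit float


def write_envi(cube: HyperspectralCube, path_base: str) -> tuple[str, str]:
    """Write ``<path_base>.hdr`` + ``<path_base>.raw`` (BSQ float32 LE)."""
    hdr_path, raw_path = path_base + ".hdr", path_base + ".raw"
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {hsipol synthetic hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    if cube.pixel_pitch_um is not None:
        lines.append(f"pixel size = {{{cube.pixel_pitch_um:.6f}, {cube.pixel_pitch_um:.6f}}}")
    with open(hdr_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype="<f4").tofile(raw_path)
    return hdr_path, raw_path


def _parse_envi_header(text: str) -> dict:
    # collapse {...} blocks onto single lines before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(hdr_path: str) -> HyperspectralCube:
    """Read an ENVI cube written by :func:`write_envi` (BSQ, float32 LE)."""
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype_code = int(fields.get("data type", "4"))
    if dtype_code not in _ENVI_DTYPE:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only band-sequential (BSQ) interleave is supported")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    raw_path = os.path.splitext(hdr_path)[0] + ".raw"
    data = np.fromfile(raw_path, dtype=_ENVI_DTYPE[dtype_code])
    if data.size != rows * cols * bands:
        raise ValueError("raw file size does not match the header dimensions")
    cube = np.moveaxis(data.reshape(bands, rows, cols), 0, 2)
    pitch = None
    if "pixel size" in fields:
        pitch = float(fields["pixel size"].strip("{} ").split(",")[0])
    return HyperspectralCube(cube, wavelengths, pixel_pitch_um=pitch)


def write_cube_npz(cube: HyperspectralCube, path: str) -> None:
    """Single-file compressed cube container with embedded wavelengths."""
    pitch = np.nan if cube.pixel_pitch_um is None else cube.pixel_pitch_um
    np.savez_compressed(path, data=cube.data, wavelengths=cube.wavelengths,
                        pixel_pitch_um=pitch)


def read_cube_npz(path: str) -> HyperspectralCube:
    with np.load(path) as z:
        pitch = float(z["pixel_pitch_um"])
        return HyperspectralCube(z["data"], z["wavelengths"],
                                 pixel_pitch_um=None if np.isnan(pitch) else pitch)


def write_rois_csv(rois: list[CellROI], path: str) -> None:
    df = pd.DataFrame({
        "x_px": [r.center_x for r in rois],
        "y_px": [r.center_y for r in rois],
        "diameter_px": [r.diameter_px for r in rois],
        "label": [r.label if r.label is not None else "" for r in rois],
        "donor": [r.donor if r.donor is not None else "" for r in rois],
    })
    df.to_csv(path, index=False)


def read_rois_csv(path: str) -> list[CellROI]:
    df = pd.read_csv(path, keep_default_na=False)
    rois = []
    for _, row in df.iterrows():
        rois.append(CellROI(
            center_x=float(row["x_px"]), center_y=float(row["y_px"]),
            diameter_px=int(row["diameter_px"]),
            label=str(row["label"]) or None,
            donor=str(row["donor"]) or None,
        ))
    return rois


def write_spectra_csv(table: SpectraTable, path: str) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_spectra_csv(path: str) -> SpectraTable:
    return SpectraTable.from_dataframe(pd.read_csv(path))
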