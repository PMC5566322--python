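"""Shared data containers for the hyperspectral polarization pipeline.

Conventions used throughout the package:

* wavelengths are in nanometres, stored as strictly increasing 1-D arrays;
* reflectance is dimensionless; it may become negative after background
  subtraction;
* image coordinates are 0-based with ``x`` = column and ``y`` = row, using
  the pixel-center convention (the center of pixel ``(0, 0)`` is at
  coordinate ``(0.0, 0.0)``);
* class labels are the strings ``"M1"`` and ``"M2"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: The two macrophage polarization states the classifier distinguishes.
CLASS_LABELS = ("M1", "M2")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on an explicit wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        vals = _as_float_array(self.values, "values")
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class CellROI:
    """Circular sampling region centred on one cell.

    ``center_x``/``center_y`` are 0-based pixel coordinates (x = column,
    y = row, pixel-center convention); ``diameter_px`` is the disk diameter
    in pixels.  ``label`` and ``donor`` are optional ground-truth metadata.
    """

    center_x: float
    center_y: float
    diameter_px: int
    label: str | None = None
    donor: str | None = None

    def __post_init__(self):
        if int(self.diameter_px) != self.diameter_px or self.diameter_px < 1:
            raise ValueError("diameter_px must be an integer >= 1")
        object.__setattr__(self, "diameter_px", int(self.diameter_px))

    @property
    def radius(self) -> float:
        return self.diameter_px / 2.0


@dataclass(frozen=True)
class HyperspectralCube:
    """A 3-D reflectance array (rows x cols x bands) with a wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_pitch_um: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        wl = _as_float_array(self.wavelengths, "wavelengths")
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if wl.ndim != 1 or wl.size != data.shape[2]:
            raise ValueError("wavelength axis must match the band dimension")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "wavelengths", wl)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass(frozen=True)
class SceneGeometry:
    """Acquisition geometry of one hyperspectral field of view.

    The study geometry is a 1 x 1 mm^2 field recorded at 512 x 512 pixels
    with ~1.6 nm spectral sampling over 500-1000 nm and 12-pixel cell
    disks (30 cells per class).  :func:`study_geometry` returns exactly
    that; :func:`default_geometry` returns a reduced field (same pixel
    pitch, fewer pixels and cells, coarser spectral step) sized for fast
    test runs.
    """

    field_width_mm: float = 1.0
    n_pixels: int = 512
    wavelength_start: float = 500.0
    wavelength_stop: float = 1000.0
    wavelength_step: float = 1.6
    cell_diameter_px: int = 12
    n_cells_per_class: int = 30

    def __post_init__(self):
        if self.field_width_mm <= 0 or self.n_pixels <= 0:
            raise ValueError("field_width_mm and n_pixels must be positive")
        if not (self.wavelength_start < self.wavelength_stop):
            raise ValueError("wavelength_start must be below wavelength_stop")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be positive")
        if self.cell_diameter_px < 1 or self.n_cells_per_class < 1:
            raise ValueError("cell_diameter_px and n_cells_per_class must be >= 1")
        if self.cell_diameter_px > self.n_pixels:
            raise ValueError("cell disks must fit inside the field")

    @property
    def pixel_pitch_um(self) -> float:
        return self.field_width_mm * 1000.0 / self.n_pixels

    @property
    def wavelengths(self) -> np.ndarray:
        """Native wavelength grid: equidistant samples spanning the full
        range, with a step as close as possible to ``wavelength_step``."""
        span = self.wavelength_stop - self.wavelength_start
        n = int(round(span / self.wavelength_step)) + 1
        return np.linspace(self.wavelength_start, self.wavelength_stop, n)


def study_geometry() -> SceneGeometry:
    """The acquisition geometry of the original study."""
    return SceneGeometry()


def default_geometry() -> SceneGeometry:
    """Reduced geometry for desk-scale runs: 128 px field at the same
    pixel pitch (0.25 mm field), ~8 nm native spectral step, 8 cells per
    class.  The full study geometry remains available via
    :func:`study_geometry`."""
    return SceneGeometry(
        field_width_mm=0.25,
        n_pixels=128,
        wavelength_step=8.0,
        n_cells_per_class=8,
    )


class SpectraTable:
    """Observations x wavelengths reflectance matrix with per-row class
    label (M1/M2) and donor identifier — the unit passed between pipeline
    stages.

    CSV layout (see :func:`hsipol.io.write_spectra_csv`): first two columns
    ``label`` and ``donor``, remaining columns named by wavelength in nm
    with one decimal.
    """

    def __init__(self, wavelengths, intensities, labels, donors):
        wl = _as_float_array(wavelengths, "wavelengths")
        X = _as_float_array(intensities, "intensities")
        labels = np.asarray(labels, dtype=object)
        donors = np.asarray(donors, dtype=object)
        if X.ndim != 2:
            raise ValueError("intensities must be 2-D (observations x wavelengths)")
        if wl.ndim != 1 or wl.size != X.shape[1]:
            raise ValueError("wavelength axis must match the intensity columns")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if labels.shape != (X.shape[0],) or donors.shape != (X.shape[0],):
            raise ValueError("labels and donors must have one entry per row")
        bad = set(labels) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}; expected {CLASS_LABELS}")
        self.wavelengths = wl
        self.intensities = X
        self.labels = labels
        self.donors = donors

    @property
    def n_obs(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def subset(self, mask) -> "SpectraTable":
        mask = np.asarray(mask)
        return SpectraTable(
            self.wavelengths, self.intensities[mask],
            self.labels[mask], self.donors[mask],
        )

    def for_donor(self, donor: str) -> "SpectraTable":
        return self.subset(self.donors == donor)

    def donor_ids(self) -> list[str]:
        """Donor identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.donors:
            seen.setdefault(d, None)
        return list(seen)

    def class_mask(self, cls: str) -> np.ndarray:
        if cls not in CLASS_LABELS:
            raise ValueError(f"unknown class label {cls!r}; expected one of {CLASS_LABELS}")
        return self.labels == cls

    @staticmethod
    def concat(tables: Sequence["SpectraTable"]) -> "SpectraTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        wl = tables[0].wavelengths
        for t in tables[1:]:
            if not np.array_equal(t.wavelengths, wl):
                raise ValueError("tables must share a wavelength grid")
        return SpectraTable(
            wl,
            np.vstack([t.intensities for t in tables]),
            np.concatenate([t.labels for t in tables]),
            np.concatenate([t.donors for t in tables]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"label": self.labels, "donor": self.donors}
        for j, w in enumerate(self.wavelengths):
            cols[f"{w:.1f}"] = self.intensities[:, j]
        return pd.DataFrame(cols)

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "SpectraTable":
        if list(df.columns[:2]) != ["label", "donor"]:
            raise ValueError("first two columns must be 'label' and 'donor'")
        wl = np.array([float(c) for c in df.columns[2:]])
        return SpectraTable(
            wl, df.iloc[:, 2:].to_numpy(dtype=float),
            df["label"].to_numpy(dtype=object),
            df["donor"].astype(str).to_numpy(dtype=object),
        )

    def __repr__(self) -> str:
        return (f"SpectraTable({self.n_obs} obs x {self.n_wavelengths} bands, "
                f"donors={self.donor_ids()})")
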