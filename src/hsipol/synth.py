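"""Synthetic hyperspectral cohorts and rendered scenes.

The original study deposited no data, so every downstream stage is
exercised against a statistical generator that reproduces the structure
its analysis relies on:

* smooth broad-band reflectance spectra (linear baseline plus Gaussian
  features);
* a class effect confined to a few localized features, applied with
  opposite sign to M1 and M2 so the pooled mean is class-independent;
* a log-normal per-cell intensity factor that creates a dominant
  *non-discriminative* variance direction, pushing the class separation
  onto a later principal component;
* per-donor additive offsets on the feature amplitudes, emulating the
  donor-to-donor variability that degrades pooled classification;
* additive per-band Gaussian noise.

The generator is statistical, not physical: no interference, scattering
or refractive-index model, and no confocal z-sectioning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import CLASS_LABELS, CellROI, HyperspectralCube, SceneGeometry, SpectraTable

#: attempts allowed when rejection-sampling cell positions before failing
PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class GaussianFeature:
    """One Gaussian spectral feature: amplitude * exp(-(l-center)^2 / (2 width^2)).

    ``width_nm`` is the Gaussian sigma.
    """

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ValueError("feature width must be > 0")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, dtype=float) - self.center_nm) / self.width_nm
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class SpectralModel:
    """Generative model of per-cell reflectance spectra.

    The mean spectrum of a cell from class ``c`` of donor ``d`` is::

        baseline(l) + sum_k (A_k + delta_{d,k}) g_k(l) + s(c) * effect(l)

    where ``baseline(l) = baseline_offset + baseline_slope * (l - 500)``,
    ``g_k`` are unit-shape Gaussian bumps with nominal amplitudes ``A_k``,
    ``delta_{d,k} ~ N(0, donor_sd^2)`` are donor offsets on those
    amplitudes, and ``s(M1) = +1``, ``s(M2) = -1``.  Each cell's spectrum
    is the class/donor mean scaled by ``exp(N(0, global_scale_sd^2))``
    plus ``N(0, noise_sd^2)`` per band.

    With ``class_effect`` amplitudes all zero the M1 and M2 populations
    are distributionally identical.
    """

    baseline_offset: float = 1.0
    baseline_slope: float = 0.0  # per nm, relative to 500 nm
    bumps: tuple[GaussianFeature, ...] = ()
    class_effect: tuple[GaussianFeature, ...] = ()
    global_scale_sd: float = 0.0
    donor_sd: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "bumps", tuple(self.bumps))
        object.__setattr__(self, "class_effect", tuple(self.class_effect))
        for sd, name in [(self.global_scale_sd, "global_scale_sd"),
                         (self.donor_sd, "donor_sd"),
                         (self.noise_sd, "noise_sd")]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        for f in self.class_effect:
            if not (500.0 <= f.center_nm <= 1000.0):
                raise ValueError("class-effect centers must lie within [500, 1000] nm")

    def scaled_effect(self, factor: float) -> "SpectralModel":
        """Copy of the model with all class-effect amplitudes multiplied by
        ``factor`` (the knob the calibration grid search turns)."""
        eff = tuple(replace(f, amplitude=f.amplitude * factor) for f in self.class_effect)
        return replace(self, class_effect=eff)


def _class_sign(cls: str) -> float:
    if cls == "M1":
        return 1.0
    if cls == "M2":
        return -1.0
    raise ValueError(f"unknown class label {cls!r}; expected one of {CLASS_LABELS}")


def make_class_spectrum(model: SpectralModel, cls: str, wavelengths) -> np.ndarray:
    """Noise-free population mean spectrum of class ``cls``.

    Deterministic: baseline + sum of bumps + sign(cls) * class effect,
    evaluated on ``wavelengths`` (must lie within [400, 1100] nm).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size and (wl.min() < 400.0 or wl.max() > 1100.0):
        raise ValueError("wavelengths must lie within [400, 1100] nm")
    sign = _class_sign(cls)
    out = model.baseline_offset + model.baseline_slope * (wl - 500.0)
    out = np.broadcast_to(out, wl.shape).astype(float).copy()
    for bump in model.bumps:
        out += bump(wl)
    for eff in model.class_effect:
        out += sign * eff(wl)
    if not np.all(np.isfinite(out)):
        raise ValueError("class spectrum is not finite; check model coefficients")
    return out


def _donor_mean_spectra(model: SpectralModel, wavelengths: np.ndarray,
                        amp_offsets: np.ndarray) -> dict[str, np.ndarray]:
    """Class mean spectra of one donor given its sampled amplitude offsets."""
    means = {}
    for cls in CLASS_LABELS:
        mu = make_class_spectrum(model, cls, wavelengths)
        for off, bump in zip(amp_offsets, model.bumps):
            mu = mu + replace(bump, amplitude=off)(wavelengths)
        means[cls] = mu
    return means


def make_cohort(model: SpectralModel, n_donors: int, n_per_class: int,
                wavelengths, seed: int) -> SpectraTable:
    """Sample a cohort of per-cell spectra.

    Returns a table with ``n_donors * 2 * n_per_class`` rows (donors in
    order ``D1, D2, ...``; within each donor all M1 rows then all M2
    rows).  Each row is the donor's class mean scaled by a per-cell
    ``exp(N(0, global_scale_sd^2))`` factor plus independent per-band
    ``N(0, noise_sd^2)`` noise.  The same seed reproduces the table
    bit for bit.
    """
    if n_donors < 1 or n_per_class < 1:
        raise ValueError("n_donors and n_per_class must be >= 1")
    wl = np.asarray(wavelengths, dtype=float)
    rng = np.random.default_rng(seed)
    rows, labels, donors = [], [], []
    for d in range(n_donors):
        donor_id = f"D{d + 1}"
        amp_offsets = rng.normal(0.0, model.donor_sd, size=len(model.bumps))
        means = _donor_mean_spectra(model, wl, amp_offsets)
        for cls in CLASS_LABELS:
            mu = means[cls]
            scales = np.exp(rng.normal(0.0, model.global_scale_sd, size=n_per_class))
            noise = rng.normal(0.0, model.noise_sd, size=(n_per_class, wl.size))
            rows.append(scales[:, None] * mu[None, :] + noise)
            labels.extend([cls] * n_per_class)
            donors.extend([donor_id] * n_per_class)
    return SpectraTable(wl, np.vstack(rows), labels, donors)


def _disk_offsets(diameter_px: int) -> tuple[np.ndarray, np.ndarray]:
    r = diameter_px / 2.0
    rad = int(np.floor(r))
    dy, dx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    inside = dx * dx + dy * dy <= r * r
    return dy[inside], dx[inside]


def place_cells(n_cells: int, geometry: SceneGeometry, seed: int) -> np.ndarray:
    """Rejection-sample integer cell centers.

    Disks lie wholly inside the field and centers are at least
    ``2 * cell_diameter_px`` apart.  Raises ``RuntimeError`` after
    ``PLACEMENT_ATTEMPTS`` failed draws rather than overlapping silently.
    """
    rng = np.random.default_rng(seed)
    r = int(np.floor(geometry.cell_diameter_px / 2.0))
    lo, hi = r, geometry.n_pixels - 1 - r
    if hi < lo:
        raise RuntimeError("cell disks do not fit inside the field")
    min_d2 = (2.0 * geometry.cell_diameter_px) ** 2
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_cells:
        if attempts >= PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells after "
                f"{PLACEMENT_ATTEMPTS} attempts; the field is too crowded")
        attempts += 1
        x = int(rng.integers(lo, hi + 1))
        y = int(rng.integers(lo, hi + 1))
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_d2 for cx, cy in centers):
            centers.append((x, y))
    return np.array(centers, dtype=int)


def render_scene(table: SpectraTable, geometry: SceneGeometry,
                 background_spectrum, seed: int,
                 noise_sd: float = 0.0) -> tuple[HyperspectralCube, list[CellROI]]:
    """Render table rows into a hyperspectral cube with ground-truth ROIs.

    Every pixel of a cell's disk carries that row's spectrum; all other
    pixels carry ``background_spectrum``; optional per-pixel, per-band
    Gaussian noise on top.  The returned ROI list matches the placement
    exactly, so extraction can be verified round-trip.
    """
    bg = np.asarray(background_spectrum, dtype=float)
    if bg.shape != table.wavelengths.shape:
        raise ValueError("background_spectrum must be on the table's wavelength grid")
    n = geometry.n_pixels
    centers = place_cells(table.n_obs, geometry, seed)
    cube = np.broadcast_to(bg, (n, n, bg.size)).astype(float).copy()
    dy, dx = _disk_offsets(geometry.cell_diameter_px)
    rois = []
    for (x, y), spectrum, label, donor in zip(
            centers, table.intensities, table.labels, table.donors):
        cube[y + dy, x + dx, :] = spectrum
        rois.append(CellROI(center_x=float(x), center_y=float(y),
                            diameter_px=geometry.cell_diameter_px,
                            label=label, donor=donor))
    if noise_sd > 0:
        rng = np.random.default_rng(seed + 1)
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)
    return HyperspectralCube(cube, table.wavelengths,
                             pixel_pitch_um=geometry.pixel_pitch_um), rois


def default_background(wavelengths) -> np.ndarray:
    """Dim, slightly sloped background reflectance used for rendered scenes."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.05 + 2e-5 * (wl - 500.0)
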