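"""Scanning-microdiffraction processing.

A tissue section on a solid substrate is rastered with a microbeam on a
square grid; every grid cell yields a 2D detector image that is reduced to
a 1D profile.  This module covers the reduction and mapping steps:

* masking substrate (e.g. mica) Bragg peaks on the detector image,
* circular (azimuthal) averaging with detector geometry,
* merging SAXS and WAXS profiles over an overlap window,
* beam-monitor normalisation,
* the cross-β heat map — per-cell integral of the sharp ~4.7 Å reflection
  (q ≈ 1.337 1/Å) above a local linear baseline, used to locate fibril-rich
  lesions,
* two-reference background subtraction
  I = (I_l − I_b) − a (I_t − I_b), with the tissue scale factor a fitted in
  a high-q window where fibrillar scattering is negligible,
* selection of background cells adjacent to a candidate lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import Profile1D

__all__ = [
    "DetectorGeometry", "ScanGrid", "BackgroundModel", "HeatMap",
    "MaskedImage", "mask_substrate_peaks", "circular_average",
    "merge_profiles", "normalize_beam", "crossbeta_heatmap",
    "subtract_background", "select_background_cells", "grid_shape_from_extent",
    "read_geometry", "write_geometry", "read_image", "write_image",
]

#: cross-β reflection position: 2π / 4.7 Å
CROSSBETA_Q = 2.0 * np.pi / 4.7


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector geometry: beam centre [px], pixel size and distance
    [mm], wavelength [Å].  q(pixel) = (4π/λ) sin(atan(radius·px/dist)/2)."""

    beam_center: tuple[float, float]        # (row, col) in pixels
    pixel_size: float
    distance: float
    wavelength: float

    def __post_init__(self):
        if self.pixel_size <= 0 or self.distance <= 0 or self.wavelength <= 0:
            raise ValueError("pixel size, distance and wavelength must be positive")

    def q_of_pixels(self, shape: tuple[int, int]) -> np.ndarray:
        rows = np.arange(shape[0])[:, None] - self.beam_center[0]
        cols = np.arange(shape[1])[None, :] - self.beam_center[1]
        radius_mm = np.hypot(rows, cols) * self.pixel_size
        two_theta = np.arctan2(radius_mm, self.distance)
        return (4.0 * np.pi / self.wavelength) * np.sin(two_theta / 2.0)


def write_geometry(path, geometry: DetectorGeometry) -> None:
    """Sidecar geometry file: key = value text."""
    Path(path).write_text(
        f"beam_center_row = {geometry.beam_center[0]}\n"
        f"beam_center_col = {geometry.beam_center[1]}\n"
        f"pixel_size_mm = {geometry.pixel_size}\n"
        f"distance_mm = {geometry.distance}\n"
        f"wavelength_A = {geometry.wavelength}\n")


def read_geometry(path) -> DetectorGeometry:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = float(v.strip())
    return DetectorGeometry(
        beam_center=(kv["beam_center_row"], kv["beam_center_col"]),
        pixel_size=kv["pixel_size_mm"], distance=kv["distance_mm"],
        wavelength=kv["wavelength_A"])


def read_image(path, dataset: str = "image") -> np.ndarray:
    """Load a detector image from TIFF or HDF5."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(p), dtype=float)
    if p.suffix.lower() in (".h5", ".hdf5"):
        import h5py
        with h5py.File(p, "r") as f:
            return np.asarray(f[dataset][()], dtype=float)
    raise ValueError(f"unsupported image format: {p.suffix}")


def write_image(path, data: np.ndarray, dataset: str = "image") -> None:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(p, np.asarray(data, dtype=np.float32))
    elif p.suffix.lower() in (".h5", ".hdf5"):
        import h5py
        with h5py.File(p, "w") as f:
            f.create_dataset(dataset, data=data)
    else:
        raise ValueError(f"unsupported image format: {p.suffix}")


@dataclass
class MaskedImage:
    """Detector counts with a persistent boolean mask (True = invalid)."""

    data: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")


def mask_substrate_peaks(image, peak_regions) -> MaskedImage:
    """Flag rectangular pixel regions (substrate Bragg peaks) as invalid.

    ``peak_regions`` is a list of (row_lo, row_hi, col_lo, col_hi) slices,
    half-open like Python ranges.  Pixels outside the regions are unchanged;
    the mask is carried with the image for downstream averaging.
    """
    img = image if isinstance(image, MaskedImage) else MaskedImage(np.array(image, dtype=float))
    mask = img.mask.copy()
    nr, nc = img.data.shape
    for (r0, r1, c0, c1) in peak_regions:
        if not (0 <= r0 <= r1 <= nr and 0 <= c0 <= c1 <= nc):
            raise ValueError(f"region {(r0, r1, c0, c1)} outside image bounds {img.data.shape}")
        mask[r0:r1, c0:c1] = True
    return MaskedImage(img.data.copy(), mask)


def circular_average(image, geometry: DetectorGeometry,
                     n_bins: int = 200) -> Profile1D:
    """Azimuthal average of a (masked) detector image into a 1D profile.

    Bins are uniform in q between the image's q extremes; each bin reports
    the mean of its unmasked pixels and the standard error of that mean.
    Empty bins are dropped.
    """
    img = image if isinstance(image, MaskedImage) else MaskedImage(np.asarray(image, dtype=float))
    valid = ~img.mask
    if not np.any(valid):
        raise ValueError("all pixels are masked; nothing to average")
    qmap = geometry.q_of_pixels(img.data.shape)
    qv = qmap[valid]
    dv = img.data[valid]
    edges = np.linspace(qv.min(), qv.max(), n_bins + 1)
    idx = np.clip(np.digitize(qv, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    total = np.bincount(idx, weights=dv, minlength=n_bins)
    total2 = np.bincount(idx, weights=dv ** 2, minlength=n_bins)
    occupied = count > 0
    mean = total[occupied] / count[occupied]
    var = total2[occupied] / count[occupied] - mean ** 2
    sem = np.sqrt(np.maximum(var, 0.0) / count[occupied])
    centers = 0.5 * (edges[:-1] + edges[1:])[occupied]
    return Profile1D(centers, mean, sem)


def merge_profiles(saxs: Profile1D, waxs: Profile1D,
                   overlap: tuple[float, float]) -> Profile1D:
    """Merge SAXS and WAXS curves, scaling WAXS onto SAXS over the overlap.

    The scalar c minimising ‖I_saxs − c·I_waxs‖² over the overlap window is
    applied to the WAXS curve; the merged profile takes SAXS points below
    the overlap midpoint and scaled WAXS points above it.
    """
    q_lo, q_hi = overlap
    s_sel = (saxs.q >= q_lo) & (saxs.q <= q_hi)
    w_sel = (waxs.q >= q_lo) & (waxs.q <= q_hi)
    if not (np.any(s_sel) and np.any(w_sel)):
        raise ValueError("overlap window is empty in one of the inputs")
    # compare on the SAXS overlap grid
    w_on_s = np.interp(saxs.q[s_sel], waxs.q, waxs.intensity)
    denom = float(w_on_s @ w_on_s)
    if denom == 0:
        raise ValueError("WAXS intensity vanishes in the overlap window")
    c = float(saxs.intensity[s_sel] @ w_on_s) / denom
    mid = 0.5 * (q_lo + q_hi)
    keep_s = saxs.q <= mid
    keep_w = waxs.q > mid
    q = np.concatenate([saxs.q[keep_s], waxs.q[keep_w]])
    i = np.concatenate([saxs.intensity[keep_s], c * waxs.intensity[keep_w]])
    s = np.concatenate([saxs.sigma[keep_s], c * waxs.sigma[keep_w]])
    order = np.argsort(q)
    q, i, s = q[order], i[order], s[order]
    # guard against duplicate abscissae at the seam
    uniq = np.concatenate([[True], np.diff(q) > 0])
    return Profile1D(q[uniq], i[uniq], s[uniq],
                     meta={"merge_scale": c, "overlap": overlap})


def normalize_beam(profile: Profile1D, monitor: float) -> Profile1D:
    """Divide intensity and sigma by a beam-monitor reading."""
    if monitor <= 0:
        raise ValueError("monitor must be positive")
    return profile.scaled(1.0 / monitor)


@dataclass
class ScanGrid:
    """Raster of 1D profiles on a square grid with a common q grid.

    profiles[iy][ix] addresses column ix (x position) and row iy; positions
    are origin + index·step in µm.
    """

    nx: int
    ny: int
    step: float
    profiles: list
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if len(self.profiles) != self.ny or any(len(row) != self.nx for row in self.profiles):
            raise ValueError("profiles must be an ny × nx nested list")
        q0 = self.profiles[0][0].q
        for row in self.profiles:
            for p in row:
                if p.q.shape != q0.shape or not np.allclose(p.q, q0):
                    raise ValueError("all cells must share a common q grid")

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0][0].q

    def cell(self, ix: int, iy: int) -> Profile1D:
        return self.profiles[iy][ix]

    def position(self, ix: int, iy: int) -> tuple[float, float]:
        return (self.origin[0] + ix * self.step, self.origin[1] + iy * self.step)

    @property
    def n_patterns(self) -> int:
        return self.nx * self.ny

    def write_dir(self, path) -> None:
        """Directory of per-cell ``row_col.dat`` files plus a manifest."""
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        (d / "manifest.txt").write_text(
            f"nx = {self.nx}\nny = {self.ny}\nstep_um = {self.step}\n"
            f"origin_um = {self.origin[0]} {self.origin[1]}\n")
        for iy in range(self.ny):
            for ix in range(self.nx):
                self.profiles[iy][ix].write(d / f"{iy:03d}_{ix:03d}.dat")

    @classmethod
    def read_dir(cls, path) -> "ScanGrid":
        d = Path(path)
        kv = {}
        for line in (d / "manifest.txt").read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        nx, ny = int(kv["nx"]), int(kv["ny"])
        step = float(kv.get("step_um", 1.0))
        origin = tuple(float(x) for x in kv.get("origin_um", "0 0").split())
        profiles = []
        for iy in range(ny):
            row = []
            for ix in range(nx):
                f = d / f"{iy:03d}_{ix:03d}.dat"
                if not f.exists():
                    raise FileNotFoundError(
                        f"scan cell (ix={ix}, iy={iy}) missing: {f}")
                row.append(Profile1D.read(f))
            profiles.append(row)
        return cls(nx, ny, step, profiles, origin)


def grid_shape_from_extent(extent_x: float, extent_y: float,
                           step: float) -> tuple[int, int]:
    """Grid points per axis for a raster over a rectangular extent [µm].

    Both end positions are included: n = extent/step + 1 per axis, so a
    300 × 400 µm² region at 5 µm steps gives 61 × 81 = 4941 patterns.
    """
    nx = int(round(extent_x / step)) + 1
    ny = int(round(extent_y / step)) + 1
    return nx, ny


@dataclass
class HeatMap:
    """ny × nx map of integrated cross-β peak intensity."""

    values: np.ndarray
    q_center: float
    q_half_width: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("heat map must be 2D")

    @property
    def argmax_cell(self) -> tuple[int, int]:
        iy, ix = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return (int(ix), int(iy))

    def write_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",",
                   header=f"crossbeta heatmap q_center={self.q_center} "
                          f"q_half_width={self.q_half_width}")

    @classmethod
    def read_csv(cls, path, q_center=CROSSBETA_Q, q_half_width=0.03) -> "HeatMap":
        return cls(np.loadtxt(path, delimiter=","), q_center, q_half_width)


def crossbeta_heatmap(scan: ScanGrid, q_center: float = 1.337,
                      q_half_width: float = 0.03) -> HeatMap:
    """Map of sharp cross-β excess per scan cell.

    In the window [q_center − w, q_center + w] a straight baseline is
    anchored at the two window-edge grid points and the intensity above it
    is integrated (trapezoid); negative integrals clip to 0.  Anchoring the
    baseline at the edges makes the map blind to any q-linear component of
    the profile, so smooth diffuse (tissue) scattering does not register.
    """
    q = scan.q
    lo, hi = q_center - q_half_width, q_center + q_half_width
    sel = (q >= lo) & (q <= hi)
    if q[0] > lo or q[-1] < hi or sel.sum() < 3:
        raise ValueError(
            f"window [{lo:.4g}, {hi:.4g}] not covered by the scan q grid")
    qs = q[sel]
    out = np.zeros((scan.ny, scan.nx))
    for iy in range(scan.ny):
        for ix in range(scan.nx):
            iv = scan.profiles[iy][ix].intensity[sel]
            base = iv[0] + (iv[-1] - iv[0]) * (qs - qs[0]) / (qs[-1] - qs[0])
            out[iy, ix] = max(np.trapezoid(iv - base, qs), 0.0)
    return HeatMap(out, q_center, q_half_width)


@dataclass(frozen=True)
class BackgroundModel:
    """Fitted tissue scale factor for two-reference subtraction."""

    a: float
    fit_range: tuple[float, float] = (1.6, 2.0)
    residual: float = 0.0


def subtract_background(lesion: Profile1D, tissue: Profile1D,
                        substrate: Profile1D,
                        fit_range: tuple[float, float] = (1.6, 2.0),
                        weighted: bool = False
                        ) -> tuple[Profile1D, BackgroundModel]:
    """Two-reference subtraction: I = (I_l − I_b) − a (I_t − I_b).

    The scale factor a minimises Σ [(I_l − I_b) − a (I_t − I_b)]² over the
    fit window — chosen at high q where fibrillar scattering is weak so that
    only the diffuse tissue component drives the fit.  With ``weighted`` the
    sum is weighted by 1/σ_l².  Sigmas propagate in quadrature.
    """
    for other in (tissue, substrate):
        if other.q.shape != lesion.q.shape or not np.allclose(other.q, lesion.q):
            raise ValueError("lesion, tissue and substrate must share a q grid")
    q = lesion.q
    lo, hi = fit_range
    sel = (q >= lo) & (q <= hi)
    if not np.any(sel):
        raise ValueError(f"fit range [{lo}, {hi}] contains no data points")
    dl = lesion.intensity - substrate.intensity
    dt = tissue.intensity - substrate.intensity
    w = 1.0 / np.where(lesion.sigma > 0, lesion.sigma, 1.0) ** 2 if weighted \
        else np.ones_like(q)
    denom = float(np.sum(w[sel] * dt[sel] ** 2))
    if denom == 0:
        raise ValueError("tissue minus substrate vanishes in the fit range; "
                         "scale factor undefined")
    a = float(np.sum(w[sel] * dl[sel] * dt[sel])) / denom
    resid = dl[sel] - a * dt[sel]
    rms = float(np.sqrt(np.mean(resid ** 2)))
    out_i = dl - a * dt
    out_s = np.sqrt(lesion.sigma ** 2 + (1 + a) ** 2 * substrate.sigma ** 2
                    + a ** 2 * tissue.sigma ** 2)
    out = Profile1D(q, out_i, out_s, meta={"background_scale": a})
    return out, BackgroundModel(a, (lo, hi), rms)


def select_background_cells(scan: ScanGrid, heat: HeatMap,
                            lesion_cell: tuple[int, int], n: int = 5,
                            annulus: tuple[float, float] = (3.0, 10.0)
                            ) -> tuple[Profile1D, list[tuple[int, int]]]:
    """Average the n quietest profiles in an annulus around a lesion cell.

    Candidate cells lie 3–10 grid steps (Euclidean) from the lesion; the n
    with the lowest heat-map values are averaged (ties broken by distance,
    then row-major index).  Returns the mean profile and the chosen cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ix0, iy0 = lesion_cell
    if not (0 <= ix0 < scan.nx and 0 <= iy0 < scan.ny):
        raise ValueError(f"lesion cell {lesion_cell} outside grid")
    if heat.values.shape != (scan.ny, scan.nx):
        raise ValueError("heat map shape does not match scan grid")
    r_in, r_out = annulus
    candidates = []
    for iy in range(scan.ny):
        for ix in range(scan.nx):
            d = np.hypot(ix - ix0, iy - iy0)
            if r_in <= d <= r_out:
                candidates.append((heat.values[iy, ix], d, iy * scan.nx + ix,
                                   ix, iy))
    if len(candidates) < n:
        raise ValueError(
            f"annulus holds {len(candidates)} cells; need {n}")
    candidates.sort()
    chosen = [(c[3], c[4]) for c in candidates[:n]]
    profs = [scan.cell(ix, iy) for ix, iy in chosen]
    mean_i = np.mean([p.intensity for p in profs], axis=0)
    mean_s = np.sqrt(np.sum([p.sigma ** 2 for p in profs], axis=0)) / len(profs)
    return Profile1D(scan.q, mean_i, mean_s,
                     meta={"background_cells": chosen}), chosen
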