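"""Synthetic data: noisy profiles, tissue curves, scan grids, detector
images, and 2D liquid-like packings with interparticle interference.

Everything here is a model of the *measurement*, used to exercise and
validate the analysis chain against known ground truth:

* counting noise — Poisson counts at a given exposure, returned on the
  model's intensity scale;
* diffuse tissue scattering — a smooth power-law + broad disordered-matter
  band near q ≈ 1.4 1/Å, deliberately featureless at high q where the
  background scale factor is fitted;
* raster scans — substrate + tissue + (inside planted plaques) fibril
  scattering with a sharp cross-β Gaussian at q ≈ 1.337 1/Å, with the
  ground-truth plaque mask returned for assertions;
* hard-core 2D packings of parallel rods, emulating the liquid-like
  ordering of concentrated gels of rod-shaped particles, with the
  interparticle structure factor S(q) = 1 + (2/N) Σ_{j<k} J0(q d_jk).

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0

from .models import CylinderSpec, cylinder_amplitude, isotropic_cylinder_intensity
from .profiles import Profile1D
from .scan import CROSSBETA_Q, DetectorGeometry, ScanGrid

__all__ = [
    "PackingSpec", "SyntheticScanSpec", "ScanTruth", "gen_profile",
    "gen_tissue_profile", "gen_substrate_profile", "gen_scan",
    "gen_packing_2d", "interference_equatorial_intensity", "render_image",
]


def gen_profile(model: Profile1D, exposure: float, seed: int) -> Profile1D:
    """Poisson-noise a model intensity at the given exposure.

    Counts are drawn with mean exposure·I and returned as counts/exposure
    with σ = sqrt(counts)/exposure (σ for zero-count bins falls back to the
    one-count level 1/exposure).
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if np.any(model.intensity < 0):
        raise ValueError("model intensity must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(exposure * model.intensity).astype(float)
    sigma = np.sqrt(np.maximum(counts, 1.0)) / exposure
    return Profile1D(model.q, counts / exposure, sigma,
                     equatorial=model.equatorial,
                     meta={**model.meta, "exposure": exposure, "seed": seed})


def gen_tissue_profile(qgrid, amplitude: float = 1.0,
                       powerlaw_exponent: float = 2.5,
                       band_center: float = 1.4,
                       band_width: float = 0.35,
                       band_height: float = 0.3) -> Profile1D:
    """Smooth diffuse scattering of a disordered macromolecular matrix.

    A low-q power law q^(−exponent) (cross-linked network, large-scale
    density fluctuations) plus a broad Gaussian band near 1.4 1/Å (the
    universal disordered-matter distance band).  The curve has no sharp
    features — in particular it is smooth at the percent level across
    1.6–2.0 1/Å, the window used to fit the tissue scale factor.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    q = np.asarray(qgrid, dtype=float)
    # soften the power law below q=0.02 to keep intensities finite
    q_eff = np.sqrt(q ** 2 + 0.02 ** 2)
    diffuse = (q_eff / 0.1) ** (-powerlaw_exponent)
    band = band_height * np.exp(-0.5 * ((q - band_center) / band_width) ** 2)
    return Profile1D(q, amplitude * (diffuse + band),
                     meta={"model": "tissue diffuse"})


def gen_substrate_profile(qgrid, level: float = 0.05,
                          spike_positions=(0.45, 0.9, 1.55),
                          spike_height: float = 2.0,
                          spike_width: float = 0.004) -> Profile1D:
    """Substrate (mica-like) scattering: flat floor plus sharp Bragg spikes."""
    q = np.asarray(qgrid, dtype=float)
    i = np.full_like(q, level)
    for qs in spike_positions:
        i = i + spike_height * np.exp(-0.5 * ((q - qs) / spike_width) ** 2)
    return Profile1D(q, i, meta={"model": "substrate"})


@dataclass(frozen=True)
class SyntheticScanSpec:
    """Conditions for a synthetic raster scan with planted plaques.

    Grid cells carry substrate + tissue·local_density, and inside planted
    plaque disks additionally the isotropic scattering of a fibril plus a
    Gaussian cross-β peak.  ``lesion_density_boost`` makes the diffuse
    component inside lesions somewhat more intense than adjacent tissue,
    as observed for dense lesions.
    """

    nx: int = 21
    ny: int = 21
    step: float = 5.0                                    # µm
    plaques: tuple = ((10, 10, 3.0),)                    # (ix, iy, radius) in cells
    tissue_amplitude: float = 1.0
    lesion_density_boost: float = 1.3
    fibril: CylinderSpec = field(default_factory=lambda: CylinderSpec(35.0, 1000.0))
    # dense lesions are dominated by fibrils: forward fibril scattering is
    # set comparable to the tissue diffuse term at the smallest q
    fibril_amplitude: float = 20.0
    crossbeta_height: float = 0.5
    crossbeta_q: float = CROSSBETA_Q
    crossbeta_width: float = 0.01                        # σ_q of the peak [1/Å]
    substrate_spikes: tuple = (0.45, 0.9, 1.55)
    # counts per intensity unit; azimuthal bins aggregate thousands of
    # detector pixels, so effective counts per q-bin are large
    exposure: float = 1e6
    seed: int = 0

    def __post_init__(self):
        for (ix, iy, rad) in self.plaques:
            if not (0 <= ix < self.nx and 0 <= iy < self.ny):
                raise ValueError(f"plaque centre {(ix, iy)} outside grid")
        if min(self.tissue_amplitude, self.fibril_amplitude,
               self.crossbeta_height) < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclass
class ScanTruth:
    """Ground truth accompanying a generated scan."""

    plaque_mask: np.ndarray          # (ny, nx) bool
    densities: np.ndarray            # (ny, nx) diffuse density multiplier
    fibril_profile: Profile1D        # noiseless fibril contribution (q<qmax part)
    tissue_profile: Profile1D
    substrate_profile: Profile1D
    lesion_scale: float              # the a-equivalent: lesion/tissue diffuse ratio


def gen_scan(spec: SyntheticScanSpec, qgrid=None) -> tuple[ScanGrid, ScanTruth]:
    """Generate a plaque-bearing raster scan plus its ground truth.

    The default q grid spans 0.005–2.2 1/Å so both the SAXS shape region
    and the cross-β / background-fit windows are covered.
    """
    q = np.linspace(0.005, 2.2, 700) if qgrid is None else np.asarray(qgrid, float)
    substrate = gen_substrate_profile(q, spike_positions=spec.substrate_spikes)
    tissue = gen_tissue_profile(q, spec.tissue_amplitude)

    fib_iso = isotropic_cylinder_intensity(q, spec.fibril)
    # normalise the fibril SAXS term to its forward value, scale by amplitude
    fib_saxs = spec.fibril_amplitude * fib_iso.intensity / fib_iso.intensity[0]
    peak = spec.crossbeta_height * np.exp(
        -0.5 * ((q - spec.crossbeta_q) / spec.crossbeta_width) ** 2)
    fibril = Profile1D(q, fib_saxs + peak, meta={"model": "fibril + crossbeta"})

    mask = np.zeros((spec.ny, spec.nx), dtype=bool)
    for (cx, cy, rad) in spec.plaques:
        yy, xx = np.mgrid[0:spec.ny, 0:spec.nx]
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= rad ** 2
    densities = np.where(mask, spec.lesion_density_boost, 1.0)

    rng = np.random.default_rng(spec.seed)
    rows = []
    for iy in range(spec.ny):
        row = []
        for ix in range(spec.nx):
            model_i = (substrate.intensity
                       + densities[iy, ix] * tissue.intensity
                       + (fibril.intensity if mask[iy, ix] else 0.0))
            cell_seed = int(rng.integers(0, 2 ** 31 - 1))
            row.append(gen_profile(Profile1D(q, model_i), spec.exposure,
                                   cell_seed))
        rows.append(row)
    grid = ScanGrid(spec.nx, spec.ny, spec.step, rows)
    truth = ScanTruth(mask, densities, fibril, tissue, substrate,
                      spec.lesion_density_boost)
    return grid, truth


@dataclass(frozen=True)
class PackingSpec:
    """Hard-core 2D point process emulating a liquid-like gel packing.

    target_nn is the desired realised mean nearest-neighbour distance [Å];
    the hard-core diameter is tuned by bisection to hit it within 2%.
    """

    n_particles: int = 200
    box: float = 4500.0
    hard_core: float | None = None      # fixed value; None = tune to target_nn
    target_nn: float = 275.0
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if not (0 < self.target_nn < self.box):
            raise ValueError("target_nn must lie in (0, box)")
        if self.hard_core is not None and self.hard_core > self.target_nn:
            raise ValueError("hard_core must be <= target_nn")


def _insert_hard_core(n: int, box: float, hard_core: float,
                      rng: np.random.Generator,
                      max_tries: int = 500000) -> np.ndarray:
    pts = np.empty((n, 2))
    count = 0
    tries = 0
    hc2 = hard_core ** 2
    while count < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} centres with hard core {hard_core:.1f} Å "
                f"in a {box:.0f} Å box")
        cand = rng.uniform(0.0, box, size=2)
        if count == 0 or np.min(np.sum((pts[:count] - cand) ** 2, axis=1)) >= hc2:
            pts[count] = cand
            count += 1
        tries += 1
    return pts


def _mean_nn(pts: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(np.mean(d[:, 1]))


def gen_packing_2d(spec: PackingSpec) -> np.ndarray:
    """Sequential random insertion with hard-core rejection.

    When ``hard_core`` is not fixed, it is tuned by bisection so the
    realised mean nearest-neighbour distance lands within 2% of
    ``target_nn``.  Deterministic for a given (spec, seed).
    """
    if spec.n_particles == 1:
        rng = np.random.default_rng(spec.seed)
        return rng.uniform(0.0, spec.box, size=(1, 2))

    def feasible(hc):
        return spec.n_particles * np.pi * (hc / 2.0) ** 2 < 0.5 * spec.box ** 2

    if spec.hard_core is not None:
        if not feasible(spec.hard_core):
            raise ValueError("requested packing density is infeasible")
        rng = np.random.default_rng(spec.seed)
        return _insert_hard_core(spec.n_particles, spec.box, spec.hard_core, rng)

    def realized(hc):
        rng = np.random.default_rng(spec.seed)
        return _mean_nn(_insert_hard_core(spec.n_particles, spec.box, hc, rng))

    lo, hi = 0.0, spec.target_nn
    if not feasible(hi):
        # largest hard core satisfying the density precondition
        hi = 2.0 * spec.box * np.sqrt(0.5 / (np.pi * spec.n_particles)) * 0.999
    nn_lo = realized(lo)
    if nn_lo > spec.target_nn * 1.02:
        raise ValueError(
            f"box too small: even without a hard core the mean NN distance is "
            f"{nn_lo:.0f} Å > target {spec.target_nn:.0f} Å")
    best_hc = lo
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        nn = realized(mid)
        if abs(nn - spec.target_nn) <= 0.02 * spec.target_nn:
            best_hc = mid
            break
        if nn < spec.target_nn:
            lo = mid
        else:
            hi = mid
        best_hc = mid
    rng = np.random.default_rng(spec.seed)
    pts = _insert_hard_core(spec.n_particles, spec.box, best_hc, rng)
    if abs(_mean_nn(pts) - spec.target_nn) > 0.02 * spec.target_nn:
        raise RuntimeError("hard-core bisection failed to reach the target "
                           "nearest-neighbour distance within 2%")
    return pts


def interference_equatorial_intensity(centers, form: CylinderSpec,
                                      qgrid) -> Profile1D:
    """Equatorial intensity of parallel rods at the given 2D centres.

    I_e(q) = |F_eq(q)|² · S(q) with F_eq the infinite-cylinder equatorial
    amplitude and S(q) = 1 + (2/N) Σ_{j<k} J0(q d_jk) the in-plane
    structure factor of the centre set (oriented-parallel-rod
    approximation: no orientational averaging of S).
    """
    pts = np.atleast_2d(np.asarray(centers, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one centre")
    q = np.asarray(qgrid, dtype=float)
    form_amp = cylinder_amplitude(q, 0.0, form)
    n = pts.shape[0]
    if n == 1:
        s_q = np.ones_like(q)
    else:
        from scipy.spatial.distance import pdist
        d = pdist(pts)
        s_q = np.empty_like(q)
        for k0 in range(0, q.size, 64):
            qs = q[k0:k0 + 64][:, None]
            s_q[k0:k0 + 64] = 1.0 + (2.0 / n) * j0(qs * d[None, :]).sum(axis=1)
    return Profile1D(q, form_amp ** 2 * s_q, equatorial=True,
                     meta={"model": "parallel rods with interference",
                           "n_particles": n})


def render_image(profile: Profile1D, geometry: DetectorGeometry,
                 shape: tuple[int, int],
                 spikes: list | None = None) -> np.ndarray:
    """Render a detector image from a radial profile (for round-trip tests).

    ``spikes`` optionally adds localized substrate-like peaks as
    (row, col, height, sigma_px) tuples.
    """
    qmap = geometry.q_of_pixels(shape)
    img = np.interp(qmap, profile.q, profile.intensity)
    if spikes:
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        for (r, c, h, s) in spikes:
            img = img + h * np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * s ** 2))
    return img
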