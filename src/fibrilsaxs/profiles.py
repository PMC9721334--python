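"""1D scattering profiles and real-space functions.

The two containers used throughout the package:

* :class:`Profile1D` — a reduced scattering curve I(q) with per-point
  uncertainties, on a strictly increasing momentum-transfer grid
  (q = 4π sin θ / λ, so a Bragg spacing d appears at q = 2π/d).
* :class:`RealSpaceFunction` — a pair distribution function P(r) or a
  correlation function a(r) on an r grid, tagged with the geometry it was
  computed in (spherical whole-particle vs fibril cross-section).

Both round-trip through plain ASCII files with ``#``-prefixed headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Profile1D", "RealSpaceFunction"]


def _as_grid(values) -> np.ndarray:
    q = np.asarray(values, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q grid must be a non-empty 1D array")
    if not np.all(np.isfinite(q)):
        raise ValueError("q grid must be finite")
    if np.any(q < 0):
        raise ValueError("q values must be >= 0")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    return q


@dataclass
class Profile1D:
    """A 1D scattering curve: q [1/Å], intensity, and uncertainty sigma.

    ``equatorial`` marks a curve that represents equatorial (fibre
    cross-section) intensity I_e(q) rather than an isotropic average;
    downstream cross-section transforms check this flag.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    equatorial: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_grid(self.q)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity and q must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is None:
            self.sigma = np.ones_like(self.q)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q must have equal length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be nonnegative")

    def __len__(self) -> int:
        return self.q.size

    def crop(self, q_min: float = -np.inf, q_max: float = np.inf) -> "Profile1D":
        """Return the sub-profile with q_min <= q <= q_max."""
        sel = (self.q >= q_min) & (self.q <= q_max)
        if not np.any(sel):
            raise ValueError(f"no points in window [{q_min}, {q_max}]")
        return replace(self, q=self.q[sel], intensity=self.intensity[sel],
                       sigma=self.sigma[sel])

    def scaled(self, c: float) -> "Profile1D":
        return replace(self, intensity=c * self.intensity, sigma=abs(c) * self.sigma)

    def write(self, path) -> None:
        """Write as 3-column ASCII (q, I, sigma) with a ``#`` header."""
        lines = ["# fibrilsaxs profile"]
        lines.append(f"# equatorial: {self.equatorial}")
        for k, v in self.meta.items():
            lines.append(f"# {k}: {v}")
        lines.append("# columns: q[1/A] intensity sigma")
        body = "\n".join(
            f"{q:.8e} {i:.8e} {s:.8e}"
            for q, i, s in zip(self.q, self.intensity, self.sigma)
        )
        Path(path).write_text("\n".join(lines) + "\n" + body + "\n")

    @classmethod
    def read(cls, path) -> "Profile1D":
        meta: dict = {}
        equatorial = False
        q, i, s = [], [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("# ").strip()
                if ":" in text:
                    k, v = text.split(":", 1)
                    k, v = k.strip(), v.strip()
                    if k == "equatorial":
                        equatorial = v.lower() == "true"
                    elif k not in ("columns",):
                        meta[k] = v
                continue
            parts = line.split()
            q.append(float(parts[0]))
            i.append(float(parts[1]))
            s.append(float(parts[2]) if len(parts) > 2 else 1.0)
        if not q:
            raise ValueError(f"no data rows in {path}")
        return cls(np.array(q), np.array(i), np.array(s),
                   equatorial=equatorial, meta=meta)


@dataclass
class RealSpaceFunction:
    """P(r) or a(r) on an r grid.

    geometry: 'spherical' (whole-particle, r² weighting) or 'cross_section'
    (projected onto the plane perpendicular to the fibril axis, r weighting).
    kind: 'pdf' or 'correlation'.
    """

    r: np.ndarray
    values: np.ndarray
    geometry: str
    kind: str
    meta: dict = field(default_factory=dict)

    _GEOMETRIES = ("spherical", "cross_section")
    _KINDS = ("pdf", "correlation")

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.values.shape:
            raise ValueError("r and values must be 1D arrays of equal length")
        if np.any(self.r < 0) or np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be nonnegative and increasing")
        if self.geometry not in self._GEOMETRIES:
            raise ValueError(f"geometry must be one of {self._GEOMETRIES}")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")

    def __call__(self, r) -> np.ndarray:
        """Linear interpolation onto arbitrary r."""
        return np.interp(r, self.r, self.values)

    def write(self, path) -> None:
        lines = ["# fibrilsaxs real-space function",
                 f"# geometry: {self.geometry}", f"# kind: {self.kind}"]
        for k, v in self.meta.items():
            lines.append(f"# {k}: {v}")
        lines.append("# columns: r[A] value")
        body = "\n".join(f"{r:.8e} {v:.8e}" for r, v in zip(self.r, self.values))
        Path(path).write_text("\n".join(lines) + "\n" + body + "\n")

    @classmethod
    def read(cls, path) -> "RealSpaceFunction":
        meta: dict = {}
        geometry, kind = "spherical", "pdf"
        r, v = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("# ").strip()
                if ":" in text:
                    k, val = (p.strip() for p in text.split(":", 1))
                    if k == "geometry":
                        geometry = val
                    elif k == "kind":
                        kind = val
                    elif k != "columns":
                        meta[k] = val
                continue
            parts = line.split()
            r.append(float(parts[0]))
            v.append(float(parts[1]))
        return cls(np.array(r), np.array(v), geometry=geometry, kind=kind, meta=meta)
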