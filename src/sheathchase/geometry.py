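"""Cell geometry: spheroplast (circle) and rod (capsule) cross-sections.

The simulation runs in the 2D focal plane. Sheath paths are straight chords,
so the only geometric queries needed are membrane sampling, chord length from
an anchor along a direction, and a rasterized cell mask for the cytosolic
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class CellShape(str, Enum):
    ROD = "rod"
    SPHEROPLAST = "spheroplast"


@dataclass(frozen=True)
class CellGeometry:
    """Cross-section of a cell in the imaging plane.

    A spheroplast is a circle of the given diameter.  A rod is a capsule
    (rectangle of width ``diameter_um`` capped with semicircles) of overall
    length ``length_um`` along the x axis.
    """

    shape: CellShape
    diameter_um: float
    length_um: float | None = None
    center_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shape = CellShape(self.shape)
        object.__setattr__(self, "shape", shape)
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if shape is CellShape.ROD:
            if self.length_um is None or self.length_um < self.diameter_um:
                raise ValueError("rod requires length_um >= diameter_um")

    # -- queries ---------------------------------------------------------

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def caliper_um(self) -> float:
        """Maximal caliper diameter; upper bound on any chord length."""
        if self.shape is CellShape.SPHEROPLAST:
            return self.diameter_um
        return float(self.length_um)

    @property
    def _half_axis_um(self) -> float:
        """Half-length of the rod's straight segment (0 for a spheroplast)."""
        if self.shape is CellShape.SPHEROPLAST:
            return 0.0
        return (self.length_um - self.diameter_um) / 2.0

    def contains(self, xy_um: np.ndarray) -> np.ndarray:
        """Boolean membership for (..., 2) points in um."""
        xy = np.asarray(xy_um, dtype=float) - np.asarray(self.center_um)
        a = self._half_axis_um
        # distance to the central segment [-a, a] x {0}
        x = np.clip(xy[..., 0], -a, a)
        d2 = (xy[..., 0] - x) ** 2 + xy[..., 1] ** 2
        return d2 <= self.radius_um**2

    def bounds_um(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cell outline."""
        cx, cy = self.center_um
        a = self._half_axis_um
        r = self.radius_um
        return (cx - a - r, cy - r, cx + a + r, cy + r)

    def area_um2(self) -> float:
        a = self._half_axis_um
        r = self.radius_um
        return np.pi * r**2 + 2 * a * self.diameter_um

    def chord_length(self, anchor_um, direction) -> float:
        """Length of the chord from ``anchor_um`` (on or inside the membrane)
        along unit vector ``direction`` until the membrane is crossed."""
        anchor = np.asarray(anchor_um, dtype=float)
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        d = d / n
        if self.shape is CellShape.SPHEROPLAST:
            # solve |anchor + t d - c|^2 = r^2 for the positive root
            p = anchor - np.asarray(self.center_um)
            b = float(np.dot(p, d))
            c = float(np.dot(p, p)) - self.radius_um**2
            disc = b * b - c
            if disc < 0:
                return 0.0
            t = -b + np.sqrt(disc)
            return max(t, 0.0)
        # capsule: bisection on the membership predicate (exit is unique
        # along a ray from an interior point of a convex body)
        hi = self.caliper_um * 1.001
        if self.contains(anchor + hi * d):
            return hi
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self.contains(anchor + mid * d):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # -- sampling --------------------------------------------------------

    def perimeter_um(self) -> float:
        return 2 * np.pi * self.radius_um + 4 * self._half_axis_um

    def membrane_point(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Point on the membrane at arc-length fraction ``s`` in [0, 1),
        plus the inward unit normal there."""
        cx, cy = self.center_um
        r = self.radius_um
        a = self._half_axis_um
        if self.shape is CellShape.SPHEROPLAST or a == 0:
            th = 2 * np.pi * s
            pt = np.array([cx + r * np.cos(th), cy + r * np.sin(th)])
            normal = np.array([-np.cos(th), -np.sin(th)])
            return pt, normal
        per = self.perimeter_um()
        t = (s % 1.0) * per
        # walk: top edge, right cap, bottom edge, left cap
        if t < 2 * a:
            pt = np.array([cx - a + t, cy + r])
            return pt, np.array([0.0, -1.0])
        t -= 2 * a
        if t < np.pi * r:
            th = np.pi / 2 - t / r
            pt = np.array([cx + a + r * np.cos(th), cy + r * np.sin(th)])
            return pt, np.array([-np.cos(th), -np.sin(th)])
        t -= np.pi * r
        if t < 2 * a:
            pt = np.array([cx + a - t, cy - r])
            return pt, np.array([0.0, 1.0])
        t -= 2 * a
        th = -np.pi / 2 - t / r
        pt = np.array([cx - a + r * np.cos(th), cy + r * np.sin(th)])
        return pt, np.array([-np.cos(th), -np.sin(th)])

    def sample_chord(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
        """Sample a nucleation chord: anchor uniform on the membrane,
        direction toward a second uniform membrane point.

        Returns (anchor_um, unit direction, chord length in um).
        """
        for _ in range(100):
            p0, _ = self.membrane_point(rng.uniform())
            p1, _ = self.membrane_point(rng.uniform())
            v = p1 - p0
            n = np.linalg.norm(v)
            if n > 1e-3:
                d = v / n
                return p0, d, self.chord_length(p0, d)
        raise RuntimeError("failed to sample a nondegenerate chord")

    def mask(
        self,
        shape_px: tuple[int, int],
        pixel_size_nm: float,
        origin_um: tuple[float, float],
    ) -> np.ndarray:
        """Rasterize cell membership on an image grid (rows=y, cols=x)."""
        h, w = shape_px
        px = pixel_size_nm / 1000.0
        x0, y0 = origin_um
        ys = y0 + (np.arange(h) + 0.5) * px
        xs = x0 + (np.arange(w) + 0.5) * px
        xx, yy = np.meshgrid(xs, ys)
        return self.contains(np.stack([xx, yy], axis=-1))
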