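"""Piecewise-constant density phantoms and noiseless projection synthesis.

Phantoms model the discrete, high-contrast density distributions met when
probing a coal seam for gas pockets or rock inclusions: a small set of
axis-aligned rectangles ``D_i`` inside ``E = [-1, 1]^2``, each with a
constant density ``c_i``, on a constant background.  Region interiors must
be pairwise disjoint (their common part has zero area).

The two built-in phantoms ``f1`` and ``f2`` each carry four rectangles with
densities 1..4.  A phantom rasterizes to a truth vector on a
:class:`~blockart.geometry.PixelGrid` either by exact area-weighted
averaging (default) or by pixel-centre sampling, and projection data are
synthesised noiselessly as ``b = A @ x_true``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidPhantomError
from .geometry import DOMAIN_MAX, DOMAIN_MIN, PixelGrid, SystemMatrix

__all__ = [
    "Rect",
    "Phantom",
    "phantom_f1",
    "phantom_f2",
    "rasterize",
    "forward_project",
    "projection_from_intensities",
    "add_projection_noise",
]


@dataclass(frozen=True)
class Rect:
    """Closed axis-aligned rectangle ``[x_lo, x_hi] x [y_lo, y_hi]``."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def __post_init__(self):
        if not (self.x_lo < self.x_hi and self.y_lo < self.y_hi):
            raise InvalidPhantomError(f"degenerate rectangle {self}")
        if (
            self.x_lo < DOMAIN_MIN
            or self.x_hi > DOMAIN_MAX
            or self.y_lo < DOMAIN_MIN
            or self.y_hi > DOMAIN_MAX
        ):
            raise InvalidPhantomError(f"rectangle {self} leaves the domain E")

    @property
    def area(self) -> float:
        return (self.x_hi - self.x_lo) * (self.y_hi - self.y_lo)

    def contains(self, x, y):
        """Membership of point(s) in the closed rectangle."""
        x, y = np.asarray(x), np.asarray(y)
        return (x >= self.x_lo) & (x <= self.x_hi) & (y >= self.y_lo) & (y <= self.y_hi)

    def overlap_area(self, other: "Rect") -> float:
        w = min(self.x_hi, other.x_hi) - max(self.x_lo, other.x_lo)
        h = min(self.y_hi, other.y_hi) - max(self.y_lo, other.y_lo)
        return max(w, 0.0) * max(h, 0.0)


@dataclass(frozen=True)
class Phantom:
    """Piecewise-constant density: rectangles with densities on a background.

    ``evaluate`` returns the density of the first region containing a point
    (regions may share boundary segments; interiors may not overlap).
    """

    regions: tuple[tuple[Rect, float], ...]
    background: float = 0.0

    def __post_init__(self):
        regions = tuple((r, float(c)) for r, c in self.regions)
        object.__setattr__(self, "regions", regions)
        for i, (ri, _) in enumerate(regions):
            for rj, _ in regions[i + 1:]:
                if ri.overlap_area(rj) > 0.0:
                    raise InvalidPhantomError(f"regions {ri} and {rj} overlap in their interiors")

    def evaluate(self, x, y):
        """Density at point(s) ``(x, y)``; vectorised."""
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        out = np.full(np.broadcast(x, y).shape, self.background, dtype=float)
        assigned = np.zeros_like(out, dtype=bool)
        for rect, c in self.regions:
            hit = rect.contains(x, y) & ~assigned
            out[hit] = c
            assigned |= hit
        return out if out.ndim else float(out)

    def total_integral(self) -> float:
        """Integral of the density over E."""
        dom = (DOMAIN_MAX - DOMAIN_MIN) ** 2
        covered = sum(r.area for r, _ in self.regions)
        return self.background * (dom - covered) + sum(c * r.area for r, c in self.regions)

    @classmethod
    def from_rectangles(cls, rows, background: float = 0.0) -> "Phantom":
        """Build from an iterable of ``(x_lo, x_hi, y_lo, y_hi, density)``."""
        return cls(tuple((Rect(a, b, c, d), v) for a, b, c, d, v in rows), background)


def phantom_f1() -> Phantom:
    """Four-rectangle test phantom with densities 1..4 (left-heavy layout)."""
    return Phantom.from_rectangles(
        [
            (-0.7, -0.4, -0.5, 0.2, 1.0),
            (-0.2, 0.2, -0.1, 0.1, 2.0),
            (-0.2, 0.2, 0.3, 0.5, 3.0),
            (0.4, 0.7, 0.4, 0.7, 4.0),
        ]
    )


def phantom_f2() -> Phantom:
    """Four-rectangle test phantom with densities 1..4 (tall central bar)."""
    return Phantom.from_rectangles(
        [
            (0.0, 0.5, 0.3, 0.5, 1.0),
            (-0.4, 0.0, -0.6, 0.7, 2.0),
            (-0.6, -0.4, -0.1, 0.1, 3.0),
            (0.0, 0.3, -0.5, -0.3, 4.0),
        ]
    )


def _axis_overlap(lo: float, hi: float, n: int) -> np.ndarray:
    """Overlap length of [lo, hi] with each of n equal cells tiling [-1, 1]."""
    h = (DOMAIN_MAX - DOMAIN_MIN) / n
    edges = DOMAIN_MIN + np.arange(n + 1) * h
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)


def rasterize(phantom: Phantom, grid: PixelGrid, method: str = "area") -> np.ndarray:
    """Truth vector of per-pixel densities, row-major per the grid convention.

    ``method="area"`` (default) sets each pixel to the exact area-weighted
    mean of the density over the pixel; rectangle/pixel overlaps are computed
    in closed form.  ``method="center"`` samples the density at pixel
    centres, giving a strictly piecewise-constant-per-pixel truth.
    """
    if method == "center":
        xs, ys = grid.centers()
        xx, yy = np.meshgrid(xs, ys)
        return np.asarray(phantom.evaluate(xx, yy), dtype=float).ravel()
    if method != "area":
        raise ValueError(f"unknown rasterization method {method!r}")
    n = grid.n
    img = np.full((n, n), phantom.background, dtype=float)
    for rect, c in phantom.regions:
        fx = _axis_overlap(rect.x_lo, rect.x_hi, n) / grid.pixel_size  # by column
        fy = _axis_overlap(rect.y_lo, rect.y_hi, n) / grid.pixel_size  # bottom-up by row
        frac = np.outer(fy[::-1], fx)  # row 0 at top
        img += (c - phantom.background) * frac
    return img.ravel()


def forward_project(A: SystemMatrix, x: np.ndarray) -> np.ndarray:
    """Noiseless projections ``b = A @ x`` (exact sparse product)."""
    csr = A.csr if isinstance(A, SystemMatrix) else A
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != csr.shape[1]:
        raise ValueError(f"density vector length {x.shape[0]} != matrix columns {csr.shape[1]}")
    return csr @ x


def projection_from_intensities(I0: float, I: float) -> float:
    """Projection value ``ln(I0 / I)`` from initial and final beam intensity."""
    if I0 <= 0.0 or I <= 0.0:
        raise ValueError("intensities must be positive")
    if I > I0:
        raise ValueError("final intensity cannot exceed the initial intensity")
    return math.log(I0 / I)


def add_projection_noise(b: np.ndarray, sigma: float, seed: int | None = None) -> np.ndarray:
    """Optional additive Gaussian noise on the projection vector."""
    rng = np.random.default_rng(seed)
    return np.asarray(b, dtype=float) + rng.normal(0.0, sigma, size=np.shape(b))
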