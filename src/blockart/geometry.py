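"""Scanning geometries on the square domain and sparse system-matrix assembly.

The object under study occupies the fixed square ``E = [-1, 1]^2``, which is
discretised into ``n x n`` congruent square pixels.  A scan is an ordered set
of rays; each ray contributes one linear equation whose coefficients are the
lengths of the intersections of the ray with the individual pixels.  Stacking
the rows gives the sparse non-negative system matrix ``A`` of ``A x = b``,
where ``x`` holds the unknown per-pixel densities and ``b`` the measured
projections (line integrals).

Two acquisition layouts are provided:

* the limited-angle *(1 x 1)* system — ``pkt`` equally spaced sources on the
  wall ``x = -1`` and ``pkt`` equally spaced detectors on the opposite wall
  ``x = +1`` (corners included).  Every source/detector pair defines a ray;
  the two pairs whose ray runs along the mesh lines ``y = +1`` and ``y = -1``
  are rejected, leaving exactly ``pkt**2 - 2`` rays.  All view directions are
  confined to one quadrant, which is what makes the data set incomplete.
* a complete-data *parallel-beam* system — ``num_angles`` view directions
  spread uniformly over [0, 180) degrees with ``rays_per_angle`` parallel
  rays per view.

Intersection lengths are computed by the Siddon parametric-crossing method:
the ray parameter values at which the segment crosses the pixel boundary
lines are sorted, and each inter-crossing interval is attributed to the pixel
containing its midpoint.  Ties at grid lines are resolved by a half-open
pixel convention (a pixel owns its lower x boundary and its upper y
boundary), which makes the assembly bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import scipy.sparse as sp

from .errors import DegenerateRayError

__all__ = [
    "DOMAIN_MIN",
    "DOMAIN_MAX",
    "PixelGrid",
    "Ray",
    "ScanGeometry",
    "SystemMatrix",
    "build_grid",
    "make_one_by_one",
    "make_parallel_beam",
    "ray_row",
    "build_system",
    "chord_length",
]

DOMAIN_MIN = -1.0
DOMAIN_MAX = 1.0

# Chords shorter than this are treated as empty (corner grazes).
_EPS_CHORD = 1e-12


def _check_positive_int(value, name: str, minimum: int) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value}")
    return int(value)


@dataclass(frozen=True)
class PixelGrid:
    """Uniform discretisation of ``E = [-1, 1]^2`` into ``n * n`` pixels.

    Pixels are indexed row-major with row 0 at the top (image convention):
    pixel ``(r, c)`` covers
    ``[-1 + c*h, -1 + (c+1)*h] x [1 - (r+1)*h, 1 - r*h]`` with ``h = 2/n``.
    A pixel owns its lower x boundary and its upper y boundary, so every
    point of E maps to exactly one pixel.
    """

    n: int

    def __post_init__(self):
        _check_positive_int(self.n, "n", 2)

    @property
    def N(self) -> int:
        """Total number of pixels, ``n**2``."""
        return self.n * self.n

    @property
    def pixel_size(self) -> float:
        """Side length of one pixel in domain units, ``2 / n``."""
        return 2.0 / self.n

    def pixel_of(self, x, y):
        """Map point(s) in E to 0-based (row, col) pixel indices."""
        h = self.pixel_size
        c = np.clip(np.floor((np.asarray(x) - DOMAIN_MIN) / h).astype(np.int64), 0, self.n - 1)
        r = np.clip(np.floor((DOMAIN_MAX - np.asarray(y)) / h).astype(np.int64), 0, self.n - 1)
        return r, c

    def flat_index(self, r, c):
        """Row-major flat pixel index."""
        return np.asarray(r) * self.n + np.asarray(c)

    def centers(self):
        """Pixel-centre coordinates as two ``(n,)`` arrays (xs by column, ys by row)."""
        h = self.pixel_size
        xs = DOMAIN_MIN + (np.arange(self.n) + 0.5) * h
        ys = DOMAIN_MAX - (np.arange(self.n) + 0.5) * h
        return xs, ys


def build_grid(n: int) -> PixelGrid:
    """Create the pixel grid for an ``n x n`` discretisation of E."""
    return PixelGrid(n)


@dataclass(frozen=True)
class Ray:
    """One source->detector segment; ``id`` is its ordinal within a geometry."""

    source: tuple[float, float]
    detector: tuple[float, float]
    id: int = 0

    def __post_init__(self):
        if tuple(self.source) == tuple(self.detector):
            raise DegenerateRayError(f"ray {self.id}: source equals detector")


@dataclass(frozen=True)
class ScanGeometry:
    """An ordered set of rays, stored as ``(m, 2)`` endpoint arrays.

    ``kind`` is ``"one_by_one"`` (opposite-wall limited-angle system, field
    ``pkt`` set) or ``"parallel_beam"`` (fields ``num_angles`` and
    ``rays_per_angle`` set).  Ray order is deterministic: source-major /
    detector-minor for the (1 x 1) system, angle-major for parallel beams.
    """

    kind: str
    sources: np.ndarray = field(repr=False)
    detectors: np.ndarray = field(repr=False)
    pkt: int | None = None
    num_angles: int | None = None
    rays_per_angle: int | None = None

    def __len__(self) -> int:
        return self.sources.shape[0]

    def ray(self, i: int) -> Ray:
        return Ray(tuple(self.sources[i]), tuple(self.detectors[i]), id=i)

    def __iter__(self) -> Iterator[Ray]:
        for i in range(len(self)):
            yield self.ray(i)

    def to_csv(self, path) -> None:
        """Write ray endpoints as CSV: ray_id, source_x, source_y, detector_x, detector_y."""
        import pandas as pd

        pd.DataFrame(
            {
                "ray_id": np.arange(len(self)),
                "source_x": self.sources[:, 0],
                "source_y": self.sources[:, 1],
                "detector_x": self.detectors[:, 0],
                "detector_y": self.detectors[:, 1],
            }
        ).to_csv(path, index=False)


def make_one_by_one(pkt: int) -> ScanGeometry:
    """Build the limited-angle (1 x 1) geometry with ``pkt`` sources/detectors.

    Sources sit at ``(-1, y_k)`` and detectors at ``(+1, y_k)`` with
    ``y_k = -1 + 2k/(pkt-1)``, corners included.  Pairs are enumerated
    source-major; the first pair (both at ``y = -1``) and the last (both at
    ``y = +1``) run along the mesh and are rejected, leaving ``pkt**2 - 2``
    rays.
    """
    pkt = _check_positive_int(pkt, "pkt", 2)
    y = np.linspace(DOMAIN_MIN, DOMAIN_MAX, pkt)
    src_y = np.repeat(y, pkt)
    det_y = np.tile(y, pkt)
    keep = np.ones(pkt * pkt, dtype=bool)
    keep[0] = False       # source y=-1 -> detector y=-1, along the bottom edge
    keep[-1] = False      # source y=+1 -> detector y=+1, along the top edge
    sources = np.column_stack([np.full(keep.sum(), DOMAIN_MIN), src_y[keep]])
    detectors = np.column_stack([np.full(keep.sum(), DOMAIN_MAX), det_y[keep]])
    return ScanGeometry("one_by_one", sources, detectors, pkt=pkt)


def make_parallel_beam(num_angles: int, rays_per_angle: int) -> ScanGeometry:
    """Build a complete-data parallel-beam geometry.

    For each angle ``theta_j = j * 180 / num_angles`` degrees the rays run in
    direction ``(cos theta, sin theta)`` with perpendicular offsets placed
    cell-centred across ``[-sqrt(2), sqrt(2)]`` (the circumscribed-circle
    extent of E).  Each ray is clipped to E; offsets whose chord through E is
    empty are dropped, so the ray count may be below
    ``num_angles * rays_per_angle``.
    """
    num_angles = _check_positive_int(num_angles, "num_angles", 1)
    rays_per_angle = _check_positive_int(rays_per_angle, "rays_per_angle", 1)
    radius = math.sqrt(2.0)
    offsets = -radius + (np.arange(rays_per_angle) + 0.5) * (2.0 * radius / rays_per_angle)
    sources, detectors = [], []
    for j in range(num_angles):
        theta = j * math.pi / num_angles
        dx, dy = math.cos(theta), math.sin(theta)
        nx, ny = -dy, dx
        for t in offsets:
            px, py = t * nx, t * ny
            clipped = _clip_segment(px - 2.0 * dx, py - 2.0 * dy, px + 2.0 * dx, py + 2.0 * dy)
            if clipped is None:
                continue
            x0, y0, x1, y1 = clipped
            if math.hypot(x1 - x0, y1 - y0) < _EPS_CHORD:
                continue
            sources.append((x0, y0))
            detectors.append((x1, y1))
    return ScanGeometry(
        "parallel_beam",
        np.asarray(sources, dtype=float).reshape(-1, 2),
        np.asarray(detectors, dtype=float).reshape(-1, 2),
        num_angles=num_angles,
        rays_per_angle=rays_per_angle,
    )


def _clip_segment(x0, y0, x1, y1):
    """Liang-Barsky clip of a segment to E; returns endpoint coords or None."""
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - DOMAIN_MIN),
        (dx, DOMAIN_MAX - x0),
        (-dy, y0 - DOMAIN_MIN),
        (dy, DOMAIN_MAX - y0),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        r = q / p
        if p < 0.0:
            if r > t1:
                return None
            if r > t0:
                t0 = r
        else:
            if r < t0:
                return None
            if r < t1:
                t1 = r
    if t1 <= t0:
        return None
    return (x0 + t0 * dx, y0 + t0 * dy, x0 + t1 * dx, y0 + t1 * dy)


def chord_length(ray: Ray) -> float:
    """Euclidean length of the ray's chord through E (0 if it misses)."""
    clipped = _clip_segment(ray.source[0], ray.source[1], ray.detector[0], ray.detector[1])
    if clipped is None:
        return 0.0
    x0, y0, x1, y1 = clipped
    return math.hypot(x1 - x0, y1 - y0)


def _trace(sx: float, sy: float, ex: float, ey: float, grid: PixelGrid):
    """Siddon trace of one segment: (sorted pixel indices, intersection lengths)."""
    vx, vy = ex - sx, ey - sy
    seg = math.hypot(vx, vy)
    if seg == 0.0:
        raise DegenerateRayError("source equals detector")
    clipped = _clip_segment(sx, sy, ex, ey)
    if clipped is None:
        raise DegenerateRayError("ray does not intersect the domain")
    x0, y0, x1, y1 = clipped
    if math.hypot(x1 - x0, y1 - y0) < _EPS_CHORD:
        raise DegenerateRayError("zero-length chord through the domain")
    # parameter range of the chord on the original segment
    if abs(vx) >= abs(vy):
        t0, t1 = (x0 - sx) / vx, (x1 - sx) / vx
    else:
        t0, t1 = (y0 - sy) / vy, (y1 - sy) / vy

    n, h = grid.n, grid.pixel_size
    parts = [np.array([t0, t1])]
    interior = np.arange(1, n)
    if vx != 0.0:
        tc = ((DOMAIN_MIN + interior * h) - sx) / vx
        parts.append(tc[(tc > t0) & (tc < t1)])
    if vy != 0.0:
        tc = ((DOMAIN_MIN + interior * h) - sy) / vy
        parts.append(tc[(tc > t0) & (tc < t1)])
    ts = np.unique(np.concatenate(parts))
    lengths = np.diff(ts) * seg
    mids = (ts[:-1] + ts[1:]) * 0.5
    mx, my = sx + mids * vx, sy + mids * vy
    r, c = grid.pixel_of(mx, my)
    j = grid.flat_index(r, c)
    uj, inv = np.unique(j, return_inverse=True)
    vals = np.zeros(uj.shape[0])
    np.add.at(vals, inv, lengths)
    keep = vals > _EPS_CHORD
    return uj[keep], vals[keep]


def ray_row(ray: Ray, grid: PixelGrid) -> sp.csr_matrix:
    """Sparse ``1 x N`` row of ray/pixel intersection lengths.

    Raises :class:`DegenerateRayError` when the ray's chord through E is
    empty; generated geometries never produce such rays.
    """
    cols, vals = _trace(ray.source[0], ray.source[1], ray.detector[0], ray.detector[1], grid)
    return sp.csr_matrix((vals, (np.zeros_like(cols), cols)), shape=(1, grid.N))


@dataclass
class SystemMatrix:
    """The sparse non-negative ``m x N`` matrix ``A`` of ``A x = b``.

    Stored row-compressed (CSR): iterating a row's nonzeros is O(nnz) and
    column sums are one pass.  Row ``i`` holds the intersection lengths of
    ray ``i`` with each pixel; each row has at most ``2n - 1`` nonzeros and
    sums to the length of the ray's chord through E.
    """

    csr: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.csr.shape

    @property
    def m_rows(self) -> int:
        return self.csr.shape[0]

    @property
    def n_cols(self) -> int:
        return self.csr.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.csr.sum(axis=1)).ravel()

    def row_nnz(self) -> np.ndarray:
        return np.diff(self.csr.indptr)

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.csr.sum(axis=0)).ravel()


def build_system(geometry: ScanGeometry, grid: PixelGrid) -> SystemMatrix:
    """Assemble the system matrix, one row per ray in geometry order."""
    indptr = np.zeros(len(geometry) + 1, dtype=np.int64)
    idx_parts, val_parts = [], []
    src, det = geometry.sources, geometry.detectors
    for i in range(len(geometry)):
        try:
            cols, vals = _trace(src[i, 0], src[i, 1], det[i, 0], det[i, 1], grid)
        except DegenerateRayError as exc:
            raise DegenerateRayError(f"ray {i}: {exc}") from exc
        idx_parts.append(cols)
        val_parts.append(vals)
        indptr[i + 1] = indptr[i] + cols.shape[0]
    indices = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=np.int64)
    data = np.concatenate(val_parts) if val_parts else np.empty(0)
    csr = sp.csr_matrix((data, indices.astype(np.int32), indptr), shape=(len(geometry), grid.N))
    return SystemMatrix(csr)
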