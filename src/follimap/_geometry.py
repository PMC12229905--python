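"""Geometric primitives for the section simulator.

HFG regions are built as a *shrunken Voronoi mosaic*: quasi-uniform
seed points tile the section into convex Voronoi cells, and each cell
is contracted about its centroid so the retained area sums exactly to
the requested coverage.  This yields compact, irregular, mutually
disjoint blocks separated by interstitial bands — and, unlike
sequential rejection placement of rigid shapes, it reaches coverages
well above the ~55% jamming limit of random sequential adsorption.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .errors import CoverageInfeasibleError, DensityInfeasibleError

#: hard upper bound on cell shrink factor, keeps interstitial gaps open
_MAX_SHRINK = 0.995


def poisson_disk_seeds(
    n: int,
    width: float,
    height: float,
    rng: np.random.Generator,
    *,
    spacing_factor: float = 0.7,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Dart-throwing sampler of ``n`` points with a minimum spacing of
    ``spacing_factor * sqrt(area / n)``; raises after the attempt budget."""
    min_d2 = (spacing_factor * math.sqrt(width * height / n)) ** 2
    pts = np.empty((n, 2))
    k = 0
    for _ in range(max_attempts):
        if k == n:
            break
        p = rng.uniform((0.0, 0.0), (width, height))
        if k == 0 or np.min(np.sum((pts[:k] - p) ** 2, axis=1)) >= min_d2:
            pts[k] = p
            k += 1
    if k < n:
        raise CoverageInfeasibleError(
            f"placed only {k}/{n} group seeds in {max_attempts} attempts; "
            "the section is too small for the requested group layout"
        )
    return pts


def bounded_voronoi_cells(seeds: np.ndarray, width: float, height: float) -> list[Polygon]:
    """Voronoi cells of ``seeds`` clipped to the section rectangle.

    Seeds are mirrored across the four edges so every real cell is
    bounded and the tessellation tiles the rectangle exactly.
    """
    s = np.asarray(seeds, dtype=float)
    mirrored = np.vstack(
        [
            s,
            s * [-1.0, 1.0],
            [2.0 * width, 0.0] + s * [-1.0, 1.0],
            s * [1.0, -1.0],
            [0.0, 2.0 * height] + s * [1.0, -1.0],
        ]
    )
    vor = Voronoi(mirrored)
    rect = box(0.0, 0.0, width, height)
    cells = []
    for i in range(len(s)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        cells.append(poly.intersection(rect))
    return cells


def _scale_about(poly: Polygon, factor: float) -> Polygon:
    c = poly.centroid
    coords = np.asarray(poly.exterior.coords)
    scaled = (coords - [c.x, c.y]) * factor + [c.x, c.y]
    return Polygon(scaled)


def _ellipse_polygon(cx, cy, a, b, angle, n_vertices: int = 64) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ca, sa = math.cos(angle), math.sin(angle)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    return Polygon(np.column_stack([cx + ex * ca - ey * sa, cy + ex * sa + ey * ca]))


def _inscribed_ellipse(cell: Polygon, area: float) -> tuple[Polygon, float]:
    """Largest ellipse aligned with the cell's minimum rotated rectangle,
    capped at ``area``; returns the ellipse and its achieved area."""
    rect = cell.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    e0 = coords[1] - coords[0]
    e1 = coords[2] - coords[1]
    l0, l1 = np.linalg.norm(e0), np.linalg.norm(e1)
    angle = math.atan2(e0[1], e0[0])
    c = cell.centroid
    a0, b0 = l0 / 2.0, l1 / 2.0
    # shrink the inscribed ellipse until it is contained in the cell
    t = min(1.0, math.sqrt(area / (math.pi * a0 * b0)))
    for _ in range(60):
        ell = _ellipse_polygon(c.x, c.y, a0 * t, b0 * t, angle)
        if cell.contains(ell):
            return ell, math.pi * a0 * t * b0 * t
        t *= 0.96
    raise CoverageInfeasibleError("could not inscribe an ellipse in a Voronoi cell")


def shrink_cells_to_coverage(
    cells: list[Polygon],
    target_area: float,
    rng: np.random.Generator,
    *,
    shape: str = "blob",
    scale_jitter_sd: float = 0.2,
) -> list[Polygon]:
    """Contract each cell about its centroid so total retained area equals
    ``target_area`` (convex-blob mode: exact; ellipse mode: within 0.5%
    relative, else :class:`CoverageInfeasibleError`)."""
    areas = np.array([c.area for c in cells])
    total = areas.sum()
    if target_area >= total * _MAX_SHRINK**2:
        raise CoverageInfeasibleError(
            f"target HFG area {target_area:.3g} mm² is not reachable: cells "
            f"cover {total:.3g} mm² and groups must stay disjoint"
        )
    jitter = np.clip(rng.normal(1.0, scale_jitter_sd, len(cells)), 0.4, 1.8)
    # per-cell retained-area weights, renormalised to the exact target
    w = areas * jitter**2
    retained = target_area * w / w.sum()
    # cap cells that would exceed the shrink bound; redistribute the excess
    for _ in range(50):
        cap = areas * _MAX_SHRINK**2
        over = retained > cap
        if not over.any():
            break
        excess = (retained[over] - cap[over]).sum()
        retained[over] = cap[over]
        room = ~over
        if not room.any():
            raise CoverageInfeasibleError("coverage target exceeds disjoint-cell capacity")
        retained[room] += excess * retained[room] / retained[room].sum()

    if shape == "blob":
        return [
            _scale_about(cell, math.sqrt(r / a))
            for cell, a, r in zip(cells, areas, retained)
        ]
    if shape == "ellipse":
        groups, achieved = [], np.empty(len(cells))
        for i, (cell, r) in enumerate(zip(cells, retained)):
            ell, a = _inscribed_ellipse(cell, r)
            groups.append(ell)
            achieved[i] = a
        shortfall = target_area - achieved.sum()
        if shortfall > 0.005 * target_area:
            raise CoverageInfeasibleError(
                f"ellipse groups reach only {achieved.sum():.3g} of "
                f"{target_area:.3g} mm²; lower target_ratio_hfg or use "
                "group_shape='blob'"
            )
        return groups
    raise ValueError(f"unknown group_shape {shape!r}")


def rasterize_groups(
    groups: list[Polygon], shape_px: tuple[int, int], mm_per_pixel: float
) -> np.ndarray:
    """Label raster of disjoint convex group polygons.

    A pixel belongs to a group iff its centre lies inside the polygon
    (half-plane test against every edge; the mosaic cells and inscribed
    ellipses are convex by construction).
    """
    h, w = shape_px
    labels = np.zeros(shape_px, dtype=np.int32)
    for i, poly in enumerate(groups, start=1):
        v = np.asarray(poly.exterior.coords)[:-1]
        # enforce counter-clockwise orientation (shoelace sign) for the test
        area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        if area2 < 0:
            v = v[::-1]
        minx, miny = v.min(axis=0)
        maxx, maxy = v.max(axis=0)
        c0 = max(0, int(minx / mm_per_pixel - 0.5))
        c1 = min(w - 1, int(maxx / mm_per_pixel + 0.5))
        r0 = max(0, int(miny / mm_per_pixel - 0.5))
        r1 = min(h - 1, int(maxy / mm_per_pixel + 0.5))
        if c1 < c0 or r1 < r0:
            continue
        px = (np.arange(c0, c1 + 1) + 0.5) * mm_per_pixel
        py = (np.arange(r0, r1 + 1) + 0.5) * mm_per_pixel
        edges = np.roll(v, -1, axis=0) - v
        # cross(edge, pixel - vertex) >= 0 for all edges <=> inside (CCW)
        cx = edges[:, 0, None] * (py[None, :] - v[:, 1, None])
        cy = edges[:, 1, None] * (px[None, :] - v[:, 0, None])
        inside = np.all(cx[:, :, None] - cy[:, None, :] >= 0.0, axis=0)
        block = labels[r0 : r1 + 1, c0 : c1 + 1]
        block[inside] = i
    return labels


# ---------------------------------------------------------------------------
# minimum-separation point placement

_GRID_CAPACITY = 6  # max points min_sep apart that fit in a min_sep x min_sep cell


@njit(cache=True)
def _accept_batch(
    cand_x,
    cand_y,
    need,
    min_sep,
    cell,
    grid_count,
    grid_x,
    grid_y,
    out_x,
    out_y,
):  # pragma: no cover - exercised through SeparationGrid
    ny, nx = grid_count.shape
    m2 = min_sep * min_sep
    placed = 0
    for i in range(cand_x.shape[0]):
        if placed >= need:
            break
        x = cand_x[i]
        y = cand_y[i]
        cx = min(max(int(x / cell), 0), nx - 1)
        cy = min(max(int(y / cell), 0), ny - 1)
        ok = True
        for gy in range(max(0, cy - 1), min(ny, cy + 2)):
            for gx in range(max(0, cx - 1), min(nx, cx + 2)):
                for j in range(grid_count[gy, gx]):
                    dx = x - grid_x[gy, gx, j]
                    dy = y - grid_y[gy, gx, j]
                    if dx * dx + dy * dy < m2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            k = grid_count[cy, cx]
            if k < grid_x.shape[2]:
                grid_x[cy, cx, k] = x
                grid_y[cy, cx, k] = y
                grid_count[cy, cx] = k + 1
                out_x[placed] = x
                out_y[placed] = y
                placed += 1
    return placed


class SeparationGrid:
    """Incremental hard-core thinning: accepts candidate points one at a
    time, rejecting any closer than ``min_sep`` to an accepted point.
    State persists across calls so the constraint holds section-wide."""

    def __init__(self, width: float, height: float, min_sep: float):
        self.min_sep = float(min_sep)
        if self.min_sep > 0:
            self.cell = self.min_sep
            nx = max(1, int(math.ceil(width / self.cell)))
            ny = max(1, int(math.ceil(height / self.cell)))
            self._count = np.zeros((ny, nx), dtype=np.int32)
            self._gx = np.zeros((ny, nx, _GRID_CAPACITY), dtype=np.float64)
            self._gy = np.zeros_like(self._gx)

    def accept(
        self, cand_x: np.ndarray, cand_y: np.ndarray, need: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Greedily accept up to ``need`` candidates in order; returns the
        accepted coordinates (possibly fewer than ``need``)."""
        if self.min_sep <= 0:
            return cand_x[:need].copy(), cand_y[:need].copy()
        out_x = np.empty(need, dtype=np.float64)
        out_y = np.empty(need, dtype=np.float64)
        placed = _accept_batch(
            np.ascontiguousarray(cand_x, dtype=np.float64),
            np.ascontiguousarray(cand_y, dtype=np.float64),
            need,
            self.min_sep,
            self.cell,
            self._count,
            self._gx,
            self._gy,
            out_x,
            out_y,
        )
        return out_x[:placed], out_y[:placed]


def place_points_in_pixels(
    pixel_rows: np.ndarray,
    pixel_cols: np.ndarray,
    n: int,
    mm_per_pixel: float,
    grid: SeparationGrid,
    rng: np.random.Generator,
    *,
    side_sign: int = 0,
    axis_origin: tuple[float, float] = (0.0, 0.0),
    axis_angle: float = 0.0,
    max_rounds: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` points uniformly over the given pixels, subject to the
    section-wide minimum separation and (optionally) to lying on one side
    of an axis through ``axis_origin`` at ``axis_angle``.

    Points are jittered uniformly inside their pixel, so every returned
    point lies in a listed pixel (raster containment by construction).
    """
    if n == 0:
        return np.empty(0), np.empty(0)
    if pixel_rows.size == 0:
        raise DensityInfeasibleError("no pixels available to place points in")
    nrm = (-math.sin(axis_angle), math.cos(axis_angle))
    got_x: list[np.ndarray] = []
    got_y: list[np.ndarray] = []
    remaining = n
    for round_ in range(max_rounds):
        batch = 3 * remaining + 16
        idx = rng.integers(0, pixel_rows.size, batch)
        u = rng.uniform(0.0, 1.0, (batch, 2))
        x = (pixel_cols[idx] + u[:, 0]) * mm_per_pixel
        y = (pixel_rows[idx] + u[:, 1]) * mm_per_pixel
        if side_sign:
            d = (x - axis_origin[0]) * nrm[0] + (y - axis_origin[1]) * nrm[1]
            keep = d * side_sign > 0
            x, y = x[keep], y[keep]
        ax, ay = grid.accept(x, y, remaining)
        got_x.append(ax)
        got_y.append(ay)
        remaining -= ax.size
        if remaining == 0:
            return np.concatenate(got_x), np.concatenate(got_y)
    raise DensityInfeasibleError(
        f"could not place {n} points at the requested density under the "
        "minimum-separation constraint"
    )
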