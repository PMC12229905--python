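"""The four hair-follicle traits and quadrat-subdivision variance.

Traits of one section:

* ``THFD``      — total hair follicle density: all follicles divided by
  the whole section area (follicles/mm²).
* ``S/P``       — secondary-to-primary follicle count ratio.
* ``Ratio-HFG`` — area fraction occupied by hair-follicle-group blocks.
* ``Int-THFD``  — follicle density inside the HFG blocks only.

When every follicle centroid lies inside an HFG block the decomposition
``THFD = Int-THFD × Ratio-HFG`` is an arithmetic identity; sections
violating it (follicles outside the mask) are flagged, never silently
corrected.

The quadrat analysis splits a section into k equal-area cells
(k = 4, 9, 16, 25, …) and summarises the spread of per-cell THFD with
the coefficient of variation, quantifying how strongly the measured
density depends on the statistical area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annotation import FolliclePointSet, HFGMask

#: identity tolerance (follicles/mm², absolute) for THFD = Int-THFD × Ratio-HFG
IDENTITY_ATOL = 1e-9


def cv(values, ddof: int = 1) -> float:
    """Coefficient of variation in percent: SD / mean × 100.

    Uses the sample standard deviation (``ddof=1``) by default.  Fewer
    than two values, or a zero mean, make the statistic undefined and
    return ``nan``.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=ddof) / mean * 100.0)


@dataclass(frozen=True)
class TraitRecord:
    """The four traits of one section plus QC counts.

    Undefined ratios (no primaries; empty mask with follicles present)
    are reported as ``nan`` together with an explanatory entry in
    ``flags`` — they are never coerced to zero.
    """

    thfd: float
    sp_ratio: float
    ratio_hfg: float
    int_thfd: float
    n_primary: int
    n_secondary: int
    n_outside_mask: int
    section_area: float
    flags: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return self.n_primary + self.n_secondary

    def identity_residual(self) -> float:
        """|THFD − Int-THFD × Ratio-HFG|; meaningful when no follicle
        lies outside the mask."""
        return abs(self.thfd - self.int_thfd * self.ratio_hfg)


def compute_traits(points: FolliclePointSet, mask: HFGMask) -> TraitRecord:
    """Compute THFD, S/P, Ratio-HFG and Int-THFD for one section.

    Membership in the mask is decided by each point's centroid (the
    pixel under it), consistent with the extraction stage.  The section
    area is the full mask raster area.
    """
    area = mask.total_area
    hfg_area = mask.hfg_area
    n_p = points.n_primary
    n_s = points.n_secondary
    n_total = n_p + n_s
    inside = (
        int(np.count_nonzero(mask.label_at(points.x, points.y))) if n_total else 0
    )

    flags: list[str] = []
    thfd = n_total / area
    ratio_hfg = hfg_area / area
    if n_p > 0:
        sp = n_s / n_p
    else:
        sp = float("nan")
        flags.append("sp_ratio_undefined:no_primary_follicles")
    if hfg_area > 0:
        int_thfd = inside / hfg_area
    elif n_total == 0:
        int_thfd = 0.0
    else:
        int_thfd = float("nan")
        flags.append("int_thfd_undefined:zero_hfg_area")
    n_outside = n_total - inside
    if n_outside:
        flags.append(f"decomposition_identity_broken:{n_outside}_outside_mask")
    return TraitRecord(
        thfd=thfd,
        sp_ratio=sp,
        ratio_hfg=ratio_hfg,
        int_thfd=int_thfd,
        n_primary=n_p,
        n_secondary=n_s,
        n_outside_mask=n_outside,
        section_area=area,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class SubdivisionResult:
    """Per-cell THFD grid and its coefficient of variation for one
    equal-area √k×√k split of a section."""

    k: int
    cell_thfd: np.ndarray
    cv: float
    mean_cell_thfd: float

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.cell_thfd.shape


def subdivide_and_cv(
    points: FolliclePointSet,
    bounds: tuple[float, float] | None = None,
    k: int = 4,
) -> SubdivisionResult:
    """Split the section into k equal-area cells and compute per-cell THFD.

    ``k`` must be a perfect square ≥ 4.  The partition is exact in
    continuous mm coordinates; cells are half-open (a point on an
    interior edge belongs to the higher-index cell) with the last row
    and column closed, so every point lands in exactly one cell.  The
    mean per-cell THFD equals the global THFD by construction.
    """
    m = math.isqrt(k)
    if m * m != k or k < 4:
        raise ValueError("k must be a perfect square >= 4")
    if bounds is None:
        bounds = (points.width_mm, points.height_mm)
    w, h = bounds
    counts, _, _ = np.histogram2d(
        points.y,
        points.x,
        bins=[np.linspace(0.0, h, m + 1), np.linspace(0.0, w, m + 1)],
    )
    cell_area = w * h / k
    cell_thfd = counts / cell_area
    return SubdivisionResult(
        k=k,
        cell_thfd=cell_thfd,
        cv=cv(cell_thfd),
        mean_cell_thfd=len(points) / (w * h),
    )


def subdivision_series(
    points: FolliclePointSet,
    bounds: tuple[float, float] | None = None,
    ks: tuple[int, ...] = (4, 9, 16, 25),
) -> dict[int, SubdivisionResult]:
    """Quadrat analysis over several split sizes (default 2×2 … 5×5)."""
    return {k: subdivide_and_cv(points, bounds, k) for k in ks}
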