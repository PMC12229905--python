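"""Body-wide spatial mapping of follicle traits.

Sections are sampled at fixed anatomical sites — 14 whole-body sites or
32 body-side sites on a radial grid — and their traits are mapped onto
a 2-D schematic body layout: inverse-distance-weighted heatmaps, site
ranking, representative-site selection and breed comparison by per-site
one-way ANOVA plus correlation of site-mean profiles.

The shipped site layouts are schematic reconstructions (dorsal sites
high on the schematic, abdominal sites low); they are coordinates for
visualisation and interpolation, not measured goat anatomy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.stats import f as f_dist

from .simulate import (
    BreedPreset,
    PRESETS,
    derive_section_seeds,
    simulate_section,
)
from .traits import TraitRecord, compute_traits

_LAYOUT_FILES = {
    "whole_body_14": "layout_whole_body_14.csv",
    "body_side_32": "layout_body_side_32.csv",
}

#: Schematic per-site THFD multipliers for the 14 whole-body sites.
#: Mean exactly 1.0; dorsal/scapular sites elevated, abdominal sites
#: (#13, #14) lowest, and site #6 at the grand mean so it is the
#: representative site by construction.
DEFAULT_SITE_PROFILE_14: dict[int, float] = {
    1: 1.18, 2: 1.15, 3: 1.12, 4: 1.20, 5: 1.05, 6: 1.00, 7: 0.93,
    8: 1.06, 9: 0.96, 10: 1.04, 11: 0.92, 12: 0.88, 13: 0.78, 14: 0.73,
}


def load_layout(name: str = "whole_body_14") -> pd.DataFrame:
    """Load a shipped site layout (columns site_id, x, y, region_label)."""
    if name not in _LAYOUT_FILES:
        raise KeyError(f"unknown layout {name!r}; options: {sorted(_LAYOUT_FILES)}")
    ref = resources.files("follimap.data").joinpath(_LAYOUT_FILES[name])
    with ref.open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class SiteRecord:
    """Traits of one section at one anatomical site of one animal."""

    site_id: int
    coord: tuple[float, float]
    animal_id: str
    breed: str
    traits: TraitRecord


@dataclass
class BodyMap:
    """Interpolated 2-D trait field over a schematic body layout."""

    layout: pd.DataFrame
    site_means: dict[int, float]
    grid: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    hull_mask: np.ndarray = field(repr=False, default=None)


def _site_mean_table(records: Iterable[SiteRecord], trait: str) -> dict[int, float]:
    vals: dict[int, list[float]] = {}
    for rec in records:
        vals.setdefault(rec.site_id, []).append(getattr(rec.traits, trait))
    return {s: float(np.mean(v)) for s, v in sorted(vals.items())}


def interpolate_map(
    records: Sequence[SiteRecord],
    grid_resolution: int = 100,
    trait: str = "thfd",
    power: float = 2.0,
) -> BodyMap:
    """Inverse-distance-weighted interpolation of per-site mean traits.

    The field is exact at site coordinates and masked (NaN) outside the
    convex hull of the sites — the map smooths between sampled sites,
    it does not extrapolate.  Requires at least three non-collinear
    sites.
    """
    site_means = _site_mean_table(records, trait)
    coords = {}
    layout_rows = []
    for rec in records:
        coords[rec.site_id] = rec.coord
        layout_rows.append((rec.site_id, *rec.coord))
    layout = (
        pd.DataFrame(sorted(set(layout_rows)), columns=["site_id", "x", "y"])
        .sort_values("site_id")
        .reset_index(drop=True)
    )
    pts = layout[["x", "y"]].to_numpy(float)
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("interpolation needs at least 3 non-collinear sites")
    vals = np.array([site_means[s] for s in layout["site_id"]])

    xs = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_resolution)
    ys = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_resolution)
    gx, gy = np.meshgrid(xs, ys)
    q = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((q[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    field_flat = np.empty(len(q))
    at_node = d < 1e-12
    exact = at_node.any(axis=1)
    field_flat[exact] = vals[np.argmax(at_node[exact], axis=1)]
    wgt = 1.0 / d[~exact] ** power
    field_flat[~exact] = (wgt * vals).sum(axis=1) / wgt.sum(axis=1)

    hull = Delaunay(pts)
    inside = hull.find_simplex(q) >= 0
    field_flat[~inside] = np.nan
    grid = field_flat.reshape(gx.shape)
    return BodyMap(
        layout=layout,
        site_means=site_means,
        grid=grid,
        grid_x=xs,
        grid_y=ys,
        hull_mask=inside.reshape(gx.shape),
    )


def idw_at(bodymap: BodyMap, x: float, y: float, power: float = 2.0) -> float:
    """Evaluate the inverse-distance-weighted field at one point."""
    pts = bodymap.layout[["x", "y"]].to_numpy(float)
    vals = np.array([bodymap.site_means[s] for s in bodymap.layout["site_id"]])
    d = np.sqrt(((pts - [x, y]) ** 2).sum(axis=1))
    if (d < 1e-12).any():
        return float(vals[np.argmin(d)])
    w = 1.0 / d**power
    return float((w * vals).sum() / w.sum())


def rank_sites(site_means: Mapping[int, float]) -> list[int]:
    """Site ids ordered by descending trait value; ties keep site-id order."""
    if not site_means:
        raise ValueError("need at least one site")
    return [s for s, _ in sorted(site_means.items(), key=lambda kv: (-kv[1], kv[0]))]


def representative_site(site_means: Mapping[int, float]) -> int:
    """The site whose mean is closest to the grand mean over sites
    (ties broken toward the smaller site id)."""
    if len(site_means) < 2:
        raise ValueError("need at least two sites")
    grand = float(np.mean(list(site_means.values())))
    return min(site_means, key=lambda s: (abs(site_means[s] - grand), s))


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from the standard sums of squares.

    Returns (F, p).  Complete separation with zero within-group
    variance yields ``F = inf`` and a p-value at the numerical floor;
    identical constant groups yield ``F = nan, p = 1``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = sum(g.size for g in groups)
    grand = sum(g.sum() for g in groups) / n
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return float("nan"), 1.0
        return float("inf"), float(np.finfo(float).tiny)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(f_dist.sf(F, df_b, df_w))


@dataclass
class BreedComparison:
    """Per-site ANOVA, breed-profile correlations and grand means."""

    per_site_anova: pd.DataFrame
    pattern_correlations: pd.DataFrame
    grand_means: pd.DataFrame
    qc_notes: list[str]


def compare_breeds(records: Sequence[SiteRecord], trait: str = "thfd") -> BreedComparison:
    """Compare breeds site by site and as whole-body profiles.

    Per site, a one-way ANOVA tests for a breed effect on the trait
    (sites where any breed has fewer than two animals are skipped with
    a QC note).  Breed pairs are additionally compared by the Pearson
    correlation of their site-mean profiles over the shared sites, and
    per-breed grand means of all four traits are reported.
    """
    breeds = sorted({r.breed for r in records})
    if len(breeds) < 2:
        raise ValueError("need records from at least two breeds")
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "breed": [r.breed for r in records],
            "animal_id": [r.animal_id for r in records],
            "value": [getattr(r.traits, trait) for r in records],
        }
    )
    qc: list[str] = []
    rows = []
    for site, sub in df.groupby("site_id"):
        groups = [sub.loc[sub.breed == b, "value"].to_numpy() for b in breeds]
        if any(g.size < 2 for g in groups):
            qc.append(f"site {site}: skipped (fewer than 2 animals in a breed)")
            continue
        F, p = anova_oneway(groups)
        rows.append({"site_id": site, "F": F, "p": p})
    per_site = pd.DataFrame(rows, columns=["site_id", "F", "p"])

    profiles = df.groupby(["breed", "site_id"])["value"].mean().unstack()
    corr_rows = []
    for b1, b2 in itertools.combinations(breeds, 2):
        common = profiles.loc[[b1, b2]].dropna(axis=1)
        r = float(np.corrcoef(common.loc[b1], common.loc[b2])[0, 1])
        corr_rows.append({"breed_a": b1, "breed_b": b2, "pearson_r": r})
    pattern = pd.DataFrame(corr_rows)

    gm_rows = []
    for b in breeds:
        recs = [r for r in records if r.breed == b]
        gm_rows.append(
            {
                "breed": b,
                "thfd": float(np.mean([r.traits.thfd for r in recs])),
                "sp_ratio": float(np.nanmean([r.traits.sp_ratio for r in recs])),
                "ratio_hfg": float(np.mean([r.traits.ratio_hfg for r in recs])),
                "int_thfd": float(np.nanmean([r.traits.int_thfd for r in recs])),
            }
        )
    grand = pd.DataFrame(gm_rows)
    return BreedComparison(per_site, pattern, grand, qc)


def simulate_breed_panel(
    preset: BreedPreset | str,
    n_animals: int,
    seed: int = 0,
    *,
    layout: pd.DataFrame | None = None,
    site_profile: Mapping[int, float] | None = None,
    section_area_mm2: float = 9.26,
    mm_per_pixel: float = 0.01,
    **config_overrides,
) -> list[SiteRecord]:
    """Simulate a whole-body sampling campaign for one breed.

    Each animal contributes one section per layout site; the site
    profile multiplies the preset's Int-THFD so the planted whole-body
    pattern (dorsal high, abdominal low) is shared across breeds.  The
    default raster scale is coarser than the rendering default because
    no image is rendered here — only mask areas and point membership
    are needed.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if layout is None:
        layout = load_layout("whole_body_14")
    if site_profile is None:
        site_profile = DEFAULT_SITE_PROFILE_14 if len(layout) == 14 else {}
    sites = list(layout.itertuples(index=False))
    seeds = derive_section_seeds(seed, n_animals * len(sites))
    records = []
    it = iter(seeds)
    for a in range(n_animals):
        animal_id = f"{preset.name}-{a + 1:02d}"
        for row in sites:
            mult = site_profile.get(row.site_id, 1.0)
            cfg = preset.to_config(
                section_area_mm2,
                seed=next(it),
                target_int_thfd=preset.int_thfd * mult,
                mm_per_pixel=mm_per_pixel,
                **config_overrides,
            )
            section = simulate_section(cfg)
            records.append(
                SiteRecord(
                    site_id=int(row.site_id),
                    coord=(float(row.x), float(row.y)),
                    animal_id=animal_id,
                    breed=preset.name,
                    traits=compute_traits(section.points, section.mask),
                )
            )
    return records
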