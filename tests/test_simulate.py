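"""Generator contracts: coverage, calibration, asymmetry, determinism."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from follimap import (
    CoverageInfeasibleError,
    FolliclePointSet,
    GroundTruthSection,
    HFGMask,
    PRESETS,
    RenderScaleError,
    SimulationConfig,
    generate_hfg_regions,
    populate_follicles,
    render_annotation_image,
    simulate_section,
    simulate_site_panel,
)
from follimap.errors import ConfigError
from follimap.simulate import DERIVED, PAPER


@pytest.mark.parametrize("preset", ["IMCG", "DBG", "F1"])
def test_region_coverage_hits_target(preset):
    """Achieved HFG coverage matches the preset target within 2% absolute."""
    cfg = PRESETS[preset].to_config(9.26, seed=7)
    mask = generate_hfg_regions(cfg)
    assert abs(mask.coverage - cfg.target_ratio_hfg) < 0.02
    assert mask.n_groups >= 1


def test_single_tiny_group_degenerate_coverage():
    cfg = SimulationConfig(
        section_width=3.0, section_height=3.0, target_ratio_hfg=0.02,
        target_int_thfd=70.0, target_sp_ratio=10.0, seed=5,
    )
    mask = generate_hfg_regions(cfg)
    assert mask.n_groups == 1
    assert mask.hfg_area == pytest.approx(0.02 * 9.0, rel=0.05)


def test_coverage_above_disjointness_limit_fails():
    cfg = SimulationConfig(
        section_width=3.0, section_height=3.0, target_ratio_hfg=0.8,
        target_int_thfd=70.0, target_sp_ratio=10.0, seed=1,
    )
    with pytest.raises(CoverageInfeasibleError):
        generate_hfg_regions(cfg)


def test_ellipse_groups_cap_coverage():
    """Inscribed-ellipse groups support moderate coverage but refuse
    targets beyond what disjoint inscribed ellipses can reach."""
    base = dict(
        section_width=3.04, section_height=3.04, target_int_thfd=70.0,
        target_sp_ratio=11.6, group_shape="ellipse", seed=7,
    )
    mask = generate_hfg_regions(SimulationConfig(target_ratio_hfg=0.30, **base))
    assert mask.coverage == pytest.approx(0.30, abs=0.02)
    with pytest.raises(CoverageInfeasibleError):
        generate_hfg_regions(SimulationConfig(target_ratio_hfg=0.70, **base))


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(section_width=3, section_height=3, target_ratio_hfg=1.2,
                         target_int_thfd=70, target_sp_ratio=10)
    with pytest.raises(ConfigError):
        SimulationConfig(section_width=-1, section_height=3, target_ratio_hfg=0.5,
                         target_int_thfd=70, target_sp_ratio=10)


def test_determinism_bit_identical():
    """Identical config + seed regenerates masks, points and images exactly."""
    cfg = PRESETS["DBG"].to_config(4.0, seed=11)
    a, b = simulate_section(cfg), simulate_section(cfg)
    assert np.array_equal(a.mask.labels, b.mask.labels)
    assert np.array_equal(a.points.x, b.points.x)
    assert np.array_equal(a.points.cls, b.points.cls)
    assert np.array_equal(render_annotation_image(a), render_annotation_image(b))


def test_point_placement_calibration(imcg_section):
    """Realized Int-THFD within 3% relative, S/P within 10% relative,
    every point on an HFG pixel, and per-group primaries in range."""
    sec = imcg_section
    cfg = sec.config_used
    stats = sec.realized_stats()
    assert stats["int_thfd"] == pytest.approx(cfg.target_int_thfd, rel=0.03)
    assert stats["sp_ratio"] == pytest.approx(cfg.target_sp_ratio, rel=0.10)
    labels_under = sec.mask.label_at(sec.points.x, sec.points.y)
    assert np.all(labels_under > 0)
    assert np.array_equal(labels_under, sec.points.group_id)
    lo, hi = cfg.primaries_per_group_range
    for n_p, _ in sec.per_group_counts:
        assert lo <= n_p <= hi


def test_min_point_separation(imcg_section):
    pts = imcg_section.points
    tree = cKDTree(np.column_stack([pts.x, pts.y]))
    d, _ = tree.query(np.column_stack([pts.x, pts.y]), k=2)
    assert d[:, 1].min() >= imcg_section.config_used.min_point_separation


def test_zero_sp_ratio_gives_all_primaries():
    cfg = PRESETS["IMCG"].to_config(4.0, seed=3, target_sp_ratio=0.0)
    sec = simulate_section(cfg)
    assert sec.points.n_secondary == 0
    assert sec.points.n_primary == len(sec.points) > 0


def test_strict_asymmetry_is_linearly_separable():
    """At asymmetry 1, each group's primaries and secondaries lie on
    opposite sides of some axis through the group centroid."""
    sec = simulate_section(PRESETS["IMCG"].to_config(9.26, seed=9,
                                                     asymmetry_strength=1.0))
    pts, mask = sec.points, sec.mask
    s = mask.mm_per_pixel
    for g in mask.group_ids:
        rows, cols = np.where(mask.labels == g)
        cx, cy = (cols.mean() + 0.5) * s, (rows.mean() + 0.5) * s
        sel = pts.group_id == g
        P = np.column_stack([pts.x[sel], pts.y[sel]])[pts.cls[sel] == "P"]
        S = np.column_stack([pts.x[sel], pts.y[sel]])[pts.cls[sel] == "S"]
        separable = False
        for phi in np.linspace(0, 2 * np.pi, 1440, endpoint=False):
            n = np.array([-np.sin(phi), np.cos(phi)])
            dP, dS = (P - [cx, cy]) @ n, (S - [cx, cy]) @ n
            if (dP.size == 0 or dP.min() > 0) and (dS.size == 0 or dS.max() < 0):
                separable = True
                break
        assert separable


def test_render_contract(imcg_section):
    """Exactly the four palette colours; dot pixel-blobs disjoint from
    each other; white fraction tracks mask coverage."""
    img = render_annotation_image(imcg_section)
    colors = {tuple(c) for c in np.unique(img.reshape(-1, 3), axis=0)}
    assert colors == {(0, 0, 0), (255, 255, 255), (0, 255, 0), (0, 0, 255)}
    white_frac = np.mean(np.all(img == 255, axis=-1))
    dot_frac = np.mean(np.all(img == (0, 255, 0), axis=-1)) + np.mean(
        np.all(img == (0, 0, 255), axis=-1)
    )
    # dots overpaint some block pixels, so pure white brackets coverage
    assert white_frac <= imcg_section.mask.coverage + 0.01
    assert imcg_section.mask.coverage <= white_frac + dot_frac + 0.01


def test_render_scale_too_coarse_fails(imcg_section):
    with pytest.raises(RenderScaleError):
        render_annotation_image(imcg_section, mm_per_pixel=0.01, dot_radius_px=2)


def test_render_empty_section_is_pure_background():
    cfg = SimulationConfig(section_width=1.0, section_height=1.0,
                           target_ratio_hfg=0.5, target_int_thfd=1.0,
                           target_sp_ratio=1.0)
    empty = GroundTruthSection(
        points=FolliclePointSet(x=[], y=[], cls=[], group_id=[],
                                width_mm=1.0, height_mm=1.0),
        mask=HFGMask(labels=np.zeros((250, 250), dtype=np.int32),
                     mm_per_pixel=0.004),
        config_used=cfg,
        per_group_counts=[],
    )
    img = render_annotation_image(empty)
    assert np.all(img == 0)


def test_site_panel_reproducible_and_independent():
    panel = simulate_site_panel("F1", 3, 4.0, seed=21)
    again = simulate_site_panel("F1", 3, 4.0, seed=21)
    assert len(panel) == 3
    seeds = {sec.config_used.seed for sec in panel}
    assert len(seeds) == 3
    for a, b in zip(panel, again):
        assert np.array_equal(a.points.x, b.points.x)
    areas = [sec.mask.total_area for sec in panel]
    assert all(a == pytest.approx(4.0, rel=0.01) for a in areas)


def test_preset_provenance_tags():
    assert PRESETS["IMCG"].provenance["sp_ratio"] == PAPER
    for breed in ("DBG", "F1"):
        assert PRESETS[breed].provenance["sp_ratio"] == DERIVED
        assert PRESETS[breed].provenance["ratio_hfg"] == PAPER
        assert PRESETS[breed].provenance["int_thfd"] == PAPER


def test_populate_rejects_empty_mask():
    cfg = SimulationConfig(section_width=1.0, section_height=1.0,
                           target_ratio_hfg=0.5, target_int_thfd=10.0,
                           target_sp_ratio=1.0)
    mask = HFGMask(labels=np.zeros((100, 100), dtype=np.int32), mm_per_pixel=0.01)
    with pytest.raises(ValueError):
        populate_follicles(mask, cfg)
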