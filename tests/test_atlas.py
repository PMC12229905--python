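"""Spatial mapping, ranking, representative site and breed comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f_oneway

from follimap import (
    DEFAULT_SITE_PROFILE_14,
    SiteRecord,
    TraitRecord,
    anova_oneway,
    compare_breeds,
    interpolate_map,
    load_layout,
    rank_sites,
    representative_site,
    simulate_breed_panel,
)
from follimap.atlas import idw_at


def _rec(site_id, x, y, thfd, animal="a1", breed="IMCG"):
    tr = TraitRecord(thfd=thfd, sp_ratio=10.0, ratio_hfg=0.5, int_thfd=2 * thfd,
                     n_primary=1, n_secondary=10, n_outside_mask=0,
                     section_area=9.26)
    return SiteRecord(site_id=site_id, coord=(x, y), animal_id=animal,
                      breed=breed, traits=tr)


class TestLayouts:
    def test_shipped_layouts_are_valid(self):
        for name, n in (("whole_body_14", 14), ("body_side_32", 32)):
            layout = load_layout(name)
            assert len(layout) == n
            assert layout.site_id.is_unique
            coords = list(zip(layout.x, layout.y))
            assert len(set(coords)) == n

    def test_site_profile_mean_is_one(self):
        vals = np.array(list(DEFAULT_SITE_PROFILE_14.values()))
        assert vals.mean() == pytest.approx(1.0)
        ranked = sorted(DEFAULT_SITE_PROFILE_14,
                        key=DEFAULT_SITE_PROFILE_14.get)
        assert set(ranked[:2]) == {13, 14}


class TestInterpolation:
    def test_constant_sites_give_constant_field(self):
        recs = [_rec(i, x, y, 5.0) for i, (x, y) in
                enumerate([(0, 0), (1, 0), (0, 1), (1, 1)], start=1)]
        bm = interpolate_map(recs, grid_resolution=21)
        inside = bm.grid[~np.isnan(bm.grid)]
        np.testing.assert_allclose(inside, 5.0)

    def test_exact_at_site_coordinates(self):
        recs = [_rec(1, 0, 0, 1.0), _rec(2, 1, 0, 4.0), _rec(3, 0.2, 1, 9.0)]
        bm = interpolate_map(recs, grid_resolution=11)
        for rec, v in zip(recs, (1.0, 4.0, 9.0)):
            assert idw_at(bm, *rec.coord) == pytest.approx(v)

    def test_field_masked_outside_hull(self):
        recs = [_rec(1, 0, 0, 1.0), _rec(2, 1, 0, 2.0), _rec(3, 0, 1, 3.0)]
        bm = interpolate_map(recs, grid_resolution=31)
        assert np.isnan(bm.grid[-1, -1])  # corner opposite the triangle
        assert np.isfinite(bm.grid).any()

    def test_planted_gradient_is_recovered_monotone(self):
        """Sites on a 4x8 lattice with value 2x: the interpolated field
        increases along x and matches the planted plane at the nodes."""
        recs = []
        sid = 1
        for ix in range(8):
            for iy in range(4):
                recs.append(_rec(sid, float(ix), float(iy), 2.0 * ix))
                sid += 1
        bm = interpolate_map(recs, grid_resolution=33)
        for rec in recs:
            planted = 2.0 * rec.coord[0]
            assert idw_at(bm, *rec.coord) == pytest.approx(planted)
        mid_row = bm.grid[16, :]
        valid = ~np.isnan(mid_row)
        diffs = np.diff(mid_row[valid])
        assert np.all(diffs > -1e-6)

    def test_too_few_or_collinear_sites_rejected(self):
        with pytest.raises(ValueError):
            interpolate_map([_rec(1, 0, 0, 1.0), _rec(2, 1, 0, 2.0)])
        collinear = [_rec(i, float(i), 0.0, 1.0) for i in range(1, 5)]
        with pytest.raises(ValueError):
            interpolate_map(collinear)


class TestRanking:
    def test_planted_whole_body_pattern_ranks_13_14_last(self):
        means = {s: 41.0 * m for s, m in DEFAULT_SITE_PROFILE_14.items()}
        order = rank_sites(means)
        assert set(order[-2:]) == {13, 14}
        assert order[0] == 4  # highest planted multiplier

    def test_single_site_and_ties(self):
        assert rank_sites({3: 1.0}) == [3]
        assert rank_sites({2: 1.0, 1: 1.0, 5: 1.0}) == [1, 2, 5]


class TestRepresentativeSite:
    def test_planted_profile_selects_site_6(self):
        means = {s: 41.0 * m for s, m in DEFAULT_SITE_PROFILE_14.items()}
        assert representative_site(means) == 6

    def test_tie_breaks_to_smaller_id(self):
        assert representative_site({1: 9.0, 2: 11.0}) == 1
        assert representative_site({9: 10.0, 4: 30.0}) == 4

    def test_middle_of_three(self):
        assert representative_site({1: 10.0, 2: 20.0, 3: 30.0}) == 2

    @settings(deadline=None, max_examples=200)
    @given(st.dictionaries(st.integers(1, 50),
                           st.floats(0.0, 100.0), min_size=2, max_size=14))
    def test_matches_exhaustive_argmin(self, means):
        grand = np.mean(list(means.values()))
        best = min(
            means, key=lambda s: (abs(means[s] - grand), s)
        )
        assert representative_site(means) == best


class TestAnova:
    def test_matches_reference_on_random_designs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            k = rng.integers(2, 5)
            n = rng.integers(3, 10)
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, n) for _ in range(k)]
            F, p = anova_oneway(groups)
            ref = f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, abs=1e-8, rel=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8, rel=1e-8)

    def test_complete_separation_guarded(self):
        F, p = anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert np.isinf(F)
        assert 0 < p < 1e-300

    def test_identical_constant_groups(self):
        F, p = anova_oneway([np.array([3.0, 3.0]), np.array([3.0, 3.0])])
        assert np.isnan(F)
        assert p == 1.0

    def test_rejects_undersized_groups(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0]), np.array([2.0, 3.0])])


class TestCompareBreeds:
    def test_undersized_site_skipped_with_note(self):
        recs = []
        for a in range(2):
            for b, breed in enumerate(["IMCG", "DBG"]):
                recs.append(_rec(1, 0, 0, 40.0 + a + b, animal=f"{breed}{a}",
                                 breed=breed))
        # site 2 has only one DBG animal
        recs.append(_rec(2, 1, 1, 44.0, animal="IMCG0", breed="IMCG"))
        recs.append(_rec(2, 1, 1, 41.0, animal="IMCG1", breed="IMCG"))
        recs.append(_rec(2, 1, 1, 39.0, animal="DBG0", breed="DBG"))
        rep = compare_breeds(recs)
        assert list(rep.per_site_anova.site_id) == [1]
        assert any("site 2" in n for n in rep.qc_notes)

    def test_single_breed_rejected(self):
        recs = [_rec(1, 0, 0, 40.0, animal=f"a{i}") for i in range(3)]
        with pytest.raises(ValueError):
            compare_breeds(recs)

    def test_simulated_panels_recover_breed_contrast(self):
        """IMCG vs DBG panels (2 animals each, quick) show higher IMCG
        THFD at almost every site and near-unit pattern correlation."""
        ra = simulate_breed_panel("IMCG", 2, seed=5)
        rb = simulate_breed_panel("DBG", 2, seed=6)
        rep = compare_breeds(ra + rb)
        gm = rep.grand_means.set_index("breed")
        assert gm.loc["IMCG", "thfd"] > gm.loc["DBG", "thfd"]
        assert rep.pattern_correlations.pearson_r.iloc[0] > 0.9
        assert (rep.per_site_anova.p < 0.05).mean() > 0.8
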