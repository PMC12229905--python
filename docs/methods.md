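# Methods

## Generative model of a skin section

A simulated section is a rectangle (default square) observed at a
physical scale `mm_per_pixel` (default 0.004 mm/px for rendered
annotations). It is built in two stages.

**HFG regions — a shrunken Voronoi mosaic.** Real hair-follicle groups
tile the skin as compact, irregular blocks separated by interstitial
bands. The generator reproduces this by (1) drawing `n` quasi-uniform
seed points by dart throwing (minimum spacing 0.7·√(A/n), bounded
attempt budget, explicit `CoverageInfeasibleError` on exhaustion),
(2) taking their Voronoi cells clipped to the section via mirrored
seeds, and (3) contracting each convex cell about its centroid so the
retained areas — jittered per cell by the configured relative spread
and renormalised — sum *exactly* to `target_ratio_hfg × section area`.
Non-overlap and containment hold by construction, and the achieved
coverage matches the target up to raster quantisation (≪ 2% absolute).
We chose this construction over sequential rejection placement of
rigid shapes because random sequential adsorption jams near ~55% area
fraction, below the ~59% coverage of cashmere-goat skin; a tessellation
contracted to the target has no such ceiling (we cap targets at 0.75 so
interstitial bands remain). `group_shape="ellipse"` instead inscribes
an area-capped ellipse in each cell, which supports only moderate
coverage and raises the same infeasibility error beyond it.

The number of groups is `target_ratio_hfg·A / (π·group_radius_mean²)`.
Preset configs derive `group_radius_mean` from the calibration targets
so the expected primaries per group sits at the midpoint of
`primaries_per_group_range` (default 2–5, "several"): mean group area
= 3.5·(1+S/P)/Int-THFD. This keeps the per-group primary range and the
global S/P and density targets simultaneously satisfiable for all
three breed presets.

**Follicles — asymmetric marked points.** The total count is
`round(Int-THFD × mask area)` (realised density error ≤ 0.5/N); the
primary count is `round(N/(1+S/P))`. Primaries are allocated to groups
proportionally to area (largest-remainder) clamped to
`primaries_per_group_range` with total-preserving repair; if the range
cannot accommodate the totals (e.g. S/P = 0), the density and ratio
targets take precedence. Each group draws a random axis through its
centroid; `ceil(asymmetry_strength · n)` of its primaries are placed on
one side and the same fraction of secondaries on the other
(`asymmetry_strength=1` ⇒ strict linear separability; default 0.9).
Points are sampled uniformly over the group's labelled pixels (jittered
within the pixel, so raster containment is exact) and thinned by a
section-wide hard-core constraint `min_point_separation` (default
0.03 mm, a realistic follicle calibre) using an incremental grid
accepted in a numba-compiled loop; candidate streams come from the
seeded NumPy generator, so output is bit-reproducible for a fixed seed.

**Rendering.** HFG pixels are painted white, then each follicle is a
filled dot (radius 2 px) of its class colour (primary green, secondary
blue) centred on the pixel containing it — the same convention as
manually marked clean images. Rendering refuses scales at which
`dot_radius ≥ min_point_separation/(2·mm_per_pixel)`, which guarantees
dots stay disjoint and the extraction round trip is exact.

## Extraction

Dots: connected components (8-connectivity) of each dot colour; one
point per component at its pixel centroid; components below 3 px are
dropped and counted in QC; off-palette pixels above a threshold raise a
warning. Blocks: 4-connected components of the block colour; dot
pixels connected to a block count as block area (dots are drawn on top
of blocks), while dot components touching no block are not groups.
Exact RGB matching is the default (clean digital annotations); a
per-channel tolerance is available for compressed inputs. Downstream
membership (Int-THFD, containment) is decided by the point centroid's
pixel, consistently in both the generator and the extractor.

## Traits and quadrat analysis

`compute_traits` uses the full raster area as the section area.
Undefined ratios (no primaries; zero mask area with follicles present)
are `nan` plus an explanatory flag — never silent zeros. The
decomposition identity is checked per section and reported, not
repaired.

`subdivide_and_cv` partitions in continuous mm coordinates into
√k×√k equal-area cells (k a perfect square ≥ 4); interior boundaries
are half-open toward the higher-index cell and the outer edge is
closed, so each point lands in exactly one cell. CV = sample SD
(ddof = 1) / mean × 100; the convention is configurable and documented
because published CV values rarely state it. `mean_cell_thfd` is
computed as total count / section area, which the equal-area partition
makes identical to the mean of per-cell densities.

## Body atlas

Site layouts (14 whole-body sites; 32 body-side sites on four rings of
eight) are schematic reconstructions shipped as CSV — coordinates for
visualisation and interpolation, not measured anatomy. The default
whole-body profile multiplies Int-THFD per site (mean exactly 1.0),
planting the dorsal-high/abdominal-low gradient with sites 13–14 lowest
and site 6 at the grand mean. Interpolation is inverse-distance
weighting with power 2, exact at nodes (nearest-node override inside
1e-12) and masked to the convex hull — a smoothing visualisation, not a
spatial model. The per-site breed test is one-way fixed-effects ANOVA
implemented from the sums of squares (p from the F distribution;
complete separation reports F = ∞ with p at the numerical floor);
whole-body patterns are compared by Pearson correlation of site-mean
profiles. Simulated panels place no animal random effect: animal means
differ only through section-level sampling noise, which keeps the
same-preset null exactly calibrated.

## Problem sizes and numerical choices

Default study conditions follow the reference design: 9.26 mm²
sections, 20-section calibration panels, 160 mm² sections for the
quadrat analysis, and 5-animal × 14-site panels per breed for breed
comparison (100 Monte-Carlo replicates in the acceptance suite).
Analysis-only simulations (no rendered image) use a 0.01 mm/px raster:
group areas and point membership are insensitive to the raster scale,
and the coarser grid keeps large Monte-Carlo runs cheap; rendering
uses 0.004 mm/px so a 2 px dot radius stays well under the separation
bound. Seeds: panels derive per-section 31-bit seeds from a master
seed via NumPy's `SeedSequence`, so every artifact regenerates
bit-identically.

## What the simulations do and do not show

The generator reproduces the *structural* sources of density
variation: block coverage, within-block density, S/P composition,
primary/secondary sidedness, hard-core point spacing and a planted
whole-body gradient. It does not emulate staining or imaging noise,
section-plane obliquity, annotation error (marks are rendered
perfectly on the palette), follicle cycling, glands, or fibre traits.
Passing tests therefore demonstrate that the measurement pipeline is
unbiased and well calibrated on clean annotations with known ground
truth; they do not certify performance on imperfect manual markings.
Published section-specific values (e.g. a CV range measured on real
sections) depend on the original tissue and are not reproduction
targets; the acceptance suite instead checks parameter *recovery* of
the printed breed parameters, exact design arithmetic and the
qualitative laws (identity, CV growth, breed separation with a
calibrated null).

## Known limitations

- Group shapes are convex (shrunken Voronoi cells or inscribed
  ellipses); real HFGs can be mildly concave.
- Coverage targets above 0.75 are rejected rather than approximated.
- The extractor assumes clean palette colours; heavily compressed or
  rescanned annotations need the colour-tolerance option and may merge
  touching dots.
- Site coordinates and the site-effect profile are reconstructions;
  analyses that depend on absolute geometry (distances on the body)
  should supply their own layout.
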