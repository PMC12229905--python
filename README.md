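# follimap

Histomorphometry of hair-follicle groups in goat skin: simulation of
follicle-group-structured skin sections, extraction of colour-annotated
sections, trait quantification, quadrat variance analysis and body-wide
spatial mapping.

## The problem

Cashmere yield is driven by how densely hair follicles populate the
skin. In goats, follicles are not scattered uniformly: they are packed
into discrete **hair-follicle groups (HFGs)** — compact blocks covering
roughly half of the skin surface, each holding a few coarse **primary**
follicles on one side and dozens of fine **secondary** (cashmere-
producing) follicles on the other. Density measured on a histological
section therefore depends on where and at what scale you measure.

`follimap` implements the quantitative side of this problem for people
who analyse annotated skin sections (or want to benchmark such an
analysis): a generator of realistic ground-truth sections, the
extraction stage for clean colour annotations, and the downstream
statistics.

## The trait system

For a section of area $A$ containing $n_P$ primary and $n_S$ secondary
follicles, with HFG blocks of total area $A_{HFG}$:

- **THFD** $= (n_P + n_S)/A$ — total hair follicle density (follicles/mm²)
- **S/P** $= n_S/n_P$ — secondary-to-primary ratio
- **Ratio-HFG** $= A_{HFG}/A$ — area fraction occupied by HFGs
- **Int-THFD** — follicle density *inside* the HFG blocks

When every follicle lies inside a block, the decomposition
$\mathrm{THFD} = \text{Int-THFD} \times \text{Ratio-HFG}$ is an
arithmetic identity; `follimap` verifies it per section and flags
violations. Spatial heterogeneity is quantified by splitting a section
into $k$ equal-area quadrats and reporting the coefficient of variation
of per-cell THFD, and by inverse-distance-weighted maps of per-site
means over a schematic body layout with per-site one-way ANOVA for
breed contrasts.

Three calibration presets encode published whole-body parameter sets:
IMCG (Inner Mongolia cashmere goat: Ratio-HFG 58.9%, Int-THFD 70.4
follicles/mm², S/P 11.6), DBG (Dazu black goat: 41%, 63.5, S/P derived
≈ 3.87) and their F1 hybrids (41.2%, 78.9, S/P derived ≈ 5.8).

## Worked example

```python
from follimap import (PRESETS, simulate_section, render_annotation_image,
                      extract_dots, extract_mask, compute_traits)

section = simulate_section(PRESETS["IMCG"].to_config(9.26, seed=42))
image = render_annotation_image(section)          # green/blue/white/black PNG
scale = section.config_used.mm_per_pixel
rec = compute_traits(extract_dots(image, scale), extract_mask(image, scale))
print(rec.thfd, rec.sp_ratio, rec.ratio_hfg, rec.int_thfd)
```

prints

```
41.44 11.80 0.589 70.37
```

i.e. the 9.26 mm² section carries 41.44 follicles/mm² overall, 11.8
secondaries per primary, HFGs covering 58.9% of the area and 70.37
follicles/mm² inside them — and 41.44 ≈ 70.37 × 0.589, the
decomposition identity, holds to machine precision. The
`examples/` directory walks through each capability (simulation,
extraction, quadrat CV, body maps, breed comparison, study design);
`follimap --help` exposes the same pipeline as shell subcommands.

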