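"""Enumerate the three-part sampling design.

Part I (7 animals × 33 right-side points) and Part II (40 animals × 14
whole-body sites) are the histology arms; Part III is the transcriptome
arm, inventoried but not counted toward the histology total.
"""

from follimap import enumerate_samples, reference_design

inventory, totals = enumerate_samples(reference_design())
print(inventory.to_string(index=False))
print()
for key, value in totals.items():
    print(f"{key}: {value}")
# histology_total = 231 + 560 = 791 skin sections.
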