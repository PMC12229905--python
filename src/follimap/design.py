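"""Sampling-design bookkeeping.

The reference study collects skin sections in three parts: Part I maps
local and body-side variation on 7 animals × 33 right-side points
(231 sections), Part II maps whole-body variation on 40 animals × 14
sites (560 sections), and Part III is a transcriptome arm whose 18
samples are tracked for completeness but are not histology sections.
The histology grand total is therefore 231 + 560 = 791.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class DesignPart:
    part_id: str
    n_animals: int
    sites_per_animal: int
    purpose: str
    counts_toward_histology: bool = True
    expected_samples: int | None = None

    @property
    def n_samples(self) -> int:
        return self.n_animals * self.sites_per_animal


@dataclass(frozen=True)
class DesignSpec:
    parts: tuple[DesignPart, ...]
    breed_roster: dict[str, int] = field(default_factory=dict)


def reference_design() -> DesignSpec:
    """The reference three-part design (7×33, 40×14, plus 18
    transcriptome samples excluded from the histology count)."""
    return DesignSpec(
        parts=(
            DesignPart(
                "I", 7, 33, "local-site and body-side spatial variation",
                expected_samples=231,
            ),
            DesignPart(
                "II", 40, 14, "whole-body spatial variation and breed comparison",
                expected_samples=560,
            ),
            DesignPart(
                "III", 18, 1, "transcriptome arm (not histology)",
                counts_toward_histology=False, expected_samples=18,
            ),
        ),
        breed_roster={"IMCG": 11 + 7, "DBG": 9, "F1": 20},
    )


def enumerate_samples(spec: DesignSpec) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expand a design into a per-part inventory and totals.

    Returns the inventory table and a totals dict with per-part counts,
    the histology total and the overall total.  A part whose declared
    ``expected_samples`` disagrees with animals × sites raises
    :class:`ConfigError` naming the violated identity.
    """
    rows = []
    for part in spec.parts:
        n = part.n_samples
        if part.expected_samples is not None and part.expected_samples != n:
            raise ConfigError(
                f"part {part.part_id}: declared {part.expected_samples} samples "
                f"but {part.n_animals} animals x {part.sites_per_animal} sites "
                f"= {n}"
            )
        rows.append(
            {
                "part_id": part.part_id,
                "n_animals": part.n_animals,
                "sites_per_animal": part.sites_per_animal,
                "n_samples": n,
                "histology": part.counts_toward_histology,
                "purpose": part.purpose,
            }
        )
    inventory = pd.DataFrame(rows)
    totals = {f"part_{r['part_id']}": int(r["n_samples"]) for r in rows}
    totals["histology_total"] = int(
        inventory.loc[inventory.histology, "n_samples"].sum()
    )
    totals["grand_total"] = int(inventory["n_samples"].sum())
    return inventory, totals
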