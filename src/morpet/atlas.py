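"""Region atlas for ROI-level analysis.

The atlas lists the analysis regions (nodes of the covariance network) and
the named subsets used for hypothesis tests: the striatum (dorsal + ventral),
and the hedonic network (orbitofrontal, cingulate, insular cortex, midbrain,
amygdala, plus the striatum).  The reference region (occipital grey matter,
negligible mu-opioid receptor density) is carried separately and is excluded
from every analysis subset and from the edge count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["RegionAtlas", "make_atlas", "MANDATORY_REGIONS"]

DORSAL_STRIATUM = ["caudate", "putamen"]
VENTRAL_STRIATUM = ["ventral_striatum"]
HEDONIC_EXTRA = ["orbitofrontal", "cingulate", "insula", "midbrain", "amygdala"]
MANDATORY_REGIONS = DORSAL_STRIATUM + VENTRAL_STRIATUM + HEDONIC_EXTRA
REFERENCE_REGION = "occipital"

# filler names for larger atlases, loosely modelled on a whole-brain grey
# matter parcellation; the remainder are generic numbered parcels
_FILLER_POOL = [
    "thalamus", "hippocampus", "parahippocampus", "frontal_sup", "frontal_mid",
    "frontal_inf", "precentral", "postcentral", "parietal_sup", "parietal_inf",
    "temporal_sup", "temporal_mid", "temporal_inf", "fusiform", "precuneus",
    "cuneus", "lingual", "supramarginal", "angular", "paracentral",
    "cerebellum_ant", "cerebellum_post", "vermis", "brainstem", "pallidum",
    "accumbens_shell", "substantia_nigra", "hypothalamus", "septum", "claustrum",
]


@dataclass
class RegionAtlas:
    """Analysis regions plus named subsets and the reference region."""

    region_names: list[str]
    subsets: dict[str, list[str]] = field(default_factory=dict)
    reference: str = REFERENCE_REGION

    def __post_init__(self):
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region names must be unique")
        if self.reference in self.region_names:
            raise ValueError("reference region must not be an analysis region")
        for name, members in self.subsets.items():
            missing = set(members) - set(self.region_names)
            if missing:
                raise ValueError(f"subset {name!r} contains unknown regions: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def all_regions(self) -> list[str]:
        """Analysis regions plus the reference (e.g. for TAC simulation/IO)."""
        return self.region_names + [self.reference]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"regions": self.region_names, "reference": self.reference,
                 "subsets": self.subsets},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "RegionAtlas":
        with open(path) as fh:
            d = json.load(fh)
        return cls(region_names=d["regions"], subsets=d["subsets"], reference=d["reference"])


def make_atlas(n_regions: int = 125) -> RegionAtlas:
    """Deterministic atlas with ``n_regions`` analysis regions.

    The mandated subset regions come first; remaining slots are filled from a
    fixed name pool then numbered parcels.  ``n_regions`` below the mandated
    subset size (8) is an error.
    """
    if n_regions < len(MANDATORY_REGIONS):
        raise ValueError(
            f"n_regions={n_regions} cannot host the mandated subsets "
            f"({len(MANDATORY_REGIONS)} regions required)"
        )
    names = list(MANDATORY_REGIONS)
    for nm in _FILLER_POOL:
        if len(names) >= n_regions:
            break
        names.append(nm)
    i = 1
    while len(names) < n_regions:
        names.append(f"parcel_{i:03d}")
        i += 1
    striatum = DORSAL_STRIATUM + VENTRAL_STRIATUM
    subsets = {
        "dorsal_striatum": list(DORSAL_STRIATUM),
        "ventral_striatum": list(VENTRAL_STRIATUM),
        "striatum": striatum,
        "hedonic_network": HEDONIC_EXTRA + striatum,
    }
    return RegionAtlas(region_names=names, subsets=subsets)
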