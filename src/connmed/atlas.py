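"""Atlas label handling for 90-region parcellations with left/right homologues.

The pipeline treats the atlas as an ordered list of ROI labels, each carrying a
hemisphere tag and a region name shared by its contralateral homologue.  The
default atlas mirrors the 90-region automated-anatomical-labelling cortical and
subcortical parcellation (45 regions x 2 hemispheres, left/right interleaved),
which contains the four regions this pipeline targets by default: thalamus,
hippocampus, caudate, and insula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["AtlasLabels", "default_atlas", "TARGET_REGIONS", "AAL90_REGIONS"]

#: Bilateral region names of the 90-region AAL-style parcellation, in standard
#: order.  Each expands to <name>_L (even index) and <name>_R (odd index).
AAL90_REGIONS: tuple[str, ...] = (
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Inf_Orb",
    "Rolandic_Oper", "Supp_Motor_Area", "Olfactory", "Frontal_Sup_Medial",
    "Frontal_Med_Orb", "Rectus", "Insula", "Cingulum_Ant", "Cingulum_Mid",
    "Cingulum_Post", "Hippocampus", "ParaHippocampal", "Amygdala", "Calcarine",
    "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid", "Occipital_Inf",
    "Fusiform", "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
)

#: Regions examined in the default association/mediation analyses.
TARGET_REGIONS: tuple[str, ...] = ("Thalamus", "Hippocampus", "Caudate", "Insula")


@dataclass(frozen=True)
class AtlasLabels:
    """Ordered ROI labels with hemisphere tags and homologue pairing.

    Parameters
    ----------
    names
        Full ROI labels in column order of the time-series matrices
        (e.g. ``"Thalamus_L"``).
    hemispheres
        ``"L"`` or ``"R"`` per ROI.
    regions
        Bilateral region name per ROI (e.g. ``"Thalamus"``).
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    regions: tuple[str, ...]
    _pairs: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.hemispheres) == len(self.regions)):
            raise ValueError("names, hemispheres and regions must align")
        pairs: dict[str, dict[str, int]] = {}
        for i, (hemi, region) in enumerate(zip(self.hemispheres, self.regions)):
            pairs.setdefault(region, {})[hemi] = i
        object.__setattr__(self, "_pairs", pairs)

    @property
    def n_rois(self) -> int:
        return len(self.names)

    def pair(self, region: str) -> tuple[int, int]:
        """Return the (left, right) ROI indices of a bilateral region."""
        try:
            members = self._pairs[region]
        except KeyError:
            raise KeyError(f"region {region!r} not in atlas") from None
        if set(members) != {"L", "R"}:
            raise ValueError(
                f"region {region!r} lacks a left/right homologue pair "
                f"(has hemispheres {sorted(members)})"
            )
        return members["L"], members["R"]

    def indices(self, region: str) -> tuple[int, ...]:
        """All ROI indices belonging to a region, in atlas order."""
        if region not in self._pairs:
            raise KeyError(f"region {region!r} not in atlas")
        return tuple(sorted(self._pairs[region].values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": range(self.n_rois),
                "name": self.names,
                "hemisphere": self.hemispheres,
                "region": self.regions,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtlasLabels":
        df = df.sort_values("index")
        return cls(
            names=tuple(df["name"]),
            hemispheres=tuple(df["hemisphere"]),
            regions=tuple(df["region"]),
        )


def default_atlas(n_rois: int = 90) -> AtlasLabels:
    """Build the default 90-ROI atlas (or its first ``n_rois`` labels).

    ROIs are ordered left/right interleaved, matching the conventional
    AAL-90 ordering.  ``n_rois`` must be even so every region stays paired.
    """
    if n_rois % 2 or n_rois < 2 or n_rois > 2 * len(AAL90_REGIONS):
        raise ValueError(f"n_rois must be even and in [2, 90], got {n_rois}")
    regions_needed = AAL90_REGIONS[: n_rois // 2]
    if n_rois < 90:
        # keep the four analysis targets present even in truncated atlases
        missing = [r for r in TARGET_REGIONS if r not in regions_needed]
        if missing:
            base = [r for r in regions_needed if r not in TARGET_REGIONS]
            regions_needed = tuple(base[: n_rois // 2 - len(TARGET_REGIONS)]) + tuple(
                r for r in TARGET_REGIONS
            )
    names, hemis, regions = [], [], []
    for region in regions_needed:
        for hemi in ("L", "R"):
            names.append(f"{region}_{hemi}")
            hemis.append(hemi)
            regions.append(region)
    return AtlasLabels(tuple(names), tuple(hemis), tuple(regions))
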