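"""Desikan-Killiany cortical parcellation and its lobe partition.

The 34 gyral labels per hemisphere are grouped into six "lobes": the four
classical lobes plus cingulate and insula kept separate. With this grouping
the temporal lobe has exactly nine subregions (including parahippocampal),
which is the granularity the hierarchical analysis descends to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError

#: The 34 Desikan-Killiany cortical labels, lower-case, hemisphere-unprefixed.
DK_LABELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
    "frontalpole",
    "insula",
)

LOBES: tuple[str, ...] = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "cingulate",
    "insula",
)

# Canonical FreeSurfer lobe assignment (insula as its own lobe).
_DEFAULT_ASSIGNMENT: dict[str, str] = {
    # frontal (11)
    "superiorfrontal": "frontal",
    "rostralmiddlefrontal": "frontal",
    "caudalmiddlefrontal": "frontal",
    "parsopercularis": "frontal",
    "parstriangularis": "frontal",
    "parsorbitalis": "frontal",
    "lateralorbitofrontal": "frontal",
    "medialorbitofrontal": "frontal",
    "precentral": "frontal",
    "paracentral": "frontal",
    "frontalpole": "frontal",
    # parietal (5)
    "superiorparietal": "parietal",
    "inferiorparietal": "parietal",
    "supramarginal": "parietal",
    "postcentral": "parietal",
    "precuneus": "parietal",
    # temporal (9)
    "superiortemporal": "temporal",
    "middletemporal": "temporal",
    "inferiortemporal": "temporal",
    "bankssts": "temporal",
    "fusiform": "temporal",
    "transversetemporal": "temporal",
    "entorhinal": "temporal",
    "temporalpole": "temporal",
    "parahippocampal": "temporal",
    # occipital (4)
    "lateraloccipital": "occipital",
    "lingual": "occipital",
    "cuneus": "occipital",
    "pericalcarine": "occipital",
    # cingulate (4)
    "rostralanteriorcingulate": "cingulate",
    "caudalanteriorcingulate": "cingulate",
    "posteriorcingulate": "cingulate",
    "isthmuscingulate": "cingulate",
    # insula (1)
    "insula": "insula",
}


@dataclass(frozen=True)
class LobeMap:
    """A partition of cortical ROI labels into lobes.

    Invariant: every label appears in exactly one lobe. The default map
    covers the full 34-label Desikan-Killiany parcellation.
    """

    assignment: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_ASSIGNMENT))

    def __post_init__(self) -> None:
        bad = {l for l in self.assignment.values() if l not in LOBES}
        if bad:
            raise ValidationError(f"unknown lobe name(s): {sorted(bad)}")

    def lobe_of(self, roi: str) -> str:
        try:
            return self.assignment[roi.lower()]
        except KeyError:
            raise ValidationError(f"ROI {roi!r} is not in the lobe map") from None

    def rois_of(self, lobe: str) -> tuple[str, ...]:
        return tuple(r for r, l in self.assignment.items() if l == lobe)

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    @property
    def lobes(self) -> tuple[str, ...]:
        return tuple(l for l in LOBES if any(v == l for v in self.assignment.values()))

    def __contains__(self, roi: str) -> bool:
        return roi.lower() in self.assignment

    def validate_complete(self, rois: Iterable[str] = DK_LABELS) -> None:
        """Assert that every given ROI is mapped exactly once."""
        missing = sorted(set(r.lower() for r in rois) - set(self.assignment))
        if missing:
            raise ValidationError(f"unmapped ROI(s): {missing}")


def default_lobe_map() -> LobeMap:
    """Canonical FreeSurfer lobe assignment of the 34 DK labels.

    Cingulate and insula are separate lobes; the temporal lobe contains
    exactly nine subregions including parahippocampal.
    """
    return LobeMap()
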