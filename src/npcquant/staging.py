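"""Cell-cycle staging from cell morphology and SPB intensity ratios.

Fission yeast grows by tip extension at near-constant width, so cell length
indexes cell-cycle progression; combined with nucleus count and septation it
yields the morphological stages. Independently, the daughter/mother SPB
intensity ratio (the new pole accumulates material through G2) gives an
SPB-duplication stage.

Boundary conventions: length bands are closed on the left (mid-G2 is
[9.5, 11) um); SPB ratio bands are [0, 0.5), [0.5, 0.8), [0.8, inf) — only
the upper band is explicitly inclusive (>= 0.8), the other boundaries are
chosen half-open so the classification is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class StageLabel(str, Enum):
    EARLY_G2 = "early_G2"
    MID_G2 = "mid_G2"
    LATE_G2_EARLY_M = "lateG2_earlyM"
    LATE_MITOSIS = "late_mitosis"
    G1_S = "G1_S"
    UNCLASSIFIED = "unclassified"
    # SPB-duplication stages
    SPB_G1_S = "spb_G1_S"
    SPB_EARLY_MID_G2 = "spb_early_mid_G2"
    SPB_LATE_G2_MITOSIS = "spb_lateG2_mitosis"


#: Length thresholds (um) separating early G2 / mid G2 / late G2-early M.
LENGTH_EARLY_MID_UM = 9.5
LENGTH_MID_LATE_UM = 11.0

#: Daughter/mother SPB intensity ratio band edges.
SPB_RATIO_G1S = 0.5
SPB_RATIO_LATE = 0.8


@dataclass
class CellMorphology:
    length_um: float
    n_nuclei: int
    septated: bool

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("cell length must be positive")
        if self.n_nuclei not in (1, 2):
            raise ValueError("n_nuclei must be 1 or 2")


def stage_cell(m: CellMorphology) -> StageLabel:
    """Morphological stage; septation takes precedence over everything else.

    early G2: mononucleate, length < 9.5 um; mid G2: [9.5, 11); late G2 /
    early mitosis: >= 11, mononucleate; late mitosis: >= 11, binucleate;
    G1/S: septated. A short binucleate cell has no stated rule and is
    returned as unclassified.
    """
    if m.septated:
        return StageLabel.G1_S
    if m.n_nuclei == 2:
        return StageLabel.LATE_MITOSIS if m.length_um >= LENGTH_MID_LATE_UM \
            else StageLabel.UNCLASSIFIED
    if m.length_um < LENGTH_EARLY_MID_UM:
        return StageLabel.EARLY_G2
    if m.length_um < LENGTH_MID_LATE_UM:
        return StageLabel.MID_G2
    return StageLabel.LATE_G2_EARLY_M


def spb_stage(daughter_intensity: float, mother_intensity: float) -> StageLabel:
    """SPB-duplication stage from the daughter/mother intensity ratio."""
    if daughter_intensity < 0 or mother_intensity < 0:
        raise ValueError("intensities must be non-negative")
    if mother_intensity <= 0:
        raise ValueError("mother intensity must be positive")
    ratio = daughter_intensity / mother_intensity
    if ratio < SPB_RATIO_G1S:
        return StageLabel.SPB_G1_S
    if ratio < SPB_RATIO_LATE:
        return StageLabel.SPB_EARLY_MID_G2
    return StageLabel.SPB_LATE_G2_MITOSIS
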