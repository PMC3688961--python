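"""Oak-decline risk rating.

Risk for oak decline is predisposed by the basal area of the decline-
susceptible red-oak group (*Quercus* section *Lobatae*) and by site quality
derived from landtype.  Cells are rated per pixel:

* high risk — low-quality sites (ridgetops, southwest-facing slopes) with
  more than 6.9 m2/ha of red-oak-group basal area, or high-quality sites
  (northeast-facing slopes, floodplains) with more than 13.8 m2/ha;
* moderate risk — 2.3 to 6.9 m2/ha (low quality) or 2.3 to 13.8 m2/ha
  (high quality), boundaries inclusive;
* low risk — less than 2.3 m2/ha on either site quality.

Because the model's functional groups split section *Lobatae* between a
"red oak" and a "black oak" group, both are counted by default
(``include_black_oak``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import CellState, SpeciesSet, ValidationError
from .landscape import Landscape

__all__ = [
    "RiskClass",
    "RiskSummary",
    "LOW_MODERATE_BA",
    "HIGH_RISK_BA_LOW_QUALITY",
    "HIGH_RISK_BA_HIGH_QUALITY",
    "red_oak_group_ba",
    "classify_cell_risk",
    "classify_landscape",
    "landscape_risk_summary",
]

LOW_MODERATE_BA = 2.3            # m2/ha; below this a cell is low risk
HIGH_RISK_BA_LOW_QUALITY = 6.9   # m2/ha; above this, high risk on low-quality sites
HIGH_RISK_BA_HIGH_QUALITY = 13.8  # m2/ha; above this, high risk on high-quality sites

RED_OAK_GROUPS = ("red_oak", "black_oak")


class RiskClass(enum.IntEnum):
    LOW = 1
    MODERATE = 2
    HIGH = 3


@dataclass(frozen=True)
class RiskSummary:
    """Percent of landscape pixels in each oak-decline risk class."""

    year: float
    pct_high: float
    pct_moderate: float
    pct_low: float

    def __post_init__(self) -> None:
        total = self.pct_high + self.pct_moderate + self.pct_low
        if abs(total - 100.0) > 1e-9:
            raise ValidationError("risk percentages must sum to 100")


def red_oak_group_ba(
    cell: CellState | Landscape,
    species_set: SpeciesSet | None = None,
    include_black_oak: bool = True,
) -> float | np.ndarray:
    """Basal area (m2/ha) of the decline-susceptible red-oak group.

    For a :class:`Landscape`, returns the (C,) per-cell vector.
    """
    groups = RED_OAK_GROUPS if include_black_oak else ("red_oak",)
    if isinstance(cell, Landscape):
        ba = cell.ba_by_species()
        idx = [cell.species_set.index(g) for g in groups if g in cell.species_set.index_by_name]
        return ba[idx].sum(axis=0)
    return sum(c.basal_area for c in cell.cohorts if c.species.name in groups)


def classify_cell_risk(roba: float, site_quality: str) -> RiskClass:
    """Risk class from red-oak-group basal area and site quality."""
    if roba < 0:
        raise ValidationError("red-oak basal area must be >= 0")
    if site_quality not in ("low", "high"):
        raise ValidationError(f"unknown site quality {site_quality!r}")
    high_bound = (
        HIGH_RISK_BA_LOW_QUALITY if site_quality == "low" else HIGH_RISK_BA_HIGH_QUALITY
    )
    if roba > high_bound:
        return RiskClass.HIGH
    if roba >= LOW_MODERATE_BA:
        return RiskClass.MODERATE
    return RiskClass.LOW


def classify_landscape(land: Landscape, include_black_oak: bool = True) -> np.ndarray:
    """(C,) integer risk codes (1 low, 2 moderate, 3 high) for every cell."""
    roba = red_oak_group_ba(land, include_black_oak=include_black_oak)
    if np.any(roba < 0):
        raise ValidationError("red-oak basal area must be >= 0")
    bound = np.where(land.low_quality, HIGH_RISK_BA_LOW_QUALITY, HIGH_RISK_BA_HIGH_QUALITY)
    codes = np.full(land.n_cells, int(RiskClass.MODERATE))
    codes[roba < LOW_MODERATE_BA] = int(RiskClass.LOW)
    codes[roba > bound] = int(RiskClass.HIGH)
    return codes


def landscape_risk_summary(
    land: Landscape, year: float = 0.0, include_black_oak: bool = True
) -> tuple[RiskSummary, np.ndarray]:
    """Risk percentages over all pixels plus the per-cell risk raster."""
    if land.n_cells == 0:
        raise ValidationError("cannot summarize a zero-cell landscape")
    codes = classify_landscape(land, include_black_oak=include_black_oak)
    n = codes.size
    pct = {k: 100.0 * np.count_nonzero(codes == int(k)) / n for k in RiskClass}
    # make the three percentages sum to exactly 100
    pct[RiskClass.LOW] = 100.0 - pct[RiskClass.HIGH] - pct[RiskClass.MODERATE]
    return (
        RiskSummary(year, pct[RiskClass.HIGH], pct[RiskClass.MODERATE], pct[RiskClass.LOW]),
        codes,
    )
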