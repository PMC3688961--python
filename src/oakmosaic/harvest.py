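"""Harvest scheduling and the three treatment types.

Harvesting is organized by management area (MA).  Each MA carries one
prescription: an entry schedule, a stand-ranking rule, an eligibility floor,
a target residual basal area, a species removal priority, and the fraction
of the MA to treat per entry.  Stands (contiguous cell groups nested in MAs)
are the scheduling unit; treatments operate on the cells of selected stands.

Prescriptions are read and written in a plain-text ``#key# value`` dialect.
Basal-area values in prescription files are interpreted as m2 per hectare.

Area accounting differs by treatment: thinning and clearcutting select
stands until the cumulative *stand* area crosses the per-entry proportion of
the MA; group selection cuts one opening per ranked stand until the
cumulative *cleared opening* area reaches that proportion, which is what
lets small scattered openings sum to the same harvested amount as
clearcutting (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import CELL_AREA_HA, SpeciesSet, ValidationError
from .landscape import Landscape
from .succession import _sprout_inplace

__all__ = [
    "HarvestPrescription",
    "load_default_prescription",
    "HarvestLedger",
    "HarvestRecord",
    "StandInfo",
    "parse_prescription",
    "format_prescription",
    "eligible_stands",
    "rank_and_select",
    "apply_thinning",
    "apply_clearcut",
    "apply_group_selection",
    "harvest_timestep",
]

log = logging.getLogger(__name__)

_EPS = 1e-9

RANK_RANDOM = 1
RANK_HIGHEST_BA = 6

#: Default Table-2-style prescription values for the study-area management plan.
DEFAULT_SPECIES_PRIORITY = {
    "hickory": 1, "maple": 2, "black_oak": 3, "red_oak": 4, "white_oak": 5, "pine": 6,
}


@dataclass
class HarvestPrescription:
    """Parameter block governing harvest within one management area."""

    management_area_id: int
    ranking: int = RANK_HIGHEST_BA
    entry_year: float = 5.0
    reentry_interval: float = 5.0
    min_stand_ba: float = 18.36          # m2/ha eligibility floor
    remove_largest_first: bool = True
    area_proportion: float = 0.03        # fraction of MA per entry
    target_ba: float = 18.36             # m2/ha residual (0 -> clearcut)
    species_priority: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PRIORITY)
    )
    treatment: str = "thinning"          # thinning | clearcut | group_selection
    opening_size_cells: float = 3.0      # mean opening size (group selection)
    proportion_basis: str = "per_entry"  # per_entry | per_year_annualized

    def __post_init__(self) -> None:
        if not (0.0 < self.area_proportion <= 1.0):
            raise ValidationError("area_proportion must be in (0, 1]")
        if self.target_ba < 0:
            raise ValidationError("target_ba must be >= 0")
        if self.treatment not in ("thinning", "clearcut", "group_selection"):
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.ranking not in (RANK_RANDOM, RANK_HIGHEST_BA):
            raise ValidationError("ranking must be 1 (random) or 6 (highest mean BA)")
        ranks = sorted(self.species_priority.values())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError("species priority ranks must be a permutation of 1..n")
        if self.opening_size_cells < 1:
            raise ValidationError("opening_size_cells must be >= 1")
        if self.proportion_basis not in ("per_entry", "per_year_annualized"):
            raise ValidationError("proportion_basis must be per_entry or per_year_annualized")

    def effective_proportion(self) -> float:
        if self.proportion_basis == "per_year_annualized":
            return min(1.0, self.area_proportion * self.reentry_interval)
        return self.area_proportion

    def due(self, year: float) -> bool:
        if year < self.entry_year:
            return False
        return (year - self.entry_year) % self.reentry_interval == 0


# ---------------------------------------------------------------------------
# the `#key# value` prescription dialect
# ---------------------------------------------------------------------------

_SPECIES_KEYS = {
    "pine": "pine", "blackoak": "black_oak", "redoak": "red_oak",
    "whiteoak": "white_oak", "hickory": "hickory", "maple": "maple",
}

_CANONICAL_LINES = [
    ("#Management Area ID#", "management_area_id"),
    ("#Ranking algorithm for stand selection:1is random stand selection, "
     "6 is highest average basal area#", "ranking"),
    ("#Entry year#", "entry_year"),
    ("#Reentry year#", "reentry_interval"),
    ("#Minimum stand harvest basal area (m^2^)#", "min_stand_ba"),
    ("#remove largest tree first#", "remove_largest_first"),
    ("#Proportion of management area to harvest#", "area_proportion"),
    ("#Target stand basal area (m^2^)#", "target_ba"),
]

_SPECIES_LABELS = {
    "pine": "Pine", "black_oak": "Black oak", "red_oak": "Red oak",
    "white_oak": "White oak", "hickory": "Hickory", "maple": "Maple",
}


def _norm(key: str) -> str:
    return re.sub(r"[^a-z0-9]", "", key.lower())


def parse_prescription(text: str) -> HarvestPrescription:
    """Parse a ``#key# value`` prescription block."""
    values: dict[str, object] = {}
    priority: dict[str, int] = {}
    in_priority = False
    for raw in text.splitlines():
        m = re.match(r"\s*#(.+?)#\s*(.*?)\s*$", raw)
        if not m:
            continue
        key, val = _norm(m.group(1)), m.group(2)
        if key.startswith("speciespriorityranking"):
            in_priority = True
            continue
        if in_priority and key in _SPECIES_KEYS:
            priority[_SPECIES_KEYS[key]] = int(float(val))
            continue
        if key.startswith("managementareaid"):
            values["management_area_id"] = int(float(val))
        elif key.startswith("rankingalgorithm"):
            values["ranking"] = int(float(val))
        elif key.startswith("entryyear"):
            values["entry_year"] = float(val)
        elif key.startswith("reentryyear"):
            values["reentry_interval"] = float(val)
        elif key.startswith("minimumstandharvestbasalarea"):
            values["min_stand_ba"] = float(val)
        elif key.startswith("removelargesttreefirst"):
            values["remove_largest_first"] = bool(int(float(val)))
        elif key.startswith("proportionofmanagementarea"):
            values["area_proportion"] = float(val)
        elif key.startswith("targetstandbasalarea"):
            values["target_ba"] = float(val)
        elif key.startswith("treatmenttype"):
            t = val.strip().lower().replace(" ", "_")
            values["treatment"] = {"clearcutting": "clearcut"}.get(t, t)
        elif key.startswith("meanopeningsize"):
            values["opening_size_cells"] = float(val)
        else:
            raise ValidationError(f"unrecognized prescription key: {m.group(1)!r}")
    if "management_area_id" not in values:
        raise ValidationError("prescription is missing a management area id")
    if priority:
        values["species_priority"] = priority
    return HarvestPrescription(**values)


def format_prescription(p: HarvestPrescription) -> str:
    """Write a prescription back out in the ``#key# value`` dialect."""
    def fmt(x):
        if isinstance(x, bool):
            return str(int(x))
        if isinstance(x, float) and x == int(x):
            return str(int(x))
        return str(x)

    lines = [f"{key}\t{fmt(getattr(p, attr))}" for key, attr in _CANONICAL_LINES]
    lines.append("#Species priority ranking for harvest#")
    for name, rank in sorted(p.species_priority.items(), key=lambda kv: kv[1]):
        lines.append(f"#{_SPECIES_LABELS.get(name, name)}#\t{rank}")
    lines.append(f"#Treatment type#\t{p.treatment}")
    if p.treatment == "group_selection":
        lines.append(f"#Mean opening size (cells)#\t{fmt(p.opening_size_cells)}")
    return "\n".join(lines) + "\n"


def load_default_prescription() -> HarvestPrescription:
    """The packaged management-plan thinning prescription block."""
    text = resources.files("oakmosaic").joinpath(
        "data/thinning_prescription.txt").read_text()
    return parse_prescription(text)


# ---------------------------------------------------------------------------
# stand bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandInfo:
    id: int
    mean_ba: float   # m2/ha, mean over the stand's cells
    area_ha: float
    cells: np.ndarray


def _stand_infos(land: Landscape, ma_id: int) -> list[StandInfo]:
    cells = np.nonzero(land.ma_id == ma_id)[0]
    if cells.size == 0:
        return []
    ba = land.total_ba()
    infos = []
    for sid in np.unique(land.stand_id[cells]):
        sc = cells[land.stand_id[cells] == sid]
        infos.append(StandInfo(int(sid), float(ba[sc].mean()), sc.size * CELL_AREA_HA, sc))
    return infos


def eligible_stands(
    stands: list[StandInfo],
    prescription: HarvestPrescription,
    year: float,
    last_treated: dict[int, float] | None = None,
) -> list[StandInfo]:
    """Stands at/above the BA floor, past entry year, and out of the reentry
    window (a stand treated exactly ``reentry_interval`` years ago is
    eligible again)."""
    if year < prescription.entry_year:
        return []
    last_treated = last_treated or {}
    out = []
    for s in stands:
        if s.mean_ba < prescription.min_stand_ba:
            continue
        if s.id in last_treated and year - last_treated[s.id] < prescription.reentry_interval:
            continue
        out.append(s)
    return out


def rank_and_select(
    stands: list[StandInfo],
    prescription: HarvestPrescription,
    ma_area_ha: float,
    rng: np.random.Generator,
) -> list[StandInfo]:
    """Rank eligible stands and accumulate them until the cumulative stand
    area crosses the per-entry proportion of the MA (overshoot by part of the
    last stand is allowed)."""
    if not stands:
        log.warning("no eligible stands in management area %d",
                    prescription.management_area_id)
        return []
    ranked = _rank(stands, prescription, rng)
    target = prescription.effective_proportion() * ma_area_ha
    sel, cum = [], 0.0
    for s in ranked:
        sel.append(s)
        cum += s.area_ha
        if cum >= target - _EPS:
            break
    return sel


def _rank(stands, prescription, rng):
    if prescription.ranking == RANK_HIGHEST_BA:
        return sorted(stands, key=lambda s: (-s.mean_ba, s.id))
    order = rng.permutation(len(stands))
    return [stands[i] for i in order]


# ---------------------------------------------------------------------------
# treatments (each returns the (S, A, cells) removal array)
# ---------------------------------------------------------------------------


def _thinning_bin_order(ss: SpeciesSet, prescription: HarvestPrescription) -> np.ndarray:
    S, A = len(ss), ss.n_bins
    rank = np.array([prescription.species_priority.get(n, len(ss) + 1) for n in ss.names])
    s_idx, a_idx = np.divmod(np.arange(S * A), A)
    dbh = ss.dbh_table.ravel()
    sign = -1.0 if prescription.remove_largest_first else 1.0
    return np.lexsort((a_idx, sign * dbh, rank[s_idx]))


def apply_thinning(
    land: Landscape, cells: np.ndarray, prescription: HarvestPrescription
) -> np.ndarray:
    """Thin the stand given by ``cells`` down to the target residual BA.

    Removal proceeds species-by-species in ascending priority rank, within a
    species largest-DBH cohorts first (when ``remove_largest_first``), whole
    trees per cell, stopping as soon as the stand mean BA is at or below the
    target.  Returns the (S, A, n_cells_in_stand) removal array.
    """
    ss = land.species_set
    n = cells.size
    removed = np.zeros((len(ss), ss.n_bins, n))
    mean_ba = float(land.total_ba()[cells].mean())
    needed = mean_ba - prescription.target_ba
    if needed <= _EPS:
        return removed
    order = _thinning_bin_order(ss, prescription)
    ba_tree = ss.ba_tree.ravel()
    for flat in order:
        if needed <= _EPS:
            break
        s, a = divmod(int(flat), ss.n_bins)
        e = ba_tree[flat] / CELL_AREA_HA / n  # stand-mean BA per removed tree
        if e <= 0:
            continue
        avail = land.density[s, a, cells] * CELL_AREA_HA  # trees per cell
        total = avail.sum()
        if total <= 0:
            continue
        if total * e <= needed + _EPS:
            take = avail.copy()
        else:
            k = math.ceil(needed / e - _EPS)
            floors = np.floor(avail + _EPS)
            cum = np.cumsum(floors)
            take = np.clip(k - (cum - floors), 0, floors)
            short = k - take.sum()
            if short > 0:  # fractional-tree tail
                fr = avail - take
                cumf = np.cumsum(fr)
                take += np.clip(short - (cumf - fr), 0, fr)
        removed[s, a, :] = take / CELL_AREA_HA
        land.density[s, a, cells] -= take / CELL_AREA_HA
        needed -= take.sum() * e
    np.clip(land.density, 0.0, None, out=land.density)
    return removed


def apply_clearcut(land: Landscape, cells: np.ndarray) -> np.ndarray:
    """Remove every cohort in every cell of the stand."""
    removed = land.density[:, :, cells].copy()
    land.density[:, :, cells] = 0.0
    return removed


def _draw_opening_size(mean: float, rng: np.random.Generator) -> int:
    return max(1, int(rng.poisson(mean)))


def _grow_opening(
    land: Landscape, stand_cells: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """A contiguous (rook-adjacency) cluster of ~``size`` cells grown from a
    uniformly chosen seed cell, confined to the stand."""
    nrows, ncols = land.shape
    stand_set = set(int(c) for c in stand_cells)
    if size >= len(stand_set):
        if size > len(stand_set):
            log.info("opening truncated to stand size %d", len(stand_set))
        return stand_cells.copy()
    seed = int(stand_cells[rng.integers(stand_cells.size)])
    chosen = {seed}
    frontier = [seed]
    while len(chosen) < size and frontier:
        i = int(rng.integers(len(frontier)))
        cell = frontier.pop(i)
        r, c = divmod(cell, ncols)
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < nrows and 0 <= nc < ncols:
                nb = nr * ncols + nc
                if nb in stand_set and nb not in chosen:
                    chosen.add(nb)
                    frontier.append(nb)
                    if len(chosen) >= size:
                        break
    return np.array(sorted(chosen))


def apply_group_selection(
    land: Landscape,
    stand_cells: np.ndarray,
    prescription: HarvestPrescription,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Clear one canopy opening inside the stand; cells outside it untouched.

    Returns ``(removal array over opening cells, opening cell indices)``.
    """
    size = _draw_opening_size(prescription.opening_size_cells, rng)
    opening = _grow_opening(land, stand_cells, size, rng)
    return apply_clearcut(land, opening), opening


# ---------------------------------------------------------------------------
# ledger and the per-step driver
# ---------------------------------------------------------------------------


@dataclass
class HarvestRecord:
    """Removals of one harvest entry step (landscape-mean units)."""

    year: float
    removed_ba_by_species: np.ndarray   # (S,) m2/ha landscape mean
    area_treated_ha: float
    pre_mean_ba: float                  # landscape mean before removal
    post_mean_ba: float                 # landscape mean after removal, before sprouting
    stands_treated: tuple[int, ...] = ()


@dataclass
class HarvestLedger:
    """Per-step harvest bookkeeping for one scenario replicate."""

    records: list[HarvestRecord] = field(default_factory=list)

    def total_removed_ba(self) -> float:
        return float(sum(r.removed_ba_by_species.sum() for r in self.records))


def validate_prescriptions(
    prescriptions: dict[int, HarvestPrescription], land: Landscape
) -> None:
    """Prescriptions must target distinct, existing management areas."""
    mas = set(np.unique(land.ma_id))
    for ma, p in prescriptions.items():
        if p.management_area_id != ma:
            raise ValidationError(
                f"prescription keyed {ma} targets management area {p.management_area_id}"
            )
        if ma not in mas:
            raise ValidationError(f"management area {ma} not present on the landscape")


def harvest_timestep(
    land: Landscape,
    prescriptions: dict[int, HarvestPrescription],
    year: float,
    rng: np.random.Generator,
    last_treated: dict[int, float] | None = None,
) -> tuple[Landscape, HarvestRecord]:
    """Apply every due prescription for this year.

    Per management area: eligibility -> ranking/selection -> treatment.
    Sprouting from harvest removals follows succession rules; sprout cohorts
    enter the ledger at age 0 so basal-area conservation
    (pre = post + removed) holds exactly across the step.
    ``last_treated`` (stand id -> year) is updated in place.
    """
    out = land.copy()
    ss = out.species_set
    last_treated = last_treated if last_treated is not None else {}
    removed = np.zeros_like(out.density)
    area_treated = 0.0
    treated_stands: list[int] = []
    pre = float(out.total_ba().mean())

    for ma in sorted(prescriptions):
        p = prescriptions[ma]
        if not p.due(year):
            continue
        stands = _stand_infos(out, ma)
        ma_area = sum(s.area_ha for s in stands)
        elig = eligible_stands(stands, p, year, last_treated)
        if p.treatment in ("thinning", "clearcut"):
            for s in rank_and_select(elig, p, ma_area, rng):
                if p.treatment == "clearcut" or p.target_ba <= 0:
                    rem = apply_clearcut(out, s.cells)
                else:
                    rem = apply_thinning(out, s.cells, p)
                removed[:, :, s.cells] += rem
                area_treated += s.area_ha
                treated_stands.append(s.id)
                last_treated[s.id] = year
        else:  # group selection: openings accumulate to the area target
            if not elig:
                log.warning("no eligible stands in management area %d", ma)
            target = p.effective_proportion() * ma_area
            cleared = 0.0
            for s in _rank(elig, p, rng):
                rem, opening = apply_group_selection(out, s.cells, p, rng)
                removed[:, :, opening] += rem
                cleared += opening.size * CELL_AREA_HA
                treated_stands.append(s.id)
                last_treated[s.id] = year
                if cleared >= target - _EPS:
                    break
            area_treated += cleared

    post = float(out.total_ba().mean())
    removed_ba = np.einsum("sac,sa->s", removed, ss.ba_tree) / out.n_cells
    if not math.isclose(pre - post, float(removed_ba.sum()), rel_tol=1e-9, abs_tol=1e-9):
        raise RuntimeError("harvest conservation audit failed")  # pragma: no cover
    # harvest-origin sprouts enter at age 0 (age 5 after this step's growth)
    _sprout_inplace(out, removed, rng, target_bin=0)
    record = HarvestRecord(year, removed_ba, area_treated, pre, post,
                           tuple(treated_stands))
    return out, record
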