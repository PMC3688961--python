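"""One 5-year succession time step.

Order of operations within a step (fixed): growth -> seed dispersal ->
establishment -> self-thinning -> longevity mortality -> resprouting of the
longevity-killed cohorts.  All stochastic draws (establishment, sprouting)
consume a single numpy Generator in species-major, raster-scan order, so a
run is bit-reproducible given its seed.

Cell-level reference implementations (operating on ``CellState`` cohort
lists) are provided next to the vectorized landscape engine; the two are held
to identical semantics by the test suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    CELL_AREA_HA,
    CELL_SIZE_M,
    CellState,
    Cohort,
    Landtype,
    SpeciesSet,
    ValidationError,
)
from .landscape import Landscape

__all__ = [
    "SeedRain",
    "StandStage",
    "grow_step",
    "disperse_seeds",
    "establish",
    "sprout",
    "self_thin",
    "longevity_mortality",
    "classify_stage",
    "succession_timestep",
    "establishment_ceiling",
]

_EPS = 1e-12


@dataclass
class SeedRain:
    """Per-cell, per-species counts of potential germinating seeds."""

    counts: np.ndarray  # (S, C) int64
    species_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValidationError("seed counts must be >= 0")


class StandStage(enum.Enum):
    INITIATION = "initiation"
    STEM_EXCLUSION = "stem_exclusion"
    UNDERSTORY_REINITIATION = "understory_reinitiation"
    OLD_GROWTH = "old_growth"


#: fraction of longevity beyond which a cohort marks a stand as old growth
OLD_GROWTH_AGE_FRACTION = 0.8


def establishment_ceiling(shade_tolerance: int) -> float:
    """Fraction of MGSO below which a species of the given shade-tolerance
    class can still establish.

    Class 1 (intolerant) only establishes in nearly open cells (GSO below
    0.3 MGSO); each class adds 0.15 MGSO, so class-5 species establish almost
    until the cell is fully occupied (0.9 MGSO).
    """
    return 0.3 + 0.15 * (shade_tolerance - 1)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def grow_step(obj: Landscape | CellState, species_set: SpeciesSet | None = None):
    """Advance every cohort by one time step; densities unchanged."""
    if isinstance(obj, Landscape):
        out = obj.copy()
        _grow_inplace(out)
        return out
    step = (species_set.step if species_set else 5.0)
    return CellState(
        obj.landtype_id,
        obj.stand_id,
        obj.management_area_id,
        [Cohort(c.species, c.age + step, c.density) for c in obj.cohorts],
        obj.ever_full,
    )


def _grow_inplace(land: Landscape) -> None:
    d = land.density
    top = d[:, -1, :].copy()
    d[:, 1:, :] = d[:, :-1, :]
    d[:, 0, :] = 0.0
    d[:, -1, :] += top  # senescent overflow bin; cleared by mortality


# ---------------------------------------------------------------------------
# seed dispersal
# ---------------------------------------------------------------------------


def _dispersal_kernel(max_distance_m: float, cell_size_m: float = CELL_SIZE_M) -> np.ndarray:
    r = int(max_distance_m // cell_size_m)
    di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return ((di**2 + dj**2) * cell_size_m**2 <= max_distance_m**2 + _EPS).astype(np.int64)


def disperse_seeds(land: Landscape, rng: np.random.Generator | None = None) -> SeedRain:
    """Seed rain from mature cohorts to all cells within the species'
    maximum seeding distance (Euclidean cell-center distance, source cell
    included).

    A cell reached by at least one mature cohort of a species receives that
    species' ``germination_seeds`` potential germinating seeds — the
    parameter is a per-cell fecundity cap, not a per-source contribution, so
    seed rain does not multiply with source density.  No seeds ever land
    beyond the distance cutoff.
    """
    ss = land.species_set
    S, C = len(ss), land.n_cells
    counts = np.zeros((S, C), dtype=np.int64)
    nrows, ncols = land.shape
    for s in range(S):
        mature = ss.mature_bins[s]
        sources = (land.density[s, mature, :] > 0).any(axis=0).reshape(nrows, ncols)
        if not sources.any() or ss.germ[s] <= 0:
            continue
        kernel = _dispersal_kernel(ss.seed_dist[s])
        reach = ndimage.convolve(sources.astype(np.int64), kernel, mode="constant", cval=0)
        counts[s] = np.where(reach.ravel() > 0, np.rint(ss.germ[s]).astype(np.int64), 0)
    return SeedRain(counts, ss.names)


# ---------------------------------------------------------------------------
# establishment
# ---------------------------------------------------------------------------


def establish(
    cell: CellState,
    seeds_by_species: dict[str, int],
    landtype: Landtype,
    rng: np.random.Generator,
    species_set: SpeciesSet,
) -> CellState:
    """Cell-level establishment: each arriving seed establishes independently
    with probability SEP, only while the cell is below MGSO and below the
    species' shade-tolerance ceiling.  Successes form an age-5 cohort."""
    from .core import growing_space_occupied

    gso = growing_space_occupied(cell, species_set)
    new = [Cohort(c.species, c.age, c.density) for c in cell.cohorts]
    step = species_set.step
    for name in species_set.names:
        n = int(seeds_by_species.get(name, 0))
        if n <= 0:
            continue
        sp = species_set[name]
        if gso >= landtype.mgso or gso >= establishment_ceiling(sp.shade_tolerance) * landtype.mgso:
            continue
        k = int(rng.binomial(n, landtype.sep.get(name, 0.0)))
        if k > 0:
            new.append(Cohort(sp, step, k / CELL_AREA_HA))
    return CellState(cell.landtype_id, cell.stand_id, cell.management_area_id,
                     new, cell.ever_full)


def _establish_inplace(land: Landscape, rain: SeedRain, rng: np.random.Generator) -> None:
    ss = land.species_set
    gso = land.gso()
    ceilings = np.array([establishment_ceiling(int(c)) for c in ss.shade])
    allowed = (gso[None, :] < land.mgso[None, :]) & (
        gso[None, :] < ceilings[:, None] * land.mgso[None, :]
    )
    n = np.where(allowed, rain.counts, 0)
    successes = rng.binomial(n, land.sep)
    land.density[:, 1, :] += successes / CELL_AREA_HA


# ---------------------------------------------------------------------------
# sprouting
# ---------------------------------------------------------------------------


def sprout(
    cell: CellState,
    removed_cohorts: list[Cohort],
    rng: np.random.Generator,
    species_set: SpeciesSet | None = None,
) -> CellState:
    """Resprouting from cohorts just killed by harvest or mortality.

    A removed cohort whose age lies in the species' sprouting window yields a
    new age-5 cohort; each removed tree sprouts independently with the
    species' vegetative reproduction probability.
    """
    step = species_set.step if species_set else 5.0
    new = [Cohort(c.species, c.age, c.density) for c in cell.cohorts]
    for c in removed_cohorts:
        sp = c.species
        if not (sp.min_sprout_age <= c.age <= sp.max_sprout_age):
            continue
        n_trees = int(math.floor(c.density * CELL_AREA_HA + 0.5))
        if n_trees <= 0 or sp.veg_repro_prob == 0.0:
            continue
        k = int(rng.binomial(n_trees, sp.veg_repro_prob))
        if k > 0:
            new.append(Cohort(sp, step, k / CELL_AREA_HA))
    return CellState(cell.landtype_id, cell.stand_id, cell.management_area_id,
                     new, cell.ever_full)


def _sprout_inplace(
    land: Landscape, removed: np.ndarray, rng: np.random.Generator, target_bin: int
) -> None:
    """Add sprout cohorts for a (S, A, C) removal array at ``target_bin``."""
    ss = land.species_set
    window = ss.sprout_bins[:, :, None]
    trees = np.floor(removed * CELL_AREA_HA + 0.5).astype(np.int64)
    trees = np.where(window, trees, 0)
    n = trees.sum(axis=1)  # (S, C): sprouting is per removed tree; pooling
    # across a species' removed cohorts is equivalent for independent draws
    successes = rng.binomial(n, ss.veg_prob[:, None])
    land.density[:, target_bin, :] += successes / CELL_AREA_HA


# ---------------------------------------------------------------------------
# self-thinning
# ---------------------------------------------------------------------------


def self_thin(
    cell: CellState, species_set: SpeciesSet, landtype: Landtype
) -> tuple[CellState, list[Cohort]]:
    """Cell-level Yoda self-thinning.

    If GSO exceeds the landtype MGSO, whole trees are removed — smallest-DBH
    cohorts first, ties broken by lower shade tolerance, then by age closest
    to longevity — until GSO drops to MGSO (within one removable tree).
    """
    from .core import growing_space_occupied

    gso = growing_space_occupied(cell, species_set)
    if gso <= landtype.mgso + _EPS:
        return cell, []
    order = sorted(
        range(len(cell.cohorts)),
        key=lambda i: (
            round(cell.cohorts[i].dbh, 9),
            cell.cohorts[i].species.shade_tolerance,
            cell.cohorts[i].species.longevity - cell.cohorts[i].age,
            species_set.index(cell.cohorts[i].species.name),
        ),
    )
    excess = gso - landtype.mgso
    new = [Cohort(c.species, c.age, c.density) for c in cell.cohorts]
    removed: list[Cohort] = []
    for i in order:
        if excess <= _EPS:
            break
        c = new[i]
        g_tree = (c.sdi / c.density / c.species.max_sdi) / CELL_AREA_HA if c.density > 0 else 0.0
        if g_tree <= 0:
            continue
        avail_trees = c.density * CELL_AREA_HA
        contrib = avail_trees * g_tree
        if contrib <= excess + _EPS:
            take_dens = c.density
        else:
            k = math.ceil(excess / g_tree - 1e-9)
            take_dens = min(k / CELL_AREA_HA, c.density)
        if take_dens > 0:
            removed.append(Cohort(c.species, c.age, take_dens))
            new[i] = Cohort(c.species, c.age, c.density - take_dens)
            excess -= take_dens * CELL_AREA_HA * g_tree
    new = [c for c in new if c.density > _EPS]
    out = CellState(cell.landtype_id, cell.stand_id, cell.management_area_id,
                    new, True)
    return out, removed


def _self_thin_inplace(land: Landscape) -> np.ndarray:
    """Vectorized self-thinning of all overstocked cells.

    Returns the (S, A, C) removal array.  Also records full occupancy in
    ``ever_full`` using the pre-thinning GSO.
    """
    ss = land.species_set
    S, A, C = land.density.shape
    removed = np.zeros((S, A, C))
    gso = land.gso()
    land.ever_full |= gso >= land.mgso - _EPS
    over = np.nonzero(gso > land.mgso + _EPS)[0]
    if over.size == 0:
        return removed

    prio = ss.thinning_priority()
    inv = np.argsort(prio)
    g = (ss.gso_coef.ravel()[prio] / CELL_AREA_HA)[:, None]  # gso per whole tree
    d = land.density[:, :, over].reshape(S * A, over.size)[prio]
    trees = d * CELL_AREA_HA
    contrib = trees * g
    cum_before = np.cumsum(contrib, axis=0) - contrib
    need = np.clip((gso[over] - land.mgso[over])[None, :] - cum_before, 0.0, None)
    take_gso = np.minimum(need, contrib)
    with np.errstate(divide="ignore", invalid="ignore"):
        take_trees = np.where(g > 0, take_gso / g, 0.0)
    partial = take_gso < contrib - _EPS
    take_trees = np.where(partial, np.minimum(np.ceil(take_trees - 1e-9), trees), take_trees)
    take_dens = take_trees / CELL_AREA_HA
    removed[:, :, over] = take_dens[inv].reshape(S, A, over.size)
    land.density[:, :, over] -= removed[:, :, over]
    np.clip(land.density, 0.0, None, out=land.density)
    land.density[land.density < 1e-9] = 0.0  # round-off residue
    return removed


# ---------------------------------------------------------------------------
# longevity mortality
# ---------------------------------------------------------------------------


def longevity_mortality(
    obj: Landscape | CellState,
) -> tuple[Landscape | CellState, list[Cohort] | np.ndarray]:
    """Remove every cohort that has reached its species' longevity."""
    if isinstance(obj, Landscape):
        out = obj.copy()
        removed = _longevity_inplace(out)
        return out, removed
    keep, removed = [], []
    for c in obj.cohorts:
        (removed if c.age >= c.species.longevity else keep).append(c)
    return (
        CellState(obj.landtype_id, obj.stand_id, obj.management_area_id, keep, obj.ever_full),
        removed,
    )


def _longevity_inplace(land: Landscape) -> np.ndarray:
    mask = land.species_set.senescent_bins[:, :, None]
    removed = np.where(mask, land.density, 0.0)
    land.density[:] = np.where(mask, 0.0, land.density)
    return removed


# ---------------------------------------------------------------------------
# stand development stage
# ---------------------------------------------------------------------------


def classify_stage(
    cell: CellState, species_set: SpeciesSet, landtype: Landtype
) -> StandStage:
    """Stand development stage from GSO, its history, and cohort ages.

    Initiation while GSO has never reached MGSO; stem exclusion while at or
    above MGSO; understory reinitiation once previously-full cells fall below
    MGSO again; old growth additionally requires a cohort at 80 % or more of
    its species' longevity.
    """
    from .core import growing_space_occupied

    gso = growing_space_occupied(cell, species_set)
    if gso >= landtype.mgso:
        return StandStage.STEM_EXCLUSION
    if not cell.ever_full:
        return StandStage.INITIATION
    if any(c.age >= OLD_GROWTH_AGE_FRACTION * c.species.longevity for c in cell.cohorts):
        return StandStage.OLD_GROWTH
    return StandStage.UNDERSTORY_REINITIATION


def stage_map(land: Landscape) -> np.ndarray:
    """(C,) array of StandStage for every cell (vectorized)."""
    ss = land.species_set
    gso = land.gso()
    old_bins = ss.bin_ages[None, :] >= OLD_GROWTH_AGE_FRACTION * ss.longevity[:, None]
    has_old = np.einsum("sac,sa->c", (land.density > 0).astype(float),
                        old_bins.astype(float)) > 0
    out = np.empty(land.n_cells, dtype=object)
    full = gso >= land.mgso
    out[:] = StandStage.INITIATION
    out[land.ever_full & ~full] = StandStage.UNDERSTORY_REINITIATION
    out[land.ever_full & ~full & has_old] = StandStage.OLD_GROWTH
    out[full] = StandStage.STEM_EXCLUSION
    return out


# ---------------------------------------------------------------------------
# full time step
# ---------------------------------------------------------------------------


def succession_timestep(land: Landscape, rng: np.random.Generator) -> Landscape:
    """One full 5-year step: growth, dispersal, establishment, self-thinning,
    longevity mortality, and resprouting of the longevity-killed cohorts.
    Pure function of (landscape state, rng state)."""
    out = land.copy()
    _grow_inplace(out)
    rain = disperse_seeds(out)
    _establish_inplace(out, rain, rng)
    _self_thin_inplace(out)
    dead = _longevity_inplace(out)
    _sprout_inplace(out, dead, rng, target_bin=1)
    return out
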