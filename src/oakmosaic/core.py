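"""Stand-level forest math and domain types.

The simulator represents a forest as a raster of 90-m cells, each holding a
ledger of species-age cohorts (trees/ha).  Everything downstream — succession,
self-thinning, harvest, risk rating — is built on four stand-level quantities
defined here:

* Reineke's stand density index, ``SDI = N * (D / 25.4 cm)**1.605``, which
  standardizes a cohort's density ``N`` to the 10-inch reference tree;
* growing-space occupancy (GSO), the sum over species of ``SDI_s / maxSDI_s``,
  a dimensionless fraction of the maximum growing space a cell can support;
* a Chapman-Richards age-DBH curve per species group, calibrated so that a
  tree reaches 95 % of its maximum DBH at its longevity;
* a power-law tree biomass allometry whose default exponent (1.5 * 1.605)
  makes density-dependent mortality along the SDI ceiling trace Yoda's -3/2
  self-thinning line exactly.

Six Ozark Highlands species functional groups (pines, black oak, red oaks,
white oaks, hickories, maples) ship as the default parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_SIZE_M",
    "CELL_AREA_HA",
    "REINEKE_REF_DBH_CM",
    "REINEKE_EXPONENT",
    "ValidationError",
    "SpeciesParams",
    "SpeciesSet",
    "Cohort",
    "Landtype",
    "CellState",
    "default_species",
    "default_landtypes",
    "dbh_from_age",
    "age_at_dbh",
    "reineke_sdi",
    "growing_space_occupied",
    "cohort_biomass",
    "species_to_csv",
    "species_from_csv",
]

CELL_SIZE_M = 90.0
CELL_AREA_HA = 0.81  # 90 m x 90 m
REINEKE_REF_DBH_CM = 25.4
REINEKE_EXPONENT = 1.605

#: Chapman-Richards shape exponent shared by all species groups.
CR_SHAPE = 1.3
#: Fraction of maximum DBH reached at longevity under the default growth rate.
DBH_AT_LONGEVITY = 0.95

DEFAULT_ALLOMETRY_B = 1.5 * REINEKE_EXPONENT  # 2.4075
DEFAULT_ALLOMETRY_A = 0.1  # kg * cm**-b

LOW_QUALITY_LABELS = frozenset({"ridgetop", "southwest_slope"})
HIGH_QUALITY_LABELS = frozenset({"northeast_slope", "floodplain"})
LANDTYPE_LABELS = ("ridgetop", "southwest_slope", "northeast_slope", "floodplain")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def _default_growth_rate(longevity: float, shape: float = CR_SHAPE) -> float:
    # k such that D(longevity) = DBH_AT_LONGEVITY * max_dbh
    return -math.log(1.0 - DBH_AT_LONGEVITY ** (1.0 / shape)) / longevity


@dataclass(frozen=True)
class SpeciesParams:
    """Vital attributes and growth/allometry coefficients for one species group."""

    name: str
    longevity: float            # years
    maturity_age: float         # years; first seed production
    shade_tolerance: int        # ordinal class 1 (intolerant) .. 5 (tolerant)
    fire_tolerance: int         # ordinal class 1..5; carried but unused
    max_seed_distance: float    # m, hard dispersal cutoff
    veg_repro_prob: float       # per-tree resprouting probability
    min_sprout_age: float       # years
    max_sprout_age: float       # years
    max_dbh: float              # cm, asymptote of the growth curve
    max_sdi: float              # trees/ha at the Reineke reference diameter
    germination_seeds: float    # potential germinating seeds per dispersal event
    growth_rate: float | None = None   # Chapman-Richards k; None -> calibrated
    allometry_a: float = DEFAULT_ALLOMETRY_A
    allometry_b: float = DEFAULT_ALLOMETRY_B

    def __post_init__(self) -> None:
        if not (self.longevity > self.maturity_age > 0):
            raise ValidationError(
                f"{self.name}: require longevity > maturity_age > 0"
            )
        if not (0.0 <= self.veg_repro_prob <= 1.0):
            raise ValidationError(f"{self.name}: veg_repro_prob outside [0, 1]")
        if not (self.min_sprout_age <= self.max_sprout_age <= self.longevity):
            raise ValidationError(
                f"{self.name}: require min_sprout_age <= max_sprout_age <= longevity"
            )
        if self.max_dbh <= 0 or self.max_sdi <= 0:
            raise ValidationError(f"{self.name}: max_dbh and max_sdi must be > 0")
        if self.germination_seeds < 0:
            raise ValidationError(f"{self.name}: germination_seeds must be >= 0")
        if self.shade_tolerance not in range(1, 6) or self.fire_tolerance not in range(1, 6):
            raise ValidationError(f"{self.name}: tolerance classes must be in 1..5")
        if self.growth_rate is None:
            object.__setattr__(
                self, "growth_rate", _default_growth_rate(self.longevity)
            )

    def dbh(self, age: float) -> float:
        return dbh_from_age(self, age)


def dbh_from_age(species: SpeciesParams, age) -> float | np.ndarray:
    """Chapman-Richards DBH (cm) at ``age`` years.

    ``D(age) = max_dbh * (1 - exp(-k * age))**p`` with ``p = 1.3``; strictly
    increasing, 0 at age 0, asymptotically below ``max_dbh``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValidationError("age must be non-negative")
    d = species.max_dbh * (1.0 - np.exp(-species.growth_rate * age)) ** CR_SHAPE
    return float(d) if d.ndim == 0 else d


def age_at_dbh(species: SpeciesParams, dbh: float) -> float:
    """Inverse of :func:`dbh_from_age` (dbh must be in ``[0, max_dbh)``)."""
    if not (0.0 <= dbh < species.max_dbh):
        raise ValidationError("dbh must be in [0, max_dbh)")
    if dbh == 0.0:
        return 0.0
    return -math.log(1.0 - (dbh / species.max_dbh) ** (1.0 / CR_SHAPE)) / species.growth_rate


@dataclass
class Cohort:
    """One species-age cohort in a cell: ``density`` trees/ha of common age."""

    species: SpeciesParams
    age: float
    density: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValidationError("cohort density must be >= 0")
        if self.age < 0:
            raise ValidationError("cohort age must be >= 0")

    @property
    def dbh(self) -> float:
        return dbh_from_age(self.species, self.age)

    @property
    def sdi(self) -> float:
        return self.density * (self.dbh / REINEKE_REF_DBH_CM) ** REINEKE_EXPONENT

    @property
    def basal_area(self) -> float:
        """m2/ha."""
        return self.density * math.pi * (self.dbh / 200.0) ** 2

    @property
    def biomass(self) -> float:
        return cohort_biomass(self)


def reineke_sdi(
    cohorts: Iterable[Cohort], species: Iterable[SpeciesParams] | None = None
) -> dict[str, float]:
    """Per-species Reineke SDI summed over cohorts.

    ``SDI_s = sum_i N_i * (D_i / 25.4)**1.605`` over the cohorts of species
    ``s``.  With ``species`` given, every listed species appears in the result
    (zero when absent from ``cohorts``).
    """
    out: dict[str, float] = {sp.name: 0.0 for sp in species} if species else {}
    for c in cohorts:
        if c.density < 0:
            raise ValidationError("cohort density must be >= 0")
        out[c.species.name] = out.get(c.species.name, 0.0) + c.sdi
    return out


def cohort_biomass(cohort: Cohort) -> float:
    """Cohort biomass (kg/ha): ``density * a * D**b``."""
    if cohort.density < 0:
        raise ValidationError("cohort density must be >= 0")
    if cohort.density == 0.0:
        return 0.0
    sp = cohort.species
    return cohort.density * sp.allometry_a * cohort.dbh ** sp.allometry_b


@dataclass(frozen=True)
class Landtype:
    """A homogeneous environmental stratum of the landscape.

    Carries the two landtype-level controls of the model: MGSO, the maximum
    growing-space occupancy a stand on this landtype can hold, and SEP, the
    per-species establishment probability of an arriving seed.
    """

    id: int
    label: str
    mgso: float
    sep: Mapping[str, float]
    site_quality: str = ""

    def __post_init__(self) -> None:
        if self.label not in LOW_QUALITY_LABELS | HIGH_QUALITY_LABELS:
            raise ValidationError(f"unknown landtype label {self.label!r}")
        quality = "low" if self.label in LOW_QUALITY_LABELS else "high"
        if self.site_quality and self.site_quality != quality:
            raise ValidationError(
                f"landtype {self.label!r} must have {quality!r} site quality"
            )
        object.__setattr__(self, "site_quality", quality)
        if not (0.0 < self.mgso <= 1.0):
            raise ValidationError("mgso must be in (0, 1]")
        for name, p in self.sep.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"SEP for {name!r} outside [0, 1]")


@dataclass
class CellState:
    """State of one 0.81-ha raster cell."""

    landtype_id: int
    stand_id: int
    management_area_id: int
    cohorts: list[Cohort] = field(default_factory=list)
    #: whether GSO has ever reached the landtype MGSO (stage bookkeeping)
    ever_full: bool = False

    area_ha: float = CELL_AREA_HA


def growing_space_occupied(
    cell: CellState | Iterable[Cohort], species_set: "SpeciesSet"
) -> float:
    """GSO of a cell: sum over species of ``SDI_s / maxSDI_s``.

    The cell is "fully occupied" when GSO reaches the landtype MGSO.
    """
    cohorts = cell.cohorts if isinstance(cell, CellState) else list(cell)
    gso = 0.0
    for c in cohorts:
        if c.species.name not in species_set.index_by_name:
            raise ValidationError(f"unknown species {c.species.name!r} in cohort ledger")
        gso += c.sdi / c.species.max_sdi
    return gso


# ---------------------------------------------------------------------------
# Species set: ordered collection with precomputed per-age-bin tables.
# ---------------------------------------------------------------------------


class SpeciesSet:
    """An ordered collection of species groups with vectorized lookup tables.

    Table order is significant: it fixes tie-breaking and the layout of the
    density arrays used by the landscape engine.  Per-age-bin tables (DBH,
    SDI coefficient, basal area and biomass per tree) are precomputed for a
    simulation time step (default 5 years).
    """

    def __init__(self, species: Sequence[SpeciesParams], step: float = 5.0):
        if not species:
            raise ValidationError("species set cannot be empty")
        names = [sp.name for sp in species]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species names")
        self.species: tuple[SpeciesParams, ...] = tuple(species)
        self.index_by_name: dict[str, int] = {n: i for i, n in enumerate(names)}
        self.names: tuple[str, ...] = tuple(names)
        self.step = float(step)

        self.longevity = np.array([sp.longevity for sp in species])
        self.maturity = np.array([sp.maturity_age for sp in species])
        self.shade = np.array([sp.shade_tolerance for sp in species])
        self.max_dbh = np.array([sp.max_dbh for sp in species])
        self.max_sdi = np.array([sp.max_sdi for sp in species])
        self.germ = np.array([sp.germination_seeds for sp in species])
        self.veg_prob = np.array([sp.veg_repro_prob for sp in species])
        self.sprout_min = np.array([sp.min_sprout_age for sp in species])
        self.sprout_max = np.array([sp.max_sprout_age for sp in species])
        self.seed_dist = np.array([sp.max_seed_distance for sp in species])

        # age-bin tables; bin a holds cohorts of age a*step
        self.n_bins = int(self.longevity.max() // step) + 2
        ages = np.arange(self.n_bins) * step  # (A,)
        self.bin_ages = ages
        k = np.array([sp.growth_rate for sp in species])[:, None]
        self.dbh_table = self.max_dbh[:, None] * (1.0 - np.exp(-k * ages[None, :])) ** CR_SHAPE
        self.sdi_coef = (self.dbh_table / REINEKE_REF_DBH_CM) ** REINEKE_EXPONENT
        self.gso_coef = self.sdi_coef / self.max_sdi[:, None]
        self.ba_tree = np.pi * (self.dbh_table / 200.0) ** 2  # m2 per tree
        a = np.array([sp.allometry_a for sp in species])[:, None]
        b = np.array([sp.allometry_b for sp in species])[:, None]
        self.w_tree = a * self.dbh_table ** b  # kg per tree
        self.mature_bins = ages[None, :] >= self.maturity[:, None]
        self.senescent_bins = ages[None, :] >= self.longevity[:, None]
        self.sprout_bins = (ages[None, :] >= self.sprout_min[:, None]) & (
            ages[None, :] <= self.sprout_max[:, None]
        )

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def __getitem__(self, key: int | str) -> SpeciesParams:
        if isinstance(key, str):
            return self.species[self.index_by_name[key]]
        return self.species[key]

    def index(self, name: str) -> int:
        try:
            return self.index_by_name[name]
        except KeyError:
            raise ValidationError(f"unknown species {name!r}") from None

    def with_germination(self, seeds: Sequence[float]) -> "SpeciesSet":
        """A copy of the set with germination-seed counts replaced (in order)."""
        if len(seeds) != len(self.species):
            raise ValidationError("need one germination-seed count per species")
        return SpeciesSet(
            [replace(sp, germination_seeds=float(g)) for sp, g in zip(self.species, seeds)],
            step=self.step,
        )

    # removal priority for self-thinning: smallest DBH first, ties by lower
    # shade tolerance, then by age closest to longevity, then table order
    def thinning_priority(self) -> np.ndarray:
        S, A = self.dbh_table.shape
        s_idx, a_idx = np.divmod(np.arange(S * A), A)
        keys = np.lexsort(
            (
                a_idx,
                s_idx,
                self.longevity[s_idx] - self.bin_ages[a_idx],
                self.shade[s_idx],
                np.round(self.dbh_table.ravel(), 9),
            )
        )
        return keys


# ---------------------------------------------------------------------------
# Default parameterization: six Ozark Highlands species functional groups.
# ---------------------------------------------------------------------------

_DEFAULT_ROWS = [
    # name, longevity, maturity, shade, fire, seed_dist, veg_prob, sprout_min,
    # sprout_max, max_dbh, max_sdi, germination_seeds
    ("pine", 200, 20, 3, 4, 200, 0.5, 1, 47, 60, 990, 50),
    ("black_oak", 120, 20, 3, 3, 200, 0.4, 10, 70, 60, 570, 90),
    ("red_oak", 150, 20, 3, 3, 200, 0.4, 10, 70, 60, 570, 90),
    ("white_oak", 300, 20, 4, 4, 200, 0.5, 10, 50, 65, 570, 90),
    ("hickory", 250, 20, 3, 3, 200, 0.5, 10, 70, 60, 570, 30),
    ("maple", 200, 20, 5, 1, 200, 0.3, 10, 70, 60, 570, 90),
]


def default_species(step: float = 5.0) -> SpeciesSet:
    """The default six-group species table for the Ozark Highlands."""
    return SpeciesSet([SpeciesParams(*row) for row in _DEFAULT_ROWS], step=step)


def default_landtypes() -> dict[int, Landtype]:
    """Four default landtypes with MGSO and SEP by species.

    Ridgetops and southwest-facing slopes are the droughty, low-quality sites
    (lower MGSO, pine/oak-favoring establishment); northeast-facing slopes and
    floodplains are the mesic, high-quality sites (higher MGSO, establishment
    shifted towards white oak and maple).
    """
    dry = {"pine": 0.35, "black_oak": 0.25, "red_oak": 0.25,
           "white_oak": 0.20, "hickory": 0.15, "maple": 0.05}
    mesic = {"pine": 0.05, "black_oak": 0.15, "red_oak": 0.20,
             "white_oak": 0.30, "hickory": 0.20, "maple": 0.40}
    return {
        1: Landtype(1, "ridgetop", 0.50, dict(dry)),
        2: Landtype(2, "southwest_slope", 0.55, dict(dry)),
        3: Landtype(3, "northeast_slope", 0.60, dict(mesic)),
        4: Landtype(4, "floodplain", 0.65, dict(mesic)),
    }


# ---------------------------------------------------------------------------
# Species-parameter CSV (vital-attribute column order, growth/allometry last).
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "name",
    "longevity_years",
    "mean_maturity_years",
    "shade_tolerance_class",
    "fire_tolerance_class",
    "max_seeding_distance_m",
    "veg_repro_prob",
    "min_sprouting_age_years",
    "max_sprouting_age_years",
    "max_dbh_cm",
    "max_sdi_trees_ha",
    "germination_seeds",
    "growth_rate",
    "allometry_a",
    "allometry_b",
]


def species_to_csv(species_set: SpeciesSet, path) -> None:
    rows = [
        (
            sp.name, sp.longevity, sp.maturity_age, sp.shade_tolerance,
            sp.fire_tolerance, sp.max_seed_distance, sp.veg_repro_prob,
            sp.min_sprout_age, sp.max_sprout_age, sp.max_dbh, sp.max_sdi,
            sp.germination_seeds, sp.growth_rate, sp.allometry_a, sp.allometry_b,
        )
        for sp in species_set
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def species_from_csv(path, step: float = 5.0) -> SpeciesSet:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"species CSV missing columns: {missing}")
    species = [
        SpeciesParams(
            name=str(r["name"]),
            longevity=float(r["longevity_years"]),
            maturity_age=float(r["mean_maturity_years"]),
            shade_tolerance=int(r["shade_tolerance_class"]),
            fire_tolerance=int(r["fire_tolerance_class"]),
            max_seed_distance=float(r["max_seeding_distance_m"]),
            veg_repro_prob=float(r["veg_repro_prob"]),
            min_sprout_age=float(r["min_sprouting_age_years"]),
            max_sprout_age=float(r["max_sprouting_age_years"]),
            max_dbh=float(r["max_dbh_cm"]),
            max_sdi=float(r["max_sdi_trees_ha"]),
            germination_seeds=float(r["germination_seeds"]),
            growth_rate=float(r["growth_rate"]) if pd.notna(r["growth_rate"]) else None,
            allometry_a=float(r["allometry_a"]),
            allometry_b=float(r["allometry_b"]),
        )
        for _, r in df.iterrows()
    ]
    return SpeciesSet(species, step=step)
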