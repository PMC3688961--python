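"""Raster landscape container.

A :class:`Landscape` stores the cohort ledgers of all cells in one dense
array ``density[species, age_bin, cell]`` (trees/ha), where age bin ``a``
holds cohorts of age ``a * step`` years.  The dense layout lets succession
and harvest operate as vectorized array passes; :class:`~oakmosaic.core.CellState`
views are available for cell-level work and round-trip exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CELL_AREA_HA,
    CELL_SIZE_M,
    CellState,
    Cohort,
    Landtype,
    SpeciesSet,
    ValidationError,
    default_landtypes,
    default_species,
)

__all__ = ["Landscape"]


class Landscape:
    """All cell states of a rectangular 90-m raster landscape."""

    def __init__(
        self,
        species_set: SpeciesSet,
        shape: tuple[int, int],
        landtype_id: np.ndarray,
        stand_id: np.ndarray,
        ma_id: np.ndarray,
        landtypes: dict[int, Landtype] | None = None,
        density: np.ndarray | None = None,
        ever_full: np.ndarray | None = None,
    ):
        self.species_set = species_set
        self.shape = (int(shape[0]), int(shape[1]))
        n = self.shape[0] * self.shape[1]
        self.landtype_id = np.asarray(landtype_id, dtype=np.int64).ravel()
        self.stand_id = np.asarray(stand_id, dtype=np.int64).ravel()
        self.ma_id = np.asarray(ma_id, dtype=np.int64).ravel()
        for name, arr in (("landtype", self.landtype_id), ("stand", self.stand_id),
                          ("management area", self.ma_id)):
            if arr.size != n:
                raise ValidationError(f"{name} raster does not match shape {self.shape}")
        self.landtypes = dict(landtypes) if landtypes is not None else default_landtypes()
        unknown = set(np.unique(self.landtype_id)) - set(self.landtypes)
        if unknown:
            raise ValidationError(f"landtype ids without definitions: {sorted(unknown)}")

        S, A = len(species_set), species_set.n_bins
        if density is None:
            density = np.zeros((S, A, n))
        self.density = np.asarray(density, dtype=float)
        if self.density.shape != (S, A, n):
            raise ValidationError(f"density must have shape {(S, A, n)}")
        if np.any(self.density < 0):
            raise ValidationError("negative cohort density")
        self.ever_full = (
            np.zeros(n, dtype=bool) if ever_full is None else np.asarray(ever_full, bool).copy()
        )

        # per-cell landtype-derived vectors
        ids = sorted(self.landtypes)
        id_pos = {i: k for k, i in enumerate(ids)}
        pos = np.array([id_pos[i] for i in self.landtype_id], dtype=np.int64)
        mgso_by = np.array([self.landtypes[i].mgso for i in ids])
        lowq_by = np.array([self.landtypes[i].site_quality == "low" for i in ids])
        self.mgso = mgso_by[pos]
        self.low_quality = lowq_by[pos]
        sep_by = np.array(
            [[self.landtypes[i].sep.get(name, 0.0) for i in ids] for name in species_set.names]
        )  # (S, n_landtypes)
        self.sep = sep_by[:, pos]  # (S, C)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.density.shape[2]

    @property
    def cell_area_ha(self) -> float:
        return CELL_AREA_HA

    @property
    def total_area_ha(self) -> float:
        return self.n_cells * CELL_AREA_HA

    def cell_centers_m(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = np.divmod(np.arange(self.n_cells), self.shape[1])
        return r * CELL_SIZE_M, c * CELL_SIZE_M

    # -- derived stand quantities -----------------------------------------
    def sdi_by_species(self) -> np.ndarray:
        """(S, C) Reineke SDI per species per cell."""
        return np.einsum("sac,sa->sc", self.density, self.species_set.sdi_coef)

    def gso(self) -> np.ndarray:
        """(C,) growing-space occupancy."""
        return np.einsum("sac,sa->c", self.density, self.species_set.gso_coef)

    def ba_by_species(self) -> np.ndarray:
        """(S, C) basal area, m2/ha."""
        return np.einsum("sac,sa->sc", self.density, self.species_set.ba_tree)

    def total_ba(self) -> np.ndarray:
        """(C,) total basal area, m2/ha."""
        return self.ba_by_species().sum(axis=0)

    def biomass(self) -> np.ndarray:
        """(C,) live biomass, kg/ha."""
        return np.einsum("sac,sa->c", self.density, self.species_set.w_tree)

    def trees_per_ha(self) -> np.ndarray:
        """(C,) total density."""
        return self.density.sum(axis=(0, 1))

    def mean_ba_by_species(self) -> np.ndarray:
        return self.ba_by_species().mean(axis=1)

    def mean_density_by_species(self) -> np.ndarray:
        return self.density.sum(axis=1).mean(axis=1)

    # -- cell-level views --------------------------------------------------
    def cell_state(self, idx: int) -> CellState:
        cohorts = []
        S, A, _ = self.density.shape
        col = self.density[:, :, idx]
        for s, a in zip(*np.nonzero(col)):
            cohorts.append(
                Cohort(self.species_set[int(s)], float(a * self.species_set.step),
                       float(col[s, a]))
            )
        return CellState(
            landtype_id=int(self.landtype_id[idx]),
            stand_id=int(self.stand_id[idx]),
            management_area_id=int(self.ma_id[idx]),
            cohorts=cohorts,
            ever_full=bool(self.ever_full[idx]),
        )

    def set_cell(self, idx: int, cohorts) -> None:
        step = self.species_set.step
        self.density[:, :, idx] = 0.0
        for c in cohorts:
            s = self.species_set.index(c.species.name)
            a = int(round(c.age / step))
            if abs(c.age - a * step) > 1e-9:
                raise ValidationError(
                    f"cohort age {c.age} is not a multiple of the {step}-y step"
                )
            if a >= self.species_set.n_bins:
                raise ValidationError(f"cohort age {c.age} beyond the age-bin table")
            self.density[s, a, idx] += c.density

    def add_cohort(self, idx: int, species_name: str, age: float, density: float) -> None:
        s = self.species_set.index(species_name)
        step = self.species_set.step
        a = int(round(age / step))
        if abs(age - a * step) > 1e-9 or a >= self.species_set.n_bins:
            raise ValidationError(f"cohort age {age} invalid for the bin table")
        if density < 0:
            raise ValidationError("density must be >= 0")
        self.density[s, a, idx] += density

    # -- bookkeeping -------------------------------------------------------
    def copy(self, species_set: SpeciesSet | None = None) -> "Landscape":
        return Landscape(
            species_set or self.species_set,
            self.shape,
            self.landtype_id.copy(),
            self.stand_id.copy(),
            self.ma_id.copy(),
            self.landtypes,
            self.density.copy(),
            self.ever_full.copy(),
        )

    def state_equal(self, other: "Landscape") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.density, other.density)
            and np.array_equal(self.ever_full, other.ever_full)
        )

    # -- cohort table serialization ----------------------------------------
    def to_cohort_frame(self) -> pd.DataFrame:
        s, a, c = np.nonzero(self.density)
        return pd.DataFrame(
            {
                "cell": c,
                "species": [self.species_set.names[i] for i in s],
                "age": a * self.species_set.step,
                "trees_per_ha": self.density[s, a, c],
            }
        ).sort_values(["cell", "species", "age"], ignore_index=True)

    def load_cohort_frame(self, df: pd.DataFrame) -> None:
        self.density[:] = 0.0
        for _, r in df.iterrows():
            self.add_cohort(int(r["cell"]), str(r["species"]), float(r["age"]),
                            float(r["trees_per_ha"]))

    @classmethod
    def empty(
        cls,
        shape: tuple[int, int],
        species_set: SpeciesSet | None = None,
        landtypes: dict[int, Landtype] | None = None,
        landtype_id: int | np.ndarray = 1,
    ) -> "Landscape":
        species_set = species_set or default_species()
        n = shape[0] * shape[1]
        lt = np.full(n, landtype_id) if np.isscalar(landtype_id) else landtype_id
        return cls(species_set, shape, lt, np.zeros(n, int), np.zeros(n, int), landtypes)
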