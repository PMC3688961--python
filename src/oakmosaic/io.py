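"""File interfaces: ESRI ASCII grids, cohort tables, landscape round-trip.

All rasters are row-major, north-up, 90-m cells, with integer codes for
categorical layers.  A landscape on disk is the raster set (landtype, stand,
management area) plus a cohort CSV (cell id, species, age, trees/ha) and the
species-parameter CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CELL_SIZE_M,
    Landtype,
    SpeciesSet,
    ValidationError,
    species_from_csv,
    species_to_csv,
)
from .landscape import Landscape

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape",
    "read_landscape",
    "write_manifest",
]

_NODATA = -9999


def write_ascii_grid(path, grid: np.ndarray, cellsize: float = CELL_SIZE_M,
                     xllcorner: float = 0.0, yllcorner: float = 0.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValidationError("ASCII grids must be 2-D")
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {xllcorner}\n"
        f"yllcorner {yllcorner}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {_NODATA}\n"
    )
    is_int = np.issubdtype(grid.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%d" if is_int else "%.6f")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                meta[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    if ("nrows" in meta and "ncols" in meta
            and grid.shape != (int(meta["nrows"]), int(meta["ncols"]))):
        raise ValidationError(f"grid body does not match header in {path}")
    return grid, meta


def _landtypes_to_dict(landtypes: dict[int, Landtype]) -> dict:
    return {
        int(i): {
            "label": lt.label,
            "mgso": float(lt.mgso),
            "sep": {k: float(v) for k, v in lt.sep.items()},
        }
        for i, lt in landtypes.items()
    }


def _landtypes_from_dict(d: dict) -> dict[int, Landtype]:
    return {
        int(i): Landtype(int(i), v["label"], float(v["mgso"]), dict(v["sep"]))
        for i, v in d.items()
    }


def write_landscape(land: Landscape, out_dir) -> dict[str, Path]:
    """Serialize a landscape as rasters + cohort CSV + species CSV + landtype YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "landtype": out / "landtype.asc",
        "stand": out / "stand.asc",
        "management_area": out / "management_area.asc",
        "cohorts": out / "cohorts.csv",
        "species": out / "species.csv",
        "landtypes": out / "landtypes.yaml",
    }
    shape = land.shape
    write_ascii_grid(paths["landtype"], land.landtype_id.reshape(shape))
    write_ascii_grid(paths["stand"], land.stand_id.reshape(shape))
    write_ascii_grid(paths["management_area"], land.ma_id.reshape(shape))
    # %.17g round-trips float64 exactly
    land.to_cohort_frame().to_csv(paths["cohorts"], index=False, float_format="%.17g")
    species_to_csv(land.species_set, paths["species"])
    with open(paths["landtypes"], "w") as fh:
        yaml.safe_dump(_landtypes_to_dict(land.landtypes), fh)
    return paths


def read_landscape(in_dir, species_set: SpeciesSet | None = None) -> Landscape:
    """Read a landscape written by :func:`write_landscape`, validating that
    the raster layers are congruent."""
    d = Path(in_dir)
    grids = {}
    for name in ("landtype", "stand", "management_area"):
        grids[name], _ = read_ascii_grid(d / f"{name}.asc")
    shapes = {name: g.shape for name, g in grids.items()}
    if len(set(shapes.values())) != 1:
        raise ValidationError(f"inconsistent raster shapes: {shapes}")
    if species_set is None:
        species_set = species_from_csv(d / "species.csv")
    with open(d / "landtypes.yaml") as fh:
        landtypes = _landtypes_from_dict(yaml.safe_load(fh))
    land = Landscape(
        species_set,
        grids["landtype"].shape,
        grids["landtype"].astype(np.int64),
        grids["stand"].astype(np.int64),
        grids["management_area"].astype(np.int64),
        landtypes,
    )
    land.load_cohort_frame(
        pd.read_csv(d / "cohorts.csv", float_precision="round_trip")
    )
    return land


def write_manifest(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
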