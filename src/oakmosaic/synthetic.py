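"""Synthetic study landscapes and the calibration harness.

No public deposit of the original inventory-initialized landscape exists, so
this module generates landscapes with its statistical structure: a
spatially autocorrelated landtype mosaic on a 90-m grid, contiguous stands
nested in management areas, and cell-level cohort ledgers drawn from a
stratified plot library (oak- vs pine-dominated forest type x size class),
emulating the plot-assignment initialization used with inventory data.
Defaults reproduce the study conditions: mature oak stands 70-100 years old
at high density, species basal-area shares of roughly 30 % white oaks,
40 % red-oak group (split 60/40 between the red-oak and black-oak groups),
10 % hickories, 5 % maples, and 15 % pines clustered in the south.

The module also provides the chi-square composition comparison and the
iterative germination-seed calibration, demonstrated as parameter recovery
against synthetic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import (
    LANDTYPE_LABELS,
    SpeciesSet,
    ValidationError,
    default_landtypes,
    default_species,
)
from .landscape import Landscape
from .succession import succession_timestep

__all__ = [
    "GeneratorConfig",
    "SyntheticPlot",
    "generate_landtype_map",
    "generate_stand_and_ma_maps",
    "build_plot_library",
    "initialize_landscape",
    "generate_landscape",
    "library_ba_shares",
    "chi_square_composition",
    "simulate_trajectory",
    "calibrate_germination_seeds",
    "CalibrationResult",
]

_EPS = 1e-9

DEFAULT_BA_SHARES = {
    "white_oak": 0.30,
    "red_oak": 0.24,   # section Lobatae 40 %, split 60/40 with black oak
    "black_oak": 0.16,
    "hickory": 0.10,
    "maple": 0.05,
    "pine": 0.15,
}

DEFAULT_LANDTYPE_PROPORTIONS = {
    "ridgetop": 0.20,
    "southwest_slope": 0.30,
    "northeast_slope": 0.30,
    "floodplain": 0.20,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-landscape generator (defaults = study conditions)."""

    shape: tuple[int, int] = (50, 50)
    landtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANDTYPE_PROPORTIONS)
    )
    smoothing_sigma: float = 3.0         # cells; landtype mosaic autocorrelation
    stand_mean_cells: float = 6.0        # ~5-ha stands (dissected terrain)
    n_management_areas: int = 6
    ba_shares: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BA_SHARES))
    oak_age_range: tuple[float, float] = (70.0, 100.0)
    ba_level: float = 22.0               # m2/ha total in mature (sawtimber) plots
    pole_fraction: float = 0.10          # fraction of cells in the poletimber size class
    pole_ba_fraction: float = 0.4        # pole-plot BA relative to ba_level
    n_oak_plots: int = 68
    n_pine_plots: int = 12
    #: plot-to-plot heterogeneity: low Dirichlet concentration and a wide
    #: lognormal BA jitter emulate the spread of real inventory plot pools
    dirichlet_concentration: float = 6.0
    ba_sigma: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.landtype_proportions.values()) - 1.0) > 1e-6:
            raise ValidationError("landtype proportions must sum to 1")
        if any(v < 0 for v in self.landtype_proportions.values()):
            raise ValidationError("landtype proportions must be >= 0")
        if abs(sum(self.ba_shares.values()) - 1.0) > 1e-6:
            raise ValidationError("basal-area shares must sum to 1")
        lo, hi = self.oak_age_range
        if not (0 <= lo <= hi <= 120):  # 120 y = shortest oak-group longevity
            raise ValidationError("oak age range must lie within [0, 120] years")


@dataclass(frozen=True)
class SyntheticPlot:
    """One representative plot: a cohort list with its stratum labels."""

    forest_type: str                      # "oak" | "pine"
    size_class: str                       # "sawtimber" | "poletimber"
    cohorts: tuple[tuple[str, float, float], ...]  # (species, age, trees/ha)

    @property
    def dominant_age(self) -> float:
        """Age of the cohort carrying the most basal area."""
        if not self.cohorts:
            return 0.0
        ss = default_species()
        return max(self.cohorts, key=lambda t: t[2] * ss[t[0]].dbh(t[1]) ** 2)[1]


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------


def generate_landtype_map(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated landtype mosaic (thresholded smoothed noise).

    Returns an (nrows, ncols) array of landtype ids 1..4 whose realized
    proportions match the configured ones to within the quantile grid.
    """
    props = [config.landtype_proportions.get(lbl, 0.0) for lbl in LANDTYPE_LABELS]
    noise = rng.normal(size=config.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=config.smoothing_sigma)
    ranks = stats.rankdata(smooth.ravel(), method="ordinal") / smooth.size
    bounds = np.cumsum(props)
    ids = np.searchsorted(bounds, ranks, side="left") + 1
    return np.minimum(ids, len(LANDTYPE_LABELS)).reshape(config.shape).astype(np.int64)


def _grow_regions(
    shape: tuple[int, int],
    cells: np.ndarray,
    n_regions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition ``cells`` into ``n_regions`` rook-contiguous regions by
    stochastic multi-source flood fill.  Returns labels (0..n-1) per cell of
    the full grid (-1 outside ``cells``)."""
    nrows, ncols = shape
    labels = np.full(nrows * ncols, -1, dtype=np.int64)
    inside = np.zeros(nrows * ncols, dtype=bool)
    inside[cells] = True
    seeds = rng.choice(cells, size=min(n_regions, cells.size), replace=False)
    frontier: list[tuple[int, int]] = []
    for k, s in enumerate(seeds):
        labels[s] = k
        frontier.append((int(s), k))
    while frontier:
        i = int(rng.integers(len(frontier)))
        cell, k = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        r, c = divmod(cell, ncols)
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < nrows and 0 <= nc < ncols:
                nb = nr * ncols + nc
                if inside[nb] and labels[nb] < 0:
                    labels[nb] = k
                    frontier.append((nb, k))
    return labels


def generate_stand_and_ma_maps(
    landtype_map: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous management areas, then contiguous stands nested inside
    them.  Returns (stand_map, ma_map), both shaped like ``landtype_map``,
    with ids starting at 1."""
    shape = landtype_map.shape
    all_cells = np.arange(landtype_map.size)
    ma = _grow_regions(shape, all_cells, config.n_management_areas, rng) + 1
    stands = np.zeros(landtype_map.size, dtype=np.int64)
    next_id = 1
    for m in np.unique(ma):
        cells = np.nonzero(ma == m)[0]
        n_stands = max(1, int(round(cells.size / config.stand_mean_cells)))
        sub = _grow_regions(shape, cells, n_stands, rng)
        stands[cells] = sub[cells] + next_id
        next_id += sub[cells].max() + 1
    return stands.reshape(shape), ma.reshape(shape)


# ---------------------------------------------------------------------------
# plot library and cell assignment
# ---------------------------------------------------------------------------

_HW_AGE_RANGES = {"hickory": (40, 70), "maple": (30, 60)}


def _snap(age: float, step: float = 5.0) -> float:
    return max(step, round(age / step) * step)


def _make_plot(
    forest_type: str,
    size_class: str,
    config: GeneratorConfig,
    species_set: SpeciesSet,
    rng: np.random.Generator,
) -> SyntheticPlot:
    ba_total = config.ba_level * float(np.exp(rng.normal(0.0, config.ba_sigma)))
    if size_class == "poletimber":
        ba_total *= config.pole_ba_fraction
        dominant = _snap(rng.uniform(20, 40))
    else:
        dominant = _snap(rng.uniform(*config.oak_age_range))
    cohorts: list[tuple[str, float, float]] = []
    if forest_type == "pine":
        names, shares = ["pine"], np.array([1.0])
    else:
        names = [n for n in config.ba_shares if n != "pine"]
        target = np.array([config.ba_shares[n] for n in names])
        target = target / target.sum()
        oak = np.array([n.endswith("oak") for n in names])
        # oak forest type: plurality of basal area in an oak group
        for _ in range(100):
            shares = rng.dirichlet(config.dirichlet_concentration * target)
            if oak[np.argmax(shares)]:
                break
    for name, share in zip(names, shares):
        if share * ba_total < 0.05:
            continue
        sp = species_set[name]
        if size_class == "poletimber":
            age = dominant
        elif name in _HW_AGE_RANGES:
            age = _snap(rng.uniform(*_HW_AGE_RANGES[name]))
        else:
            age = dominant
        ba_tree = math.pi * (sp.dbh(age) / 200.0) ** 2
        cohorts.append((name, age, share * ba_total / ba_tree))
    return SyntheticPlot(forest_type, size_class, tuple(cohorts))


def build_plot_library(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[SyntheticPlot]:
    """Stratified plot library: oak/pine forest type x sawtimber/poletimber.

    Oak sawtimber plots carry dominant oak cohorts aged within the
    configured range at high density; pine plots are reserved for the
    southern management block.
    """
    if config.n_oak_plots <= 0 or config.n_pine_plots <= 0:
        raise ValidationError("plot library requires at least one plot per forest type")
    ss = default_species()
    n_oak_pole = max(3, config.n_oak_plots // 4)
    n_pine_pole = max(2, config.n_pine_plots // 4)
    lib = []
    for _ in range(config.n_oak_plots):
        lib.append(_make_plot("oak", "sawtimber", config, ss, rng))
    for _ in range(n_oak_pole):
        lib.append(_make_plot("oak", "poletimber", config, ss, rng))
    for _ in range(config.n_pine_plots):
        lib.append(_make_plot("pine", "sawtimber", config, ss, rng))
    for _ in range(n_pine_pole):
        lib.append(_make_plot("pine", "poletimber", config, ss, rng))
    return lib


def library_ba_shares(
    library: list[SyntheticPlot], config: GeneratorConfig, species_set: SpeciesSet | None = None
) -> np.ndarray:
    """Expected landscape basal-area shares implied by the library, weighting
    each stratum by the cell fraction it will be assigned to."""
    ss = species_set or default_species()
    pine_frac = config.ba_shares.get("pine", 0.0)
    ft_frac = {"oak": 1.0 - pine_frac, "pine": pine_frac}
    sc_frac = {"sawtimber": 1.0 - config.pole_fraction, "poletimber": config.pole_fraction}
    counts: dict[tuple[str, str], int] = {}
    for p in library:
        counts[(p.forest_type, p.size_class)] = counts.get((p.forest_type, p.size_class), 0) + 1
    ba = np.zeros(len(ss))
    for p in library:
        w = ft_frac[p.forest_type] * sc_frac[p.size_class] / counts[(p.forest_type, p.size_class)]
        for name, age, dens in p.cohorts:
            sp = ss[name]
            ba[ss.index(name)] += w * dens * math.pi * (sp.dbh(age) / 200.0) ** 2
    return ba / ba.sum()


def initialize_landscape(
    maps: tuple[np.ndarray, np.ndarray, np.ndarray],
    library: list[SyntheticPlot],
    config: GeneratorConfig,
    rng: np.random.Generator,
    species_set: SpeciesSet | None = None,
) -> Landscape:
    """Assign one stratum-matched plot to every cell.

    ``maps`` is (landtype, stand, management area).  The pine forest-type
    stratum occupies the southernmost cells (the configured pine share of the
    landscape); the poletimber stratum is scattered.  Raises when a cell's
    stratum has no plots in the library.
    """
    landtype_map, stand_map, ma_map = maps
    ss = species_set or default_species()
    shape = landtype_map.shape
    n = landtype_map.size
    land = Landscape(ss, shape, landtype_map.ravel(), stand_map.ravel(), ma_map.ravel(),
                     default_landtypes())

    pine_cells = int(round(config.ba_shares.get("pine", 0.0) * n))
    forest_type = np.array(["oak"] * n, dtype=object)
    if pine_cells:
        forest_type[n - pine_cells:] = "pine"  # southern (bottom) block
    size_class = np.where(rng.random(n) < config.pole_fraction, "poletimber", "sawtimber")

    pools: dict[tuple[str, str], list[SyntheticPlot]] = {}
    for p in library:
        pools.setdefault((p.forest_type, p.size_class), []).append(p)

    step = ss.step
    for idx in range(n):
        stratum = (forest_type[idx], str(size_class[idx]))
        pool = pools.get(stratum)
        if not pool:
            raise ValidationError(f"no library plots for stratum {stratum}")
        plot = pool[int(rng.integers(len(pool)))]
        for name, age, dens in plot.cohorts:
            land.density[ss.index(name), int(round(age / step)), idx] += dens
    return land


def generate_landscape(
    config: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
    species_set: SpeciesSet | None = None,
) -> Landscape:
    """Convenience wrapper: maps + library + assignment under one seed."""
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lt = generate_landtype_map(config, rng)
    stands, ma = generate_stand_and_ma_maps(lt, config, rng)
    library = build_plot_library(config, rng)
    return initialize_landscape((lt, stands, ma), library, config, rng, species_set)


# ---------------------------------------------------------------------------
# composition comparison and germination-seed calibration
# ---------------------------------------------------------------------------


def chi_square_composition(predicted, observed) -> tuple[float, int, float]:
    """Pearson chi-square between predicted and observed per-species vectors.

    ``chi2 = sum (pred - obs)**2 / obs`` with df = n_groups - 1.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValidationError("predicted and observed must have the same length")
    if np.any(obs <= 0):
        raise ValidationError(
            "observed categories must be > 0 (collapse empty categories first)"
        )
    stat = float(((pred - obs) ** 2 / obs).sum())
    df = obs.size - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def simulate_trajectory(
    land: Landscape,
    n_steps: int,
    seed: int,
    germination_seeds=None,
) -> dict[str, np.ndarray]:
    """Run ``n_steps`` succession steps and return the per-step landscape-mean
    density and basal-area vectors by species.

    ``density`` and ``ba`` are (n_steps, S) arrays (steps 1..n); the final
    rows are the end-of-run vectors.
    """
    ss = land.species_set
    if germination_seeds is not None:
        ss = ss.with_germination(germination_seeds)
    cur = land.copy(species_set=ss)
    rng = np.random.default_rng(seed)
    dens, ba = [], []
    for _ in range(n_steps):
        cur = succession_timestep(cur, rng)
        dens.append(cur.mean_density_by_species())
        ba.append(cur.mean_ba_by_species())
    return {"density": np.array(dens), "ba": np.array(ba)}


@dataclass
class CalibrationResult:
    seeds: np.ndarray          # fitted germination-seed counts, per species
    chi_square: float          # final combined chi-square
    n_cycles: int
    converged: bool
    at_bounds: np.ndarray      # per-species flag: fit pinned at a search bound


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = c if fc <= fd else d
    return x, min(fc, fd)


def calibrate_germination_seeds(
    landscape_t0: Landscape,
    observed_trajectory: dict[str, np.ndarray],
    bounds: tuple[float, float] | list[tuple[float, float]],
    tol: float = 1.0,
    n_steps: int = 6,
    seed: int = 0,
    max_cycles: int = 10,
    initial=None,
) -> CalibrationResult:
    """Fit per-species germination-seed counts to an observed trajectory.

    Coordinate-wise golden-section search minimizing the combined chi-square
    between the predicted and observed per-step density and basal-area
    vectors over ``n_steps`` succession steps, cycling over species until no
    count moves by more than ``tol`` (or ``max_cycles`` is hit, flagged
    unconverged).
    """
    ss = landscape_t0.species_set
    S = len(ss)
    if isinstance(bounds, tuple) and np.isscalar(bounds[0]):
        bounds = [bounds] * S
    if len(bounds) != S:
        raise ValidationError("need one (lo, hi) bound pair per species")
    obs_d = np.asarray(observed_trajectory["density"], dtype=float)
    obs_b = np.asarray(observed_trajectory["ba"], dtype=float)

    cache: dict[tuple, float] = {}

    def objective(g: np.ndarray) -> float:
        key = tuple(np.round(g, 6))
        if key not in cache:
            pred = simulate_trajectory(landscape_t0, n_steps, seed, germination_seeds=g)
            stat = 0.0
            for p, o in ((pred["density"], obs_d), (pred["ba"], obs_b)):
                m = o > 0
                stat += float(((p[m] - o[m]) ** 2 / o[m]).sum())
            cache[key] = stat
        return cache[key]

    g = np.array(
        [np.clip(x, lo, hi) for x, (lo, hi) in zip(
            initial if initial is not None else ss.germ, bounds)],
        dtype=float,
    )
    best = objective(g)
    n_cycles, converged = 0, False
    if best == 0.0:
        converged = True
    while not converged and n_cycles < max_cycles:
        n_cycles += 1
        max_move = 0.0
        for s in range(S):
            lo, hi = bounds[s]

            def f(x, s=s):
                trial = g.copy()
                trial[s] = x
                return objective(trial)

            x, fx = _golden_section(f, lo, hi, tol)
            if fx < best - 1e-12:
                max_move = max(max_move, abs(x - g[s]))
                g[s], best = x, fx
        if max_move <= tol:
            converged = True
    at_bounds = np.array(
        [min(abs(x - lo), abs(x - hi)) <= tol for x, (lo, hi) in zip(g, bounds)]
    )
    return CalibrationResult(g, best, n_cycles, converged, at_bounds)
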