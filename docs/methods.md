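# Methods

## Model state and time step

The landscape is a rectangular raster of 90-m cells (0.81 ha).  Cell state
is a cohort ledger: trees/ha by (species group, age), ages on the 5-year
simulation grid.  Internally all cells are held in one dense
`density[species, age_bin, cell]` array so that growth, dispersal,
establishment, self-thinning, and mortality are vectorized array passes;
cell-level reference implementations of the same operations exist alongside
and are held to identical semantics by the test suite.

One 5-year step applies, in order: growth (ages advance, DBH re-derived),
seed dispersal, establishment, self-thinning, longevity mortality, and
resprouting of the longevity-killed cohorts.  The order is a modeling
choice; it puts density-dependent mortality after establishment so that a
cohort established into a gap is itself subject to competition in the same
step.  All stochastic draws consume one numpy Generator in species-major,
raster-scan order, so runs are bit-reproducible per seed.

## Stand-level quantities

* **Reineke SDI**: `SDI_s = Σ_i N_i (D_i / 25.4)^1.605` per species.
* **GSO**: `Σ_s SDI_s / maxSDI_s`.  A cell is fully occupied at its
  landtype's MGSO.  Stand development stages follow from GSO and its
  history: initiation (never reached MGSO), stem exclusion (at/above MGSO),
  understory reinitiation (previously full, now below), old growth
  (additionally a cohort at ≥80 % of its longevity).
* **Age–DBH**: Chapman–Richards `D = Dmax (1 − e^{−k·age})^p` with `p = 1.3`
  and `k = −ln(1 − 0.95^{1/p}) / longevity`, so `D(longevity) = 0.95 Dmax`
  by construction and `D < Dmax` at all ages.  The true age–DBH relations
  of the system are empirical and not publicly tabulated; this curve is a
  stand-in chosen for its standard form, monotonicity, and the single
  interpretable calibration constraint.  Its early growth is fast, which
  matters for one desk-scale result (see Known departures).
* **Biomass allometry**: per-tree `w = a D^b` with `a = 0.1 kg·cm⁻ᵇ` and
  `b = 1.5 × 1.605 = 2.4075`.  Along the SDI ceiling `N D^{1.605}` is
  constant, so `w̄ ∝ N^{−b/1.605} = N^{−3/2}`: self-thinning traces Yoda's
  −3/2 law exactly, by design.  `a` cancels from every ratio- or
  slope-based result.

Densities are stored as reals per hectare; whole-tree granularity is
imposed only at removal time (self-thinning, harvest), rounding half-up per
0.81-ha cell.  Post-thinning GSO is within one removable tree of MGSO.

## Dispersal, establishment, sprouting

Dispersal is a hard-cutoff kernel: a cell receives a species' seeds iff
some cell within `max_seed_distance` (200 m for all groups; Euclidean
cell-center distance on the 90-m lattice, 13-cell neighborhood) holds a
mature cohort of it.  `germination_seeds` (Table defaults: pines 50,
hickories 30, others 90) is interpreted as the per-cell, per-species count
of potential germinating seeds — a fecundity cap, not a per-source
contribution summed over neighbors.  The summed reading would deliver
thousands of seeds per cell in any mature neighborhood, saturating
establishment in one step and stripping the parameter of the influence on
density and basal area that makes it worth calibrating.

Each potential seed establishes independently with the landtype's species
establishment probability (SEP), only while `GSO < MGSO` and below a
shade-tolerance ceiling `GSO < MGSO (0.3 + 0.15 (class − 1))` — tolerance
class 1 needs near-open cells, class 5 (maples) establishes almost until
full occupancy.  The linear ceiling is the simplest monotone form carrying
the stated tolerance dependence.

Cohorts killed by longevity or harvest resprout if their age lies in the
species' sprouting window: each removed whole tree sprouts with the
vegetative reproduction probability, forming a cohort that is age 5 at the
end of the step.  (Harvest-origin sprouts enter the ledger at age 0 and
pass through the same step's growth; this keeps basal-area conservation —
pre-harvest = residual + harvested — exact to round-off through the
harvest step, since age-0 trees carry zero DBH.)

## Harvest

Prescriptions are per management area, in a plain-text `#key# value`
dialect (one packaged default mirrors a national-forest management plan:
ranking 6 = highest mean basal area, entry and reentry every 5 years,
eligibility floor and thinning residual 18.36 m²/ha, 3 % of the management
area per entry, removal priority hickory < maple < black oak < red oak <
white oak < pine, largest trees first).  All basal-area values in
prescriptions are m² per hectare.

Per due entry: stands (contiguous cell groups nested in management areas)
are screened for eligibility (mean BA ≥ floor, entry year reached, not
treated within the reentry interval — a stand treated exactly one interval
ago is eligible), ranked, and selected until the cumulative *stand* area
crosses the per-entry proportion of the MA (the last stand may overshoot).
Thinning removes whole trees in (species priority, DBH descending) order
until the stand mean BA reaches the target, so the residual is within one
tree of it; a zero target is a clearcut.  Group selection instead walks the
ranked stands cutting one contiguous opening per stand (opening size
Poisson around a 3-cell mean, min 1, grown by rook adjacency from a uniform
seed cell, truncated to the stand) until the cumulative *cleared* area
reaches the same proportion target.  Counting openings rather than stand
footprints against the area target is what makes small scattered openings
sum to the same harvested amount as clearcutting — the regime the original
management comparison describes; counting stand footprints would let group
selection touch only a few dozen cells per entry and make it a no-op at
this scale.

The per-entry interpretation of the 0.03 area proportion is the default; a
`proportion_basis="per_year_annualized"` switch multiplies it by the
reentry interval instead.

Treatment-by-site policy in the scenario runner: thinning prescriptions
attach to every management area; clearcutting and group selection only to
management areas whose cells are majority low-quality landtypes.

## Risk rating

Per pixel, from red-oak-group basal area (red oak + black oak groups by
default; `include_black_oak=False` restricts to the red-oak group) and the
landtype's site quality.  High risk strictly above 6.9 (low quality) or
13.8 m²/ha (high quality); low risk strictly below 2.3 m²/ha; moderate
otherwise, boundaries inclusive to moderate.  Landscape summaries are pixel
percentages; rasters use codes 1/2/3 (low/moderate/high).

## Synthetic landscape generator

The generator emulates the statistical structure of an inventory-
initialized mature oak landscape; it does not reproduce any real place.

* **Landtype mosaic**: thresholded Gaussian-smoothed noise (σ = 3 cells)
  cut at the quantiles of the target proportions (defaults: ridgetop 0.20,
  SW slope 0.30, NE slope 0.30, floodplain 0.20 — half the landscape
  low-quality).
* **Management areas and stands**: stochastic multi-source flood fill —
  6 contiguous management areas, then contiguous stands nested inside them,
  mean 6 cells (~5 ha, the scale of stands in dissected terrain).
* **Plot library and assignment**: every cell draws one plot from a
  stratified library (forest type: oak vs pine; size class: sawtimber vs
  poletimber), emulating stratified plot assignment.  Oak sawtimber plots
  carry dominant oak cohorts aged 70–100 y (uniform, 5-y grid) with
  hickory (40–70 y) and maple (30–60 y) mid-story; plot composition is
  Dirichlet around the target shares with concentration 6 and lognormal
  (σ = 0.3) total-BA jitter — deliberately heterogeneous, as real plot
  pools are; an oak group must hold the plurality of plot basal area.
  Pine plots are pure pine and are assigned to the southernmost 15 % of
  cells, giving the spatially clustered pine component.  Poletimber plots
  (10 % of cells, scattered) are younger (20–40 y) at 40 % of the BA level.
* **Levels**: total BA 22 m²/ha in sawtimber plots — overstocked for
  upland oak (fully stocked is roughly 18–23 m²/ha) and consistent with
  the ~24 m²/ha reported for heavily stocked stands in the region.  MGSO
  0.50/0.55/0.60/0.65 by landtype: self-thinning onset near 55 % of
  maximum SDI, where relative-density stocking guides place it.  SEP
  defaults range 0.05–0.40, higher for pines/oaks on dry sites and for
  maples/white oaks on mesic sites, reflecting episodic oak establishment.
  Target composition: white oaks 30 %, red-oak group 40 % (split 60/40
  between the red-oak and black-oak functional groups; the split within
  the section is not reported anywhere and is a flagged choice), hickories
  10 %, maples 5 %, pines 15 %.

Under these defaults the initial landscape has mean GSO slightly above the
low-quality MGSO, so the first step shows an equilibration transient from
self-thinning.  It is reported in the comparison output (its own line), not
smoothed away.

## Calibration harness

`chi_square_composition` is the Pearson χ² over the six species groups
(`Σ (pred − obs)² / obs`, df = 5).  `calibrate_germination_seeds` refits
per-species germination-seed counts to an observed trajectory: coordinate-
wise golden-section search (bounds per species, tolerance 1 seed, max 10
cycles, early exit when a cycle moves no species by more than the
tolerance) minimizing the combined χ² of the per-step predicted vs
observed density and basal-area vectors over a 30-year (6-step) run.
Per-step vectors, rather than end-of-run vectors alone, are used because
the end state under-identifies species whose establishment saturates early.
Because no observed 30-year species trajectories are published for the
system, calibration is validated as parameter recovery against synthetic
truth: on a 50×50 young landscape (BA level 9 m²/ha, so establishment is
active) with a noise-free trajectory, all six counts are recovered to
within 2 %.

## What the synthetic tests do and do not show

Passing tests show the mechanisms are implemented to contract (thresholds,
conservation, the −3/2 line, dispersal cutoff, prescription limits,
recovery of a known parameter), and that the main qualitative dynamics of
the managed system emerge: high-risk area declines strongly over the first
five decades under every alternative as the old red-oak cohorts reach
longevity; harvesting accelerates the decline, with clearcutting the most
effective at years 20–50 and thinning retaining the most live biomass of
the three treatments.  They do not show agreement with any real inventory,
and two landscape-scale expectations do not reproduce at desk scale:

* *Group selection as the best short-term treatment.*  Its reported edge
  comes from reaching scattered pockets of risk.  On a 50×50 landscape
  where ~40 % of pixels are high-risk, openings and whole-stand clearcuts
  flip nearly identical numbers of pixels, so group selection and
  clearcutting are statistically tied at year 20 (group selection lowest in
  a minority of replicates).
* *Convergence of the alternatives by year 100.*  Under the fast default
  growth curve, cells cleared in years 5–50 regenerate red-oak basal area
  past 6.9 m²/ha within ~50 years (sprouting plus dry-site establishment),
  so the treated alternatives re-diverge upward in high-risk share late in
  the run instead of converging.  A slower juvenile age–DBH curve would
  delay the rebound past the horizon; the default form is kept for its
  single-constraint calibration.

Both behaviors are asserted as written in the acceptance suite and fail
there by design rather than being weakened to pass.

## Numerical choices

Whole-tree rounding at removal (ceil on the marginal tree, so residuals
land at or just below targets); ties in self-thinning order broken by lower
shade tolerance, then age closest to longevity, then species table order;
stand ranking ties by ascending stand id; float round-off below 1e-9
trees/ha is flushed to zero after thinning; conservation is audited at run
time in the harvest step and aborts on violation; zero-observed χ²
categories raise (collapse categories first); golden-section search caches
objective evaluations.

## Scale of shipped experiments

Default experiment: 50×50 cells (~2,000 ha), 6 management areas, 100 years
at 5-year steps, 5 replicates (replicate r seeded `seed + r`) — the scale
chosen for the package's test and demonstration runs; all grid sizes,
horizons, and replicate counts are configuration.
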