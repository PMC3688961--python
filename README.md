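# oakmosaic

Cohort-based forest landscape simulation for evaluating how harvest
alternatives — thinning, clearcutting, and group selection — mitigate oak
decline in Central Hardwood Forest landscapes.

## The problem

Oak decline is the progressive dieback and mortality of oaks driven by
predisposing factors (old, dense stands of decline-susceptible red-oak-group
species on droughty sites), inciting factors (drought, defoliation), and
contributing agents (insects, pathogens).  Managers use harvesting to remove
susceptible trees before decline sets in, but the landscape-scale, century-
scale consequences of different treatment types are hard to observe
directly.  `oakmosaic` is a desk-scale simulator for exactly that question:
it couples a raster forest-succession model, a management-area harvest
scheduler, and a pixel-level oak-decline risk classifier, with a synthetic
landscape generator that reproduces the statistical structure of a mature,
overstocked Ozark Highlands oak landscape.

## The model

Each 90-m cell (0.81 ha) carries a ledger of species-age cohorts
(trees/ha) for six species functional groups (pines, black oak, red oaks,
white oaks, hickories, maples).  Stand dynamics run on a 5-year step from
four quantities:

* **Reineke SDI** — `SDI = N (D / 25.4 cm)^1.605`, density standardized to
  the 10-inch reference tree; each species group has a maximum SDI.
* **Growing-space occupancy** — `GSO = Σ_s SDI_s / maxSDI_s`; a cell is
  fully occupied when GSO reaches its landtype's maximum (MGSO).
* **Age–DBH growth** — Chapman–Richards `D(age) = Dmax (1 − e^{−k·age})^p`,
  `k` calibrated so `D(longevity) = 0.95 Dmax`.
* **Self-thinning** — when GSO exceeds MGSO, trees are removed smallest
  first until the cell returns to MGSO; with the default biomass allometry
  `w = a D^{1.5·1.605}` this walks Yoda's −3/2 line
  (`log w̄ = −3/2 log N + c`) exactly.

Seed dispersal is limited to 200 m; establishment needs open growing space
(scaled by shade tolerance), a landtype-specific establishment probability,
and at most `germination_seeds` potential seeds per cell per step.  Cohorts
die at their species' longevity, and killed or harvested cohorts of
sprouting age resprout with the species' vegetative reproduction
probability.

Harvesting is prescription-driven per management area (Table-dialect
`#key# value` files): stands above an 18.36 m²/ha floor are ranked (highest
basal area first, or random), selected to cover 3 % of the management area
per 5-year entry, and treated by thinning to a residual basal area (species
priority: hickory, maple, black oak, red oak, white oak, pine; largest
trees first), clearcutting, or group-selection openings (mean 3 cells).

Oak-decline risk is rated per pixel from red-oak-group basal area (red oak
+ black oak groups) and site quality: **high** above 6.9 m²/ha on
low-quality sites (ridgetops, SW slopes) or above 13.8 m²/ha on
high-quality sites (NE slopes, floodplains); **low** below 2.3 m²/ha;
**moderate** between.

## Worked example

Compare all four alternatives (5 replicates each, 100 years, default
synthetic landscape):

```sh
oakmosaic compare --seed 0 --replicates 5 --out runs/demo
```

which prints (abridged):

```
no_harvest:      high-risk % at y20/50/100 = 48.41/32.49/23.35; final biomass = 132.0 Mg/ha
thinning:        high-risk % at y20/50/100 = 46.65/32.10/23.79; final biomass = 118.6 Mg/ha
clearcutting:    high-risk % at y20/50/100 = 45.78/30.22/29.88; final biomass = 110.6 Mg/ha
group_selection: high-risk % at y20/50/100 = 46.09/30.85/30.28; final biomass = 117.9 Mg/ha

biomass retention ranking: no_harvest > thinning > group_selection > clearcutting
```

Read: every alternative shows the strong natural decline of high-risk area
over the first five decades (the old red-oak cohorts die and are replaced);
harvesting accelerates it, clearcutting most in the short and medium term;
thinning retains the most live biomass of the three treatments because it
only removes down to the 18.36 m²/ha residual.  `runs/demo` holds the
per-step time series (basal area and harvested basal area by species,
biomass, risk shares) as CSV, risk-class rasters at years 0/20/50/100 as
ESRI ASCII grids, a comparison table, and run manifests with the replicate
seeds.

Other verbs: `oakmosaic synth` (generate and save a landscape),
`oakmosaic simulate` (one alternative), `oakmosaic risk` (rate a saved
landscape).  Library use mirrors the CLI: see `oakmosaic.run_scenario`,
`oakmosaic.succession_timestep`, `oakmosaic.harvest_timestep`,
`oakmosaic.landscape_risk_summary`, `oakmosaic.calibrate_germination_seeds`.

## Limitations

The landscape is synthetic: it matches the target composition (≈30 % white
oaks, 40 % red-oak group, 10 % hickories, 5 % maples, 15 % spatially
clustered pines, oak cohorts 70–100 years old at high density) in
distribution, not any real inventory.  Fire, wind, insects, and drought are
not simulated (fire tolerance is carried as a parameter but unused), and
there is no economic valuation.  See `docs/methods.md` for model details,
parameter defaults, and known departures of desk-scale behavior from
landscape-scale expectations.
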