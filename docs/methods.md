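# Methods

## Model and assumptions

`ecofoot` implements the standard Leontief demand-pull model over an
environmentally extended MRIO table. The economy is assumed productive: the
technical-coefficient matrix `A` must have spectral radius strictly below 1,
estimated by 100 power-iteration steps from a positive start vector (exact in
the limit for non-negative matrices by Perron–Frobenius) and gated at
`1 − 1e-9`. The full explicit inverse `L = (I − A)⁻¹` is computed with a
dense solve rather than per-demand linear solves because source attribution
needs every column of `L`; the residual `‖L(I−A) − I‖_max` is checked against
`1e-9` and the computation refused if it fails. At desk scale (`s` up to a
few hundred) this is cheap.

Zero-output sectors follow a 0/0 → 0 convention: their coefficient and
intensity columns are zero, and any nonzero transaction or pressure recorded
against them is raised as an account inconsistency rather than propagated as
an infinity, since a silent `inf` would poison the inverse. Negative final
demand (inventory draw-down) is legal and only warned about; negative
transactions or outputs are errors. Negative footprint contributions arising
from negative demand are propagated unclipped, and all column normalizations
(domestic shares, transfer percentages, contributor rankings) use signed
sums — clipping would break conservation.

Impacts are carried in PDF·yr (potentially disappeared fraction of species
integrated over time) throughout; pathway rows may be summed per consumer
because all pathways damage the same area of protection, ecosystem quality,
in one common unit. Impact pathways are treated as independent: no
synergistic multi-stressor interactions are modelled.

## Characterization factors

Gridded factor layers are collapsed to one value per country with a
pressure-weighted mean over the country's valid cells. The weighted mean is
evaluated in shifted form `c_min + Σ w (c − c_min) / Σ w`, which is
algebraically identical to `Σ w c / Σ w` but recovers a spatially constant
factor exactly in floating point and is better conditioned when factors span
a narrow range. Where a country's total mapped pressure is zero the
unweighted arithmetic mean of its factor cells is used (the weighted mean is
undefined there and the two coincide in the uniform limit); a country with
no valid cells gets factor 0 with a warning rather than being dropped.

Weighting semantics are deliberately generic: the function weights by
whatever pressure layer the caller supplies (emission mass for emissions,
occupied area or consumed volume for land and water), leaving the proxy
choice to data preparation.

All co-used layers must share one grid shape and geotransform; the module
raises on mismatch. Regridding heterogeneous native resolutions is a
scientific choice, not plumbing, so it is required as an explicit
pre-processing step and never done silently. Raster row 0 is the northern
edge; masks are exclusive cell-center assignments; no partial-cell area
weighting.

Within a country, all sectors share the country factor (`expand_cf` repeats
columns over sector blocks). Greenhouse gases take a single global factor —
their damage is independent of the emission location — so pressure and
impact footprints are exactly proportional for them. Forestry uses a
weighted average of intensive- and extensive-forestry factors with default
weights (0.5, 0.5), configurable; agricultural cropland uses the
annual-crops factor. Unit conversions are exact rational factors
(Gg → kg: 1e6; Ha → km²: 1e-2; m³, kg unchanged).

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the analysis relies on, not
any particular year's economy:

- **Accounts.** Allocation shares and magnitudes are heavy-tailed
  (lognormal), as real IO tables are highly skewed. Every column of `A` sums
  to `intermediate_share` (default 0.45) split domestic/foreign by
  `trade_openness` (default 0.25), which bounds the spectral radius by the
  column sum. Final-demand totals are drawn strictly positive and gross
  output solved as `x = (I − A)⁻¹ y`, so the row balance `x = Z·1 + Y·1` is
  exact to solver precision (~1e-15 relative) and every account entry
  non-negative. Balance is imposed by construction, not by RAS-style
  iterative adjustment, for determinism and exact conservation in tests.
- **Satellite.** Thirteen pressure rows follow the standard registry
  (Gg, m³, Ha, kg) with unit-typical lognormal magnitudes.
- **Rasters.** The grid is tiled into rectangular country blocks; factor
  cells sit at a baseline of 1e-12 PDF·yr per unit, multiplied by
  `cf_contrast` inside hotspot countries, with multiplicative lognormal cell
  noise of sigma `cf_noise` (default 0.25, mean-corrected). Pressure cells
  are drawn independently of the factors — pressures lie where the economy
  is, not where the species are. `cf_contrast` defaults to 30: observed
  country-mean factors differ by factors of a few between neighbouring large
  economies and by orders of magnitude between hotspot and non-hotspot
  countries, and 30 sits in that range while keeping 6-country summaries
  stable.

All draws are seeded; each component (structure, demand, allocation,
satellite, factors, pressure grids) uses its own substream derived from
`(seed, component-tag)`, so adding a component never perturbs another's
draws and identical seeds are bit-identical.

The **burden-shift scenario** fixes six countries in two groups: H (R00–R02)
is the hotspot group, L (R03–R05) carries 4-fold pressure-intensive sectors.
Its factor rasters are piecewise-constant per country (`cf_noise = 0`): the
collapse check — forcing `cf_contrast = 1` must make pressure and impact
group-share tables coincide to 1e-10 — requires factors that are exactly
uniform at contrast 1, which cell noise would break. With contrast > 1 the
qualitative pattern (H's origin share of impact exceeds its origin share of
pressure) holds by construction for every seed, because group factors differ
by a strict ratio while attributed pressure is conserved.

What passing these tests does **not** show about real data: synthetic
economies have no sector heterogeneity in factor exposure within a country,
no negative inventory entries, no price effects, and factor geography far
simpler than ecoregion- or watershed-resolved factor sets; results on real
MRIO databases additionally inherit those databases' allocation and
aggregation errors, which are not modelled.

## Reporting conventions

Standard scores use the population (divide-by-n) standard deviation — the
country set is the full population of interest; the choice rescales both
axes identically and cannot change rank order. A constant vector maps to
all-zero scores with σ recorded as 0, and the comparison correlation is
reported as 0.0 in that degenerate case (Pearson is undefined there). The
score difference is pressure score minus impact score, so positive values
mark countries whose burden falls when switching to the impact metric.
Ranking ties break lexicographically by region identifier for
reproducibility. The optional log view uses log10 of strictly positive
values, dropping non-positive entries with a recorded count.

Group transfer percentages are normalized per consumer column (each column
of `column_percent` sums to 100 when its absolute total is nonzero), so a
cell reads "share of this consumer group's footprint originating in that
origin group".

## Numerical choices and tolerances

- Balance validation: relative residual `|x_i − (Σ_j Z_ij + Σ_c Y_ic)| /
  max(x_i, 1)`, default tolerance 1e-6 (the generator meets 1e-8).
- Inverse residual: 1e-9 max-abs; spectral gate `1 − 1e-9`.
- Aggregate/source-resolved consistency: 1e-10 relative by construction.
- Double precision throughout; no iterative refinement.
- TSV round-trips use shortest-repr floats and `round_trip` parsing, so
  write-then-read is bit-exact.

## I/O formats

Tab-delimited UTF-8 matrices with explicit two-row axis headers (region,
sector); satellite rows carry their unit in the row index. Rasters are
single-band GeoTIFFs written and read through `tifffile` with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA); the
country mask stores its region list in a JSON sidecar. Mapping and scenario
configuration are YAML; bundles are tied together by a JSON manifest. No
vendor MRIO layout is parsed; adapters for distribution-specific formats are
future work.

## Known limitations

- Country-level factor aggregation blurs sub-national hotspots; large,
  ecologically varied countries are the worst case.
- The reported unit is PDF·yr everywhere; no time-horizon division to a
  dimensionless PDF is applied, and outputs state the unit explicitly.
- Land pressures can be grouped for reporting (cropland + pasture +
  forestry), but shares are computed on ungrouped rows.
- No uncertainty propagation, structural decomposition, supply-side (Ghosh)
  model, or price rebasing.
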