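# ecofoot

Consumption-based footprints traditionally report environmental *pressures* —
cubic meters of water withdrawn, hectares occupied, gigagrams of CO₂ emitted —
attributed to the nation whose final demand drives them. But a hectare of
pasture in a biodiversity hotspot and a hectare on species-poor rangeland are
not the same event for ecosystems. `ecofoot` extends pressure accounting to
**ecosystem impact footprints**: it links an environmentally extended
multi-regional input-output (EE-MRIO) model to spatially explicit life-cycle
impact-assessment characterization factors, measuring potential biodiversity
damage in units of potentially disappeared fraction of species (PDF·yr).

It is written for industrial ecologists and ecological economists who want to
run, test, or extend impact-footprint accounting without first assembling the
very large external datasets real studies use: the package ships a synthetic
generator producing balanced MRIO accounts, physical satellite accounts, and
raster "worlds" with controllable characterization-factor geography, so every
step of the pipeline is verifiable at desk scale.

## The model

With `n` regions and `k` sectors per region (`s = n·k` region-sector pairs):

- technical coefficients `A = Z x̂⁻¹` from the transaction matrix `Z` and
  gross output `x`; the total-requirements (Leontief inverse) matrix
  `L = (I − A)⁻¹`, gated on spectral radius < 1;
- pressure footprint `D = f̂ L Y`, where `f = F x̂⁻¹` is the satellite account
  `F` (an `r × s` matrix of physical pressures) normalized by output and `Y`
  is final demand per consuming nation;
- country characterization factors by pressure-weighted zonal aggregation of
  gridded factor maps `C` and pressure maps `F` over a country's cells `m`:
  `CF_country = Σ_m F_m C_m / Σ_m F_m` (arithmetic mean fallback where the
  country's total mapped pressure is zero); greenhouse gases take a single
  global factor;
- impact footprint `Q = (C ∘ f) L Y` (Hadamard product of the expanded
  country factors with the intensity), in PDF·yr;
- source attribution: diagonalizing the intensity row instead of summing it
  yields an `s × n` origin-by-consumer table, aggregated over sector blocks
  to an `n × n` table per pressure, from which domestic shares and group
  (e.g. income-class) transfer tables follow;
- pressure-vs-impact comparison by independent standardization of each
  footprint vector to standard scores `(x − μ)/σ` (population σ).

Thirteen pressures map onto eight impact pathways (climate change, water
stress, three land-occupation types, freshwater and marine eutrophication,
terrestrial acidification) with fixed unit conversions (Gg → kg, Ha → km²).

## Worked example

The built-in burden-shift scenario has six countries in two groups: `H`
(R00–R02) hosts high characterization factors (a biodiversity-hotspot group),
`L` (R03–R05) exports pressure-intensive goods:

```python
import numpy as np
from ecofoot import (burden_shift_scenario, source_attribution,
                     group_transfers, pressure_impact_comparison)
from ecofoot.pipeline import run_bundle

bundle = burden_shift_scenario(seed=1)
res = run_bundle(bundle)

pa = source_attribution("pasture", res.pressure, bundle.accounts.index)
ia = source_attribution("pasture", res.impact, bundle.accounts.index)
tp = group_transfers(pa, bundle.grouping, groups=bundle.groups)
ti = group_transfers(ia, bundle.grouping, groups=bundle.groups)
print(np.round(tp.column_percent, 1))   # pressure, origin rows x consumer cols
print(np.round(ti.column_percent, 1))   # impact
```

prints

```
[[51.5 15.1]
 [48.5 84.9]]
[[97.  84.2]
 [ 3.  15.8]]
```

Read column-wise: under the pressure metric 48.5% of group H's pasture
footprint originates in group L, but under the impact metric only 3% does —
the burden, measured as potential species loss, shifts onto the high-factor
group itself. The standardized comparison makes the same point per country:

```python
p = res.pressure.row("pasture")
comp = pressure_impact_comparison(res.pressure.aggregate[p],
                                  res.impact.aggregate[p],
                                  regions=bundle.accounts.index.regions)
print(round(comp.correlation, 3))
```

gives `-0.064`: country rankings under pressure and impact are essentially
unrelated in this world, whereas a spatially uniform factor (the
greenhouse-gas case) forces correlation 1 exactly.

The same pipeline runs from the shell over on-disk bundles (TSV matrices,
GeoTIFF rasters, YAML mapping):

```sh
ecofoot simulate --seed 1 --burden-shift --out bundle/
ecofoot footprint --bundle bundle/ --grouping bundle/grouping.tsv --out results/
ecofoot report --bundle bundle/ --pressure "blue water consumption" --out report/
```

## Layout

- `ecofoot.mrio` — accounts, validation, Leontief algebra
- `ecofoot.characterization` — zonal CF aggregation, pressure mapping, units
- `ecofoot.footprint` — footprint tensors, attribution, transfers
- `ecofoot.reporting` — standard scores, comparisons, top contributors
- `ecofoot.synthetic` — scenario generators and the burden-shift bundle
- `ecofoot.io` — TSV/GeoTIFF/YAML readers and writers
- `ecofoot.pipeline` — end-to-end orchestration; `ecofoot.cli` — the CLI

See `docs/methods.md` for modelling assumptions, parameter choices, and
limitations.
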