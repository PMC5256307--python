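"""End-to-end orchestration: accounts + satellite + geography → footprints.

Thin glue over the mrio, characterization and footprint modules; it owns no
science of its own.  Given an input bundle it maps and unit-converts the
satellite, builds the country characterization-factor matrix (zonal
aggregation for spatially differentiated pressures, one global value for
greenhouse gases), runs the Leontief chain, and returns both footprint
tensors plus the Leontief solution for reuse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .characterization import (
    CountryCF,
    DEFAULT_MAPPING,
    MappedSatellite,
    PressureMapping,
    aggregate_cf,
    combine_pathway_cf,
    expand_cf,
    map_pressures,
    uniform_cf,
)
from .errors import StructuralError
from .footprint import (
    AttributionTable,
    FootprintTensor,
    impact_footprint,
    resource_footprint,
    source_attribution,
)
from .mrio import (
    LeontiefSolution,
    MRIOAccounts,
    SatelliteAccount,
    leontief_inverse,
    normalize_satellite,
)
from .synthetic import BurdenShiftBundle, SyntheticWorld


def build_country_cf(
    satellite: SatelliteAccount,
    world: SyntheticWorld | None,
    uniform_values: Mapping[str, float] | float = 0.0,
    mapping: PressureMapping = DEFAULT_MAPPING,
) -> tuple[MappedSatellite, CountryCF]:
    """Assemble the r x n country CF matrix for a mapped satellite.

    Spatially differentiated pressures are aggregated from the world's
    factor/pressure raster pairs; non-spatial pressures take a uniform
    global value (scalar, or per-pressure mapping).
    """
    mapped = map_pressures(satellite, mapping)
    regions = satellite.index.regions
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for lab in mapped.labels:
        entry = mapping.entry(lab)
        if entry.spatial:
            if world is None or lab not in world.factor_layers:
                raise StructuralError(
                    f"no factor layer for spatially differentiated pressure {lab!r}"
                )
            rows[lab] = aggregate_cf(
                world.pressure_layers[lab], world.factor_layers[lab], world.masks
            )
            provenance[lab] = "aggregated"
        else:
            value = (
                uniform_values
                if isinstance(uniform_values, (int, float))
                else uniform_values[lab]
            )
            rows[lab] = uniform_cf(float(value), regions)
            provenance[lab] = "uniform"
    cf = combine_pathway_cf(rows, mapped, regions, provenance)
    return mapped, cf


@dataclass
class PipelineResult:
    """Everything one footprint run produces."""

    mapped: MappedSatellite
    country_cf: CountryCF
    leontief: LeontiefSolution
    pressure: FootprintTensor
    impact: FootprintTensor

    def attribution(self, pressure: str, kind: str = "impact") -> AttributionTable:
        tensor = self.impact if kind == "impact" else self.pressure
        return source_attribution(pressure, tensor, tensor.index)

    @property
    def pathways(self) -> tuple[str, ...]:
        return self.mapped.pathways


def run_pipeline(
    accounts: MRIOAccounts,
    satellite: SatelliteAccount,
    world: SyntheticWorld | None = None,
    country_cf: CountryCF | None = None,
    uniform_values: Mapping[str, float] | float = 0.0,
    mapping: PressureMapping = DEFAULT_MAPPING,
) -> PipelineResult:
    """Run the full chain on one input bundle.

    Either a prebuilt ``country_cf`` (aligned with the mapped satellite) or
    a ``world`` of rasters must be supplied.
    """
    if country_cf is None:
        mapped, country_cf = build_country_cf(
            satellite, world, uniform_values=uniform_values, mapping=mapping
        )
    else:
        mapped = map_pressures(satellite, mapping)
        if country_cf.labels != mapped.labels:
            raise StructuralError(
                "country CF rows are not aligned with the mapped satellite"
            )
    index = accounts.index
    sol = leontief_inverse(accounts.A)
    f_norm = normalize_satellite(mapped.F, accounts.x)
    pressure = resource_footprint(
        f_norm, sol.L, accounts.Y, index, mapped.labels, mapped.units
    )
    C_exp = expand_cf(country_cf.C, index)
    impact = impact_footprint(C_exp, f_norm, sol.L, accounts.Y, index, mapped.labels)
    return PipelineResult(
        mapped=mapped,
        country_cf=country_cf,
        leontief=sol,
        pressure=pressure,
        impact=impact,
    )


def run_bundle(bundle: BurdenShiftBundle) -> PipelineResult:
    """Run the pipeline on a burden-shift bundle."""
    return run_pipeline(
        bundle.accounts,
        bundle.satellite,
        world=bundle.world,
        uniform_values=bundle.uniform_cf_value,
        mapping=bundle.mapping,
    )
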