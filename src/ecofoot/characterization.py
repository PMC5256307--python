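"""Country-level characterization factors from gridded layers.

Life-cycle impact assessment supplies characterization factors (CFs) —
potential biodiversity damage, in PDF·yr, per physical unit of pressure —
on grids much finer than the national resolution of MRIO accounts.  This
module collapses a CF raster to one factor per country by weighting each
grid cell with the local pressure (emission-weighted for emissions,
resource-weighted for water and land), applies the fixed pressure →
impact-pathway mapping with its unit conversions, and expands country
factors to the region-sector axis of the economic model.

All co-used layers must share one grid and geotransform; regridding of
native CF resolutions is a documented pre-processing step, not performed
here.  Raster row 0 is the northern edge; masks assign cell centers; no
partial-cell area weighting is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    AssemblyError,
    DataError,
    MappingError,
    ParameterError,
    StructuralError,
    UnitError,
)
from .mrio import RegionSectorIndex, SatelliteAccount

#: mask value for cells belonging to no country (ocean, unclaimed).
NO_COUNTRY = -1

#: exact unit conversions, (unit_in, unit_out) -> multiplicative factor.
UNIT_CONVERSIONS: dict[tuple[str, str], float] = {
    ("Gg", "kg"): 1e6,
    ("Ha", "km2"): 1e-2,
    ("m3", "m3"): 1.0,
    ("kg", "kg"): 1.0,
}


@dataclass(frozen=True)
class GeoTransform:
    """Affine georeference of a north-up raster: origin and cell size.

    ``x_origin, y_origin`` locate the outer corner of cell (0, 0); row 0 is
    the northern edge, so y decreases down the rows by ``dy``.
    """

    x_origin: float = 0.0
    y_origin: float = 0.0
    dx: float = 1.0
    dy: float = 1.0


@dataclass
class RasterLayer:
    """Single-band raster with an affine georeference and a nodata sentinel."""

    values: np.ndarray
    transform: GeoTransform = field(default_factory=GeoTransform)
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean grid of cells carrying data (finite and not nodata)."""
        valid = np.isfinite(self.values)
        if self.nodata is not None:
            valid &= self.values != self.nodata
        return valid


@dataclass
class CountryMaskSet:
    """Exclusive assignment of grid cells to regions.

    ``mask`` holds, per cell, the integer position of the owning region in
    ``regions`` or :data:`NO_COUNTRY`.
    """

    mask: np.ndarray
    regions: tuple[str, ...]
    transform: GeoTransform = field(default_factory=GeoTransform)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise StructuralError("country mask must be integer-valued")
        self.regions = tuple(self.regions)
        ids = np.unique(self.mask)
        ids = ids[ids != NO_COUNTRY]
        if ids.size and (ids.min() < 0 or ids.max() >= len(self.regions)):
            raise StructuralError("mask contains ids outside the region list")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass
class CountryCF:
    """Characterization factors per pressure (rows) and country (columns).

    Units are PDF·yr per physical unit of the (converted) pressure.
    ``provenance`` records per row whether the factor came from zonal
    aggregation of a raster or from a globally uniform value.
    """

    labels: tuple[str, ...]
    C: np.ndarray
    units: tuple[str, ...]
    regions: tuple[str, ...]
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.units = tuple(self.units)
        self.regions = tuple(self.regions)
        self.provenance = tuple(self.provenance)
        self.C = np.asarray(self.C, dtype=float)
        r, n = len(self.labels), len(self.regions)
        if self.C.shape != (r, n):
            raise StructuralError(f"C has shape {self.C.shape}, expected {(r, n)}")
        if not np.isfinite(self.C).all() or (self.C < 0).any():
            raise DataError("characterization factors must be finite and non-negative")
        for p in self.provenance:
            if p not in ("aggregated", "uniform"):
                raise StructuralError(f"unknown provenance tag {p!r}")


@dataclass(frozen=True)
class MappingEntry:
    """One row of the pressure → impact-pathway table."""

    pressure: str
    pathway: str
    unit_in: str
    unit_out: str
    conversion: float
    spatial: bool  # False for globally uniform factors (greenhouse gases)


@dataclass(frozen=True)
class PressureMapping:
    """Fixed mapping from satellite pressure rows to impact pathways."""

    entries: tuple[MappingEntry, ...]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.conversion <= 0:
                raise ParameterError(
                    f"conversion factor for {e.pressure!r} must be positive"
                )

    def entry(self, pressure: str) -> MappingEntry:
        for e in self.entries:
            if e.pressure == pressure:
                return e
        raise MappingError(f"no mapping entry for pressure {pressure!r}")

    def pressures(self) -> tuple[str, ...]:
        return tuple(e.pressure for e in self.entries)


def _table3(pressure, pathway, unit_in, unit_out, spatial=True) -> MappingEntry:
    conv = UNIT_CONVERSIONS[(unit_in, unit_out)]
    return MappingEntry(pressure, pathway, unit_in, unit_out, conv, spatial)


#: The standard thirteen-pressure mapping: greenhouse gases to climate
#: change (globally uniform CF), blue water to water stress, three land
#: occupation types, agricultural P and N to freshwater and marine
#: eutrophication, and three acidifying gases to terrestrial acidification.
DEFAULT_MAPPING = PressureMapping(
    entries=(
        _table3("CO2", "climate change", "Gg", "kg", spatial=False),
        _table3("CO2 biomass burning", "climate change", "Gg", "kg", spatial=False),
        _table3("CH4", "climate change", "Gg", "kg", spatial=False),
        _table3("N2O", "climate change", "Gg", "kg", spatial=False),
        _table3("blue water consumption", "water stress", "m3", "m3"),
        _table3("agricultural land", "land occupation, annual crops", "Ha", "km2"),
        _table3("pasture", "land occupation, pasture", "Ha", "km2"),
        _table3("forested area", "land occupation, forestry", "Ha", "km2"),
        _table3("P application", "freshwater eutrophication", "kg", "kg"),
        _table3("N application", "marine eutrophication", "kg", "kg"),
        _table3("NH3", "terrestrial acidification", "Gg", "kg"),
        _table3("NOx", "terrestrial acidification", "Gg", "kg"),
        _table3("SO2", "terrestrial acidification", "Gg", "kg"),
    )
)


def _check_aligned(*layers) -> None:
    shapes = [
        tuple(lay.values.shape) if hasattr(lay, "values") else tuple(lay.mask.shape)
        for lay in layers
    ]
    transforms = [lay.transform for lay in layers]
    if len(set(shapes)) != 1:
        raise AlignmentError(f"grid shapes differ: {shapes}")
    if len(set(transforms)) != 1:
        raise AlignmentError(f"geotransforms differ: {transforms}")


def aggregate_cf(
    pressure_layer: RasterLayer,
    cf_layer: RasterLayer,
    masks: CountryMaskSet,
) -> np.ndarray:
    """Pressure-weighted mean characterization factor per country.

    For each country the factor is ``Σ_m F_m · C_m / Σ_m F_m`` over the
    country's valid cells, with ``F`` the local pressure and ``C`` the local
    factor.  Where the country's total pressure is zero the unweighted
    arithmetic mean of its factor cells is returned (the weighted mean is
    undefined there, and the two agree in the spatially uniform limit).  A
    country with no valid cells gets 0 with a warning.

    Returns a vector of length ``masks.n_regions``.
    """
    _check_aligned(pressure_layer, cf_layer, masks)
    p_valid = pressure_layer.valid_mask()
    c_valid = cf_layer.valid_mask()
    valid = p_valid & c_valid
    if (pressure_layer.values[p_valid] < 0).any():
        raise DataError("negative pressure cell(s) in pressure layer")
    out = np.zeros(masks.n_regions)
    for i, region in enumerate(masks.regions):
        cells = (masks.mask == i) & valid
        if not cells.any():
            warnings.warn(
                f"country {region!r} has no valid cells; factor set to 0",
                stacklevel=2,
            )
            continue
        w = pressure_layer.values[cells]
        c = cf_layer.values[cells]
        wsum = w.sum()
        if wsum > 0:
            # shifted form of sum(w*c)/sum(w): recovers a spatially constant
            # factor exactly and is better conditioned for narrow ranges
            cmin = c.min()
            out[i] = cmin + (w * (c - cmin)).sum() / wsum
        else:
            out[i] = c.mean()
    return out


def uniform_cf(value: float, regions: Sequence[str]) -> np.ndarray:
    """Globally uniform factor: every country receives ``value``.

    Used for greenhouse gases, whose damage is independent of the point of
    emission.
    """
    if value < 0:
        raise DataError(f"characterization factor must be non-negative, got {value}")
    return np.full(len(regions), float(value))


def forestry_cf(
    cf_intensive: np.ndarray,
    cf_extensive: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Weighted average of intensive- and extensive-forestry factors.

    ``weights`` must be non-negative and sum to one (checked to 1e-12).
    """
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-12:
        raise ParameterError(f"forestry weights {weights} must be >=0 and sum to 1")
    a = np.asarray(cf_intensive, dtype=float)
    b = np.asarray(cf_extensive, dtype=float)
    if a.shape != b.shape:
        raise StructuralError("forestry factor vectors differ in length")
    return w1 * a + w2 * b


def expand_cf(C: np.ndarray, index: RegionSectorIndex) -> np.ndarray:
    """Repeat country columns over sectors: ``r x n`` → ``r x s``.

    All sectors of a country share the country factor (within one country
    the factor does not vary by land parcel or activity).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != index.n_regions:
        raise StructuralError(
            f"C has {C.shape[1]} columns but index has {index.n_regions} regions"
        )
    return np.repeat(C, index.n_sectors, axis=1)


@dataclass
class MappedSatellite:
    """Satellite rows matched to pathways and converted to CF denominator units."""

    index: RegionSectorIndex
    labels: tuple[str, ...]
    pathways: tuple[str, ...]
    F: np.ndarray  # converted physical totals, r x s
    units: tuple[str, ...]  # post-conversion units


def map_pressures(
    satellite: SatelliteAccount,
    mapping: PressureMapping = DEFAULT_MAPPING,
    ignore: Sequence[str] = (),
) -> MappedSatellite:
    """Match satellite rows to impact pathways and convert units.

    Each matched row is scaled by its conversion factor so that its unit
    equals the characterization-factor denominator (Gg → kg by 1e6,
    Ha → km² by 1e-2, m³ and kg unchanged).  Rows listed in ``ignore`` are
    dropped; any other unmapped row raises, listing the offending labels.
    """
    known = set(mapping.pressures())
    unmapped = [
        lab for lab in satellite.labels if lab not in known and lab not in set(ignore)
    ]
    if unmapped:
        raise MappingError(f"unmapped satellite pressure label(s): {unmapped}")
    keep, pathways, units_out, rows = [], [], [], []
    for i, lab in enumerate(satellite.labels):
        if lab in set(ignore):
            continue
        e = mapping.entry(lab)
        if satellite.units[i] != e.unit_in:
            raise UnitError(
                f"pressure {lab!r} has unit {satellite.units[i]!r}, "
                f"mapping expects {e.unit_in!r}"
            )
        keep.append(lab)
        pathways.append(e.pathway)
        units_out.append(e.unit_out)
        rows.append(satellite.F[i] * e.conversion)
    return MappedSatellite(
        index=satellite.index,
        labels=tuple(keep),
        pathways=tuple(pathways),
        F=np.array(rows),
        units=tuple(units_out),
    )


def combine_pathway_cf(
    rows: Mapping[str, np.ndarray],
    mapped: MappedSatellite,
    regions: Sequence[str],
    provenance: Mapping[str, str] | None = None,
) -> CountryCF:
    """Assemble per-pressure CF vectors into an ``r x n`` matrix in satellite order.

    ``rows`` maps each mapped pressure label to its per-country factor
    vector.  Two pressures sharing a pathway (e.g. CO₂ and CH₄, both
    climate change) each keep their own row.  Input ordering is irrelevant:
    the output row order is tied to the mapped satellite.
    """
    provenance = dict(provenance or {})
    missing = [lab for lab in mapped.labels if lab not in rows]
    if missing:
        raise AssemblyError(f"missing characterization-factor row(s): {missing}")
    n = len(regions)
    C = np.zeros((len(mapped.labels), n))
    prov = []
    for i, lab in enumerate(mapped.labels):
        v = np.asarray(rows[lab], dtype=float)
        if v.shape != (n,):
            raise StructuralError(
                f"factor vector for {lab!r} has shape {v.shape}, expected {(n,)}"
            )
        C[i] = v
        prov.append(provenance.get(lab, "aggregated"))
    return CountryCF(
        labels=mapped.labels,
        C=C,
        units=tuple(f"PDF·yr/{u}" for u in mapped.units),
        regions=tuple(regions),
        provenance=tuple(prov),
    )
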