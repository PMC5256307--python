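"""Synthetic economies and synthetic raster worlds for the footprint pipeline.

Real applications of impact-footprint accounting rest on two external data
products: a global MRIO database and a set of gridded biodiversity
characterization factors.  This module generates structurally faithful
stand-ins for both so the whole pipeline is testable at desk scale:

* balanced non-negative MRIO accounts whose technical-coefficient matrix
  has all column sums equal to ``intermediate_share`` (hence spectral
  radius strictly below one),
* non-negative satellite accounts per pressure with the standard unit
  registry, with heavy-tailed (lognormal) magnitudes as in real IO tables,
* rectangular-block country rasters where characterization factors are
  elevated by ``cf_contrast`` inside "hotspot" (high-endemism) countries
  while pressure cells are drawn independently of the factors.

A ready-made ``burden_shift_scenario`` builds a two-group world — high-
factor importers vs low-factor pressure-intensive exporters — whose
qualitative outcome (the high-factor group's origin share of the impact
footprint exceeds its origin share of the pressure footprint) is known by
construction and machine-checkable.

All draws are seeded; each component draws from its own substream derived
from the scenario seed, so adding a component never perturbs another's
draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .characterization import (
    DEFAULT_MAPPING,
    NO_COUNTRY,
    CountryMaskSet,
    GeoTransform,
    PressureMapping,
    RasterLayer,
)
from .errors import ParameterError
from .mrio import MRIOAccounts, RegionSectorIndex, SatelliteAccount

# fixed substream tags (seed, tag) -> independent generator
_STREAM_STRUCTURE = 1
_STREAM_DEMAND = 2
_STREAM_ALLOCATION = 3
_STREAM_SATELLITE = 4
_STREAM_FACTORS = 5
_STREAM_PRESSURE_GRID = 6

#: typical satellite magnitudes per unit label (lognormal scale parameter)
_SATELLITE_SCALE = {"Gg": 1e2, "m3": 1e6, "Ha": 1e4, "kg": 1e5}

#: baseline characterization factor per pathway kind (PDF·yr per converted unit)
_CF_BASELINE = 1e-12


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic world.

    trade_openness
        Share of intermediate and final purchases sourced abroad, in [0, 1).
    intermediate_share
        Column sum of the coefficient matrix A, in (0, 1); bounds the
        spectral radius of A from above.
    cf_contrast
        Ratio of hotspot-country to baseline characterization factors
        (>= 1).  The default 30 reflects factor geographies in which
        high-endemism countries carry factors one or more orders of
        magnitude above the rest.
    cf_noise
        Lognormal sigma of multiplicative cell-level factor noise; 0 gives
        piecewise-constant factors per country.
    """

    n_regions: int = 6
    k_sectors: int = 4
    trade_openness: float = 0.25
    intermediate_share: float = 0.45
    cf_contrast: float = 30.0
    cf_noise: float = 0.25
    grid_shape: tuple[int, int] = (48, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.k_sectors < 1:
            raise ParameterError("n_regions and k_sectors must be positive")
        if not (0.0 <= self.trade_openness < 1.0):
            raise ParameterError("trade_openness must lie in [0, 1)")
        if not (0.0 < self.intermediate_share < 1.0):
            raise ParameterError("intermediate_share must lie in (0, 1)")
        if self.cf_contrast < 1.0:
            raise ParameterError("cf_contrast must be >= 1")
        if self.cf_noise < 0.0:
            raise ParameterError("cf_noise must be >= 0")
        if self.grid_shape[0] * self.grid_shape[1] < self.n_regions:
            raise ParameterError("more regions than grid cells")

    def make_index(self) -> RegionSectorIndex:
        return RegionSectorIndex(
            regions=[f"R{i:02d}" for i in range(self.n_regions)],
            sectors=[f"S{j:02d}" for j in range(self.k_sectors)],
        )


def _allocation_shares(
    rng: np.random.Generator,
    n: int,
    own_region: np.ndarray,
    openness: float,
) -> np.ndarray:
    """Column-stochastic s x s shares with a fixed domestic/foreign split.

    Each column sums to 1; the domestic block of a column sums to
    (1 - openness) whenever foreign suppliers exist.
    """
    s = own_region.size
    w = rng.lognormal(mean=0.0, sigma=1.0, size=(s, s))
    shares = np.empty_like(w)
    for j in range(s):
        dom = own_region == own_region[j]
        if n == 1:
            shares[:, j] = w[:, j] / w[:, j].sum()
            continue
        col = np.empty(s)
        col[dom] = (1.0 - openness) * w[dom, j] / w[dom, j].sum()
        col[~dom] = openness * w[~dom, j] / w[~dom, j].sum()
        shares[:, j] = col
    return shares


def generate_mrio(
    spec: ScenarioSpec,
    pressure_scale: np.ndarray | None = None,
    mapping: PressureMapping = DEFAULT_MAPPING,
) -> tuple[MRIOAccounts, SatelliteAccount]:
    """Generate balanced accounts and a satellite account from a scenario spec.

    Construction guarantees, not just approximates, the structural
    invariants: every column of A sums to ``intermediate_share`` (so the
    spectral radius is bounded by it), final-demand totals are drawn
    strictly positive and gross output solved as ``x = (I−A)⁻¹ y``, making
    the row balance ``x = Z·1 + Y·1`` exact to solver precision with all
    quantities non-negative.

    ``pressure_scale`` optionally multiplies satellite columns per
    region-sector pair (used to make exporter groups pressure-intensive).
    """
    index = spec.make_index()
    n, s = spec.n_regions, index.size
    own = index.region_of_pair()

    rng_a = _rng(spec.seed, _STREAM_STRUCTURE)
    A = spec.intermediate_share * _allocation_shares(
        rng_a, n, own, spec.trade_openness
    )

    rng_y = _rng(spec.seed, _STREAM_DEMAND)
    y_total = rng_y.lognormal(mean=math.log(100.0), sigma=1.0, size=s)
    x = np.linalg.solve(np.eye(s) - A, y_total)
    Z = A * x[np.newaxis, :]

    # allocate each origin row's final demand across consuming nations
    rng_c = _rng(spec.seed, _STREAM_ALLOCATION)
    w = rng_c.lognormal(mean=0.0, sigma=1.0, size=(s, n))
    Y = np.empty((s, n))
    for i in range(s):
        if n == 1:
            Y[i, 0] = y_total[i]
            continue
        dom = np.arange(n) == own[i]
        shares = np.empty(n)
        shares[dom] = (1.0 - spec.trade_openness) * w[i, dom] / w[i, dom].sum()
        shares[~dom] = spec.trade_openness * w[i, ~dom] / w[i, ~dom].sum()
        Y[i] = y_total[i] * shares

    accounts = MRIOAccounts(index=index, Z=Z, x=x, Y=Y)

    rng_f = _rng(spec.seed, _STREAM_SATELLITE)
    labels = mapping.pressures()
    units = tuple(mapping.entry(lab).unit_in for lab in labels)
    F = np.empty((len(labels), s))
    for i, unit in enumerate(units):
        F[i] = rng_f.lognormal(mean=0.0, sigma=1.0, size=s) * _SATELLITE_SCALE[unit]
    if pressure_scale is not None:
        F = F * np.asarray(pressure_scale, dtype=float)[np.newaxis, :]
    satellite = SatelliteAccount(index=index, labels=labels, F=F, units=units)
    return accounts, satellite


@dataclass
class SyntheticWorld:
    """Country mask plus per-pressure factor and pressure rasters."""

    masks: CountryMaskSet
    factor_layers: dict[str, RasterLayer]
    pressure_layers: dict[str, RasterLayer]
    hotspots: tuple[str, ...]


def _tile_mask(n: int, shape: tuple[int, int]) -> np.ndarray:
    """Partition the grid into rectangular country blocks; spare tiles get NO_COUNTRY."""
    rows, cols = shape
    tiles_x = math.ceil(math.sqrt(n))
    tiles_y = math.ceil(n / tiles_x)
    mask = np.full(shape, NO_COUNTRY, dtype=np.int32)
    r_edges = np.linspace(0, rows, tiles_y + 1).astype(int)
    c_edges = np.linspace(0, cols, tiles_x + 1).astype(int)
    rid = 0
    for ty in range(tiles_y):
        for tx in range(tiles_x):
            if rid >= n:
                break
            mask[r_edges[ty] : r_edges[ty + 1], c_edges[tx] : c_edges[tx + 1]] = rid
            rid += 1
    return mask


def generate_world(
    spec: ScenarioSpec,
    hotspots: Sequence[str],
    pressures: Sequence[str] | None = None,
    mapping: PressureMapping = DEFAULT_MAPPING,
) -> SyntheticWorld:
    """Generate a country mask and per-pressure factor/pressure raster pairs.

    Factor cells sit at a common baseline, multiplied by ``cf_contrast``
    inside hotspot countries, with multiplicative lognormal noise of sigma
    ``cf_noise``.  Pressure cells are drawn independently of the factors
    (pressures are where the economy is, not where the species are).  Only
    spatially differentiated pressures get layers by default; globally
    uniform ones (greenhouse gases) need no geography.
    """
    index = spec.make_index()
    regions = index.regions
    unknown = [h for h in hotspots if h not in regions]
    if unknown:
        raise ParameterError(f"hotspot region(s) {unknown} not in the scenario")
    if pressures is None:
        pressures = [e.pressure for e in mapping.entries if e.spatial]
    transform = GeoTransform(x_origin=-180.0, y_origin=90.0, dx=1.0, dy=1.0)
    mask = _tile_mask(spec.n_regions, spec.grid_shape)
    masks = CountryMaskSet(mask=mask, regions=regions, transform=transform)
    hot = np.isin(mask, [regions.index(h) for h in hotspots])

    rng_c = _rng(spec.seed, _STREAM_FACTORS)
    rng_p = _rng(spec.seed, _STREAM_PRESSURE_GRID)
    factor_layers: dict[str, RasterLayer] = {}
    pressure_layers: dict[str, RasterLayer] = {}
    for lab in pressures:
        base = np.full(spec.grid_shape, _CF_BASELINE)
        base[hot] *= spec.cf_contrast
        if spec.cf_noise > 0:
            base = base * rng_c.lognormal(
                mean=-0.5 * spec.cf_noise**2, sigma=spec.cf_noise, size=spec.grid_shape
            )
        base[mask == NO_COUNTRY] = np.nan
        factor_layers[lab] = RasterLayer(values=base, transform=transform)
        press = rng_p.lognormal(mean=0.0, sigma=1.0, size=spec.grid_shape)
        press[mask == NO_COUNTRY] = np.nan
        pressure_layers[lab] = RasterLayer(values=press, transform=transform)
    return SyntheticWorld(
        masks=masks,
        factor_layers=factor_layers,
        pressure_layers=pressure_layers,
        hotspots=tuple(hotspots),
    )


@dataclass
class BurdenShiftBundle:
    """A complete input bundle with machine-checkable qualitative expectations.

    Group ``H`` (first half of the regions) hosts high characterization
    factors; group ``L`` exports pressure-intensive goods.  Expected, for
    every spatially differentiated pressure:

    i.  L's origin share of the global pressure footprint exceeds its
        origin share of the global impact footprint;
    ii. H's origin share of the impact footprint exceeds its origin share
        of the pressure footprint;
    iii. with ``cf_contrast`` forced to 1 the pressure and impact group
        share tables coincide.
    """

    spec: ScenarioSpec
    accounts: MRIOAccounts
    satellite: SatelliteAccount
    world: SyntheticWorld
    uniform_cf_value: float
    grouping: dict[str, str]
    groups: tuple[str, str] = ("H", "L")
    mapping: PressureMapping = field(default_factory=lambda: DEFAULT_MAPPING)


#: how much more pressure-intensive the exporter group's sectors are
_EXPORTER_INTENSITY = 4.0


def burden_shift_scenario(
    seed: int, cf_contrast: float | None = None
) -> BurdenShiftBundle:
    """Construct the two-group burden-shift world for a given seed.

    Six countries in two groups: H = {R00..R02} with hotspot factors,
    L = {R03..R05} whose sectors carry ``_EXPORTER_INTENSITY``-fold
    pressure intensity.  Factor rasters are piecewise-constant per country
    (``cf_noise=0``) so that forcing ``cf_contrast=1`` makes them exactly
    spatially uniform and the pressure/impact share tables collapse onto
    each other.
    """
    spec = ScenarioSpec(
        n_regions=6,
        k_sectors=4,
        trade_openness=0.35,
        intermediate_share=0.45,
        cf_contrast=30.0 if cf_contrast is None else float(cf_contrast),
        cf_noise=0.0,
        grid_shape=(48, 48),
        seed=seed,
    )
    index = spec.make_index()
    n_h = spec.n_regions // 2
    hotspots = index.regions[:n_h]
    grouping = {
        r: ("H" if i < n_h else "L") for i, r in enumerate(index.regions)
    }
    own = index.region_of_pair()
    pressure_scale = np.where(own >= n_h, _EXPORTER_INTENSITY, 1.0)
    accounts, satellite = generate_mrio(spec, pressure_scale=pressure_scale)
    world = generate_world(spec, hotspots=hotspots)
    return BurdenShiftBundle(
        spec=spec,
        accounts=accounts,
        satellite=satellite,
        world=world,
        uniform_cf_value=_CF_BASELINE,
        grouping=grouping,
    )


def with_cf_contrast(bundle: BurdenShiftBundle, cf_contrast: float) -> BurdenShiftBundle:
    """Rebuild the same bundle (same seed) with a different factor contrast."""
    return burden_shift_scenario(bundle.spec.seed, cf_contrast=cf_contrast)
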