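"""Pressure and impact footprints, source attribution, and transfer tables.

The demand-pull footprint of a pressure is ``D = f L Y`` where ``f`` is the
output-normalized satellite (pressure per monetary unit), ``L`` the
total-requirements matrix and ``Y`` final demand by consuming nation.  The
impact footprint characterizes the intensity first with the country
characterization factors expanded to the sector axis, using a Hadamard
product: ``Q = (C ∘ f) L Y``, in PDF·yr.

Both the per-consumer aggregate (``r x n``) and the source-resolved form
(``s x n`` per pressure — diagonalize the intensity row instead of summing
it) are first-class; a consistency invariant ties them together.  Summing
the source-resolved table over each origin country's sector block gives the
``n x n`` origin-by-consumer attribution table from which domestic shares
and group (e.g. income class) transfer tables are derived.

Negative final demand propagates to negative contributions; nothing is
clipped, so conservation holds with signed sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import GroupingError, StructuralError, UnitError
from .mrio import RegionSectorIndex

IMPACT_UNIT = "PDF·yr"


@dataclass
class FootprintTensor:
    """Footprints for every pressure: aggregate ``r x n`` and source-resolved ``r x s x n``.

    ``aggregate[p, c]`` is consumer ``c``'s footprint of pressure ``p``;
    ``source_resolved[p, i, c]`` attributes it to the origin region-sector
    pair ``i``.  Column sums of the source-resolved slab reproduce the
    aggregate row.
    """

    kind: str  # "pressure" | "impact"
    index: RegionSectorIndex
    labels: tuple[str, ...]
    aggregate: np.ndarray
    source_resolved: np.ndarray
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("pressure", "impact"):
            raise StructuralError(f"unknown footprint kind {self.kind!r}")
        self.labels = tuple(self.labels)
        self.units = tuple(self.units)
        r, s, n = len(self.labels), self.index.size, self.index.n_regions
        if self.aggregate.shape != (r, n):
            raise StructuralError(
                f"aggregate has shape {self.aggregate.shape}, expected {(r, n)}"
            )
        if self.source_resolved.shape != (r, s, n):
            raise StructuralError(
                f"source_resolved has shape {self.source_resolved.shape}, "
                f"expected {(r, s, n)}"
            )
        if len(self.units) != r:
            raise StructuralError("one unit per pressure row required")

    def row(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise StructuralError(f"unknown pressure label {label!r}") from None

    def consistency_error(self) -> float:
        """Max relative gap between source-resolved column sums and the aggregate."""
        colsum = self.source_resolved.sum(axis=1)
        scale = np.maximum(np.abs(self.aggregate), 1e-300)
        return float((np.abs(colsum - self.aggregate) / scale).max())


@dataclass
class AttributionTable:
    """``n x n`` origin-country (rows) by consuming-country (columns) table."""

    pressure: str
    regions: tuple[str, ...]
    table: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        n = len(self.regions)
        if self.table.shape != (n, n):
            raise StructuralError(
                f"attribution table has shape {self.table.shape}, expected {(n, n)}"
            )


@dataclass
class GroupTransferTable:
    """Transfers between country groups, absolute and as percent of each consumer column."""

    grouping_label: str
    groups: tuple[str, ...]
    absolute: np.ndarray
    column_percent: np.ndarray
    unit: str


def _footprint(
    intensity: np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    index: RegionSectorIndex,
    labels: Sequence[str],
    units: Sequence[str],
    kind: str,
) -> FootprintTensor:
    s, n = index.size, index.n_regions
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape[1:] != (s,) or L.shape != (s, s) or Y.shape != (s, n):
        raise StructuralError(
            f"incompatible shapes: intensity {intensity.shape}, L {L.shape}, Y {Y.shape}"
        )
    LY = L @ Y  # s x n, total output per unit of each nation's demand bundle
    # diag(intensity row) @ LY, vectorized over pressures
    source = intensity[:, :, np.newaxis] * LY[np.newaxis, :, :]
    aggregate = intensity @ LY
    return FootprintTensor(
        kind=kind,
        index=index,
        labels=tuple(labels),
        aggregate=aggregate,
        source_resolved=source,
        units=tuple(units),
    )


def resource_footprint(
    f_norm: np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    index: RegionSectorIndex,
    labels: Sequence[str],
    units: Sequence[str],
) -> FootprintTensor:
    """Pressure footprint ``D = f L Y`` with its source-resolved form."""
    return _footprint(f_norm, L, Y, index, labels, units, kind="pressure")


def impact_footprint(
    C_expanded: np.ndarray,
    f_norm: np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    index: RegionSectorIndex,
    labels: Sequence[str],
) -> FootprintTensor:
    """Impact footprint ``Q = (C ∘ f) L Y`` in PDF·yr.

    ``C_expanded`` is the country characterization-factor matrix repeated
    over sectors (``r x s``), Hadamard-multiplied into the intensity before
    the Leontief chain.
    """
    C_expanded = np.asarray(C_expanded, dtype=float)
    f_norm = np.asarray(f_norm, dtype=float)
    if C_expanded.shape != f_norm.shape:
        raise StructuralError(
            f"C {C_expanded.shape} and f_norm {f_norm.shape} must share shape"
        )
    if (C_expanded < 0).any():
        raise StructuralError("characterization factors must be non-negative")
    labels = tuple(labels)
    units = (IMPACT_UNIT,) * len(labels)
    return _footprint(C_expanded * f_norm, L, Y, index, labels, units, kind="impact")


def source_attribution(
    pressure: str, footprint: FootprintTensor, index: RegionSectorIndex
) -> AttributionTable:
    """Aggregate the ``s x n`` source-resolved table over origin-country sector blocks."""
    p = footprint.row(pressure)
    n, k = index.n_regions, index.n_sectors
    table = footprint.source_resolved[p].reshape(n, k, n).sum(axis=1)
    return AttributionTable(
        pressure=pressure,
        regions=index.regions,
        table=table,
        unit=footprint.units[p],
    )


def domestic_share(attr: AttributionTable) -> np.ndarray:
    """Diagonal cell over column sum per consumer; 0 where the column sum is 0."""
    totals = attr.table.sum(axis=0)
    diag = np.diag(attr.table)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(totals != 0, diag / np.where(totals == 0, 1.0, totals), 0.0)
    return share


def group_transfers(
    attr: AttributionTable,
    grouping: Mapping[str, str],
    grouping_label: str = "group",
    groups: Sequence[str] | None = None,
) -> GroupTransferTable:
    """Sum the attribution table into group blocks (e.g. World Bank income classes).

    ``column_percent`` normalizes each consumer column to 100 — the entry
    (g, h) reads "g percent of group h's footprint originates in group g".
    Columns with zero absolute total are all zeros.  Group order follows
    ``groups`` if given, else first appearance in the region list.
    """
    unmapped = [r for r in attr.regions if r not in grouping]
    if unmapped:
        raise GroupingError(f"countries without group assignment: {unmapped}")
    if groups is None:
        seen: list[str] = []
        for r in attr.regions:
            g = grouping[r]
            if g not in seen:
                seen.append(g)
        groups = seen
    groups = tuple(groups)
    gi = {g: i for i, g in enumerate(groups)}
    for r in attr.regions:
        if grouping[r] not in gi:
            raise GroupingError(f"group {grouping[r]!r} missing from group order")
    idx = np.array([gi[grouping[r]] for r in attr.regions])
    g = len(groups)
    absolute = np.zeros((g, g))
    np.add.at(absolute, (idx[:, None], idx[None, :]), attr.table)
    totals = absolute.sum(axis=0)
    column_percent = np.zeros_like(absolute)
    nonzero = totals != 0
    column_percent[:, nonzero] = 100.0 * absolute[:, nonzero] / totals[nonzero]
    return GroupTransferTable(
        grouping_label=grouping_label,
        groups=groups,
        absolute=absolute,
        column_percent=column_percent,
        unit=attr.unit,
    )


@dataclass
class TotalImpact:
    """Per-consumer total impact and per-pathway shares of the global total."""

    regions: tuple[str, ...]
    per_consumer: np.ndarray
    pathway_totals: dict[str, float]
    pathway_shares: dict[str, float]
    unit: str = IMPACT_UNIT


def total_impact(
    impact: FootprintTensor, pathways: Sequence[str] | None = None
) -> TotalImpact:
    """Sum PDF·yr impacts over all pressures per consumer; share per pathway.

    All impact pathways converge on one area of protection (ecosystem
    quality) with one common unit, so rows may be summed.  Mixed units
    raise.
    """
    bad = [u for u in impact.units if u != IMPACT_UNIT]
    if bad or impact.kind != "impact":
        raise UnitError(
            f"total impact requires all rows in {IMPACT_UNIT}; got {impact.units}"
        )
    if pathways is None:
        pathways = impact.labels
    if len(tuple(pathways)) != len(impact.labels):
        raise StructuralError("one pathway label required per pressure row")
    per_consumer = impact.aggregate.sum(axis=0)
    grand = float(impact.aggregate.sum())
    totals: dict[str, float] = {}
    for pw, row in zip(pathways, impact.aggregate):
        totals[pw] = totals.get(pw, 0.0) + float(row.sum())
    shares = {
        pw: (t / grand if grand != 0 else 0.0) for pw, t in totals.items()
    }
    return TotalImpact(
        regions=impact.index.regions,
        per_consumer=per_consumer,
        pathway_totals=totals,
        pathway_shares=shares,
    )
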