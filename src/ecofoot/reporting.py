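"""Standardized pressure-vs-impact comparison, rankings, and contributor tables.

Pressure footprints (physical units) and impact footprints (PDF·yr) are not
directly comparable, so each vector is standardized independently to
standard scores ``(x - μ) / σ`` with the population standard deviation —
the country set is the whole population of interest, not a sample.  Equal
scores put a country on the 45° line of the comparison scatter; the score
difference (pressure minus impact) measures how far the switch from a
pressure to an impact metric moves the country.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import StructuralError
from .footprint import AttributionTable


@dataclass(frozen=True)
class StandardScoreVector:
    """Standard scores with the mean and population sd they were built from."""

    scores: np.ndarray
    mu: float
    sigma: float


def standard_scores(v: Sequence[float]) -> StandardScoreVector:
    """Standardize ``v`` to mean 0 and population sd 1.

    A constant vector (σ = 0) maps to all-zero scores with ``sigma``
    recorded as 0.  Standardization is invariant to positive affine
    rescaling of the input.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise StructuralError("input must be a non-empty 1-D vector")
    mu = float(v.mean())
    sigma = float(v.std())  # population (divide-by-n)
    if sigma == 0.0:
        return StandardScoreVector(scores=np.zeros_like(v), mu=mu, sigma=0.0)
    return StandardScoreVector(scores=(v - mu) / sigma, mu=mu, sigma=sigma)


@dataclass
class ComparisonTable:
    """Per-country pressure vs impact values and scores, plus their correlation.

    ``table`` columns: pressure, impact, pressure_score, impact_score,
    score_difference (pressure_score − impact_score), and, when requested,
    log10 ranking columns (NaN for non-positive entries).  ``correlation``
    is the Pearson correlation of the two score vectors; 0.0 is reported in
    the degenerate case where either vector is constant.
    """

    table: pd.DataFrame
    correlation: float
    n_dropped_log: int = 0


def pressure_impact_comparison(
    pressure: Sequence[float],
    impact: Sequence[float],
    regions: Sequence[str] | None = None,
    log_ranks: bool = False,
) -> ComparisonTable:
    """Standardize a pressure and an impact footprint vector and compare them.

    With a globally uniform characterization factor the impact is a positive
    multiple of the pressure, the score vectors coincide, every country sits
    on the 45° line, and the correlation is exactly 1.
    """
    p = np.asarray(pressure, dtype=float)
    q = np.asarray(impact, dtype=float)
    if p.shape != q.shape:
        raise StructuralError(
            f"pressure {p.shape} and impact {q.shape} vectors differ in length"
        )
    if regions is None:
        regions = [f"R{i}" for i in range(p.size)]
    if len(regions) != p.size:
        raise StructuralError("region labels do not match vector length")
    ps = standard_scores(p)
    qs = standard_scores(q)
    if ps.sigma == 0.0 or qs.sigma == 0.0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(ps.scores, qs.scores)[0, 1])
        corr = max(-1.0, min(1.0, corr))
    data = {
        "pressure": p,
        "impact": q,
        "pressure_score": ps.scores,
        "impact_score": qs.scores,
        "score_difference": ps.scores - qs.scores,
    }
    n_dropped = 0
    if log_ranks:
        # log10 rankings need strictly positive values; others are dropped (NaN)
        lp = np.where(p > 0, np.log10(np.where(p > 0, p, 1.0)), np.nan)
        lq = np.where(q > 0, np.log10(np.where(q > 0, q, 1.0)), np.nan)
        n_dropped = int(np.isnan(lp).sum() + np.isnan(lq).sum())
        data["log10_pressure"] = lp
        data["log10_impact"] = lq
    table = pd.DataFrame(data, index=pd.Index(regions, name="region"))
    return ComparisonTable(table=table, correlation=corr, n_dropped_log=n_dropped)


@dataclass(frozen=True)
class Contributor:
    """One origin country's contribution to a consumer's footprint column."""

    origin: str
    value: float
    percent: float
    domestic: bool


def top_contributors(
    attr: AttributionTable, consumer: str, k: int
) -> list[Contributor]:
    """Rank origin countries by share of a consumer's footprint column.

    Shares are percent of the (signed) column total, sorted descending;
    ties break lexicographically by region identifier.  The consumer's own
    row is flagged domestic.  A zero column total yields an empty list with
    a warning.
    """
    if k < 1:
        raise StructuralError("k must be >= 1")
    try:
        c = attr.regions.index(consumer)
    except ValueError:
        raise StructuralError(f"unknown consumer {consumer!r}") from None
    column = attr.table[:, c]
    total = column.sum()
    if total == 0:
        warnings.warn(
            f"zero column total for consumer {consumer!r}; no contributors",
            stacklevel=2,
        )
        return []
    shares = 100.0 * column / total
    order = sorted(range(len(shares)), key=lambda i: (-shares[i], attr.regions[i]))
    return [
        Contributor(
            origin=attr.regions[i],
            value=float(column[i]),
            percent=float(shares[i]),
            domestic=attr.regions[i] == consumer,
        )
        for i in order[:k]
    ]
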