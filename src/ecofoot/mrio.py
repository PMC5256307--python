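"""Data model, validation, and Leontief algebra for multi-regional input-output accounts.

A multi-regional input-output (MRIO) table records the monetary flows among
all sectors of all regions of an economy.  With ``n`` regions and ``k``
sectors per region there are ``s = n * k`` region-sector pairs.  The core
objects are

* ``Z`` — the ``s x s`` inter-industry transaction matrix,
* ``x`` — the ``s``-vector of gross sector outputs,
* ``Y`` — the ``s x n`` final-demand matrix (one column per consuming nation),
* ``A = Z x̂⁻¹`` — the technical-coefficient ("technology") matrix, giving
  intermediate inputs per unit of output, and
* ``L = (I − A)⁻¹`` — the Leontief inverse or total-requirements matrix,
  capturing all direct and indirect production needed per unit of final
  demand.

Physical pressures (emissions, land, water, nutrients) enter through an
``r x s`` satellite account ``F``, normalized by output to intensities
``f = F x̂⁻¹``.

Conventions
-----------
Zero-output sectors yield zero coefficients and zero intensities (0/0 → 0);
a nonzero numerator over zero output is an account inconsistency, never an
infinity.  Negative final demand is legal (inventory draw-down) and only
warned about; negative ``Z`` or ``x`` entries are errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    AccountInconsistencyError,
    NonProductiveEconomyError,
    NumericalError,
    StructuralError,
    UnitError,
)

#: Physical units accepted for satellite-account rows.
UNIT_REGISTRY = frozenset({"Gg", "m3", "Ha", "kg"})

#: Power-iteration steps used to estimate the spectral radius of A.
SPECTRAL_ITERATIONS = 100

#: Productive-economy gate: spectral radius must be strictly below this.
SPECTRAL_THRESHOLD = 1.0 - 1e-9

#: Default max-abs tolerance on the inverse residual ||L(I-A) - I||_max.
INVERSE_RESIDUAL_TOL = 1e-9

#: Default relative tolerance for row balance in validate_accounts.
BALANCE_TOL = 1e-6


@dataclass(frozen=True)
class RegionSectorIndex:
    """Ordered labelling of the ``s = n * k`` region-sector pairs.

    Pairs are grouped in contiguous blocks by region: all sectors of
    region 0 first, then all sectors of region 1, and so on.

    Parameters
    ----------
    regions
        Ordered region identifiers, length ``n``.
    sectors
        Ordered sector identifiers shared by every region, length ``k``.
    """

    regions: tuple[str, ...]
    sectors: tuple[str, ...]

    def __init__(self, regions: Sequence[str], sectors: Sequence[str]) -> None:
        object.__setattr__(self, "regions", tuple(regions))
        object.__setattr__(self, "sectors", tuple(sectors))
        if len(set(self.regions)) != len(self.regions):
            raise StructuralError("duplicate region identifiers")
        if len(set(self.sectors)) != len(self.sectors):
            raise StructuralError("duplicate sector identifiers")
        if not self.regions or not self.sectors:
            raise StructuralError("regions and sectors must be non-empty")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def size(self) -> int:
        """Number of region-sector pairs, ``s = n * k``."""
        return self.n_regions * self.n_sectors

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((r, sec) for r in self.regions for sec in self.sectors)

    def region_slice(self, region: str) -> slice:
        """Contiguous slice of the pair axis belonging to ``region``."""
        try:
            i = self.regions.index(region)
        except ValueError:
            raise StructuralError(f"unknown region {region!r}") from None
        k = self.n_sectors
        return slice(i * k, (i + 1) * k)

    def region_of_pair(self) -> np.ndarray:
        """Integer region index of each of the ``s`` pairs."""
        return np.repeat(np.arange(self.n_regions), self.n_sectors)


def technical_coefficients(Z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Compute the technical-coefficient matrix ``A`` with ``A_ij = Z_ij / x_j``.

    Columns belonging to zero-output sectors are all zero (0/0 → 0).  A
    nonzero transaction into a zero-output sector is an account
    inconsistency and raises, naming the sector.

    Parameters
    ----------
    Z
        Non-negative ``s x s`` transaction matrix, monetary units.
    x
        Non-negative gross-output vector, length ``s``.
    """
    Z = np.asarray(Z, dtype=float)
    x = np.asarray(x, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1] or x.shape != (Z.shape[0],):
        raise StructuralError(f"incompatible shapes Z{Z.shape}, x{x.shape}")
    if (Z < 0).any() or (x < 0).any():
        raise AccountInconsistencyError("negative entries in Z or x")
    zero = x == 0
    if Z[:, zero].any():
        bad = np.flatnonzero(zero & (Z != 0).any(axis=0))
        raise AccountInconsistencyError(
            f"nonzero transactions into zero-output sector(s) {bad.tolist()}"
        )
    safe = np.where(zero, 1.0, x)
    A = Z / safe[np.newaxis, :]
    A[:, zero] = 0.0
    return A


def normalize_satellite(F: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Normalize a satellite account by sector output: ``f_ij = F_ij / x_j``.

    Same zero-output convention as :func:`technical_coefficients`.
    """
    F = np.asarray(F, dtype=float)
    x = np.asarray(x, dtype=float)
    if F.ndim != 2 or F.shape[1] != x.shape[0]:
        raise StructuralError(f"incompatible shapes F{F.shape}, x{x.shape}")
    if (F < 0).any():
        raise AccountInconsistencyError("negative satellite entries")
    zero = x == 0
    if F[:, zero].any():
        bad = np.flatnonzero(zero & (F != 0).any(axis=0))
        raise AccountInconsistencyError(
            f"nonzero pressure in zero-output sector(s) {bad.tolist()}"
        )
    safe = np.where(zero, 1.0, x)
    f = F / safe[np.newaxis, :]
    f[:, zero] = 0.0
    return f


def spectral_radius(A: np.ndarray, iterations: int = SPECTRAL_ITERATIONS) -> float:
    """Estimate the spectral radius of a non-negative matrix by power iteration.

    For a non-negative matrix the dominant (Perron) eigenvalue is real and
    non-negative, so power iteration from a strictly positive start vector
    converges to it.
    """
    A = np.asarray(A, dtype=float)
    s = A.shape[0]
    v = np.full(s, 1.0 / np.sqrt(s))
    rho = 0.0
    for _ in range(iterations):
        w = A @ v
        nrm = float(np.linalg.norm(w))
        if nrm == 0.0:
            return 0.0
        rho = nrm
        v = w / nrm
    return rho


@dataclass(frozen=True)
class LeontiefSolution:
    """Total-requirements matrix ``L = (I − A)⁻¹`` with its residual diagnostics."""

    L: np.ndarray
    spectral_radius_estimate: float
    residual: float


def leontief_inverse(
    A: np.ndarray, residual_tol: float = INVERSE_RESIDUAL_TOL
) -> LeontiefSolution:
    """Invert ``I − A`` after gating on productivity of the economy.

    The spectral radius of ``A`` is estimated by power iteration; a value at
    or above ``1 − 1e-9`` means the economy consumes at least as much as it
    produces and the Neumann series ``I + A + A² + ...`` diverges, so the
    inverse is refused.  The full explicit inverse is returned because
    source attribution needs every column of ``L``.

    Raises
    ------
    NonProductiveEconomyError
        If the spectral radius estimate is >= the gate, or ``I − A`` is
        numerically singular.
    NumericalError
        If ``||L(I−A) − I||_max`` exceeds ``residual_tol``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise StructuralError(f"A must be square, got {A.shape}")
    if (A < 0).any():
        raise AccountInconsistencyError("A must be non-negative")
    rho = spectral_radius(A)
    if rho >= SPECTRAL_THRESHOLD:
        raise NonProductiveEconomyError(
            f"spectral radius estimate {rho:.6g} >= {SPECTRAL_THRESHOLD}; "
            "economy is not productive"
        )
    eye = np.eye(A.shape[0])
    try:
        L = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError as exc:
        raise NonProductiveEconomyError(f"I - A is singular: {exc}") from exc
    residual = float(np.abs(L @ (eye - A) - eye).max())
    if residual > residual_tol:
        raise NumericalError(
            f"inverse residual {residual:.3g} exceeds tolerance {residual_tol:.3g}"
        )
    return LeontiefSolution(L=L, spectral_radius_estimate=rho, residual=residual)


@dataclass
class MRIOAccounts:
    """A labelled multi-regional input-output account.

    ``A`` is derived lazily from ``Z`` and ``x`` on first access.
    """

    index: RegionSectorIndex
    Z: np.ndarray
    x: np.ndarray
    Y: np.ndarray
    _A: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        s, n = self.index.size, self.index.n_regions
        self.Z = np.asarray(self.Z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Z.shape != (s, s):
            raise StructuralError(f"Z has shape {self.Z.shape}, expected {(s, s)}")
        if self.x.shape != (s,):
            raise StructuralError(f"x has shape {self.x.shape}, expected {(s,)}")
        if self.Y.shape != (s, n):
            raise StructuralError(f"Y has shape {self.Y.shape}, expected {(s, n)}")

    @property
    def A(self) -> np.ndarray:
        if self._A is None:
            self._A = technical_coefficients(self.Z, self.x)
        return self._A


@dataclass
class SatelliteAccount:
    """Physical pressure account: one row per pressure, one column per sector.

    Each row carries a unit label from :data:`UNIT_REGISTRY`.
    """

    index: RegionSectorIndex
    labels: tuple[str, ...]
    F: np.ndarray
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.units = tuple(self.units)
        self.F = np.asarray(self.F, dtype=float)
        r, s = len(self.labels), self.index.size
        if self.F.shape != (r, s):
            raise StructuralError(f"F has shape {self.F.shape}, expected {(r, s)}")
        if len(self.units) != r:
            raise StructuralError("one unit label required per pressure row")
        if len(set(self.labels)) != r:
            raise StructuralError("duplicate pressure labels")
        for lab, unit in zip(self.labels, self.units):
            if unit not in UNIT_REGISTRY:
                raise UnitError(
                    f"unit {unit!r} of pressure {lab!r} not in registry "
                    f"{sorted(UNIT_REGISTRY)}"
                )
        if (self.F < 0).any():
            raise AccountInconsistencyError("negative satellite entries")

    @property
    def n_pressures(self) -> int:
        return len(self.labels)

    def intensities(self, x: np.ndarray) -> np.ndarray:
        """Pressure per monetary unit of output, ``f = F x̂⁻¹``."""
        return normalize_satellite(self.F, x)

    def row(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise StructuralError(f"unknown pressure label {label!r}") from None


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_accounts`.

    ``residuals`` holds, per sector, ``|x_i − (Σ_j Z_ij + Σ_c Y_ic)| / max(x_i, 1)``.
    """

    residuals: np.ndarray
    max_residual: float
    errors: tuple[str, ...]
    warnings: tuple[str, ...]
    tolerance: float

    @property
    def passed(self) -> bool:
        return not self.errors and self.max_residual <= self.tolerance


def validate_accounts(
    accounts: MRIOAccounts, tolerance: float = BALANCE_TOL
) -> ValidationReport:
    """Check row balance ``x = Z·1 + Y·1`` and sign conventions.

    Negative final-demand entries are warnings (inventory changes are
    legitimate); negative ``Z`` or ``x`` entries are errors.
    """
    Z, x, Y = accounts.Z, accounts.x, accounts.Y
    errors: list[str] = []
    warnings: list[str] = []
    if (Z < 0).any():
        errors.append(f"{int((Z < 0).sum())} negative transaction entries in Z")
    if (x < 0).any():
        errors.append(f"{int((x < 0).sum())} negative gross-output entries in x")
    if (Y < 0).any():
        warnings.append(
            f"{int((Y < 0).sum())} negative final-demand entries in Y "
            "(allowed, e.g. inventory changes)"
        )
    supplied = Z.sum(axis=1) + Y.sum(axis=1)
    residuals = np.abs(x - supplied) / np.maximum(x, 1.0)
    return ValidationReport(
        residuals=residuals,
        max_residual=float(residuals.max()),
        errors=tuple(errors),
        warnings=tuple(warnings),
        tolerance=tolerance,
    )


def replace(obj, **changes):
    """Thin re-export of :func:`dataclasses.replace` for account objects."""
    return dataclasses.replace(obj, **changes)
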