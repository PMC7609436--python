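"""Domain types for the cellular Potts model (CPM) engine.

The lattice is a 2D rectangular grid of sites.  Axis 0 is the
anterior–posterior (AP) axis with row 0 anterior-most; axis 1 is the
medio-lateral (ML) axis.  Every site is owned by exactly one cell id
``sigma``; id 0 is the medium.  Everything outside the grid is a fixed
medium frame (no wraparound).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellType",
    "CellRecord",
    "AdhesionMatrix",
    "ModelParams",
    "PotentialField",
    "CopyAttempt",
    "LatticeState",
    "MEDIUM_ID",
    "N_TYPES",
]

MEDIUM_ID = 0


class CellType(enum.IntEnum):
    """Cell types of the gastrulating mesoderm model.

    MEDIUM is the cell-free background; LEADING_EDGE the first-involuting,
    highly adhesive marginal cells; PPL the prechordal plate; NC the trailing
    notochordal plate; LPM the flanking lateral plate mesoderm.
    """

    MEDIUM = 0
    LEADING_EDGE = 1
    PPL = 2
    NC = 3
    LPM = 4


N_TYPES = len(CellType)


@dataclass
class CellRecord:
    """Per-cell bookkeeping: type, volume/surface state and targets.

    Volume ``V`` is the number of lattice sites owned; surface ``S`` is the
    number of heterolabel neighbour links of the cell under the configured
    neighbourhood.  A cell whose volume reaches zero is flagged ``removed``
    and never reacquires sites.
    """

    id: int
    type: CellType
    V0: float
    S0: float
    V: int = 0
    S: int = 0
    removed: bool = False

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError("cell id must be a positive integer")
        if self.type == CellType.MEDIUM:
            raise ValueError("the medium has no CellRecord")


class AdhesionMatrix:
    """Symmetric type-pair contact energies J(tau, tau').

    Uses the contact-energy sign convention: each heterolabel neighbour link
    between sites of types tau, tau' contributes J(tau, tau') to the total
    energy, so *lower* J means *stronger* effective adhesion.  The bonding
    preference of a type pair relative to medium contact is
    ``gamma = J(tau, M) + J(tau', M) - J(tau, tau')`` (work of adhesion);
    doubling a pair's bond strength means doubling gamma.
    """

    def __init__(self, J: np.ndarray | None = None):
        if J is None:
            J = np.zeros((N_TYPES, N_TYPES), float)
        J = np.asarray(J, dtype=float)
        if J.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"J must be {N_TYPES}x{N_TYPES} (one row per cell type)")
        if not np.allclose(J, J.T):
            raise ValueError("J must be symmetric")
        self.J = 0.5 * (J + J.T)

    def __getitem__(self, pair: tuple[int, int]) -> float:
        a, b = pair
        return float(self.J[int(a), int(b)])

    def set(self, a: int, b: int, value: float) -> None:
        self.J[int(a), int(b)] = value
        self.J[int(b), int(a)] = value

    def bond_strength(self, a: int, b: int) -> float:
        """Work of adhesion gamma = J(a,M) + J(b,M) - J(a,b)."""
        m = CellType.MEDIUM
        return self[a, m] + self[b, m] - self[a, b]

    def with_bond_strength(self, a: int, b: int, gamma: float) -> "AdhesionMatrix":
        """Return a copy where pair (a, b) has work of adhesion ``gamma``."""
        out = AdhesionMatrix(self.J.copy())
        m = CellType.MEDIUM
        out.set(a, b, self[a, m] + self[b, m] - gamma)
        return out

    def copy(self) -> "AdhesionMatrix":
        return AdhesionMatrix(self.J.copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AdhesionMatrix) and np.array_equal(self.J, other.J)


# Moore (8-neighbour) and von Neumann (4-neighbour) offsets.
MOORE = tuple(
    (da, dm) for da in (-1, 0, 1) for dm in (-1, 0, 1) if (da, dm) != (0, 0)
)
VON_NEUMANN = ((-1, 0), (1, 0), (0, -1), (0, 1))

# Source candidates: all sites within Chebyshev distance 2 of the target.
CHEBYSHEV2 = tuple(
    (da, dm)
    for da in (-2, -1, 0, 1, 2)
    for dm in (-2, -1, 0, 1, 2)
    if (da, dm) != (0, 0)
)


@dataclass
class ModelParams:
    """CPM parameters in reduced units.

    lambda_V, lambda_S : volume / surface constraint stiffnesses.
    lambda_M           : mobility constant coupling the AP potential.
    T                  : Metropolis temperature (> 0).
    mu_by_type         : mobility per cell type; medium is pinned to 0 and
                         the mesodermal baseline is 1 (reduced units).
    neighbourhood      : 'moore' (default) or 'von_neumann', used for both
                         the adhesion sum and the surface definition.
    seed               : seed for the single pseudo-random stream.
    """

    lambda_V: float = 2.0
    lambda_S: float = 0.2
    lambda_M: float = 8.0
    T: float = 8.0
    mu_by_type: dict[CellType, float] = field(
        default_factory=lambda: {
            CellType.MEDIUM: 0.0,
            CellType.LEADING_EDGE: 1.0,
            CellType.PPL: 1.0,
            CellType.NC: 1.0,
            CellType.LPM: 1.0,
        }
    )
    neighbourhood: str = "moore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature T must be > 0")
        if self.lambda_V < 0 or self.lambda_S < 0:
            raise ValueError("constraint stiffnesses must be >= 0")
        if self.neighbourhood not in ("moore", "von_neumann"):
            raise ValueError("neighbourhood must be 'moore' or 'von_neumann'")
        if self.mu_by_type.get(CellType.MEDIUM, 0.0) != 0.0:
            raise ValueError("medium mobility must be 0")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        return MOORE if self.neighbourhood == "moore" else VON_NEUMANN

    def mu_array(self) -> np.ndarray:
        mu = np.zeros(N_TYPES, float)
        for t, v in self.mu_by_type.items():
            mu[int(t)] = v
        return mu


@dataclass
class PotentialField:
    """Linear anterior–posterior potential c biasing motile cells.

    ``c`` is affine in the AP row index and constant along ML.  A copy
    attempt by a motile cell changes the energy by
    ``mu * lambda_M * (c(source) - c(target))`` so with
    ``anterior_favourable=True`` the ramp is built so that anterior-directed
    copies (target row < source row) are energetically favourable.
    """

    slope: float = 1.0
    anterior_favourable: bool = True

    def values(self, n_ap: int) -> np.ndarray:
        ap = np.arange(n_ap, dtype=float)
        # c increasing toward the anterior makes c(source) - c(target) < 0
        # for anterior-directed copies.
        if self.anterior_favourable:
            return self.slope * (n_ap - 1 - ap)
        return self.slope * ap

    def c(self, ap_index: int, n_ap: int) -> float:
        if self.anterior_favourable:
            return self.slope * (n_ap - 1 - ap_index)
        return self.slope * float(ap_index)


@dataclass
class CopyAttempt:
    """One label-copy attempt: source label copied into the target site."""

    target: tuple[int, int]
    source_site: tuple[int, int] | None  # None when the source is off-grid medium
    source_label: int
    dH_bond: float = 0.0
    dH_mobility: float = 0.0
    accepted: bool = False

    @property
    def dH(self) -> float:
        return self.dH_bond + self.dH_mobility


class LatticeState:
    """The CPM configuration: owner grid plus per-cell bookkeeping.

    Parameters
    ----------
    shape : (n_ap, n_ml) number of lattice sites along AP and ML.
    site_size : physical edge length of one site in micrometres.
    """

    def __init__(self, shape: tuple[int, int], site_size: float = 2.0):
        self.owner = np.zeros(shape, dtype=np.int32)
        self.site_size = float(site_size)
        self.cells: dict[int, CellRecord] = {}
        self.step_count = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.owner.shape

    def add_cell(self, record: CellRecord, sites: np.ndarray) -> None:
        """Place a new cell on currently medium-owned sites."""
        sites = np.asarray(sites)
        if record.id in self.cells:
            raise ValueError(f"cell id {record.id} already exists")
        rows, cols = sites[:, 0], sites[:, 1]
        if np.any(self.owner[rows, cols] != MEDIUM_ID):
            raise ValueError("cannot place a cell on occupied sites")
        self.owner[rows, cols] = record.id
        self.cells[record.id] = record
        record.V = len(sites)

    def type_of(self, label: int) -> CellType:
        if label == MEDIUM_ID:
            return CellType.MEDIUM
        return self.cells[label].type

    def type_grid(self) -> np.ndarray:
        """Per-site cell-type codes (int array, medium = 0)."""
        max_id = max(self.cells.keys(), default=0)
        lut = np.zeros(max_id + 1, dtype=np.int32)
        for cid, rec in self.cells.items():
            lut[cid] = int(rec.type)
        return lut[self.owner]

    def copy(self) -> "LatticeState":
        import dataclasses

        out = LatticeState(self.shape, self.site_size)
        out.owner = self.owner.copy()
        out.cells = {cid: dataclasses.replace(rec) for cid, rec in self.cells.items()}
        out.step_count = self.step_count
        return out

    def recount(self, params: ModelParams) -> None:
        """Recompute every cell's V and S from the grid (oracle-grade)."""
        from .energy import surface_counts

        vols = np.bincount(self.owner.ravel(), minlength=max(self.cells, default=0) + 1)
        surf = surface_counts(self, params)
        for cid, rec in self.cells.items():
            rec.V = int(vols[cid]) if cid < len(vols) else 0
            rec.S = int(surf.get(cid, 0))
            if rec.V == 0:
                rec.removed = True
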