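"""Energy functions of the cellular Potts model.

The total energy is the Glazier–Graner–Hogeweg Hamiltonian

    H = sum_links J(tau, tau') * (1 - delta_{sigma sigma'})
      + sum_cells lambda_V (V - V0)^2
      + sum_cells lambda_S (S - S0)^2

where the adhesion sum runs over unordered neighbour-site links (Moore
neighbourhood by default), the Kronecker delta removes same-cell links, and
the medium carries no volume or surface term.  Sites outside the grid belong
to a fixed medium frame, so links crossing the grid boundary contribute
J(tau, MEDIUM).

Directed motility enters as an extra term for a copy attempt only
(it is a non-equilibrium drive, not part of H):

    dH_M = mu(tau(source)) * lambda_M * (c(source) - c(target))

with c an affine anterior–posterior potential.

Retired cells (volume driven to zero) keep their now-constant penalty
``lambda_V V0^2 + lambda_S S0^2`` in H.  This makes the energy change of the
killing move include the ``(0 - V0)^2`` transition and keeps local deltas
identically equal to full-recompute differences; a constant offset never
affects the dynamics.
"""

from __future__ import annotations

import math

import numpy as np

from .types import (
    MEDIUM_ID,
    AdhesionMatrix,
    CellType,
    CopyAttempt,
    LatticeState,
    ModelParams,
    PotentialField,
)

__all__ = [
    "total_hamiltonian",
    "bond_energy_delta",
    "mobility_delta",
    "metropolis_accept",
    "surface_counts",
]


def _neighbour_labels(state: LatticeState, a: int, m: int, params: ModelParams):
    """Labels of the neighbourhood of site (a, m); off-grid -> medium."""
    n_ap, n_ml = state.shape
    out = []
    for da, dm in params.offsets:
        aa, mm = a + da, m + dm
        if 0 <= aa < n_ap and 0 <= mm < n_ml:
            out.append(int(state.owner[aa, mm]))
        else:
            out.append(MEDIUM_ID)
    return out


def surface_counts(state: LatticeState, params: ModelParams) -> dict[int, int]:
    """Heterolabel-link count per cell id, by exhaustive link enumeration.

    Every unordered heterolabel link counts toward the surface of both of
    its cell endpoints; links to the medium (including the off-grid frame)
    count toward the cell endpoint only.
    """
    return _surface_counts_vec(state, params)


def _link_pairs(state: LatticeState, params: ModelParams):
    """Yield (label_a, label_b) arrays for every unordered neighbour link.

    In-grid links are enumerated once via half the neighbourhood directions;
    links to the off-grid medium frame are enumerated over all directions
    (each involves exactly one in-grid site, paired with medium).
    """
    owner = state.owner
    n_ap, n_ml = owner.shape
    half = [(da, dm) for (da, dm) in params.offsets if (da, dm) > (0, 0)]
    # (da, dm) > (0, 0) lexicographically selects one direction per +/- pair
    for da, dm in half:
        a0, a1 = max(0, -da), min(n_ap, n_ap - da)
        m0, m1 = max(0, -dm), min(n_ml, n_ml - dm)
        A = owner[a0:a1, m0:m1]
        B = owner[a0 + da : a1 + da, m0 + dm : m1 + dm]
        yield A.ravel(), B.ravel()
    # frame links: for every direction, sites whose neighbour is off-grid
    for da, dm in params.offsets:
        rows = np.arange(n_ap)
        cols = np.arange(n_ml)
        aa = rows[:, None] + da
        mm = cols[None, :] + dm
        off = (aa < 0) | (aa >= n_ap) | (mm < 0) | (mm >= n_ml)
        labs = owner[off]
        yield labs, np.zeros_like(labs)


def _surface_counts_vec(state: LatticeState, params: ModelParams) -> dict[int, int]:
    counts = np.zeros(max(state.cells, default=0) + 1, dtype=np.int64)
    for A, B in _link_pairs(state, params):
        het = A != B
        a, b = A[het], B[het]
        counts += np.bincount(a, minlength=len(counts))[: len(counts)] if len(a) else 0
        counts += np.bincount(b, minlength=len(counts))[: len(counts)] if len(b) else 0
    return {cid: int(counts[cid]) for cid in state.cells}


def total_hamiltonian(
    state: LatticeState, J: AdhesionMatrix, params: ModelParams
) -> float:
    """Full recompute of the CPM Hamiltonian (adhesion + volume + surface).

    Volumes and surfaces are recounted from the grid rather than trusted
    from the cached bookkeeping, so this doubles as the oracle for the
    incremental updates.
    """
    tg = state.type_grid()
    max_id = max(state.cells, default=0)
    type_lut = np.zeros(max_id + 1, dtype=np.int64)
    for cid, rec in state.cells.items():
        type_lut[cid] = int(rec.type)

    adhesion = 0.0
    for A, B in _link_pairs(state, params):
        het = A != B
        if not het.any():
            continue
        ta = type_lut[A[het]]
        tb = type_lut[B[het]]
        adhesion += float(J.J[ta, tb].sum())

    vols = np.bincount(state.owner.ravel(), minlength=max_id + 1)
    surf = _surface_counts_vec(state, params)
    constraint = 0.0
    for cid, rec in state.cells.items():
        V = int(vols[cid]) if cid < len(vols) else 0
        S = surf.get(cid, 0)
        constraint += params.lambda_V * (V - rec.V0) ** 2
        constraint += params.lambda_S * (S - rec.S0) ** 2
    return adhesion + constraint


def bond_energy_delta(
    state: LatticeState,
    attempt: CopyAttempt,
    J: AdhesionMatrix,
    params: ModelParams,
) -> float:
    """Local energy change dH_B of copying the source label into the target.

    Only the links incident to the target site and the volume/surface terms
    of the touched cells change, so the delta is computed from the target's
    neighbourhood alone.  Equals ``H(after) - H(before)`` exactly.
    """
    a, m = attempt.target
    n_ap, n_ml = state.shape
    if not (0 <= a < n_ap and 0 <= m < n_ml):
        raise IndexError(f"target site {attempt.target} outside the grid")
    old = int(state.owner[a, m])
    new = int(attempt.source_label)
    if new == old:
        return 0.0
    t_old = int(state.type_of(old))
    t_new = int(state.type_of(new))

    neigh = _neighbour_labels(state, a, m, params)

    # --- adhesion: links incident to the target flip their contribution
    d_adh = 0.0
    for nb in neigh:
        t_nb = int(state.type_of(nb))
        if nb != new:
            d_adh += J.J[t_new, t_nb]
        if nb != old:
            d_adh -= J.J[t_old, t_nb]

    # --- volume terms of the two touched cells
    d_vol = 0.0
    if old != MEDIUM_ID:
        rec = state.cells[old]
        d_vol += params.lambda_V * (
            (rec.V - 1 - rec.V0) ** 2 - (rec.V - rec.V0) ** 2
        )
    if new != MEDIUM_ID:
        rec = state.cells[new]
        d_vol += params.lambda_V * (
            (rec.V + 1 - rec.V0) ** 2 - (rec.V - rec.V0) ** 2
        )

    # --- surface terms: cells o, s and every neighbour cell whose link to
    # the target flips heterolabel status
    dS: dict[int, int] = {}
    if old != MEDIUM_ID:
        dS[old] = dS.get(old, 0) - sum(1 for nb in neigh if nb != old)
    if new != MEDIUM_ID:
        dS[new] = dS.get(new, 0) + sum(1 for nb in neigh if nb != new)
    for nb in neigh:
        if nb == MEDIUM_ID:
            continue
        dS[nb] = dS.get(nb, 0) + int(nb != new) - int(nb != old)
    d_surf = 0.0
    for cid, ds in dS.items():
        if ds == 0:
            continue
        rec = state.cells[cid]
        d_surf += params.lambda_S * (
            (rec.S + ds - rec.S0) ** 2 - (rec.S - rec.S0) ** 2
        )

    return float(d_adh + d_vol + d_surf)


def mobility_delta(
    attempt: CopyAttempt,
    field: PotentialField,
    params: ModelParams,
    source_type: CellType,
    n_ap: int,
) -> float:
    """Directed-motility energy change mu * lambda_M * (c(source) - c(target)).

    The mobility is that of the *source* cell (the cell attempting to expand);
    medium has mobility zero, so retraction moves carry no drive.
    """
    mu = params.mu_by_type.get(CellType(source_type), 0.0)
    if mu == 0.0 or attempt.source_site is None:
        return 0.0
    c_src = field.c(attempt.source_site[0], n_ap)
    c_tgt = field.c(attempt.target[0], n_ap)
    return float(mu * params.lambda_M * (c_src - c_tgt))


def metropolis_accept(dH: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dH/T)).

    Negative dH is always accepted; dH = 0 is accepted (e^0 = 1).
    """
    if T <= 0:
        raise ValueError("temperature T must be > 0")
    if dH < 0:
        return True
    return bool(rng.random() < math.exp(-dH / T))
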