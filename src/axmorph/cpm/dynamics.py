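"""Metropolis Monte Carlo dynamics of the CPM.

Copy-attempt protocol: a surface site is chosen as the target; a candidate
source site is drawn uniformly from the sites within Chebyshev distance 2 of
the target (off-grid candidates are the medium frame); the owner label of
that site is copied into the target if the Metropolis criterion accepts the
total energy change dH = dH_B + dH_M.  A surface site is any site whose
neighbourhood contains a differently owned site.  Picking a source owned by
the target's own cell is a no-op (counted as an attempt, never as an
acceptance).

One Monte Carlo step (MCS) performs one attempt per surface site enumerated
in row-major order from a snapshot taken at the start of the step.

This module is the readable reference implementation with full per-attempt
records; long scenario runs go through the numba kernel in ``_kernels``,
which follows the identical protocol (see ``scenarios.run_until_stop``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import bond_energy_delta, metropolis_accept, mobility_delta
from .types import (
    CHEBYSHEV2,
    MEDIUM_ID,
    AdhesionMatrix,
    CopyAttempt,
    LatticeState,
    ModelParams,
    PotentialField,
)

__all__ = ["surface_sites", "attempt_copy", "monte_carlo_step", "StepStats"]


def surface_sites(state: LatticeState, params: ModelParams) -> np.ndarray:
    """Row-major (ap, ml) indices of all surface sites.

    A site is a surface site when its neighbourhood (off-grid = medium)
    contains at least one differently owned site.  On an all-medium lattice
    there are none.
    """
    owner = state.owner
    n_ap, n_ml = owner.shape
    diff = np.zeros(owner.shape, dtype=bool)
    for da, dm in params.offsets:
        shifted = np.full(owner.shape, MEDIUM_ID, dtype=owner.dtype)
        a0, a1 = max(0, -da), min(n_ap, n_ap - da)
        m0, m1 = max(0, -dm), min(n_ml, n_ml - dm)
        shifted[a0:a1, m0:m1] = owner[a0 + da : a1 + da, m0 + dm : m1 + dm]
        diff |= shifted != owner
    return np.argwhere(diff)


def _evaluate(
    state: LatticeState,
    target: tuple[int, int],
    src_off: tuple[int, int],
    J: AdhesionMatrix,
    params: ModelParams,
    field: PotentialField | None,
) -> CopyAttempt:
    """Build a CopyAttempt for the given target site and source offset."""
    n_ap, n_ml = state.shape
    sa, sm = target[0] + src_off[0], target[1] + src_off[1]
    if 0 <= sa < n_ap and 0 <= sm < n_ml:
        source_site: tuple[int, int] | None = (sa, sm)
        source_label = int(state.owner[sa, sm])
    else:
        source_site = None  # off-grid medium frame
        source_label = MEDIUM_ID
    attempt = CopyAttempt(
        target=tuple(target), source_site=source_site, source_label=source_label
    )
    if source_label == int(state.owner[target[0], target[1]]):
        return attempt  # self-copy: no-op, dH fields stay 0, never accepted
    attempt.dH_bond = bond_energy_delta(state, attempt, J, params)
    if field is not None and source_label != MEDIUM_ID:
        attempt.dH_mobility = mobility_delta(
            attempt, field, params, state.cells[source_label].type, n_ap
        )
    return attempt


def _apply(state: LatticeState, attempt: CopyAttempt, params: ModelParams) -> None:
    """Commit an accepted attempt with incremental V/S bookkeeping."""
    a, m = attempt.target
    old = int(state.owner[a, m])
    new = int(attempt.source_label)
    neigh = []
    n_ap, n_ml = state.shape
    for da, dm in params.offsets:
        aa, mm = a + da, m + dm
        lab = int(state.owner[aa, mm]) if 0 <= aa < n_ap and 0 <= mm < n_ml else MEDIUM_ID
        neigh.append(lab)
    state.owner[a, m] = new
    if old != MEDIUM_ID:
        rec = state.cells[old]
        rec.V -= 1
        rec.S -= sum(1 for nb in neigh if nb != old)
        if rec.V == 0:
            rec.removed = True
    if new != MEDIUM_ID:
        rec = state.cells[new]
        rec.V += 1
        rec.S += sum(1 for nb in neigh if nb != new)
    # neighbour cells (including old/new appearing as neighbours) whose link
    # to the target flips heterolabel status
    for nb in set(neigh):
        if nb == MEDIUM_ID:
            continue
        ds = neigh.count(nb) * (int(nb != new) - int(nb != old))
        if ds and nb in state.cells:
            state.cells[nb].S += ds


def attempt_copy(
    state: LatticeState,
    rng: np.random.Generator,
    J: AdhesionMatrix,
    params: ModelParams,
    field: PotentialField | None = None,
) -> tuple[LatticeState, CopyAttempt | None]:
    """Perform one random copy attempt in place.

    Returns the (mutated) state and the attempt record, or ``None`` when the
    lattice has no surface sites (all medium).
    """
    sites = surface_sites(state, params)
    if len(sites) == 0:
        return state, None
    target = tuple(sites[rng.integers(len(sites))])
    src_off = CHEBYSHEV2[rng.integers(len(CHEBYSHEV2))]
    attempt = _evaluate(state, target, src_off, J, params, field)
    if attempt.source_label == int(state.owner[target]):
        return state, attempt
    if metropolis_accept(attempt.dH, params.T, rng):
        attempt.accepted = True
        _apply(state, attempt, params)
    return state, attempt


@dataclass
class StepStats:
    """Per-MCS statistics: attempts, acceptances and end-of-step energy."""

    attempts: int
    accepted: int
    energy: float


def monte_carlo_step(
    state: LatticeState,
    rng: np.random.Generator,
    J: AdhesionMatrix,
    params: ModelParams,
    field: PotentialField | None = None,
) -> tuple[LatticeState, StepStats]:
    """One MCS: one attempt per surface site snapshotted at step start."""
    from .energy import total_hamiltonian

    sites = surface_sites(state, params)
    accepted = 0
    for target in sites:
        src_off = CHEBYSHEV2[rng.integers(len(CHEBYSHEV2))]
        attempt = _evaluate(state, tuple(target), src_off, J, params, field)
        if attempt.source_label == int(state.owner[target[0], target[1]]):
            continue
        if metropolis_accept(attempt.dH, params.T, rng):
            attempt.accepted = True
            _apply(state, attempt, params)
            accepted += 1
    state.step_count += 1
    return state, StepStats(
        attempts=len(sites),
        accepted=accepted,
        energy=total_hamiltonian(state, J, params),
    )
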