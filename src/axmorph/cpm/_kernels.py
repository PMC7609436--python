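"""Numba-compiled Monte Carlo sweeps for scenario-scale CPM runs.

Implements exactly the protocol of :mod:`axmorph.cpm.dynamics` (Moore
neighbourhood): per sweep, one copy attempt per surface site enumerated
row-major from a snapshot taken at sweep start; the source candidate is a
uniform draw from the 24 sites within Chebyshev distance 2 (off-grid =
medium); self-copies are no-ops; Metropolis acceptance at temperature T.

The kernel mutates the owner grid and the per-cell V/S bookkeeping arrays in
place and can log every non-trivial attempt (target, source, dH, accepted)
so tests can replay a run through the pure-Python energy functions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighbourhood and Chebyshev-2 source offsets, row-major order.
_OFFS8 = np.array(
    [(da, dm) for da in (-1, 0, 1) for dm in (-1, 0, 1) if (da, dm) != (0, 0)],
    dtype=np.int64,
)
_OFFS24 = np.array(
    [
        (da, dm)
        for da in (-2, -1, 0, 1, 2)
        for dm in (-2, -1, 0, 1, 2)
        if (da, dm) != (0, 0)
    ],
    dtype=np.int64,
)


@njit(cache=False)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _surface_sites(owner, out_a, out_m):
    n_ap, n_ml = owner.shape
    n = 0
    for a in range(n_ap):
        for m in range(n_ml):
            lab = owner[a, m]
            found = False
            for k in range(8):
                aa = a + _OFFS8[k, 0]
                mm = m + _OFFS8[k, 1]
                if 0 <= aa < n_ap and 0 <= mm < n_ml:
                    nb = owner[aa, mm]
                else:
                    nb = 0
                if nb != lab:
                    found = True
                    break
            if found:
                out_a[n] = a
                out_m[n] = m
                n += 1
    return n


@njit(cache=False)
def total_energy(owner, type_by_id, V, V0, S, S0, J, lamV, lamS, n_cells):
    """Full Hamiltonian recompute (adhesion over unordered links + constraints)."""
    n_ap, n_ml = owner.shape
    adh = 0.0
    for a in range(n_ap):
        for m in range(n_ml):
            lab = owner[a, m]
            t = type_by_id[lab]
            for k in range(8):
                da = _OFFS8[k, 0]
                dm = _OFFS8[k, 1]
                aa = a + da
                mm = m + dm
                inside = 0 <= aa < n_ap and 0 <= mm < n_ml
                if inside:
                    # count each in-grid unordered link once
                    if da > 0 or (da == 0 and dm > 0):
                        nb = owner[aa, mm]
                        if nb != lab:
                            adh += J[t, type_by_id[nb]]
                else:
                    # frame links: one in-grid endpoint, count every direction
                    if lab != 0:
                        adh += J[t, 0]
    cons = 0.0
    for cid in range(1, n_cells + 1):
        cons += lamV * (V[cid] - V0[cid]) ** 2
        cons += lamS * (S[cid] - S0[cid]) ** 2
    return adh + cons


@njit(cache=False)
def run_sweeps(
    owner,
    type_by_id,
    V,
    V0,
    S,
    S0,
    removed,
    J,
    mu,
    lamV,
    lamS,
    lamM,
    c_ap,
    T,
    n_sweeps,
    stats_out,  # (n_sweeps, 3): attempts, accepted, energy
    compute_energy,
    log_int,  # (cap, 6): ta, tm, sa, sm, source_label, accepted   (sa=-9 off-grid)
    log_f,  # (cap,): dH
    log_start,
):
    n_ap, n_ml = owner.shape
    cap = log_int.shape[0]
    log_n = log_start
    surf_a = np.empty(n_ap * n_ml, np.int64)
    surf_m = np.empty(n_ap * n_ml, np.int64)
    nb_lab = np.empty(8, np.int64)
    ids = np.empty(12, np.int64)
    ds = np.empty(12, np.int64)

    for sweep in range(n_sweeps):
        n_surf = _surface_sites(owner, surf_a, surf_m)
        accepted = 0
        for i in range(n_surf):
            a = surf_a[i]
            m = surf_m[i]
            k = np.random.randint(24)
            sa = a + _OFFS24[k, 0]
            sm = m + _OFFS24[k, 1]
            if 0 <= sa < n_ap and 0 <= sm < n_ml:
                new = owner[sa, sm]
                src_inside = True
            else:
                new = 0
                src_inside = False
            old = owner[a, m]
            if new == old:
                continue
            t_old = type_by_id[old]
            t_new = type_by_id[new]

            for q in range(8):
                aa = a + _OFFS8[q, 0]
                mm = m + _OFFS8[q, 1]
                if 0 <= aa < n_ap and 0 <= mm < n_ml:
                    nb_lab[q] = owner[aa, mm]
                else:
                    nb_lab[q] = 0

            # adhesion delta over the 8 links incident to the target
            d_adh = 0.0
            for q in range(8):
                t_nb = type_by_id[nb_lab[q]]
                if nb_lab[q] != new:
                    d_adh += J[t_new, t_nb]
                if nb_lab[q] != old:
                    d_adh -= J[t_old, t_nb]

            # volume deltas
            d_vol = 0.0
            if old != 0:
                d_vol += lamV * ((V[old] - 1 - V0[old]) ** 2 - (V[old] - V0[old]) ** 2)
            if new != 0:
                d_vol += lamV * ((V[new] + 1 - V0[new]) ** 2 - (V[new] - V0[new]) ** 2)

            # surface deltas for every touched cell
            n_ids = 0
            if old != 0:
                c = 0
                for q in range(8):
                    if nb_lab[q] != old:
                        c += 1
                ids[n_ids] = old
                ds[n_ids] = -c
                n_ids += 1
            if new != 0:
                c = 0
                for q in range(8):
                    if nb_lab[q] != new:
                        c += 1
                ids[n_ids] = new
                ds[n_ids] = c
                n_ids += 1
            for q in range(8):
                nb = nb_lab[q]
                if nb == 0:
                    continue
                d = (1 if nb != new else 0) - (1 if nb != old else 0)
                if d == 0:
                    continue
                found = False
                for j in range(n_ids):
                    if ids[j] == nb:
                        ds[j] += d
                        found = True
                        break
                if not found:
                    ids[n_ids] = nb
                    ds[n_ids] = d
                    n_ids += 1
            d_surf = 0.0
            for j in range(n_ids):
                cid = ids[j]
                if ds[j] != 0:
                    d_surf += lamS * (
                        (S[cid] + ds[j] - S0[cid]) ** 2 - (S[cid] - S0[cid]) ** 2
                    )

            dH = d_adh + d_vol + d_surf

            # directed-motility drive (source cell only; medium has mu = 0)
            if new != 0 and src_inside:
                dH += mu[t_new] * lamM * (c_ap[sa] - c_ap[a])

            if dH < 0.0:
                acc = True
            else:
                acc = np.random.random() < np.exp(-dH / T)

            if log_n < cap:
                log_int[log_n, 0] = a
                log_int[log_n, 1] = m
                log_int[log_n, 2] = sa if src_inside else -9
                log_int[log_n, 3] = sm if src_inside else -9
                log_int[log_n, 4] = new
                log_int[log_n, 5] = 1 if acc else 0
                log_f[log_n] = dH
                log_n += 1

            if acc:
                accepted += 1
                owner[a, m] = new
                if old != 0:
                    V[old] -= 1
                    if V[old] == 0:
                        removed[old] = 1
                if new != 0:
                    V[new] += 1
                for j in range(n_ids):
                    S[ids[j]] += ds[j]

        stats_out[sweep, 0] = n_surf
        stats_out[sweep, 1] = accepted
        if compute_energy:
            stats_out[sweep, 2] = total_energy(
                owner, type_by_id, V, V0, S, S0, J, lamV, lamS, len(V) - 1
            )
        else:
            stats_out[sweep, 2] = np.nan
    return log_n
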