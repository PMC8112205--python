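"""Numba-compiled Monte Carlo inner loops.

Flat-array layout; the caller precomputes the periodic neighbor table
``nbr[i, 0..3]`` (up, down, left, right) and the occupancy position
lists.  Running energies are updated incrementally; callers verify the
bookkeeping against a full recompute after the run.
"""

import numpy as np
from numba import njit

#: sample columns: cycle, e_total, e_bend, e_bind, e_rp, e_rr,
#: n_complex, n_receptors_on_raft, n_patches_in_well
N_SAMPLE_COLS = 9


@njit(cache=True, fastmath=True)
def _lap(l, nbr, i):
    return l[nbr[i, 0]] + l[nbr[i, 1]] + l[nbr[i, 2]] + l[nbr[i, 3]] - 4.0 * l[i]


@njit(cache=True, fastmath=True)
def full_energies(l, mp, mm, npr, nbr, kappa, a, ub, lb, lc, ua, u):
    """Direct summation of the four energy terms on flat arrays."""
    half = 0.5 * lb
    k2a2 = kappa / (2.0 * a * a)
    e_bend = 0.0
    e_bind = 0.0
    e_rp = 0.0
    e_rr = 0.0
    for i in range(l.shape[0]):
        lap = _lap(l, nbr, i)
        e_bend += lap * lap
        if mp[i] == 1 and mm[i] == 1 and (lc - half < l[i] < lc + half):
            e_bind -= ub
        if mp[i] == 1 and npr[i] == 1:
            e_rp -= ua
        if npr[i] == 1:
            if npr[nbr[i, 1]] == 1:  # down bond, counted once
                e_rr -= u
            if npr[nbr[i, 3]] == 1:  # right bond, counted once
                e_rr -= u
    return k2a2 * e_bend, e_bind, e_rp, e_rr


@njit(cache=True, fastmath=True)
def run_mc(
    l,
    mp,
    mm,
    npr,
    nbr,
    rec_list,
    lig_list,
    raft_list,
    rec_pos,
    lig_pos,
    raft_pos,
    kappa,
    a,
    ub,
    lb,
    lc,
    ua,
    u,
    n_height,
    n_protein,
    n_raft,
    step_height,
    n_relax_cycles,
    n_sample_cycles,
    sample_interval,
    seed,
    samples,
):
    """Metropolis run: relax then sample.  Mutates all state arrays.

    Returns (e_bend, e_bind, e_rp, e_rr, n_samples, accepted[3], attempted[3]).
    """
    np.random.seed(seed)
    half = 0.5 * lb
    k2a2 = kappa / (2.0 * a * a)
    n_sites = l.shape[0]
    e_bend, e_bind, e_rp, e_rr = full_energies(
        l, mp, mm, npr, nbr, kappa, a, ub, lb, lc, ua, u
    )
    # cached Laplacian field, updated incrementally on accepted height moves
    lap = np.empty(n_sites)
    for i in range(n_sites):
        lap[i] = _lap(l, nbr, i)
    n_rec = rec_list.shape[0]
    n_lig = lig_list.shape[0]
    n_raft_tot = raft_list.shape[0]
    total = n_height + n_protein + n_raft
    acc = np.zeros(3, np.int64)
    att = np.zeros(3, np.int64)
    s_idx = 0
    n_cycles = n_relax_cycles + n_sample_cycles
    for cyc in range(n_cycles):
        for _t in range(total):
            r = np.random.random() * total
            if r < n_height:
                att[0] += 1
                i = np.random.randint(n_sites)
                dl = (2.0 * np.random.random() - 1.0) * step_height
                lnew = l[i] + dl
                if lnew < 0.0:
                    continue  # hard-wall rejection
                lap0 = lap[i]
                d_eb = (lap0 - 4.0 * dl) ** 2 - lap0 * lap0
                for k in range(4):
                    lapn = lap[nbr[i, k]]
                    d_eb += (lapn + dl) ** 2 - lapn * lapn
                d_eb *= k2a2
                d_bind = 0.0
                if mp[i] == 1 and mm[i] == 1:
                    w0 = lc - half < l[i] < lc + half
                    w1 = lc - half < lnew < lc + half
                    if w1 and not w0:
                        d_bind = -ub
                    elif w0 and not w1:
                        d_bind = ub
                dh = d_eb + d_bind
                if dh <= 0.0 or np.random.random() < np.exp(-dh):
                    l[i] = lnew
                    lap[i] -= 4.0 * dl
                    for k in range(4):
                        lap[nbr[i, k]] += dl
                    e_bend += d_eb
                    e_bind += d_bind
                    acc[0] += 1
            elif r < n_height + n_protein:
                if n_rec + n_lig == 0:
                    continue
                att[1] += 1
                pidx = np.random.randint(n_rec + n_lig)
                if pidx < n_rec:
                    i = rec_list[pidx]
                    j = nbr[i, np.random.randint(4)]
                    if mp[j] == 1:
                        continue  # single occupancy
                    d_bind = 0.0
                    if mm[i] == 1 and (lc - half < l[i] < lc + half):
                        d_bind += ub
                    if mm[j] == 1 and (lc - half < l[j] < lc + half):
                        d_bind -= ub
                    d_rp = ua * (np.float64(npr[i]) - np.float64(npr[j]))
                    dh = d_bind + d_rp
                    if dh <= 0.0 or np.random.random() < np.exp(-dh):
                        mp[i] = 0
                        mp[j] = 1
                        rec_list[pidx] = j
                        rec_pos[i] = -1
                        rec_pos[j] = pidx
                        e_bind += d_bind
                        e_rp += d_rp
                        acc[1] += 1
                else:
                    lidx = pidx - n_rec
                    i = lig_list[lidx]
                    j = nbr[i, np.random.randint(4)]
                    if mm[j] == 1:
                        continue
                    d_bind = 0.0
                    if mp[i] == 1 and (lc - half < l[i] < lc + half):
                        d_bind += ub
                    if mp[j] == 1 and (lc - half < l[j] < lc + half):
                        d_bind -= ub
                    if d_bind <= 0.0 or np.random.random() < np.exp(-d_bind):
                        mm[i] = 0
                        mm[j] = 1
                        lig_list[lidx] = j
                        lig_pos[i] = -1
                        lig_pos[j] = lidx
                        e_bind += d_bind
                        acc[1] += 1
            else:
                if n_raft_tot == 0:
                    continue
                att[2] += 1
                ridx = np.random.randint(n_raft_tot)
                i = raft_list[ridx]
                j = nbr[i, np.random.randint(4)]
                if npr[j] == 1:
                    continue  # raft number conserved; no stacking
                bonds_i = (
                    npr[nbr[i, 0]] + npr[nbr[i, 1]] + npr[nbr[i, 2]] + npr[nbr[i, 3]]
                )
                bonds_j = 0
                for k in range(4):
                    jn = nbr[j, k]
                    if jn != i and npr[jn] == 1:
                        bonds_j += 1
                d_rr = u * (np.float64(bonds_i) - np.float64(bonds_j))
                d_rp = ua * (np.float64(mp[i]) - np.float64(mp[j]))
                dh = d_rr + d_rp
                if dh <= 0.0 or np.random.random() < np.exp(-dh):
                    npr[i] = 0
                    npr[j] = 1
                    raft_list[ridx] = j
                    raft_pos[i] = -1
                    raft_pos[j] = ridx
                    e_rr += d_rr
                    e_rp += d_rp
                    acc[2] += 1
        if cyc >= n_relax_cycles and (cyc - n_relax_cycles + 1) % sample_interval == 0:
            n_complex = 0
            n_on_raft = 0
            for k in range(n_rec):
                i = rec_list[k]
                if mm[i] == 1 and (lc - half < l[i] < lc + half):
                    n_complex += 1
                if npr[i] == 1:
                    n_on_raft += 1
            n_in_well = 0
            for i in range(n_sites):
                if lc - half < l[i] < lc + half:
                    n_in_well += 1
            samples[s_idx, 0] = cyc + 1
            samples[s_idx, 1] = e_bend + e_bind + e_rp + e_rr
            samples[s_idx, 2] = e_bend
            samples[s_idx, 3] = e_bind
            samples[s_idx, 4] = e_rp
            samples[s_idx, 5] = e_rr
            samples[s_idx, 6] = n_complex
            samples[s_idx, 7] = n_on_raft
            samples[s_idx, 8] = n_in_well
            s_idx += 1
    return e_bend, e_bind, e_rp, e_rr, s_idx, acc, att


def neighbor_table(L: int) -> np.ndarray:
    """Periodic neighbor indices for a flattened L x L lattice."""
    idx = np.arange(L * L).reshape(L, L)
    nbr = np.empty((L * L, 4), dtype=np.int64)
    nbr[:, 0] = np.roll(idx, 1, axis=0).ravel()
    nbr[:, 1] = np.roll(idx, -1, axis=0).ravel()
    nbr[:, 2] = np.roll(idx, 1, axis=1).ravel()
    nbr[:, 3] = np.roll(idx, -1, axis=1).ravel()
    return nbr
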