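"""Numba kernels for the Metropolis dynamics.

The hot loop lives here: single-monomer hops with geometric screening
(excluded volume + bond restrictions) followed by the Metropolis test, with
incremental energy bookkeeping. Positions are unwrapped int64; occupancy is
a (L,L,L) uint8 grid indexed modulo L; ``u_tab`` holds the precomputed pair
energies for the three in-cutoff squared separations (slot d2-4 for
d2 = 4, 5, 6).

Everything is deterministic for a fixed seed (numba's np.random state is
per-thread and seeded inside the kernel).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def total_energy_nb(pos, seq_idx, u_tab, L):
    """O(N^2) total pair energy under the minimum-image convention."""
    n = pos.shape[0]
    half = L // 2
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (pos[j, 0] - pos[i, 0] + half) % L - half
            dy = (pos[j, 1] - pos[i, 1] + half) % L - half
            dz = (pos[j, 2] - pos[i, 2] + half) % L - half
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < 8:
                e += u_tab[d2 - 4, seq_idx[i], seq_idx[j]]
    return e


@njit(cache=True)
def pair_tables(u_tab, seq_idx):
    """Per-pair energy rows u3[i, j, slot] (slot = d2 - 4), contiguous."""
    n = seq_idx.size
    u3 = np.empty((n, n, 3), dtype=np.float64)
    for i in range(n):
        for j in range(n):
            for s in range(3):
                u3[i, j, s] = u_tab[s, seq_idx[i], seq_idx[j]]
    return u3


@njit(cache=True)
def run_mc(pos, occ, seq_idx, u_tab, thermal, bond_tab, L, T,
           n_mcs, sample_every, seed):
    """Run n_mcs Monte Carlo steps (N attempts each) at temperature T.

    Mutates ``pos`` and ``occ`` in place and returns
    (sample_pos, sample_E, sample_acc, sample_t, E_final) where samples
    include the initial state at t = 0 and ``sample_acc`` holds cumulative
    per-residue acceptance counts.
    """
    n = pos.shape[0]
    half = L // 2
    np.random.seed(seed)
    u3 = pair_tables(u_tab, seq_idx)

    n_samples = n_mcs // sample_every + 1
    s_pos = np.empty((n_samples, n, 3), dtype=np.int64)
    s_e = np.empty(n_samples, dtype=np.float64)
    s_acc = np.zeros((n_samples, n), dtype=np.int64)
    s_t = np.empty(n_samples, dtype=np.int64)

    acc = np.zeros(n, dtype=np.int64)
    energy = total_energy_nb(pos, seq_idx, u_tab, L)
    s_pos[0] = pos
    s_e[0] = energy
    s_t[0] = 0
    si = 1

    for t in range(1, n_mcs + 1):
        for _ in range(n):
            i = np.random.randint(0, n)
            d = np.random.randint(0, 6)
            axis = d >> 1
            sgn = 1 if (d & 1) == 0 else -1

            px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
            nx, ny, nz = px, py, pz
            if axis == 0:
                nx += sgn
            elif axis == 1:
                ny += sgn
            else:
                nz += sgn

            # bond restriction for the (up to two) adjacent bonds
            ok = True
            for j in (i - 1, i + 1):
                if 0 <= j < n:
                    vx = pos[j, 0] - nx
                    vy = pos[j, 1] - ny
                    vz = pos[j, 2] - nz
                    if vx < -3 or vx > 3 or vy < -3 or vy > 3 or vz < -3 or vz > 3:
                        ok = False
                        break
                    if bond_tab[vx + 3, vy + 3, vz + 3] == 0:
                        ok = False
                        break
            if not ok:
                continue

            # excluded volume: the 4 newly claimed sites must be free
            if axis == 0:
                pc = (px + 2) % L if sgn > 0 else (px - 1) % L
                a0, a1 = py % L, (py + 1) % L
                b0, b1 = pz % L, (pz + 1) % L
                if (occ[pc, a0, b0] or occ[pc, a0, b1]
                        or occ[pc, a1, b0] or occ[pc, a1, b1]):
                    continue
            elif axis == 1:
                pc = (py + 2) % L if sgn > 0 else (py - 1) % L
                a0, a1 = px % L, (px + 1) % L
                b0, b1 = pz % L, (pz + 1) % L
                if (occ[a0, pc, b0] or occ[a0, pc, b1]
                        or occ[a1, pc, b0] or occ[a1, pc, b1]):
                    continue
            else:
                pc = (pz + 2) % L if sgn > 0 else (pz - 1) % L
                a0, a1 = px % L, (px + 1) % L
                b0, b1 = py % L, (py + 1) % L
                if (occ[a0, b0, pc] or occ[a0, b1, pc]
                        or occ[a1, b0, pc] or occ[a1, b1, pc]):
                    continue

            # Metropolis on the energy change; the new separation reuses the
            # old minimum image with only the moved axis adjusted (a unit
            # step changes the wrapped component by at most one re-wrap)
            de = 0.0
            if thermal:
                row = u3[i]
                for j in range(n):
                    if j == i:
                        continue
                    # any component beyond 3 keeps both the old and the
                    # stepped separation outside the sqrt(8) cutoff
                    dx = (pos[j, 0] - px + half) % L - half
                    if dx > 3 or dx < -3:
                        continue
                    dy = (pos[j, 1] - py + half) % L - half
                    if dy > 3 or dy < -3:
                        continue
                    dz = (pos[j, 2] - pz + half) % L - half
                    if dz > 3 or dz < -3:
                        continue
                    if axis == 0:
                        c_old, c_new = dx, dx - sgn
                    elif axis == 1:
                        c_old, c_new = dy, dy - sgn
                    else:
                        c_old, c_new = dz, dz - sgn
                    if c_new > half:
                        c_new -= L
                    elif c_new < -half:
                        c_new += L
                    d2 = dx * dx + dy * dy + dz * dz
                    d2n = d2 - c_old * c_old + c_new * c_new
                    if d2 < 8:
                        de -= row[j, d2 - 4]
                    if d2n < 8:
                        de += row[j, d2n - 4]
                if de > 0.0 and np.random.random() >= np.exp(-de / T):
                    continue

            # accept: move the blocked face of 4 sites
            if axis == 0:
                fc = px % L if sgn > 0 else (px + 1) % L
                a0, a1 = py % L, (py + 1) % L
                b0, b1 = pz % L, (pz + 1) % L
                occ[fc, a0, b0] = 0; occ[fc, a0, b1] = 0
                occ[fc, a1, b0] = 0; occ[fc, a1, b1] = 0
                occ[pc, a0, b0] = 1; occ[pc, a0, b1] = 1
                occ[pc, a1, b0] = 1; occ[pc, a1, b1] = 1
            elif axis == 1:
                fc = py % L if sgn > 0 else (py + 1) % L
                a0, a1 = px % L, (px + 1) % L
                b0, b1 = pz % L, (pz + 1) % L
                occ[a0, fc, b0] = 0; occ[a0, fc, b1] = 0
                occ[a1, fc, b0] = 0; occ[a1, fc, b1] = 0
                occ[a0, pc, b0] = 1; occ[a0, pc, b1] = 1
                occ[a1, pc, b0] = 1; occ[a1, pc, b1] = 1
            else:
                fc = pz % L if sgn > 0 else (pz + 1) % L
                a0, a1 = px % L, (px + 1) % L
                b0, b1 = py % L, (py + 1) % L
                occ[a0, b0, fc] = 0; occ[a0, b1, fc] = 0
                occ[a1, b0, fc] = 0; occ[a1, b1, fc] = 0
                occ[a0, b0, pc] = 1; occ[a0, b1, pc] = 1
                occ[a1, b0, pc] = 1; occ[a1, b1, pc] = 1

            pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
            energy += de
            acc[i] += 1

        if t % sample_every == 0:
            s_pos[si] = pos
            s_e[si] = energy
            s_acc[si] = acc
            s_t[si] = t
            si += 1

    return s_pos, s_e, s_acc, s_t, energy
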