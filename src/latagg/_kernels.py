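"""Numba kernels: incremental contact energies, move attempts, MC drivers.

Everything here operates on flat numpy arrays so the inner loop compiles to
machine code:

    occ     (Lx, Ly, Lz) int32 occupancy grid: -1 empty, -2 surface site,
            chain * M + bead for chain beads
    chains  (N, M, 3) int64 bead coordinates
    seq     (M,) int64 bead type codes (H=0, P=1, +=2, -=3)
    e_tab   (4, 4) float64 bead-bead contact matrix
    aff     (4,) float64 surface affinity row (zeros in bulk)

Boundary handling: x and y always wrap; z wraps in bulk (``z_wall`` false)
and is hard-bounded in slab mode, where chain beads are restricted to
z in [1, Lz-1].

All randomness comes from numba's internal np.random state, seeded once
per driver call, so trajectories are reproducible for a given seed.
"""

import math

import numpy as np
from numba import njit

EMPTY = -1
SURF = -2


@njit(cache=True)
def _wrap1(v, L):
    if v >= L:
        return v - L
    if v < 0:
        return v + L
    return v


@njit(cache=True)
def _mimg(d, L):
    # minimum-image of a 1-D coordinate difference
    d = d % L
    if d > L // 2:
        d -= L
    elif d < -(L - 1) // 2:
        d += L
    return d


@njit(cache=True)
def _mi_dist1(ax, ay, az, bx, by, bz, Lx, Ly, Lz, z_wall):
    dx = abs(_mimg(bx - ax, Lx))
    dy = abs(_mimg(by - ay, Ly))
    dz = bz - az if z_wall else _mimg(bz - az, Lz)
    return dx + dy + abs(dz) == 1


@njit(cache=True)
def segment_energy(occ, seq, e_tab, aff, chain, idxs, pos, M, z_wall):
    """Contact energy of a bead segment against the rest of the system.

    The segment's beads must already be absent from ``occ``.  Pairs within
    the segment are counted once; same-chain pairs that are successive in
    sequence are excluded.
    """
    Lx, Ly, Lz = occ.shape
    e = 0.0
    n = len(idxs)
    for k in range(n):
        x, y, z = pos[k, 0], pos[k, 1], pos[k, 2]
        t = seq[idxs[k]]
        for d in range(6):
            nx, ny, nz = x, y, z
            if d == 0:
                nx = _wrap1(x + 1, Lx)
            elif d == 1:
                nx = _wrap1(x - 1, Lx)
            elif d == 2:
                ny = _wrap1(y + 1, Ly)
            elif d == 3:
                ny = _wrap1(y - 1, Ly)
            elif d == 4:
                nz = z + 1
                if z_wall:
                    if nz >= Lz:
                        continue
                else:
                    nz = _wrap1(nz, Lz)
            else:
                nz = z - 1
                if z_wall:
                    if nz < 0:
                        continue
                else:
                    nz = _wrap1(nz, Lz)
            code = occ[nx, ny, nz]
            if code == EMPTY:
                continue
            if code == SURF:
                e += aff[t]
            else:
                oc = code // M
                ob = code % M
                if oc == chain and abs(ob - idxs[k]) < 2:
                    continue
                e += e_tab[t, seq[ob]]
        # pairs inside the segment (same chain by construction)
        for l in range(k + 1, n):
            if abs(idxs[k] - idxs[l]) < 2:
                continue
            if _mi_dist1(
                x, y, z, pos[l, 0], pos[l, 1], pos[l, 2], Lx, Ly, Lz, z_wall
            ):
                e += e_tab[t, seq[idxs[l]]]
    return e


@njit(cache=True)
def total_energy3(chains, occ, seq, e_tab, aff, z_wall):
    """(E_intra, E_inter, E_surf) by a neighbour-shell scan over all beads."""
    Lx, Ly, Lz = occ.shape
    N, M = chains.shape[0], chains.shape[1]
    e_intra = 0.0
    e_inter = 0.0
    e_surf = 0.0
    for c in range(N):
        for i in range(M):
            x, y, z = chains[c, i, 0], chains[c, i, 1], chains[c, i, 2]
            t = seq[i]
            for d in range(6):
                nx, ny, nz = x, y, z
                if d == 0:
                    nx = _wrap1(x + 1, Lx)
                elif d == 1:
                    nx = _wrap1(x - 1, Lx)
                elif d == 2:
                    ny = _wrap1(y + 1, Ly)
                elif d == 3:
                    ny = _wrap1(y - 1, Ly)
                elif d == 4:
                    nz = z + 1
                    if z_wall:
                        if nz >= Lz:
                            continue
                    else:
                        nz = _wrap1(nz, Lz)
                else:
                    nz = z - 1
                    if z_wall:
                        if nz < 0:
                            continue
                    else:
                        nz = _wrap1(nz, Lz)
                code = occ[nx, ny, nz]
                if code == EMPTY:
                    continue
                if code == SURF:
                    e_surf += aff[t]
                else:
                    oc = code // M
                    ob = code % M
                    if oc == c:
                        if abs(ob - i) >= 2:
                            e_intra += 0.5 * e_tab[t, seq[ob]]
                    else:
                        e_inter += 0.5 * e_tab[t, seq[ob]]
    return e_intra, e_inter, e_surf


@njit(cache=True)
def inter_chain_contacts(chains, occ, z_wall):
    """Number of distance-1 bead pairs belonging to different chains."""
    Lx, Ly, Lz = occ.shape
    N, M = chains.shape[0], chains.shape[1]
    twice = 0
    for c in range(N):
        for i in range(M):
            x, y, z = chains[c, i, 0], chains[c, i, 1], chains[c, i, 2]
            for d in range(6):
                nx, ny, nz = x, y, z
                if d == 0:
                    nx = _wrap1(x + 1, Lx)
                elif d == 1:
                    nx = _wrap1(x - 1, Lx)
                elif d == 2:
                    ny = _wrap1(y + 1, Ly)
                elif d == 3:
                    ny = _wrap1(y - 1, Ly)
                elif d == 4:
                    nz = z + 1
                    if z_wall:
                        if nz >= Lz:
                            continue
                    else:
                        nz = _wrap1(nz, Lz)
                else:
                    nz = z - 1
                    if z_wall:
                        if nz < 0:
                            continue
                    else:
                        nz = _wrap1(nz, Lz)
                code = occ[nx, ny, nz]
                if code >= 0 and code // M != c:
                    twice += 1
    return twice // 2


@njit(cache=True)
def _rot90_axis(dx, dy, dz, axis, sign):
    # 90-degree rotation of an integer vector about a coordinate axis
    if axis == 0:
        return dx, -sign * dz, sign * dy
    if axis == 1:
        return sign * dz, dy, -sign * dx
    return -sign * dy, sign * dx, dz


@njit(cache=True)
def _cross(ax, ay, az, bx, by, bz):
    return ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx


@njit(cache=True)
def attempt_move(chains, occ, seq, e_tab, aff, T, p_global, z_wall, zmin):
    """One elementary Metropolis attempt; mutates chains/occ on acceptance.

    Returns (accepted, dE): dE is 0.0 whenever the attempt was rejected
    (by geometry or by the acceptance test).  Geometrically impossible
    picks are null moves that still consume the attempt, preserving
    detailed balance.
    """
    Lx, Ly, Lz = occ.shape
    N, M = chains.shape[0], chains.shape[1]
    if N == 0:
        return False, 0.0
    zmax = Lz - 1

    old = np.empty((M, 3), dtype=np.int64)
    new = np.empty((M, 3), dtype=np.int64)
    idxs = np.empty(M, dtype=np.int64)

    if np.random.random() < p_global:
        # ---- global move: whole-chain 90-degree rotation or unit translation
        c = np.random.randint(N)
        nmov = M
        for i in range(M):
            idxs[i] = i
            old[i, 0] = chains[c, i, 0]
            old[i, 1] = chains[c, i, 1]
            old[i, 2] = chains[c, i, 2]
        if np.random.random() < 0.5:
            pivot = np.random.randint(M)
            axis = np.random.randint(3)
            sign = 1 if np.random.random() < 0.5 else -1
            px, py, pz = old[pivot, 0], old[pivot, 1], old[pivot, 2]
            for i in range(M):
                dx = _mimg(old[i, 0] - px, Lx)
                dy = _mimg(old[i, 1] - py, Ly)
                dz = old[i, 2] - pz if z_wall else _mimg(old[i, 2] - pz, Lz)
                rx, ry, rz = _rot90_axis(dx, dy, dz, axis, sign)
                new[i, 0] = _wrap1((px + rx) % Lx, Lx)
                new[i, 1] = _wrap1((py + ry) % Ly, Ly)
                nz = pz + rz
                if z_wall:
                    if nz < zmin or nz > zmax:
                        return False, 0.0
                    new[i, 2] = nz
                else:
                    new[i, 2] = nz % Lz
        else:
            d = np.random.randint(6)
            sx = 1 if d == 0 else (-1 if d == 1 else 0)
            sy = 1 if d == 2 else (-1 if d == 3 else 0)
            sz = 1 if d == 4 else (-1 if d == 5 else 0)
            for i in range(M):
                new[i, 0] = _wrap1(old[i, 0] + sx, Lx)
                new[i, 1] = _wrap1(old[i, 1] + sy, Ly)
                nz = old[i, 2] + sz
                if z_wall:
                    if nz < zmin or nz > zmax:
                        return False, 0.0
                    new[i, 2] = nz
                else:
                    new[i, 2] = _wrap1(nz, Lz)
    else:
        # ---- local move keyed on a uniformly chosen bead
        c = np.random.randint(N)
        i = np.random.randint(M)
        if i == 0 or i == M - 1:
            # tail rotation: move the end bead to a neighbour of its anchor
            adj = 1 if i == 0 else M - 2
            d = np.random.randint(6)
            ax_, ay_, az_ = chains[c, adj, 0], chains[c, adj, 1], chains[c, adj, 2]
            nx, ny, nz = ax_, ay_, az_
            if d == 0:
                nx = _wrap1(ax_ + 1, Lx)
            elif d == 1:
                nx = _wrap1(ax_ - 1, Lx)
            elif d == 2:
                ny = _wrap1(ay_ + 1, Ly)
            elif d == 3:
                ny = _wrap1(ay_ - 1, Ly)
            elif d == 4:
                nz = az_ + 1
            else:
                nz = az_ - 1
            if z_wall:
                if nz < zmin or nz > zmax:
                    return False, 0.0
            else:
                nz = _wrap1(nz, Lz)
            if nx == chains[c, i, 0] and ny == chains[c, i, 1] and nz == chains[c, i, 2]:
                return False, 0.0  # null pick: proposed site = current site
            if occ[nx, ny, nz] != EMPTY:
                return False, 0.0
            nmov = 1
            idxs[0] = i
            old[0, 0] = chains[c, i, 0]
            old[0, 1] = chains[c, i, 1]
            old[0, 2] = chains[c, i, 2]
            new[0, 0], new[0, 1], new[0, 2] = nx, ny, nz
        elif np.random.random() < 0.5:
            # corner flip: bead i to the fourth corner of its plaquette
            ax_, ay_, az_ = chains[c, i - 1, 0], chains[c, i - 1, 1], chains[c, i - 1, 2]
            bx, by, bz = chains[c, i + 1, 0], chains[c, i + 1, 1], chains[c, i + 1, 2]
            dx = abs(_mimg(bx - ax_, Lx))
            dy = abs(_mimg(by - ay_, Ly))
            dz = abs(bz - az_) if z_wall else abs(_mimg(bz - az_, Lz))
            if dx + dy + dz != 2 or dx == 2 or dy == 2 or dz == 2:
                return False, 0.0  # collinear neighbours: no corner here
            x, y, z = chains[c, i, 0], chains[c, i, 1], chains[c, i, 2]
            nx = _wrap1((x + _mimg(ax_ - x, Lx) + _mimg(bx - x, Lx)) % Lx, Lx)
            ny = _wrap1((y + _mimg(ay_ - y, Ly) + _mimg(by - y, Ly)) % Ly, Ly)
            if z_wall:
                nz = z + (az_ - z) + (bz - z)
                if nz < zmin or nz > zmax:
                    return False, 0.0
            else:
                nz = (z + _mimg(az_ - z, Lz) + _mimg(bz - z, Lz)) % Lz
            if occ[nx, ny, nz] != EMPTY:
                return False, 0.0
            nmov = 1
            idxs[0] = i
            old[0, 0], old[0, 1], old[0, 2] = x, y, z
            new[0, 0], new[0, 1], new[0, 2] = nx, ny, nz
        else:
            # crankshaft: rotate the U-segment (i, i+1) about its anchors
            if i > M - 3:
                return False, 0.0
            ax_, ay_, az_ = chains[c, i - 1, 0], chains[c, i - 1, 1], chains[c, i - 1, 2]
            bx, by, bz = chains[c, i + 2, 0], chains[c, i + 2, 1], chains[c, i + 2, 2]
            ex = _mimg(bx - ax_, Lx)
            ey = _mimg(by - ay_, Ly)
            ez = bz - az_ if z_wall else _mimg(bz - az_, Lz)
            if abs(ex) + abs(ey) + abs(ez) != 1:
                return False, 0.0  # anchors not adjacent: no U-segment
            ux = _mimg(chains[c, i, 0] - ax_, Lx)
            uy = _mimg(chains[c, i, 1] - ay_, Ly)
            uz = chains[c, i, 2] - az_ if z_wall else _mimg(chains[c, i, 2] - az_, Lz)
            k = np.random.randint(3)  # 90, 180 or 270 degrees about the axis
            if k == 0:
                vx, vy, vz = _cross(ex, ey, ez, ux, uy, uz)
            elif k == 1:
                vx, vy, vz = -ux, -uy, -uz
            else:
                cx, cy, cz = _cross(ex, ey, ez, ux, uy, uz)
                vx, vy, vz = -cx, -cy, -cz
            n1z = az_ + vz
            n2z = bz + vz
            if z_wall:
                if n1z < zmin or n1z > zmax or n2z < zmin or n2z > zmax:
                    return False, 0.0
            else:
                n1z = _wrap1(n1z % Lz, Lz)
                n2z = _wrap1(n2z % Lz, Lz)
            n1x = (ax_ + vx) % Lx
            n1y = (ay_ + vy) % Ly
            n2x = (bx + vx) % Lx
            n2y = (by + vy) % Ly
            if occ[n1x, n1y, n1z] != EMPTY or occ[n2x, n2y, n2z] != EMPTY:
                return False, 0.0
            nmov = 2
            idxs[0] = i
            idxs[1] = i + 1
            for kk in range(2):
                old[kk, 0] = chains[c, i + kk, 0]
                old[kk, 1] = chains[c, i + kk, 1]
                old[kk, 2] = chains[c, i + kk, 2]
            new[0, 0], new[0, 1], new[0, 2] = n1x, n1y, n1z
            new[1, 0], new[1, 1], new[1, 2] = n2x, n2y, n2z

    # ---- shared clash check (multi-bead moves) + energy + acceptance
    for k in range(nmov):
        occ[old[k, 0], old[k, 1], old[k, 2]] = EMPTY
    clash = False
    for k in range(nmov):
        if occ[new[k, 0], new[k, 1], new[k, 2]] != EMPTY:
            clash = True
            break
        # multi-bead: also forbid two moved beads landing on one site
        for l in range(k):
            if (
                new[k, 0] == new[l, 0]
                and new[k, 1] == new[l, 1]
                and new[k, 2] == new[l, 2]
            ):
                clash = True
                break
        if clash:
            break
    if clash:
        for k in range(nmov):
            occ[old[k, 0], old[k, 1], old[k, 2]] = chains.shape[1] * c + idxs[k]
        return False, 0.0

    e_before = segment_energy(occ, seq, e_tab, aff, c, idxs[:nmov], old[:nmov], M, z_wall)
    e_after = segment_energy(occ, seq, e_tab, aff, c, idxs[:nmov], new[:nmov], M, z_wall)
    dE = e_after - e_before
    accept = dE <= 0.0 or np.random.random() < math.exp(-dE / T)
    if accept:
        for k in range(nmov):
            ii = idxs[k]
            chains[c, ii, 0] = new[k, 0]
            chains[c, ii, 1] = new[k, 1]
            chains[c, ii, 2] = new[k, 2]
            occ[new[k, 0], new[k, 1], new[k, 2]] = M * c + ii
        return True, dE
    for k in range(nmov):
        occ[old[k, 0], old[k, 1], old[k, 2]] = M * c + idxs[k]
    return False, 0.0


@njit(cache=True)
def run_dynamics(
    chains,
    occ,
    seq,
    e_tab,
    aff,
    z_wall,
    zmin,
    T,
    p_global,
    n_steps,
    attempts_per_step,
    measure_every,
    seed,
    q_fib,
    threshold,
    stop_on_passage,
):
    """Metropolis trajectory with periodic measurements and first passage.

    One MCS = ``attempts_per_step`` elementary attempts (1 by default, N*M
    in sweep mode).  Measurements (energies, inter-chain contact count) are
    recorded at step 0 and every ``measure_every`` MCS; the first measured
    MCS with contacts >= threshold * q_fib is the first-passage time.
    Returns (n_meas, mcs, e_intra, e_inter, e_surf, contacts,
    first_passage, n_accepted).
    """
    np.random.seed(seed)
    n_max = n_steps // measure_every + 2
    mcs_out = np.zeros(n_max, dtype=np.int64)
    ei_out = np.zeros(n_max)
    ee_out = np.zeros(n_max)
    es_out = np.zeros(n_max)
    q_out = np.zeros(n_max, dtype=np.int64)

    ei, ee, es = total_energy3(chains, occ, seq, e_tab, aff, z_wall)
    q = inter_chain_contacts(chains, occ, z_wall)
    mcs_out[0], ei_out[0], ee_out[0], es_out[0], q_out[0] = 0, ei, ee, es, q
    n_meas = 1
    first_passage = -1
    if q_fib > 0 and q >= threshold * q_fib:
        first_passage = 0
        if stop_on_passage:
            return n_meas, mcs_out, ei_out, ee_out, es_out, q_out, 0, 0

    n_accepted = 0
    for step in range(1, n_steps + 1):
        for _ in range(attempts_per_step):
            acc, _dE = attempt_move(
                chains, occ, seq, e_tab, aff, T, p_global, z_wall, zmin
            )
            if acc:
                n_accepted += 1
        if step % measure_every == 0 or step == n_steps:
            ei, ee, es = total_energy3(chains, occ, seq, e_tab, aff, z_wall)
            q = inter_chain_contacts(chains, occ, z_wall)
            mcs_out[n_meas] = step
            ei_out[n_meas] = ei
            ee_out[n_meas] = ee
            es_out[n_meas] = es
            q_out[n_meas] = q
            n_meas += 1
            if first_passage < 0 and q_fib > 0 and q >= threshold * q_fib:
                first_passage = step
                if stop_on_passage:
                    break
    return n_meas, mcs_out, ei_out, ee_out, es_out, q_out, first_passage, n_accepted


@njit(cache=True)
def run_anneal(
    chains,
    occ,
    seq,
    e_tab,
    aff,
    z_wall,
    zmin,
    temps,
    steps_per_temp,
    p_global,
    seed,
):
    """Simulated annealing pass; returns the lowest-energy state visited.

    The running energy is maintained incrementally from accepted dE values
    (exact for contact energies on the 0.05 eps_H grid) and re-anchored
    from a full recomputation at every temperature change.
    """
    np.random.seed(seed)
    ei, ee, es = total_energy3(chains, occ, seq, e_tab, aff, z_wall)
    current = ei + ee + es
    best = current
    best_chains = chains.copy()
    for t_idx in range(len(temps)):
        T = temps[t_idx]
        for _ in range(steps_per_temp):
            acc, dE = attempt_move(
                chains, occ, seq, e_tab, aff, T, p_global, z_wall, zmin
            )
            if acc:
                current += dE
                if current < best - 1e-9:
                    best = current
                    best_chains[:] = chains
        ei, ee, es = total_energy3(chains, occ, seq, e_tab, aff, z_wall)
        current = ei + ee + es
    return best, best_chains


@njit(cache=True)
def run_energy_histogram(
    chains,
    occ,
    seq,
    e_tab,
    aff,
    z_wall,
    zmin,
    T,
    p_global,
    n_steps,
    burn_in,
    thin,
    seed,
    e_min,
    n_bins,
):
    """Occupancy tally of total-energy levels on the 0.05 eps_H grid.

    After ``burn_in`` attempts, the running energy is binned every ``thin``
    attempts (thinning de-correlates successive samples for chi-square
    comparison against exact Boltzmann weights).
    """
    np.random.seed(seed)
    ei, ee, es = total_energy3(chains, occ, seq, e_tab, aff, z_wall)
    current = ei + ee + es
    counts = np.zeros(n_bins, dtype=np.int64)
    for step in range(1, n_steps + 1):
        acc, dE = attempt_move(chains, occ, seq, e_tab, aff, T, p_global, z_wall, zmin)
        if acc:
            current += dE
        if step > burn_in and step % thin == 0:
            b = int(round((current - e_min) / 0.05))
            if 0 <= b < n_bins:
                counts[b] += 1
    return counts
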