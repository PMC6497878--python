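"""Numba-compiled Monte-Carlo and counting kernels.

Everything here operates on plain NumPy arrays so the jitted code stays
simple; the public modules wrap these in typed containers. All kernels are
single-threaded and seed numba's internal RNG explicitly, which makes every
simulation bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Nearest-neighbour steps on the simple cubic lattice.
_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


# ---------------------------------------------------------------------------
# Lattice growth (conformation-dependent polymerization)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _occupied_neighbors(grid, x, y, z, hx, hy, hz):
    """Count occupied nearest neighbours of a candidate site, excluding the
    current chain head (every candidate touches the head, so counting it
    would wash out the crowding bias).  Sites outside the grid count as
    occupied: walls behave like filled space."""
    lx, ly, lz = grid.shape
    n = 0
    for s in range(6):
        nx = x + _STEPS[s, 0]
        ny = y + _STEPS[s, 1]
        nz = z + _STEPS[s, 2]
        if nx == hx and ny == hy and nz == hz:
            continue
        if nx < 0 or ny < 0 or nz < 0 or nx >= lx or ny >= ly or nz >= lz:
            n += 1
        elif grid[nx, ny, nz]:
            n += 1
    return n


@njit(cache=True)
def grow_chain(n_mono, bias, eps, side, rad2, random_start, seed,
               backtrack_limit, max_restarts, max_trap_events):
    """Grow a self-avoiding walk on the cubic lattice with the
    conformation-dependent polymerization rule.

    Each unoccupied neighbour of the head is weighted 1 + bias * n where n is
    its number of occupied neighbours; occupied neighbours carry weight eps
    and, when drawn, are rejected and the step resampled.  ``rad2`` > 0
    confines growth to a sphere of that squared radius about the grid centre;
    otherwise the grid boundary is the only wall.  On trapping the walk
    backtracks up to ``backtrack_limit`` monomers; if trapping persists the
    walk restarts from scratch (at most ``max_restarts`` times).

    Returns (coords, ok) with coords in grid-frame integer coordinates.
    """
    np.random.seed(seed)
    grid = np.zeros((side, side, side), dtype=np.uint8)
    coords = np.zeros((n_mono, 3), dtype=np.int64)
    cx = side // 2

    weights = np.zeros(6)
    occ = np.zeros(6, dtype=np.uint8)

    for _restart in range(max_restarts + 1):
        grid[:, :, :] = 0
        if random_start:
            while True:
                x = np.random.randint(0, side)
                y = np.random.randint(0, side)
                z = np.random.randint(0, side)
                if rad2 <= 0.0 or (
                    (x - cx) ** 2 + (y - cx) ** 2 + (z - cx) ** 2
                ) <= rad2:
                    break
        else:
            x = cx
            y = cx
            z = cx
        grid[x, y, z] = 1
        coords[0, 0] = x
        coords[0, 1] = y
        coords[0, 2] = z
        placed = 1
        trap_events = 0
        failed = False

        while placed < n_mono:
            hx = coords[placed - 1, 0]
            hy = coords[placed - 1, 1]
            hz = coords[placed - 1, 2]
            total = 0.0
            free_total = 0.0
            for s in range(6):
                nx = hx + _STEPS[s, 0]
                ny = hy + _STEPS[s, 1]
                nz = hz + _STEPS[s, 2]
                w = 0.0
                o = np.uint8(0)
                if (
                    nx < 0 or ny < 0 or nz < 0
                    or nx >= side or ny >= side or nz >= side
                ):
                    w = 0.0  # hard wall: not even a rejected attempt
                elif rad2 > 0.0 and (
                    (nx - cx) ** 2 + (ny - cx) ** 2 + (nz - cx) ** 2
                ) > rad2:
                    w = 0.0
                elif grid[nx, ny, nz]:
                    w = eps
                    o = np.uint8(1)
                else:
                    w = 1.0 + bias * _occupied_neighbors(
                        grid, nx, ny, nz, hx, hy, hz)
                    free_total += w
                weights[s] = w
                occ[s] = o
                total += w

            if free_total <= 0.0:
                # trapped: backtrack, then restart if that keeps failing
                trap_events += 1
                if trap_events > max_trap_events:
                    failed = True
                    break
                freed = 0
                while freed < backtrack_limit and placed > 1:
                    placed -= 1
                    grid[coords[placed, 0], coords[placed, 1],
                         coords[placed, 2]] = 0
                    freed += 1
                if placed <= 1:
                    failed = True
                    break
                continue

            # sample a step; occupied draws are rejected and resampled
            chosen = -1
            for _try in range(10000):
                r = np.random.random() * total
                acc = 0.0
                pick = 5
                for s in range(6):
                    acc += weights[s]
                    if r < acc:
                        pick = s
                        break
                if occ[pick]:
                    continue  # rejected step
                if weights[pick] <= 0.0:
                    continue
                chosen = pick
                break
            if chosen < 0:
                failed = True
                break
            coords[placed, 0] = hx + _STEPS[chosen, 0]
            coords[placed, 1] = hy + _STEPS[chosen, 1]
            coords[placed, 2] = hz + _STEPS[chosen, 2]
            grid[coords[placed, 0], coords[placed, 1], coords[placed, 2]] = 1
            placed += 1

        if not failed:
            return coords, True
    return coords, False


# ---------------------------------------------------------------------------
# Equilibrium globule: slithering-snake + kink-flip Monte Carlo in a sphere
# ---------------------------------------------------------------------------

@njit(cache=True)
def equilibrate_snake(coords, side, rad2, n_attempts, p_reptation, seed):
    """Equilibrate a confined lattice self-avoiding walk in place.

    Moves: slithering-snake reptation (probability ``p_reptation``),
    otherwise a kink (corner) flip at an interior monomer or a one-bond end
    rotation.  All moves are symmetric proposals, so the stationary
    distribution is uniform over confined self-avoiding walks.  The chain is
    held in a ring buffer so reptation is O(1).

    Returns (coords_out, n_accepted).
    """
    np.random.seed(seed)
    n = coords.shape[0]
    cx = side // 2
    grid = np.zeros((side, side, side), dtype=np.uint8)
    bx = np.empty(n, dtype=np.int64)
    by = np.empty(n, dtype=np.int64)
    bz = np.empty(n, dtype=np.int64)
    for k in range(n):
        bx[k] = coords[k, 0]
        by[k] = coords[k, 1]
        bz[k] = coords[k, 2]
        grid[bx[k], by[k], bz[k]] = 1
    start = 0
    accepted = 0

    for _a in range(n_attempts):
        if np.random.random() < p_reptation:
            head_end = np.random.random() < 0.5
            d = np.random.randint(0, 6)
            if head_end:
                tip = (start + n - 1) % n
                opp = start
            else:
                tip = start
                opp = (start + n - 1) % n
            nxp = bx[tip] + _STEPS[d, 0]
            nyp = by[tip] + _STEPS[d, 1]
            nzp = bz[tip] + _STEPS[d, 2]
            if (
                nxp < 0 or nyp < 0 or nzp < 0
                or nxp >= side or nyp >= side or nzp >= side
            ):
                continue
            if rad2 > 0.0 and (
                (nxp - cx) ** 2 + (nyp - cx) ** 2 + (nzp - cx) ** 2
            ) > rad2:
                continue
            # free the opposite end first (the snake may bite its own tail)
            grid[bx[opp], by[opp], bz[opp]] = 0
            if grid[nxp, nyp, nzp]:
                grid[bx[opp], by[opp], bz[opp]] = 1
                continue
            grid[nxp, nyp, nzp] = 1
            bx[opp] = nxp
            by[opp] = nyp
            bz[opp] = nzp
            if head_end:
                start = (start + 1) % n
            else:
                start = (start + n - 1) % n
            accepted += 1
        else:
            k = np.random.randint(0, n)
            bk = (start + k) % n
            if k == 0 or k == n - 1:
                # end rotation about the adjacent monomer
                adj = (start + 1) % n if k == 0 else (start + n - 2) % n
                d = np.random.randint(0, 6)
                nxp = bx[adj] + _STEPS[d, 0]
                nyp = by[adj] + _STEPS[d, 1]
                nzp = bz[adj] + _STEPS[d, 2]
            else:
                prv = (start + k - 1) % n
                nxt = (start + k + 1) % n
                dx1 = bx[prv] - bx[bk]
                dy1 = by[prv] - by[bk]
                dz1 = bz[prv] - bz[bk]
                dx2 = bx[nxt] - bx[bk]
                dy2 = by[nxt] - by[bk]
                dz2 = bz[nxt] - bz[bk]
                if dx1 * dx2 + dy1 * dy2 + dz1 * dz2 != 0:
                    continue  # collinear or folded: no corner to flip
                nxp = bx[prv] + bx[nxt] - bx[bk]
                nyp = by[prv] + by[nxt] - by[bk]
                nzp = bz[prv] + bz[nxt] - bz[bk]
            if (
                nxp < 0 or nyp < 0 or nzp < 0
                or nxp >= side or nyp >= side or nzp >= side
            ):
                continue
            if rad2 > 0.0 and (
                (nxp - cx) ** 2 + (nyp - cx) ** 2 + (nzp - cx) ** 2
            ) > rad2:
                continue
            if grid[nxp, nyp, nzp]:
                continue
            grid[bx[bk], by[bk], bz[bk]] = 0
            grid[nxp, nyp, nzp] = 1
            bx[bk] = nxp
            by[bk] = nyp
            bz[bk] = nzp
            accepted += 1

    out = np.empty((n, 3), dtype=np.int64)
    for k in range(n):
        bk = (start + k) % n
        out[k, 0] = bx[bk]
        out[k, 1] = by[bk]
        out[k, 2] = bz[bk]
    return out, accepted


# ---------------------------------------------------------------------------
# Off-lattice randomization: crankshaft moves at fixed bond length
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cell_index(x, y, z, ox, oy, oz, nxc, nyc, nzc):
    ix = int(np.floor(x - ox))
    iy = int(np.floor(y - oy))
    iz = int(np.floor(z - oz))
    if ix < 0 or iy < 0 or iz < 0 or ix >= nxc or iy >= nyc or iz >= nzc:
        return -1
    return (ix * nyc + iy) * nzc + iz


@njit(cache=True)
def anneal_chain(coords, n_snapshots, n_moves, max_angle_scale, hard_core,
                 seed):
    """Randomize a conformation off-lattice with bond-preserving moves.

    Interior monomers rotate about the axis through their two bonded
    neighbours (crankshaft); end monomers rotate about their single
    neighbour around a random axis.  Both moves preserve bond lengths
    exactly.  A move is rejected if any non-bonded pair would come closer
    than ``hard_core``.  After every ``n_moves`` accepted-or-rejected
    attempts a snapshot of the coordinates is recorded.

    ``max_angle_scale`` sets the maximum displacement (lattice units) of the
    moved monomer; the rotation angle is drawn uniformly from
    [-a, a] with a = min(pi, max_angle_scale / lever-arm).

    Returns an array of shape (n_snapshots, n, 3).
    """
    np.random.seed(seed)
    n = coords.shape[0]
    pos = coords.copy()
    hc2 = hard_core * hard_core

    # cell list with unit cells over a padded bounding box
    pad = 6.0
    ox = pos[:, 0].min() - pad
    oy = pos[:, 1].min() - pad
    oz = pos[:, 2].min() - pad
    nxc = int(np.ceil(pos[:, 0].max() + pad - ox)) + 1
    nyc = int(np.ceil(pos[:, 1].max() + pad - oy)) + 1
    nzc = int(np.ceil(pos[:, 2].max() + pad - oz)) + 1
    ncell = nxc * nyc * nzc
    cap = 12
    cells = np.full((ncell, cap), -1, dtype=np.int64)
    ccount = np.zeros(ncell, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    slot_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], ox, oy, oz,
                        nxc, nyc, nzc)
        cells[c, ccount[c]] = i
        cell_of[i] = c
        slot_of[i] = ccount[c]
        ccount[c] += 1

    snaps = np.empty((n_snapshots, n, 3))

    for snap in range(n_snapshots):
        for _mv in range(n_moves):
            i = np.random.randint(0, n)
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]
            if i == 0 or i == n - 1:
                j = 1 if i == 0 else n - 2
                axx = np.random.normal()
                axy = np.random.normal()
                axz = np.random.normal()
                anorm = np.sqrt(axx * axx + axy * axy + axz * axz)
                if anorm < 1e-12:
                    continue
                axx /= anorm
                axy /= anorm
                axz /= anorm
                vx = px - pos[j, 0]
                vy = py - pos[j, 1]
                vz = pz - pos[j, 2]
                lever = np.sqrt(vx * vx + vy * vy + vz * vz)
                cxx = pos[j, 0]
                cyy = pos[j, 1]
                czz = pos[j, 2]
            else:
                a = i - 1
                b = i + 1
                axx = pos[b, 0] - pos[a, 0]
                axy = pos[b, 1] - pos[a, 1]
                axz = pos[b, 2] - pos[a, 2]
                anorm = np.sqrt(axx * axx + axy * axy + axz * axz)
                if anorm < 1e-9:
                    continue
                axx /= anorm
                axy /= anorm
                axz /= anorm
                # project i onto the axis through a
                wx = px - pos[a, 0]
                wy = py - pos[a, 1]
                wz = pz - pos[a, 2]
                t = wx * axx + wy * axy + wz * axz
                cxx = pos[a, 0] + t * axx
                cyy = pos[a, 1] + t * axy
                czz = pos[a, 2] + t * axz
                vx = px - cxx
                vy = py - cyy
                vz = pz - czz
                lever = np.sqrt(vx * vx + vy * vy + vz * vz)
                if lever < 1e-9:
                    continue  # on the axis: rotation is a no-op
            amax = max_angle_scale / max(lever, 1e-9)
            if amax > np.pi:
                amax = np.pi
            ang = (2.0 * np.random.random() - 1.0) * amax
            ca = np.cos(ang)
            sa = np.sin(ang)
            # Rodrigues rotation of v about the unit axis
            dotav = axx * vx + axy * vy + axz * vz
            rx = vx * ca + (axy * vz - axz * vy) * sa \
                + axx * dotav * (1.0 - ca)
            ry = vy * ca + (axz * vx - axx * vz) * sa \
                + axy * dotav * (1.0 - ca)
            rz = vz * ca + (axx * vy - axy * vx) * sa \
                + axz * dotav * (1.0 - ca)
            qx = cxx + rx
            qy = cyy + ry
            qz = czz + rz
            cnew = _cell_index(qx, qy, qz, ox, oy, oz, nxc, nyc, nzc)
            if cnew < 0:
                continue
            # hard-core check against all monomers in the 27 surrounding cells
            ix = cnew // (nyc * nzc)
            iy = (cnew // nzc) % nyc
            iz = cnew % nzc
            ok = True
            for ddx in range(-1, 2):
                for ddy in range(-1, 2):
                    for ddz in range(-1, 2):
                        jx = ix + ddx
                        jy = iy + ddy
                        jz = iz + ddz
                        if (
                            jx < 0 or jy < 0 or jz < 0
                            or jx >= nxc or jy >= nyc or jz >= nzc
                        ):
                            continue
                        cc = (jx * nyc + jy) * nzc + jz
                        for s in range(ccount[cc]):
                            j2 = cells[cc, s]
                            if j2 == i:
                                continue
                            ddx2 = pos[j2, 0] - qx
                            ddy2 = pos[j2, 1] - qy
                            ddz2 = pos[j2, 2] - qz
                            if (
                                ddx2 * ddx2 + ddy2 * ddy2 + ddz2 * ddz2
                                < hc2
                            ):
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            # accept: update cell list and position
            cold = cell_of[i]
            if cnew != cold:
                if ccount[cnew] >= cap:
                    continue  # cell full (essentially never at this density)
                s_old = slot_of[i]
                last = ccount[cold] - 1
                mover = cells[cold, last]
                cells[cold, s_old] = mover
                slot_of[mover] = s_old
                cells[cold, last] = -1
                ccount[cold] = last
                cells[cnew, ccount[cnew]] = i
                slot_of[i] = ccount[cnew]
                cell_of[i] = cnew
                ccount[cnew] += 1
            pos[i, 0] = qx
            pos[i, 1] = qy
            pos[i, 2] = qz
        snaps[snap] = pos
    return snaps


# ---------------------------------------------------------------------------
# Contact counting
# ---------------------------------------------------------------------------

@njit(cache=True)
def count_contacts(snaps, threshold, out):
    """Accumulate snapshot contacts into ``out`` (int32, n x n).

    A pair (i, j), i != j, scores one count per snapshot in which their
    Euclidean distance is strictly below ``threshold``.
    """
    n_snap = snaps.shape[0]
    n = snaps.shape[1]
    t2 = threshold * threshold
    for s in range(n_snap):
        pos = snaps[s]
        ox = pos[:, 0].min()
        oy = pos[:, 1].min()
        oz = pos[:, 2].min()
        nxc = int(np.floor((pos[:, 0].max() - ox) / threshold)) + 1
        nyc = int(np.floor((pos[:, 1].max() - oy) / threshold)) + 1
        nzc = int(np.floor((pos[:, 2].max() - oz) / threshold)) + 1
        ncell = nxc * nyc * nzc
        ccount = np.zeros(ncell, dtype=np.int64)
        cell_of = np.empty(n, dtype=np.int64)
        for i in range(n):
            ix = int(np.floor((pos[i, 0] - ox) / threshold))
            iy = int(np.floor((pos[i, 1] - oy) / threshold))
            iz = int(np.floor((pos[i, 2] - oz) / threshold))
            c = (ix * nyc + iy) * nzc + iz
            cell_of[i] = c
            ccount[c] += 1
        cstart = np.zeros(ncell + 1, dtype=np.int64)
        for c in range(ncell):
            cstart[c + 1] = cstart[c] + ccount[c]
        fill = cstart[:-1].copy()
        members = np.empty(n, dtype=np.int64)
        for i in range(n):
            c = cell_of[i]
            members[fill[c]] = i
            fill[c] += 1
        for i in range(n):
            ci = cell_of[i]
            ix = ci // (nyc * nzc)
            iy = (ci // nzc) % nyc
            iz = ci % nzc
            for ddx in range(-1, 2):
                for ddy in range(-1, 2):
                    for ddz in range(-1, 2):
                        jx = ix + ddx
                        jy = iy + ddy
                        jz = iz + ddz
                        if (
                            jx < 0 or jy < 0 or jz < 0
                            or jx >= nxc or jy >= nyc or jz >= nzc
                        ):
                            continue
                        cc = (jx * nyc + jy) * nzc + jz
                        for s2 in range(cstart[cc], cstart[cc + 1]):
                            j = members[s2]
                            if j <= i:
                                continue
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            dz = pos[j, 2] - pos[i, 2]
                            if dx * dx + dy * dy + dz * dz < t2:
                                out[i, j] += 1
                                out[j, i] += 1
    return out


# ---------------------------------------------------------------------------
# Louvain local moving on a dense modularity-gain matrix
# ---------------------------------------------------------------------------

@njit(cache=True)
def louvain_local_move(B, labels, order, tol):
    """One full local-moving phase of Louvain on a dense gain matrix.

    B[i, j] holds A_ij - gamma * P_ij at the current aggregation level
    (diagonal entries are self-weights and never change with moves, so they
    are ignored).  Nodes are swept in ``order`` repeatedly until a full pass
    improves the objective by less than ``tol``; ties in the best target
    community are broken toward the lowest community id.

    Returns (total_gain, n_moves); ``labels`` is modified in place.
    """
    k = B.shape[0]
    w = np.zeros(k)
    total_gain = 0.0
    total_moves = 0
    while True:
        pass_gain = 0.0
        for oi in range(k):
            i = order[oi]
            for c in range(k):
                w[c] = 0.0
            for j in range(k):
                if j != i:
                    w[labels[j]] += B[i, j]
            cur = labels[i]
            best = cur
            best_w = w[cur]
            for c in range(k):
                if w[c] > best_w + 1e-12:
                    best_w = w[c]
                    best = c
            if best != cur:
                pass_gain += best_w - w[cur]
                labels[i] = best
                total_moves += 1
        total_gain += pass_gain
        if pass_gain < tol:
            break
    return total_gain, total_moves
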