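"""Numba kernels for surface queries, spatial hashing and network stepping.

Everything here operates on flat numpy arrays owned by the Python-level
classes in :mod:`cmtsim.geometry` and :mod:`cmtsim.engine`.  The kernels are
deliberately free of Python objects so that a full simulation step runs as a
single compiled loop.  All randomness inside the stepping kernel comes from
numba's internal numpy-compatible RNG, seeded once per run via
:func:`seed_rng`; the draw order is fixed by the serial loop structure, which
makes trajectories bit-reproducible for a given seed and configuration.
"""

import math

import numpy as np
from numba import njit

# counter slots shared between the kernel and the Python wrapper
C_STEP = 0       # global step counter
C_NMT = 1        # microtubule slots used (creation ids are 0..C_NMT-1)
C_FREETOP = 2    # segment free-list height
C_NKEYS = 3      # occupied keys in the spatial-hash table
C_NSEG = 4       # live segments
C_FALLBACK = 5   # weak-anchoring retry budget exhaustions
C_ADDED = 6      # total segments appended
C_REMOVED = 7    # total segments removed
C_NUC = 8        # total nucleation events
C_NMT_LIVE = 9   # live microtubules
C_CAT_MT = 10    # catastrophes induced by filament encounters
C_CAT_MEM = 11   # catastrophes induced by the membrane
C_ZIP = 12       # zipper classifications
N_COUNTERS = 13

# float parameter slots
P_ELL = 0
P_RD = 1
P_BD = 2
P_NS = 3
P_NP = 4
P_COSA = 5
P_SINA = 6
P_BUCKET = 7
P_RINT = 8     # microtubule interaction radius (25 nm)
P_DMEM = 9     # membrane interaction distance (10 nm)
N_PARAMS = 10

# int parameter slots
I_NTRIALS = 0   # nucleation trials per step (surface area in units of ell^2)
I_ANCHOR = 1    # 0 weak, 1 strong
I_CUE = 2       # 0 none, 1 circumferential
I_NUCMODE = 3   # 0 isotropic, 1 tangential
N_IPARAMS = 4

STATUS_OK = 0
STATUS_GROW_SEGS = 1
STATUS_GROW_MTS = 2
STATUS_GROW_HASH = 3

_ON_SURFACE_TOL = 1e-9


# ---------------------------------------------------------------------------
# closest point on a triangle (Ericson, "Real-Time Collision Detection")
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _closest_on_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    abx = bx - ax; aby = by - ay; abz = bz - az
    acx = cx - ax; acy = cy - ay; acz = cz - az
    apx = px - ax; apy = py - ay; apz = pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az, 1.0, 0.0, 0.0
    bpx = px - bx; bpy = py - by; bpz = pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz, 0.0, 1.0, 0.0
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return ax + v * abx, ay + v * aby, az + v * abz, 1.0 - v, v, 0.0
    cpx = px - cx; cpy = py - cy; cpz = pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz, 0.0, 0.0, 1.0
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return ax + w * acx, ay + w * acy, az + w * acz, 1.0 - w, 0.0, w
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (bx + w * (cx - bx), by + w * (cy - by), bz + w * (cz - bz),
                0.0, 1.0 - w, w)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return (ax + abx * v + acx * w, ay + aby * v + acy * w,
            az + abz * v + acz * w, 1.0 - v - w, v, w)


# ---------------------------------------------------------------------------
# nearest-surface probe over a uniform triangle grid
# ---------------------------------------------------------------------------
# TV: (F, 9) triangle vertices, VN: (F, 9) per-corner vertex normals.
# The grid bins every triangle into all cells overlapped by its AABB, so a
# ring-by-ring search that stops once (ring-1)*cell exceeds the best distance
# is exact: any closer triangle would have been binned in a visited cell.

@njit(cache=True)
def _probe_one(px, py, pz, TV, VN, glo, inv_cell, cell, gnx, gny, gnz,
               cstart, ctris):
    cxi = int(math.floor((px - glo[0]) * inv_cell))
    cyi = int(math.floor((py - glo[1]) * inv_cell))
    czi = int(math.floor((pz - glo[2]) * inv_cell))
    if cxi < 0: cxi = 0
    if cxi > gnx - 1: cxi = gnx - 1
    if cyi < 0: cyi = 0
    if cyi > gny - 1: cyi = gny - 1
    if czi < 0: czi = 0
    if czi > gnz - 1: czi = gnz - 1

    best_d2 = 1.0e300
    bf = -1
    bqx = 0.0; bqy = 0.0; bqz = 0.0
    bu = 0.0; bv = 0.0; bw = 0.0
    max_ring = gnx + gny + gnz
    for k in range(max_ring + 1):
        if bf >= 0 and (k - 1) * cell > math.sqrt(best_d2):
            break
        x0 = cxi - k
        if x0 < 0: x0 = 0
        x1 = cxi + k
        if x1 > gnx - 1: x1 = gnx - 1
        for ix in range(x0, x1 + 1):
            dxr = ix - cxi
            if dxr < 0: dxr = -dxr
            y0 = cyi - k
            if y0 < 0: y0 = 0
            y1 = cyi + k
            if y1 > gny - 1: y1 = gny - 1
            for iy in range(y0, y1 + 1):
                dyr = iy - cyi
                if dyr < 0: dyr = -dyr
                on_shell_xy = dxr == k or dyr == k
                z0 = czi - k
                if z0 < 0: z0 = 0
                z1 = czi + k
                if z1 > gnz - 1: z1 = gnz - 1
                for iz in range(z0, z1 + 1):
                    if not on_shell_xy:
                        dzr = iz - czi
                        if dzr < 0: dzr = -dzr
                        if dzr != k:
                            continue
                    c = (ix * gny + iy) * gnz + iz
                    for ti in range(cstart[c], cstart[c + 1]):
                        t = ctris[ti]
                        qx, qy, qz, u, v, w = _closest_on_tri(
                            px, py, pz,
                            TV[t, 0], TV[t, 1], TV[t, 2],
                            TV[t, 3], TV[t, 4], TV[t, 5],
                            TV[t, 6], TV[t, 7], TV[t, 8])
                        ddx = px - qx; ddy = py - qy; ddz = pz - qz
                        d2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if d2 < best_d2:
                            best_d2 = d2
                            bf = t
                            bqx = qx; bqy = qy; bqz = qz
                            bu = u; bv = v; bw = w
    nx = bu * VN[bf, 0] + bv * VN[bf, 3] + bw * VN[bf, 6]
    ny = bu * VN[bf, 1] + bv * VN[bf, 4] + bw * VN[bf, 7]
    nz = bu * VN[bf, 2] + bv * VN[bf, 5] + bw * VN[bf, 8]
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn > 0.0:
        nx /= nn; ny /= nn; nz /= nn
    dist = math.sqrt(best_d2)
    sgn = (px - bqx) * nx + (py - bqy) * ny + (pz - bqz) * nz
    return bqx, bqy, bqz, nx, ny, nz, dist, sgn


@njit(cache=True)
def probe_points(points, TV, VN, glo, inv_cell, cell, gnx, gny, gnz,
                 cstart, ctris, out_near, out_norm, out_dist, out_sign):
    n = points.shape[0]
    for i in range(n):
        qx, qy, qz, nx, ny, nz, dist, sgn = _probe_one(
            points[i, 0], points[i, 1], points[i, 2],
            TV, VN, glo, inv_cell, cell, gnx, gny, gnz, cstart, ctris)
        out_near[i, 0] = qx; out_near[i, 1] = qy; out_near[i, 2] = qz
        out_norm[i, 0] = nx; out_norm[i, 1] = ny; out_norm[i, 2] = nz
        out_dist[i] = dist
        out_sign[i] = sgn


@njit(cache=True)
def sample_surface(u, TV, VN, cum_area, out_pos, out_norm):
    """Area-weighted surface sampling from uniform triples ``u`` in [0,1)."""
    n = u.shape[0]
    nf = cum_area.shape[0]
    for i in range(n):
        f = np.searchsorted(cum_area, u[i, 0])
        if f >= nf:
            f = nf - 1
        r1 = math.sqrt(u[i, 1])
        b0 = 1.0 - r1
        b1 = r1 * (1.0 - u[i, 2])
        b2 = r1 * u[i, 2]
        for j in range(3):
            out_pos[i, j] = (b0 * TV[f, j] + b1 * TV[f, 3 + j]
                             + b2 * TV[f, 6 + j])
            out_norm[i, j] = (b0 * VN[f, j] + b1 * VN[f, 3 + j]
                              + b2 * VN[f, 6 + j])
        nn = math.sqrt(out_norm[i, 0] ** 2 + out_norm[i, 1] ** 2
                       + out_norm[i, 2] ** 2)
        if nn > 0.0:
            out_norm[i, 0] /= nn
            out_norm[i, 1] /= nn
            out_norm[i, 2] /= nn


# ---------------------------------------------------------------------------
# spatial hash: open-addressed table of 50 nm buckets with per-bucket
# intrusive chains (S_cellnext)
# ---------------------------------------------------------------------------

_OFFSET = 1 << 20  # recenters integer cell coordinates into 21 bits


@njit(cache=True, inline="always")
def _cell_key(ix, iy, iz):
    return (((ix + _OFFSET) << 42) | ((iy + _OFFSET) << 21) | (iz + _OFFSET))


@njit(cache=True, inline="always")
def _key_slot(key, tab_key, mask):
    h = np.uint64(key) * np.uint64(0x9E3779B97F4A7C15)
    h ^= h >> np.uint64(31)
    s = np.int64(h & np.uint64(mask))
    while True:
        k = tab_key[s]
        if k == key or k == -1:
            return s
        s = (s + 1) & mask


@njit(cache=True, inline="always")
def _pos_key(x, y, z, inv_bucket):
    return _cell_key(int(math.floor(x * inv_bucket)),
                     int(math.floor(y * inv_bucket)),
                     int(math.floor(z * inv_bucket)))


@njit(cache=True, inline="always")
def _hash_insert(i, key, tab_key, tab_head, mask, S_cellnext, ctr):
    s = _key_slot(key, tab_key, mask)
    if tab_key[s] == -1:
        tab_key[s] = key
        tab_head[s] = -1
        ctr[C_NKEYS] += 1
    S_cellnext[i] = tab_head[s]
    tab_head[s] = i


@njit(cache=True, inline="always")
def _hash_remove(i, key, tab_key, tab_head, mask, S_cellnext):
    s = _key_slot(key, tab_key, mask)
    j = tab_head[s]
    if j == i:
        tab_head[s] = S_cellnext[i]
        return
    while S_cellnext[j] != i:
        j = S_cellnext[j]
    S_cellnext[j] = S_cellnext[i]


@njit(cache=True)
def hash_rebuild(tab_key, tab_head, mask, S_alive, S_pos, S_cellnext,
                 inv_bucket, cap, ctr):
    tab_key[:] = -1
    tab_head[:] = -1
    ctr[C_NKEYS] = 0
    for i in range(cap):
        if S_alive[i] == 1:
            key = _pos_key(S_pos[i, 0], S_pos[i, 1], S_pos[i, 2], inv_bucket)
            _hash_insert(i, key, tab_key, tab_head, mask, S_cellnext, ctr)


@njit(cache=True)
def hash_query(px, py, pz, radius, bucket, tab_key, tab_head, mask,
               S_cellnext, S_alive, out):
    """Collect live segments from every bucket overlapped by the query ball.

    Returns a superset of the true neighbours (bucket granularity); callers
    filter by exact distance.  Requires ``radius <= bucket``.
    """
    inv = 1.0 / bucket
    x0 = int(math.floor((px - radius) * inv))
    x1 = int(math.floor((px + radius) * inv))
    y0 = int(math.floor((py - radius) * inv))
    y1 = int(math.floor((py + radius) * inv))
    z0 = int(math.floor((pz - radius) * inv))
    z1 = int(math.floor((pz + radius) * inv))
    n = 0
    for ix in range(x0, x1 + 1):
        for iy in range(y0, y1 + 1):
            for iz in range(z0, z1 + 1):
                key = _cell_key(ix, iy, iz)
                s = _key_slot(key, tab_key, mask)
                if tab_key[s] != key:
                    continue
                j = tab_head[s]
                while j != -1:
                    if S_alive[j] == 1 and n < out.shape[0]:
                        out[n] = j
                        n += 1
                    j = S_cellnext[j]
    return n


# ---------------------------------------------------------------------------
# random directions and the growth-direction rule
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rand_unit():
    # normalized 3D Gaussian: exactly isotropic
    while True:
        x = np.random.normal(0.0, 1.0)
        y = np.random.normal(0.0, 1.0)
        z = np.random.normal(0.0, 1.0)
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            inv = 1.0 / math.sqrt(n2)
            return x * inv, y * inv, z * inv


@njit(cache=True, inline="always")
def _propose_dir(tx, ty, tz, rd, bd, bx, by, bz):
    # weighted average of previous direction, fresh random unit vector and
    # (optionally) the cue direction, renormalized; zero-norm combinations
    # trigger a redraw of the random vector
    while True:
        ux, uy, uz = _rand_unit()
        w = 1.0 - rd - bd
        vx = w * tx + rd * ux + bd * bx
        vy = w * ty + rd * uy + bd * by
        vz = w * tz + rd * uz + bd * bz
        n2 = vx * vx + vy * vy + vz * vz
        if n2 > 1e-18:
            inv = 1.0 / math.sqrt(n2)
            return vx * inv, vy * inv, vz * inv


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def free_walk_correlations(n_traj, n_steps, rd, record_every):
    """Tangent-tangent correlation of unconstrained growth (no interactions).

    Returns the mean of t(s).t(0) over trajectories at s = 0, record_every,
    2*record_every, ...  Uses the same RNG stream and direction rule as the
    stepping kernel.
    """
    n_rec = n_steps // record_every + 1
    acc = np.zeros(n_rec, dtype=np.float64)
    for t in range(n_traj):
        ox, oy, oz = _rand_unit()
        dx, dy, dz = ox, oy, oz
        acc[0] += 1.0
        for s in range(1, n_steps + 1):
            dx, dy, dz = _propose_dir(dx, dy, dz, rd, 0.0, 0.0, 0.0, 0.0)
            if s % record_every == 0:
                acc[s // record_every] += ox * dx + oy * dy + oz * dz
    return acc / n_traj


# ---------------------------------------------------------------------------
# network stepping kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def step_kernel(n_target, steps_done,
                S_pos, S_dir, S_mt, S_next, S_prev, S_cellnext, S_alive,
                free_idx,
                M_head, M_tail, M_nseg, M_minus, M_cat, M_alive, M_birth,
                M_nextchk,
                tab_key, tab_head, mask,
                TV, VN, glo, inv_cell, gcell, gnx, gny, gnz, cstart, ctris,
                cum_area,
                P, IP, cue_axis, cue_center, ctr):
    """Advance the network by up to ``n_target`` steps.

    Returns a status code; on STATUS_GROW_* the Python wrapper enlarges the
    relevant arrays and re-enters.  ``steps_done[0]`` tracks progress.
    """
    ell = P[P_ELL]
    rd = P[P_RD]
    bd = P[P_BD]
    ns = P[P_NS]
    npr = P[P_NP]
    cos_a = P[P_COSA]
    sin_a = P[P_SINA]
    bucket = P[P_BUCKET]
    inv_bucket = 1.0 / bucket
    rint = P[P_RINT]
    rint2 = rint * rint
    dmem = P[P_DMEM]
    ntrials = IP[I_NTRIALS]
    strong = IP[I_ANCHOR] == 1
    has_cue = IP[I_CUE] == 1
    nuc_tangential = IP[I_NUCMODE] == 1 or strong

    while steps_done[0] < n_target:
        # capacity guards: worst case one append per live MT plus nucleations
        if ctr[C_FREETOP] < ctr[C_NMT_LIVE] + 4096:
            return STATUS_GROW_SEGS
        if ctr[C_NMT] + 4096 > M_head.shape[0]:
            return STATUS_GROW_MTS
        if 2 * ctr[C_NKEYS] + 4096 > mask + 1:
            return STATUS_GROW_HASH
        step = ctr[C_STEP]

        # --- (1) nucleation ------------------------------------------------
        n_new = np.random.binomial(ntrials, npr)
        for _ in range(n_new):
            u1 = np.random.random()
            u2 = np.random.random()
            u3 = np.random.random()
            f = np.searchsorted(cum_area, u1)
            if f >= cum_area.shape[0]:
                f = cum_area.shape[0] - 1
            r1 = math.sqrt(u2)
            b0 = 1.0 - r1
            b1 = r1 * (1.0 - u3)
            b2 = r1 * u3
            px = b0 * TV[f, 0] + b1 * TV[f, 3] + b2 * TV[f, 6]
            py = b0 * TV[f, 1] + b1 * TV[f, 4] + b2 * TV[f, 7]
            pz = b0 * TV[f, 2] + b1 * TV[f, 5] + b2 * TV[f, 8]
            nx = b0 * VN[f, 0] + b1 * VN[f, 3] + b2 * VN[f, 6]
            ny = b0 * VN[f, 1] + b1 * VN[f, 4] + b2 * VN[f, 7]
            nz = b0 * VN[f, 2] + b1 * VN[f, 5] + b2 * VN[f, 8]
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
            nx /= nn; ny /= nn; nz /= nn
            if nuc_tangential:
                while True:
                    ux, uy, uz = _rand_unit()
                    dp = ux * nx + uy * ny + uz * nz
                    dx = ux - dp * nx
                    dy = uy - dp * ny
                    dz = uz - dp * nz
                    n2 = dx * dx + dy * dy + dz * dz
                    if n2 > 1e-12:
                        inv = 1.0 / math.sqrt(n2)
                        dx *= inv; dy *= inv; dz *= inv
                        break
            else:
                while True:
                    dx, dy, dz = _rand_unit()
                    if dx * nx + dy * ny + dz * nz <= 1e-12:
                        break
            m = int(ctr[C_NMT])
            ctr[C_NMT] += 1
            ctr[C_NMT_LIVE] += 1
            M_alive[m] = 1
            M_minus[m] = 0
            M_cat[m] = 0
            M_birth[m] = step
            M_nseg[m] = 1
            M_nextchk[m] = 0
            ctr[C_FREETOP] -= 1
            s0 = free_idx[ctr[C_FREETOP]]
            ex = px + ell * dx
            ey = py + ell * dy
            ez = pz + ell * dz
            # a tangential step off a curved region can leave the mesh by a
            # fraction of a nanometre; keep every endpoint inside (strong
            # anchoring keeps it exactly on the surface)
            qx, qy, qz, _nx, _ny, _nz, _d, sgn = _probe_one(
                ex, ey, ez, TV, VN, glo, inv_cell, gcell,
                gnx, gny, gnz, cstart, ctris)
            if strong or sgn > _ON_SURFACE_TOL:
                ex = qx; ey = qy; ez = qz
                vx = ex - px; vy = ey - py; vz = ez - pz
                vn = math.sqrt(vx * vx + vy * vy + vz * vz)
                if vn > 1e-12:
                    dx = vx / vn; dy = vy / vn; dz = vz / vn
            S_pos[s0, 0] = ex; S_pos[s0, 1] = ey; S_pos[s0, 2] = ez
            S_dir[s0, 0] = dx; S_dir[s0, 1] = dy; S_dir[s0, 2] = dz
            S_mt[s0] = m
            S_next[s0] = -1
            S_prev[s0] = -1
            S_alive[s0] = 1
            M_head[m] = s0
            M_tail[m] = s0
            key = _pos_key(ex, ey, ez, inv_bucket)
            _hash_insert(s0, key, tab_key, tab_head, mask, S_cellnext, ctr)
            ctr[C_NSEG] += 1
            ctr[C_ADDED] += 1
            ctr[C_NUC] += 1

        n_mts = int(ctr[C_NMT])

        # --- (2) minus-end updates, creation order -------------------------
        for m in range(n_mts):
            if M_alive[m] == 0 or M_birth[m] == step:
                continue
            if M_minus[m] == 1:
                h = M_head[m]
                key = _pos_key(S_pos[h, 0], S_pos[h, 1], S_pos[h, 2],
                               inv_bucket)
                _hash_remove(h, key, tab_key, tab_head, mask, S_cellnext)
                S_alive[h] = 0
                free_idx[ctr[C_FREETOP]] = h
                ctr[C_FREETOP] += 1
                ctr[C_NSEG] -= 1
                ctr[C_REMOVED] += 1
                nh = S_next[h]
                M_head[m] = nh
                if nh != -1:
                    S_prev[nh] = -1
                M_nseg[m] -= 1
                if M_nseg[m] == 0:
                    M_alive[m] = 0
                    M_tail[m] = -1
                    ctr[C_NMT_LIVE] -= 1
            else:
                if np.random.random() < ns:
                    M_minus[m] = 1

        # --- (3) plus-end updates, creation order --------------------------
        for m in range(n_mts):
            if M_alive[m] == 0 or M_birth[m] == step:
                continue
            if M_cat[m] == 1:
                t = M_tail[m]
                key = _pos_key(S_pos[t, 0], S_pos[t, 1], S_pos[t, 2],
                               inv_bucket)
                _hash_remove(t, key, tab_key, tab_head, mask, S_cellnext)
                S_alive[t] = 0
                free_idx[ctr[C_FREETOP]] = t
                ctr[C_FREETOP] += 1
                ctr[C_NSEG] -= 1
                ctr[C_REMOVED] += 1
                pt = S_prev[t]
                M_tail[m] = pt
                if pt != -1:
                    S_next[pt] = -1
                M_nseg[m] -= 1
                if M_nseg[m] == 0:
                    M_alive[m] = 0
                    M_head[m] = -1
                    ctr[C_NMT_LIVE] -= 1
                continue

            t = M_tail[m]
            tx = S_pos[t, 0]; ty = S_pos[t, 1]; tz = S_pos[t, 2]
            tdx = S_dir[t, 0]; tdy = S_dir[t, 1]; tdz = S_dir[t, 2]

            # cue direction at the tip (circumferential to cue_axis)
            bx = 0.0; by = 0.0; bz = 0.0
            bd_eff = 0.0
            if has_cue:
                rx = tx - cue_center[0]
                ry = ty - cue_center[1]
                rz = tz - cue_center[2]
                pr = rx * cue_axis[0] + ry * cue_axis[1] + rz * cue_axis[2]
                rx -= pr * cue_axis[0]
                ry -= pr * cue_axis[1]
                rz -= pr * cue_axis[2]
                rn = math.sqrt(rx * rx + ry * ry + rz * rz)
                if rn > 1e-9:
                    rx /= rn; ry /= rn; rz /= rn
                    bx = cue_axis[1] * rz - cue_axis[2] * ry
                    by = cue_axis[2] * rx - cue_axis[0] * rz
                    bz = cue_axis[0] * ry - cue_axis[1] * rx
                    bd_eff = bd

            ndx, ndy, ndz = _propose_dir(tdx, tdy, tdz, rd, bd_eff,
                                         bx, by, bz)

            # (a) encounter with another microtubule within 25 nm of the tip
            best = -1
            best_d2 = rint2
            x0 = int(math.floor((tx - rint) * inv_bucket))
            x1 = int(math.floor((tx + rint) * inv_bucket))
            y0 = int(math.floor((ty - rint) * inv_bucket))
            y1 = int(math.floor((ty + rint) * inv_bucket))
            z0 = int(math.floor((tz - rint) * inv_bucket))
            z1 = int(math.floor((tz + rint) * inv_bucket))
            for ix in range(x0, x1 + 1):
                for iy in range(y0, y1 + 1):
                    for iz in range(z0, z1 + 1):
                        key = _cell_key(ix, iy, iz)
                        s = _key_slot(key, tab_key, mask)
                        if tab_key[s] != key:
                            continue
                        j = tab_head[s]
                        while j != -1:
                            if S_alive[j] == 1 and S_mt[j] != m:
                                ddx = S_pos[j, 0] - tx
                                ddy = S_pos[j, 1] - ty
                                ddz = S_pos[j, 2] - tz
                                d2 = (ddx * ddx + ddy * ddy + ddz * ddz)
                                if d2 < best_d2 or (
                                        d2 == best_d2 and best != -1 and (
                                        S_mt[j] < S_mt[best] or
                                        (S_mt[j] == S_mt[best] and j < best))):
                                    best = j
                                    best_d2 = d2
                            j = S_cellnext[j]
            if best != -1:
                c = (tdx * S_dir[best, 0] + tdy * S_dir[best, 1]
                     + tdz * S_dir[best, 2])
                ac = c if c >= 0.0 else -c
                if ac > cos_a:
                    # zipper: the host's line direction (sign chosen to keep
                    # growing the same way) becomes the reference direction;
                    # the per-step directional noise applies around it, so a
                    # bundled tip stays aligned yet can drift off by noise
                    sgn = 1.0 if c >= 0.0 else -1.0
                    ctr[C_ZIP] += 1
                    ndx, ndy, ndz = _propose_dir(
                        sgn * S_dir[best, 0], sgn * S_dir[best, 1],
                        sgn * S_dir[best, 2], rd, bd_eff, bx, by, bz)
                    ex = tx + ell * ndx
                    ey = ty + ell * ndy
                    ez = tz + ell * ndz
                    if strong:
                        qx, qy, qz, _nx, _ny, _nz, _d, _s = _probe_one(
                            ex, ey, ez, TV, VN, glo, inv_cell, gcell,
                            gnx, gny, gnz, cstart, ctris)
                        ex = qx; ey = qy; ez = qz
                        vx = ex - tx; vy = ey - ty; vz = ez - tz
                        vn = math.sqrt(vx * vx + vy * vy + vz * vz)
                        if vn > 1e-12:
                            ndx = vx / vn; ndy = vy / vn; ndz = vz / vn
                    elif M_nextchk[m] <= step:
                        # tip may be near the membrane: keep endpoint inside
                        qx, qy, qz, nx2, ny2, nz2, _d, s2 = _probe_one(
                            ex, ey, ez, TV, VN, glo, inv_cell, gcell,
                            gnx, gny, gnz, cstart, ctris)
                        if s2 > _ON_SURFACE_TOL:
                            ex = qx; ey = qy; ez = qz
                            vx = ex - tx; vy = ey - ty; vz = ez - tz
                            vn = math.sqrt(vx * vx + vy * vy + vz * vz)
                            if vn > 1e-12:
                                ndx = vx / vn; ndy = vy / vn; ndz = vz / vn
                    _append_seg(m, ex, ey, ez, ndx, ndy, ndz,
                                S_pos, S_dir, S_mt, S_next, S_prev, S_alive,
                                free_idx, M_tail, M_nseg,
                                tab_key, tab_head, mask, S_cellnext,
                                inv_bucket, ctr)
                else:
                    M_cat[m] = 1
                    ctr[C_CAT_MT] += 1
                continue

            # (b) membrane interaction, then (c) free growth
            if strong:
                qx, qy, qz, nx, ny, nz, dist, sgn = _probe_one(
                    tx, ty, tz, TV, VN, glo, inv_cell, gcell,
                    gnx, gny, gnz, cstart, ctris)
                dp = ndx * nx + ndy * ny + ndz * nz
                pdx = ndx - dp * nx
                pdy = ndy - dp * ny
                pdz = ndz - dp * nz
                n2 = pdx * pdx + pdy * pdy + pdz * pdz
                tries = 0
                while n2 < 1e-12 and tries < 8:
                    ndx, ndy, ndz = _propose_dir(tdx, tdy, tdz, rd, bd_eff,
                                                 bx, by, bz)
                    dp = ndx * nx + ndy * ny + ndz * nz
                    pdx = ndx - dp * nx
                    pdy = ndy - dp * ny
                    pdz = ndz - dp * nz
                    n2 = pdx * pdx + pdy * pdy + pdz * pdz
                    tries += 1
                inv = 1.0 / math.sqrt(n2)
                pdx *= inv; pdy *= inv; pdz *= inv
                ex = tx + ell * pdx
                ey = ty + ell * pdy
                ez = tz + ell * pdz
                qx, qy, qz, _nx, _ny, _nz, _d, _s = _probe_one(
                    ex, ey, ez, TV, VN, glo, inv_cell, gcell,
                    gnx, gny, gnz, cstart, ctris)
                vx = qx - tx; vy = qy - ty; vz = qz - tz
                vn = math.sqrt(vx * vx + vy * vy + vz * vz)
                if vn > 1e-12:
                    pdx = vx / vn; pdy = vy / vn; pdz = vz / vn
                    ex = qx; ey = qy; ez = qz
                _append_seg(m, ex, ey, ez, pdx, pdy, pdz,
                            S_pos, S_dir, S_mt, S_next, S_prev, S_alive,
                            free_idx, M_tail, M_nseg,
                            tab_key, tab_head, mask, S_cellnext,
                            inv_bucket, ctr)
            else:
                if M_nextchk[m] > step:
                    _append_seg(m, tx + ell * ndx, ty + ell * ndy,
                                tz + ell * ndz, ndx, ndy, ndz,
                                S_pos, S_dir, S_mt, S_next, S_prev, S_alive,
                                free_idx, M_tail, M_nseg,
                                tab_key, tab_head, mask, S_cellnext,
                                inv_bucket, ctr)
                    continue
                qx, qy, qz, nx, ny, nz, dist, sgn = _probe_one(
                    tx, ty, tz, TV, VN, glo, inv_cell, gcell,
                    gnx, gny, gnz, cstart, ctris)
                if dist > dmem:
                    # the 10 nm rule cannot trigger for the next
                    # (dist - dmem)/ell steps: growth moves the tip by at
                    # most ell per step
                    skip = int((dist - dmem) / ell)
                    M_nextchk[m] = step + (skip if skip > 1 else 1)
                    _append_seg(m, tx + ell * ndx, ty + ell * ndy,
                                tz + ell * ndz, ndx, ndy, ndz,
                                S_pos, S_dir, S_mt, S_next, S_prev, S_alive,
                                free_idx, M_tail, M_nseg,
                                tab_key, tab_head, mask, S_cellnext,
                                inv_bucket, ctr)
                    continue
                # within 10 nm of the membrane: steep approach -> catastrophe
                dp = ndx * nx + ndy * ny + ndz * nz
                if (dp if dp >= 0.0 else -dp) > sin_a:
                    M_cat[m] = 1
                    ctr[C_CAT_MEM] += 1
                    continue
                accepted = False
                for _try in range(32):
                    ex = tx + ell * ndx
                    ey = ty + ell * ndy
                    ez = tz + ell * ndz
                    # tangent-halfspace pretest (cheap, conservative for a
                    # convex surface); exact containment via a fresh probe
                    if ((ex - qx) * nx + (ey - qy) * ny
                            + (ez - qz) * nz <= _ON_SURFACE_TOL):
                        q2x, q2y, q2z, n2x, n2y, n2z, _d2, s2 = _probe_one(
                            ex, ey, ez, TV, VN, glo, inv_cell, gcell,
                            gnx, gny, gnz, cstart, ctris)
                        if s2 <= _ON_SURFACE_TOL:
                            accepted = True
                            break
                    ndx, ndy, ndz = _propose_dir(tdx, tdy, tdz, rd, bd_eff,
                                                 bx, by, bz)
                if not accepted:
                    ctr[C_FALLBACK] += 1
                    dp = ndx * nx + ndy * ny + ndz * nz
                    pdx = ndx - dp * nx
                    pdy = ndy - dp * ny
                    pdz = ndz - dp * nz
                    n2 = pdx * pdx + pdy * pdy + pdz * pdz
                    if n2 < 1e-12:
                        dp = tdx * nx + tdy * ny + tdz * nz
                        pdx = tdx - dp * nx
                        pdy = tdy - dp * ny
                        pdz = tdz - dp * nz
                        n2 = pdx * pdx + pdy * pdy + pdz * pdz
                    inv = 1.0 / math.sqrt(n2)
                    ndx = pdx * inv; ndy = pdy * inv; ndz = pdz * inv
                    ex = tx + ell * ndx
                    ey = ty + ell * ndy
                    ez = tz + ell * ndz
                    q2x, q2y, q2z, n2x, n2y, n2z, _d2, s2 = _probe_one(
                        ex, ey, ez, TV, VN, glo, inv_cell, gcell,
                        gnx, gny, gnz, cstart, ctris)
                    if s2 > _ON_SURFACE_TOL:
                        ex = q2x; ey = q2y; ez = q2z
                        vx = ex - tx; vy = ey - ty; vz = ez - tz
                        vn = math.sqrt(vx * vx + vy * vy + vz * vz)
                        if vn > 1e-12:
                            ndx = vx / vn; ndy = vy / vn; ndz = vz / vn
                _append_seg(m, ex, ey, ez, ndx, ndy, ndz,
                            S_pos, S_dir, S_mt, S_next, S_prev, S_alive,
                            free_idx, M_tail, M_nseg,
                            tab_key, tab_head, mask, S_cellnext,
                            inv_bucket, ctr)

        ctr[C_STEP] += 1
        steps_done[0] += 1
    return STATUS_OK


@njit(cache=True, inline="always")
def _append_seg(m, ex, ey, ez, dx, dy, dz,
                S_pos, S_dir, S_mt, S_next, S_prev, S_alive,
                free_idx, M_tail, M_nseg,
                tab_key, tab_head, mask, S_cellnext, inv_bucket, ctr):
    ctr[C_FREETOP] -= 1
    s0 = free_idx[ctr[C_FREETOP]]
    S_pos[s0, 0] = ex; S_pos[s0, 1] = ey; S_pos[s0, 2] = ez
    S_dir[s0, 0] = dx; S_dir[s0, 1] = dy; S_dir[s0, 2] = dz
    S_mt[s0] = m
    S_next[s0] = -1
    t = M_tail[m]
    S_prev[s0] = t
    S_next[t] = s0
    M_tail[m] = s0
    M_nseg[m] += 1
    S_alive[s0] = 1
    key = _pos_key(ex, ey, ez, inv_bucket)
    _hash_insert(s0, key, tab_key, tab_head, mask, S_cellnext, ctr)
    ctr[C_NSEG] += 1
    ctr[C_ADDED] += 1


@njit(cache=True)
def extract_snapshot(n_mts, M_alive, M_head, S_next, S_pos, S_dir,
                     out_mt, out_si, out_pos, out_dir):
    k = 0
    for m in range(n_mts):
        if M_alive[m] == 0:
            continue
        j = M_head[m]
        si = 0
        while j != -1:
            out_mt[k] = m
            out_si[k] = si
            out_pos[k, 0] = S_pos[j, 0]
            out_pos[k, 1] = S_pos[j, 1]
            out_pos[k, 2] = S_pos[j, 2]
            out_dir[k, 0] = S_dir[j, 0]
            out_dir[k, 1] = S_dir[j, 1]
            out_dir[k, 2] = S_dir[j, 2]
            k += 1
            si += 1
            j = S_next[j]
    return k
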