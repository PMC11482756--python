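"""Numba kernels: pairwise writhe, twist extraction, and the Metropolis loop.

Everything here operates on plain float64 arrays; the object-level API lives
in :mod:`ringtwist.engine` and :mod:`ringtwist.topology`.  Conventions:

* the chain is ``nseg`` straight segments over a *circuit* of ``ncv``
  vertices (``ncv = nseg`` for closed chains; for the end-clamped linear
  mode the circuit appends a fixed far-away virtual return path, so
  ``ncv > nseg + 1`` and only segments ``0..nseg-1`` are physical),
* junction ``j`` sits between segments ``j-1`` and ``j`` (circularly for
  closed chains); its twist angle ``phi[j]`` is the rotation of the material
  frame about the tangent after removing the bend by the minimal
  (parallel-transport) rotation,
* energies are accumulated in kBT units.

The Metropolis kernel keeps Tw + Wr running exactly: crankshaft and vertex
moves recompute the junction angles they touch and the writhe terms of moved
segment pairs, so a legitimate move changes Tw + Wr only at round-off while
a strand passage jumps it by ±2 (a frame wrap by ±1) — the guard rejects
anything beyond 0.45 turns.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWOPI = 2.0 * math.pi
# squared-norm threshold below which a writhe pair is treated as coplanar
_DEG2 = 1e-20
# midpoint distances below this (nm) count as hard overlap
HARD_CORE = 1e-3

# move-kind indices for the acceptance counters
MOVE_CRANK = 0
MOVE_VERTEX = 1
MOVE_TWIST = 2


# ----------------------------------------------------------------------
# pairwise writhe (Gauss double integral for two straight segments,
# evaluated in closed form as the signed solid angle of the Gauss map)
# ----------------------------------------------------------------------
@njit(cache=True, fastmath=True, inline="always")
def _clip1(x):
    if x > 1.0:
        return 1.0
    if x < -1.0:
        return -1.0
    return x


@njit(cache=True, fastmath=True)
def pair_writhe(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """Writhe contribution of segment a→b and segment c→d.

    The contribution is the signed solid angle of the Gauss-map
    quadrilateral (the four unit vectors joining segment endpoints) divided
    by 2π — equivalently the Gauss double integral over both orderings of
    the pair divided by 4π, times two.  The quadrilateral area is evaluated
    as two spherical triangles with the atan2 (van Oosterom–Strackee)
    formula, which stays well-conditioned for near-crossing segments where
    arcsine-based forms lose precision.  Summing over unordered
    non-adjacent pairs gives the writhe.
    """
    # unit vectors from segment-1 endpoints to segment-2 endpoints
    ux1 = cx - ax; uy1 = cy - ay; uz1 = cz - az       # a: 1→3
    ux2 = dx - ax; uy2 = dy - ay; uz2 = dz - az       # b: 1→4
    ux3 = dx - bx; uy3 = dy - by; uz3 = dz - bz       # c: 2→4
    ux4 = cx - bx; uy4 = cy - by; uz4 = cz - bz       # d: 2→3
    q1 = ux1 * ux1 + uy1 * uy1 + uz1 * uz1
    q2 = ux2 * ux2 + uy2 * uy2 + uz2 * uz2
    q3 = ux3 * ux3 + uy3 * uy3 + uz3 * uz3
    q4 = ux4 * ux4 + uy4 * uy4 + uz4 * uz4
    if q1 < _DEG2 or q2 < _DEG2 or q3 < _DEG2 or q4 < _DEG2:
        return 0.0  # shared endpoint: coplanar, zero contribution
    i1 = 1.0 / math.sqrt(q1); ux1 *= i1; uy1 *= i1; uz1 *= i1
    i2 = 1.0 / math.sqrt(q2); ux2 *= i2; uy2 *= i2; uz2 *= i2
    i3 = 1.0 / math.sqrt(q3); ux3 *= i3; uy3 *= i3; uz3 *= i3
    i4 = 1.0 / math.sqrt(q4); ux4 *= i4; uy4 *= i4; uz4 *= i4

    # triangle (a, b, c)
    n1 = (ux1 * (uy2 * uz3 - uz2 * uy3)
          + uy1 * (uz2 * ux3 - ux2 * uz3)
          + uz1 * (ux2 * uy3 - uy2 * ux3))
    d1 = (1.0 + ux1 * ux2 + uy1 * uy2 + uz1 * uz2
          + ux2 * ux3 + uy2 * uy3 + uz2 * uz3
          + ux3 * ux1 + uy3 * uy1 + uz3 * uz1)
    # triangle (a, c, d)
    n2 = (ux1 * (uy3 * uz4 - uz3 * uy4)
          + uy1 * (uz3 * ux4 - ux3 * uz4)
          + uz1 * (ux3 * uy4 - uy3 * ux4))
    d2 = (1.0 + ux1 * ux3 + uy1 * uy3 + uz1 * uz3
          + ux3 * ux4 + uy3 * uy4 + uz3 * uz4
          + ux4 * ux1 + uy4 * uy1 + uz4 * uz1)
    omega = 0.0
    if n1 != 0.0:
        omega += 2.0 * math.atan2(n1, d1)
    if n2 != 0.0:
        omega += 2.0 * math.atan2(n2, d2)
    # the quadrilateral traversal above is clockwise for a right-handed
    # (positive-writhe) crossing, hence the sign flip
    return -omega / TWOPI


@njit(cache=True)
def polygon_writhe(pos):
    """Writhe of the closed polygon whose vertices are the rows of ``pos``."""
    nv = pos.shape[0]
    w = 0.0
    for i in range(nv - 2):
        jmax = nv if i > 0 else nv - 1  # skip the (0, nv-1) adjacent pair
        for j in range(i + 2, jmax):
            jp = j + 1
            if jp == nv:
                jp = 0
            w += pair_writhe(
                pos[i, 0], pos[i, 1], pos[i, 2],
                pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2],
                pos[j, 0], pos[j, 1], pos[j, 2],
                pos[jp, 0], pos[jp, 1], pos[jp, 2],
            )
    return w


@njit(cache=True)
def _wr_cross_delta(pos, ncv, a, m, buf):
    """Writhe change from replacing vertices a..a+m (mod ncv) by ``buf``.

    ``buf`` holds the m+1 new vertex positions (endpoints included; the two
    extreme entries equal the old pivots for rigid moves).  Only pairs
    (moved segment, fixed segment) contribute: moved–moved pairs are rigid
    or adjacent in the moves this kernel proposes.
    Returns wr_new − wr_old.
    """
    old = 0.0
    new = 0.0
    for t in range(m):
        s = a + t
        if s >= ncv:
            s -= ncv
        sp = s + 1
        if sp == ncv:
            sp = 0
        for j in range(ncv):
            dj = j - a
            if dj < 0:
                dj += ncv
            if dj < m:
                continue  # j is a moved segment
            jp = j + 1
            if jp == ncv:
                jp = 0
            if jp == s or j == sp:
                continue  # adjacent: exactly zero
            old += pair_writhe(
                pos[s, 0], pos[s, 1], pos[s, 2],
                pos[sp, 0], pos[sp, 1], pos[sp, 2],
                pos[j, 0], pos[j, 1], pos[j, 2],
                pos[jp, 0], pos[jp, 1], pos[jp, 2],
            )
            new += pair_writhe(
                buf[t, 0], buf[t, 1], buf[t, 2],
                buf[t + 1, 0], buf[t + 1, 1], buf[t + 1, 2],
                pos[j, 0], pos[j, 1], pos[j, 2],
                pos[jp, 0], pos[jp, 1], pos[jp, 2],
            )
    return new - old


# ----------------------------------------------------------------------
# frames and junction angles
# ----------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def _rotate(vx, vy, vz, kx, ky, kz, c, s):
    """Rodrigues rotation of v about unit axis k with cos=c, sin=s."""
    kdv = kx * vx + ky * vy + kz * vz
    cxx = ky * vz - kz * vy
    cyy = kz * vx - kx * vz
    czz = kx * vy - ky * vx
    omc = 1.0 - c
    return (
        vx * c + cxx * s + kx * kdv * omc,
        vy * c + cyy * s + ky * kdv * omc,
        vz * c + czz * s + kz * kdv * omc,
    )


@njit(cache=True)
def junction_angles(e0x, e0y, e0z, f0x, f0y, f0z,
                    e1x, e1y, e1z, f1x, f1y, f1z):
    """Bend angle and twist angle across one junction.

    The twist angle is the rotation from the parallel-transported f̂ of the
    incoming segment to the f̂ of the outgoing segment, measured about the
    outgoing tangent; range (−π, π].  A 180° bend has no minimal transport
    and returns (π, nan).
    """
    c = e0x * e1x + e0y * e1y + e0z * e1z
    axx = e0y * e1z - e0z * e1y
    ayy = e0z * e1x - e0x * e1z
    azz = e0x * e1y - e0y * e1x
    s = math.sqrt(axx * axx + ayy * ayy + azz * azz)
    theta = math.atan2(s, c)
    if s < 1e-14:
        if c < 0.0:
            return theta, math.nan
        px, py, pz = f0x, f0y, f0z
    else:
        inv = 1.0 / s
        px, py, pz = _rotate(f0x, f0y, f0z, axx * inv, ayy * inv, azz * inv, c, s)
    # angle from transported f to f1 about e1
    gx = e1y * pz - e1z * py
    gy = e1z * px - e1x * pz
    gz = e1x * py - e1y * px
    sphi = gx * f1x + gy * f1y + gz * f1z
    cphi = px * f1x + py * f1y + pz * f1z
    return theta, math.atan2(sphi, cphi)


@njit(cache=True)
def all_junction_angles(eh, fh, closed):
    """theta, phi arrays over all junctions (entry 0 is 0/0 when open)."""
    n = eh.shape[0]
    theta = np.zeros(n)
    phi = np.zeros(n)
    j0 = 0 if closed else 1
    for j in range(j0, n):
        jm = j - 1 if j > 0 else n - 1
        th, ph = junction_angles(
            eh[jm, 0], eh[jm, 1], eh[jm, 2], fh[jm, 0], fh[jm, 1], fh[jm, 2],
            eh[j, 0], eh[j, 1], eh[j, 2], fh[j, 0], fh[j, 1], fh[j, 2],
        )
        theta[j] = th
        phi[j] = ph
    return theta, phi


# ----------------------------------------------------------------------
# total energies (from scratch; the MC loop keeps running values and the
# engine audits against these)
# ----------------------------------------------------------------------
@njit(cache=True)
def total_energies(pos, eh, fh, slen, phi, nseg, ncv, closed,
                   A, C, l0, ks2, esk, kappa, cutoff, hc, excl):
    eb = 0.0
    et = 0.0
    j0 = 0 if closed else 1
    for j in range(j0, nseg):
        jm = j - 1 if j > 0 else nseg - 1
        th, _ = junction_angles(
            eh[jm, 0], eh[jm, 1], eh[jm, 2], fh[jm, 0], fh[jm, 1], fh[jm, 2],
            eh[j, 0], eh[j, 1], eh[j, 2], fh[j, 0], fh[j, 1], fh[j, 2],
        )
        eb += A[j] / (2.0 * l0) * th * th
        et += C[j] / (2.0 * l0) * phi[j] * phi[j]
    es = 0.0
    for i in range(nseg):
        ip = i + 1
        if ip == ncv:
            ip = 0
        for j in range(i + 1, nseg):
            d = j - i
            if closed and nseg - d < d:
                d = nseg - d
            if d <= excl:
                continue
            jp = j + 1
            if jp == ncv:
                jp = 0
            r = seg_distance(
                pos[i, 0], pos[i, 1], pos[i, 2],
                pos[ip, 0], pos[ip, 1], pos[ip, 2],
                pos[j, 0], pos[j, 1], pos[j, 2],
                pos[jp, 0], pos[jp, 1], pos[jp, 2])
            if r < hc:
                es = math.inf
                break
            if r < cutoff:
                es += esk * math.exp(-kappa * r) / r
        if es == math.inf:
            break
    est = 0.0
    for i in range(nseg):
        d = slen[i] - l0
        est += ks2 * d * d
    return eb, et, es, est


# ----------------------------------------------------------------------
# the Metropolis kernel
# ----------------------------------------------------------------------
@njit(cache=True)
def _record(samp_phi, samp_len, samp_wr, samp_tw, samp_e,
            pos_stride, samp_pos, isamp, phi, slen, run, energies,
            nseg, nv_chain, pos):
    for j in range(nseg):
        samp_phi[isamp, j] = phi[j]
        samp_len[isamp, j] = slen[j]
    samp_tw[isamp] = run[0] / TWOPI
    samp_wr[isamp] = run[1]
    for q in range(4):
        samp_e[isamp, q] = energies[q]
    if pos_stride > 0 and isamp % pos_stride == 0:
        row = isamp // pos_stride
        if row < samp_pos.shape[0]:
            for v in range(nv_chain):
                samp_pos[row, v, 0] = pos[v, 0]
                samp_pos[row, v, 1] = pos[v, 1]
                samp_pos[row, v, 2] = pos[v, 2]

@njit(cache=True, fastmath=True)
def seg_distance(p1x, p1y, p1z, q1x, q1y, q1z,
                 p2x, p2y, p2z, q2x, q2y, q2z):
    """Minimum distance between segments p1→q1 and p2→q2 (clamped
    closest-point parametrization)."""
    d1x = q1x - p1x; d1y = q1y - p1y; d1z = q1z - p1z
    d2x = q2x - p2x; d2y = q2y - p2y; d2z = q2z - p2z
    rx = p1x - p2x; ry = p1y - p2y; rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    c = d1x * rx + d1y * ry + d1z * rz
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > 1e-12 * a * e:
        s = (b * f - c * e) / denom
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    if e > 1e-30:
        t = (b * s + f) / e
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
        s = -c / a
    elif t > 1.0:
        t = 1.0
        s = (b - c) / a
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    wx = rx + s * d1x - t * d2x
    wy = ry + s * d1y - t * d2y
    wz = rz + s * d1z - t * d2z
    return math.sqrt(wx * wx + wy * wy + wz * wz)


@njit(cache=True)
def _es_seg(ax, ay, az, bx, by, bz, pos, ncv, nseg, s, closed, excl,
            esk, kappa, cutoff, hc, skip_lo, skip_m):
    """DH energy of the segment a→b against all chain segments outside the
    moved block [skip_lo, skip_lo+skip_m) (mod chain), with contour
    exclusion relative to segment index s.  The interaction distance is the
    segment–segment minimum distance; below the hard-core diameter ``hc``
    the energy is infinite.  A midpoint prefilter skips far pairs."""
    mx = 0.5 * (ax + bx)
    my = 0.5 * (ay + by)
    mz = 0.5 * (az + bz)
    lh = 0.5 * math.sqrt((bx - ax) ** 2 + (by - ay) ** 2 + (bz - az) ** 2)
    en = 0.0
    for j in range(nseg):
        dj = j - skip_lo
        if dj < 0:
            dj += nseg
        if dj < skip_m:
            continue
        d = j - s
        if d < 0:
            d = -d
        if closed and nseg - d < d:
            d = nseg - d
        if d <= excl:
            continue
        jp = j + 1
        if jp == ncv:
            jp = 0
        jx0 = pos[j, 0]; jy0 = pos[j, 1]; jz0 = pos[j, 2]
        jx1 = pos[jp, 0]; jy1 = pos[jp, 1]; jz1 = pos[jp, 2]
        cjx = 0.5 * (jx0 + jx1) - mx
        cjy = 0.5 * (jy0 + jy1) - my
        cjz = 0.5 * (jz0 + jz1) - mz
        lj = 0.5 * math.sqrt((jx1 - jx0) ** 2 + (jy1 - jy0) ** 2 + (jz1 - jz0) ** 2)
        reach = cutoff + lh + lj
        if cjx * cjx + cjy * cjy + cjz * cjz > reach * reach:
            continue
        r = seg_distance(ax, ay, az, bx, by, bz, jx0, jy0, jz0, jx1, jy1, jz1)
        if r < hc:
            return math.inf
        if r < cutoff:
            en += esk * math.exp(-kappa * r) / r
    return en


@njit(cache=True)
def mc_kernel(pos, fh, eh, slen, phi,
              nseg, ncv, closed,
              A, C, l0, ks2, esk, kappa, cutoff, hc, excl,
              guard_on, lk_book,
              run, energies,
              p_crank, p_vertex, mmax, amp_c, amp_v, amp_t,
              vlo, vhi, clo, chi, tlo, thi,
              n_steps, sample_every,
              samp_phi, samp_len, samp_wr, samp_tw, samp_e,
              pos_stride, samp_pos, samp_start,
              seed, att, acc, guard_rej):
    """Run ``n_steps`` Metropolis moves in place.

    ``run[0]`` is the running total twist in radians, ``run[1]`` the running
    writhe; ``energies`` holds (bend, twist, electrostatic, stretch) in kBT.
    Samples are written every ``sample_every`` steps starting at row
    ``samp_start``; returns the next free sample row.
    """
    np.random.seed(seed)
    nv_chain = nseg if closed else nseg + 1
    buf = np.empty((nseg + 2, 3))
    isamp = samp_start
    smax = samp_phi.shape[0]

    for step in range(n_steps):
        # record BEFORE the move so rejected/aborted proposals cannot skip
        # a sampling point; the final point is recorded after the loop
        if sample_every > 0 and step > 0 and step % sample_every == 0 \
                and isamp < smax:
            _record(samp_phi, samp_len, samp_wr, samp_tw, samp_e,
                    pos_stride, samp_pos, isamp, phi, slen, run, energies,
                    nseg, nv_chain, pos)
            isamp += 1
        r = np.random.random()
        if r < p_crank:
            kind = MOVE_CRANK
        elif r < p_crank + p_vertex:
            kind = MOVE_VERTEX
        else:
            kind = MOVE_TWIST
        att[kind] += 1

        if kind == MOVE_TWIST:
            # twist exchange between an arbitrary junction pair (i, j):
            # +δ at junction i, −δ at junction j, realized by rotating every
            # segment frame between them about its own tangent by δ.
            # Total twist is conserved exactly and the twist field mixes
            # globally (O(N) relaxation instead of diffusive O(N²)).
            i = tlo + np.random.randint(0, thi - tlo)
            j = tlo + np.random.randint(0, thi - tlo)
            if i == j:
                continue
            if i > j:
                i, j = j, i
                beta = -amp_t * (2.0 * np.random.random() - 1.0)
            else:
                beta = amp_t * (2.0 * np.random.random() - 1.0)
            phi_i_new = phi[i] + beta
            phi_j_new = phi[j] - beta
            dE = (C[i] / (2.0 * l0) * (phi_i_new * phi_i_new - phi[i] * phi[i])
                  + C[j] / (2.0 * l0) * (phi_j_new * phi_j_new - phi[j] * phi[j]))
            if dE <= 0.0 or np.random.random() < math.exp(-dE):
                c = math.cos(beta)
                s = math.sin(beta)
                for seg in range(i, j):
                    fx, fy, fz = _rotate(fh[seg, 0], fh[seg, 1], fh[seg, 2],
                                         eh[seg, 0], eh[seg, 1], eh[seg, 2],
                                         c, s)
                    fh[seg, 0] = fx; fh[seg, 1] = fy; fh[seg, 2] = fz
                phi[i] = phi_i_new
                phi[j] = phi_j_new
                energies[1] += dE
                acc[kind] += 1
        else:
            # ---- backbone move: contiguous segment block [a, a+m) ----
            if kind == MOVE_CRANK:
                a = clo + np.random.randint(0, chi - clo)
                m = 2 + np.random.randint(0, mmax - 1)
                if not closed and a + m > nseg - 1:
                    continue  # infeasible pivot pair; counts as rejected
                b = a + m
                if b >= ncv:
                    b -= ncv
                axx = pos[b, 0] - pos[a, 0]
                ayy = pos[b, 1] - pos[a, 1]
                azz = pos[b, 2] - pos[a, 2]
                an = math.sqrt(axx * axx + ayy * ayy + azz * azz)
                if an < 1e-9:
                    continue
                axx /= an; ayy /= an; azz /= an
                ang = amp_c * (2.0 * np.random.random() - 1.0)
                ca = math.cos(ang)
                sa = math.sin(ang)
                buf[0, 0] = pos[a, 0]; buf[0, 1] = pos[a, 1]; buf[0, 2] = pos[a, 2]
                for t in range(1, m):
                    v = a + t
                    if v >= ncv:
                        v -= ncv
                    vx = pos[v, 0] - pos[a, 0]
                    vy = pos[v, 1] - pos[a, 1]
                    vz = pos[v, 2] - pos[a, 2]
                    wx, wy, wz = _rotate(vx, vy, vz, axx, ayy, azz, ca, sa)
                    buf[t, 0] = pos[a, 0] + wx
                    buf[t, 1] = pos[a, 1] + wy
                    buf[t, 2] = pos[a, 2] + wz
                buf[m, 0] = pos[b, 0]; buf[m, 1] = pos[b, 1]; buf[m, 2] = pos[b, 2]
                rigid = True
            else:
                i = vlo + np.random.randint(0, vhi - vlo)
                a = i - 1
                if a < 0:
                    a += ncv
                m = 2
                buf[0, 0] = pos[a, 0]; buf[0, 1] = pos[a, 1]; buf[0, 2] = pos[a, 2]
                buf[1, 0] = pos[i, 0] + amp_v * np.random.normal()
                buf[1, 1] = pos[i, 1] + amp_v * np.random.normal()
                buf[1, 2] = pos[i, 2] + amp_v * np.random.normal()
                ip = i + 1
                if ip >= ncv:
                    ip -= ncv
                buf[2, 0] = pos[ip, 0]; buf[2, 1] = pos[ip, 1]; buf[2, 2] = pos[ip, 2]
                rigid = False
                ang = 0.0
                ca = 1.0
                sa = 0.0

            # new tangents/frames/lengths of moved segments, stored locally
            ebuf = np.empty((m, 3))
            fbuf = np.empty((m, 3))
            lbuf = np.empty(m)
            bad = False
            for t in range(m):
                dxx = buf[t + 1, 0] - buf[t, 0]
                dyy = buf[t + 1, 1] - buf[t, 1]
                dzz = buf[t + 1, 2] - buf[t, 2]
                ln = math.sqrt(dxx * dxx + dyy * dyy + dzz * dzz)
                if ln < 1e-9:
                    bad = True
                    break
                lbuf[t] = ln
                ebuf[t, 0] = dxx / ln; ebuf[t, 1] = dyy / ln; ebuf[t, 2] = dzz / ln
                s = a + t
                if s >= ncv:
                    s -= ncv
                if rigid:
                    fx, fy, fz = _rotate(fh[s, 0], fh[s, 1], fh[s, 2],
                                         axx, ayy, azz, ca, sa)
                else:
                    # minimal rotation taking the old tangent to the new one
                    cxe = eh[s, 1] * ebuf[t, 2] - eh[s, 2] * ebuf[t, 1]
                    cye = eh[s, 2] * ebuf[t, 0] - eh[s, 0] * ebuf[t, 2]
                    cze = eh[s, 0] * ebuf[t, 1] - eh[s, 1] * ebuf[t, 0]
                    sn = math.sqrt(cxe * cxe + cye * cye + cze * cze)
                    cn = (eh[s, 0] * ebuf[t, 0] + eh[s, 1] * ebuf[t, 1]
                          + eh[s, 2] * ebuf[t, 2])
                    if sn < 1e-14:
                        if cn < 0.0:
                            bad = True
                            break
                        fx, fy, fz = fh[s, 0], fh[s, 1], fh[s, 2]
                    else:
                        inv = 1.0 / sn
                        fx, fy, fz = _rotate(fh[s, 0], fh[s, 1], fh[s, 2],
                                             cxe * inv, cye * inv, cze * inv,
                                             cn, sn)
                fbuf[t, 0] = fx; fbuf[t, 1] = fy; fbuf[t, 2] = fz
            if bad:
                continue

            # --- junction terms: bend + twist at affected junctions ---
            # rigid moves touch junctions a and a+m; vertex moves a, a+1, a+2
            dE_b = 0.0
            dE_t = 0.0
            dTw = 0.0
            jn_idx = np.empty(3, dtype=np.int64)
            jn_phi = np.empty(3)
            kq = 0
            # rigid arcs only change the two boundary junctions (a and a+m);
            # a vertex move (m=2) changes junctions a, a+1 and a+2
            for qi in range(2 if rigid else 3):
                q = qi * m if rigid else qi
                jv = a + q  # junction at vertex a+q
                if jv >= ncv:
                    jv -= ncv
                if not closed and (jv < 1 or jv > nseg - 1):
                    continue  # clamped/open end: no junction
                # incoming segment jv-1, outgoing segment jv; use buffered
                # values when the segment is in the moved block
                qm = q - 1  # block-local index of incoming segment
                if 0 <= qm < m:
                    e0x = ebuf[qm, 0]; e0y = ebuf[qm, 1]; e0z = ebuf[qm, 2]
                    f0x = fbuf[qm, 0]; f0y = fbuf[qm, 1]; f0z = fbuf[qm, 2]
                else:
                    sm = jv - 1
                    if sm < 0:
                        sm += nseg
                    e0x = eh[sm, 0]; e0y = eh[sm, 1]; e0z = eh[sm, 2]
                    f0x = fh[sm, 0]; f0y = fh[sm, 1]; f0z = fh[sm, 2]
                if 0 <= q < m:
                    e1x = ebuf[q, 0]; e1y = ebuf[q, 1]; e1z = ebuf[q, 2]
                    f1x = fbuf[q, 0]; f1y = fbuf[q, 1]; f1z = fbuf[q, 2]
                else:
                    so = jv if jv < nseg else jv - nseg
                    e1x = eh[so, 0]; e1y = eh[so, 1]; e1z = eh[so, 2]
                    f1x = fh[so, 0]; f1y = fh[so, 1]; f1z = fh[so, 2]
                th_new, ph_new = junction_angles(e0x, e0y, e0z, f0x, f0y, f0z,
                                                 e1x, e1y, e1z, f1x, f1y, f1z)
                if math.isnan(ph_new):
                    bad = True
                    break
                jj = jv if jv < nseg else jv - nseg
                # unwrap against the stored angle: the twist coordinate is
                # continuous, while atan2 reports it only modulo 2π (a free
                # nicked junction can legitimately wander past ±π)
                ph_new -= TWOPI * math.floor((ph_new - phi[jj]) / TWOPI + 0.5)
                # old angles: bend recomputed from stored tangents, twist stored
                smj = jj - 1 if jj > 0 else nseg - 1
                th_old, _ = junction_angles(
                    eh[smj, 0], eh[smj, 1], eh[smj, 2],
                    fh[smj, 0], fh[smj, 1], fh[smj, 2],
                    eh[jj, 0], eh[jj, 1], eh[jj, 2],
                    fh[jj, 0], fh[jj, 1], fh[jj, 2])
                dE_b += A[jj] / (2.0 * l0) * (th_new * th_new - th_old * th_old)
                dE_t += C[jj] / (2.0 * l0) * (ph_new * ph_new - phi[jj] * phi[jj])
                dTw += ph_new - phi[jj]
                jn_idx[kq] = jj
                jn_phi[kq] = ph_new
                kq += 1
            if bad:
                continue

            # --- stretch ---
            dE_s = 0.0
            if not rigid:
                for t in range(m):
                    s = a + t
                    if s >= ncv:
                        s -= ncv
                    d_new = lbuf[t] - l0
                    d_old = slen[s] - l0
                    dE_s += ks2 * (d_new * d_new - d_old * d_old)

            # --- electrostatics + hard core: moved vs unmoved segments ---
            dE_e = 0.0
            overlap = False
            for t in range(m):
                s = a + t
                if s >= ncv:
                    s -= ncv
                if s >= nseg:
                    continue  # virtual closure segments carry no charge
                en = _es_seg(buf[t, 0], buf[t, 1], buf[t, 2],
                             buf[t + 1, 0], buf[t + 1, 1], buf[t + 1, 2],
                             pos, ncv, nseg, s, closed, excl,
                             esk, kappa, cutoff, hc, a, m)
                if en == math.inf:
                    overlap = True
                    break
                sp = s + 1
                if sp == ncv:
                    sp = 0
                eo = _es_seg(pos[s, 0], pos[s, 1], pos[s, 2],
                             pos[sp, 0], pos[sp, 1], pos[sp, 2],
                             pos, ncv, nseg, s, closed, excl,
                             esk, kappa, cutoff, hc, a, m)
                dE_e += en - eo
            if overlap:
                continue

            dE = dE_b + dE_t + dE_s + dE_e
            if dE <= 0.0 or np.random.random() < math.exp(-dE):
                dWr = _wr_cross_delta(pos, ncv, a, m, buf)
                if guard_on and abs(dTw / TWOPI + dWr) > 0.45:
                    guard_rej[0] += 1
                    continue
                # ---- commit ----
                for t in range(1, m):
                    v = a + t
                    if v >= ncv:
                        v -= ncv
                    pos[v, 0] = buf[t, 0]
                    pos[v, 1] = buf[t, 1]
                    pos[v, 2] = buf[t, 2]
                for t in range(m):
                    s = a + t
                    if s >= ncv:
                        s -= ncv
                    if s >= nseg:
                        continue
                    eh[s, 0] = ebuf[t, 0]; eh[s, 1] = ebuf[t, 1]; eh[s, 2] = ebuf[t, 2]
                    fh[s, 0] = fbuf[t, 0]; fh[s, 1] = fbuf[t, 1]; fh[s, 2] = fbuf[t, 2]
                    slen[s] = lbuf[t]
                for q in range(kq):
                    phi[jn_idx[q]] = jn_phi[q]
                run[0] += dTw
                run[1] += dWr
                energies[0] += dE_b
                energies[1] += dE_t
                energies[2] += dE_e
                energies[3] += dE_s
                acc[kind] += 1

    if sample_every > 0 and n_steps > 0 and n_steps % sample_every == 0 \
            and isamp < smax:
        _record(samp_phi, samp_len, samp_wr, samp_tw, samp_e,
                pos_stride, samp_pos, isamp, phi, slen, run, energies,
                nseg, nv_chain, pos)
        isamp += 1
    return isamp
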