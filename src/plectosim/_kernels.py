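"""Numba kernels: Metropolis sampling and Brownian dynamics of bead rings.

Shared conventions
------------------
* coordinates are unwrapped (contiguous molecules); periodic interactions
  use the minimum-image convention with ``box <= 0`` meaning no box;
* rings are stored back to back in one (M * n, 3) array, all of equal
  length n; ``closed = False`` treats each chain as open;
* the excluded volume is the purely repulsive cut Lennard-Jones potential
  (r_cut = 1 sigma), bonded neighbours excluded;
* supercoiling in the Monte Carlo kernel enters through the torsionally
  equilibrated effective energy  (2 pi^2 k_twist / n) (dLk - Wr)^2
  obtained by integrating the uniform harmonic twist out of White's
  theorem, with the ring writhe tracked incrementally move by move;
* crankshaft rotations displace every bead by less than ``d_max`` so that
  with the hard excluded-volume core strand passages (topology changes)
  are geometrically blocked.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# small geometry helpers


@njit(cache=False, inline="always")
def _cross(a, b, out):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=False, inline="always")
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=False, inline="always")
def _norm(a):
    return np.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


@njit(cache=False)
def _rotate(v, k, c, s, out):
    """Rodrigues rotation of v about unit axis k by angle with cos c, sin s."""
    kx = np.empty(3)
    _cross(k, v, kx)
    kv = _dot(k, v)
    for d in range(3):
        out[d] = v[d] * c + kx[d] * s + k[d] * kv * (1.0 - c)


@njit(cache=False, inline="always")
def _lj_rep(r2, eps, rcut2):
    if r2 >= rcut2:
        return 0.0
    if r2 < 0.25:
        return 1.0e30  # deep-core guard: effectively rejects the move
    inv2 = 1.0 / r2
    inv6 = inv2 * inv2 * inv2
    return 4.0 * eps * (inv6 * inv6 - inv6)


@njit(cache=False, inline="always")
def _ep_pair_energy(r, eps, rcut, shift):
    if r >= rcut:
        return 0.0
    inv6 = 1.0 / r**6
    return 4.0 * eps * (inv6 * inv6 - inv6) - shift


@njit(cache=False, inline="always")
def _asin_clip(x):
    if x > 1.0:
        x = 1.0
    elif x < -1.0:
        x = -1.0
    return np.arcsin(x)


@njit(cache=False)
def _omega(p1, p2, p3, p4):
    """Signed solid angle / 4 pi of segment pair (p1->p2), (p3->p4)."""
    r13x = p3[0] - p1[0]
    r13y = p3[1] - p1[1]
    r13z = p3[2] - p1[2]
    r14x = p4[0] - p1[0]
    r14y = p4[1] - p1[1]
    r14z = p4[2] - p1[2]
    r23x = p3[0] - p2[0]
    r23y = p3[1] - p2[1]
    r23z = p3[2] - p2[2]
    r24x = p4[0] - p2[0]
    r24y = p4[1] - p2[1]
    r24z = p4[2] - p2[2]
    # normals of the tetrahedron faces
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x
    l1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    l2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    l3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    l4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if l1 < 1e-14 or l2 < 1e-14 or l3 < 1e-14 or l4 < 1e-14:
        return 0.0
    om = (
        _asin_clip((n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2))
        + _asin_clip((n2x * n3x + n2y * n3y + n2z * n3z) / (l2 * l3))
        + _asin_clip((n3x * n4x + n3y * n4y + n3z * n4z) / (l3 * l4))
        + _asin_clip((n4x * n1x + n4y * n1y + n4z * n1z) / (l4 * l1))
    )
    # sign from (r34 x r12) . r13
    r12x = p2[0] - p1[0]
    r12y = p2[1] - p1[1]
    r12z = p2[2] - p1[2]
    r34x = p4[0] - p3[0]
    r34y = p4[1] - p3[1]
    r34z = p4[2] - p3[2]
    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    sgn = cx * r13x + cy * r13y + cz * r13z
    if sgn > 0.0:
        s = 1.0
    elif sgn < 0.0:
        s = -1.0
    else:
        s = 0.0
    return om * s / (4.0 * np.pi)


@njit(cache=False)
def writhe_ring(pos):
    """Full writhe of one closed polygonal ring, (n, 3) array."""
    n = pos.shape[0]
    wr = 0.0
    for i in range(n - 2):
        jmax = n if i > 0 else n - 1  # skip closure-adjacent pair (0, n-1)
        for j in range(i + 2, jmax):
            wr += _omega(pos[i], pos[(i + 1) % n], pos[j], pos[(j + 1) % n])
    return 2.0 * wr


# ---------------------------------------------------------------------------
# incremental cell list (periodic boxes only)


@njit(cache=False, inline="always")
def _cell_of_coord(x, y, z, box, ncs):
    cs = box / ncs
    ix = int((x - box * np.floor(x / box)) / cs)
    iy = int((y - box * np.floor(y / box)) / cs)
    iz = int((z - box * np.floor(z / box)) / cs)
    if ix >= ncs:
        ix = ncs - 1
    if iy >= ncs:
        iy = ncs - 1
    if iz >= ncs:
        iz = ncs - 1
    return (ix * ncs + iy) * ncs + iz


@njit(cache=False, inline="always")
def _cell_insert(b, c, head, nxt, cell_of):
    nxt[b] = head[c]
    head[c] = b
    cell_of[b] = c


@njit(cache=False)
def _cell_remove(b, head, nxt, cell_of):
    c = cell_of[b]
    cur = head[c]
    if cur == b:
        head[c] = nxt[b]
        return
    while nxt[cur] != b:
        cur = nxt[cur]
    nxt[cur] = nxt[b]


@njit(cache=False)
def _cell_update(b, pos, box, ncs, head, nxt, cell_of):
    c_new = _cell_of_coord(pos[b, 0], pos[b, 1], pos[b, 2], box, ncs)
    if c_new != cell_of[b]:
        _cell_remove(b, head, nxt, cell_of)
        _cell_insert(b, c_new, head, nxt, cell_of)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo


@njit(cache=False)
def _bend_angle_energy(pa, pb, pc, kappa):
    """kappa (1 - cos theta) for the junction at pb."""
    e1 = np.empty(3)
    e2 = np.empty(3)
    for d in range(3):
        e1[d] = pb[d] - pa[d]
        e2[d] = pc[d] - pb[d]
    n1 = _norm(e1)
    n2 = _norm(e2)
    return kappa * (1.0 - _dot(e1, e2) / (n1 * n2))


@njit(cache=False)
def _pair_dist2(pos, a, b, box):
    dx = pos[b, 0] - pos[a, 0]
    dy = pos[b, 1] - pos[a, 1]
    dz = pos[b, 2] - pos[a, 2]
    if box > 0.0:
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=False)
def _dist2_vec(p, q, box):
    dx = q[0] - p[0]
    dy = q[1] - p[1]
    dz = q[2] - p[2]
    if box > 0.0:
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=False)
def mc_run(
    pos,
    n_ring,
    m_rings,
    box,
    closed,
    kappa,
    eps_rep,
    k_twist,
    delta_lk,
    wr,
    ep_i,
    ep_j,
    ep_eps,
    ep_rcut,
    bias_k,
    bias_d0,
    n_sweeps,
    sample_every,
    d_max,
    max_arc,
    angle_cap,
    p_translate,
    trans_step,
    wr_refresh,
    use_cell_list,
    seed,
):
    """Metropolis sampler for M equal rings (or open chains).

    Moves: displacement-capped crankshaft rotations (plus tail rotations
    for open chains) and, for multi-ring systems, rigid molecule
    translations.  Samples coordinates every ``sample_every`` sweeps.

    ``bias_k > 0`` adds a harmonic umbrella restraint
    (bias_k/2)(d - bias_d0)^2 on the site-pair distance (per ring), used
    for free-energy estimates along the pair separation.

    Returns (samples, wr_samples, n_accept, n_trial).
    """
    np.random.seed(seed)
    ntot = n_ring * m_rings
    rcut2 = 1.0
    n_samples = n_sweeps // sample_every if sample_every > 0 else 0
    samples = np.empty((n_samples, ntot, 3))
    wr_samples = np.empty((n_samples, m_rings))
    twist_coupling = 0.0
    if k_twist > 0.0 and closed:
        twist_coupling = 2.0 * np.pi * np.pi * k_twist / n_ring
    ep_on = ep_i >= 0 and ep_j >= 0 and (ep_eps > 0.0 or bias_k > 0.0)
    ep_shift = 0.0
    if ep_on:
        inv6 = 1.0 / ep_rcut**6
        ep_shift = 4.0 * ep_eps * (inv6 * inv6 - inv6)

    newp = np.empty((n_ring, 3))  # scratch for moved beads
    moved = np.empty(n_ring, np.int64)
    in_moved = np.zeros(ntot, np.uint8)
    axis = np.empty(3)
    tmp = np.empty(3)
    n_accept = 0
    n_trial = 0
    isample = 0

    # incremental cell list: the 27-neighbourhood of a 1.8-sigma cell covers
    # the LJ cutoff plus the displacement cap of any capped move
    shell = 1.0 + max(d_max, trans_step * 1.8)
    ncs = int(box / shell) if box > 0.0 else 0
    use_cells = use_cell_list == 1 and box > 0.0 and ncs >= 3
    if use_cells:
        head = np.full(ncs * ncs * ncs, -1, np.int64)
        nxt = np.full(ntot, -1, np.int64)
        cell_of = np.empty(ntot, np.int64)
        for b in range(ntot):
            _cell_insert(
                b, _cell_of_coord(pos[b, 0], pos[b, 1], pos[b, 2], box, ncs),
                head, nxt, cell_of,
            )
    else:
        head = np.empty(0, np.int64)
        nxt = np.empty(0, np.int64)
        cell_of = np.empty(0, np.int64)

    for sweep in range(n_sweeps):
        for _ in range(ntot):
            n_trial += 1
            m = np.random.randint(m_rings)
            off = m * n_ring
            do_translate = m_rings > 1 and np.random.random() < p_translate

            if do_translate:
                # rigid translation of ring m; only inter-ring EV changes
                dxv = np.empty(3)
                for d in range(3):
                    dxv[d] = trans_step * (2.0 * np.random.random() - 1.0)
                dnorm = _norm(dxv)
                prune2 = (1.0 + dnorm) * (1.0 + dnorm)
                dE = 0.0
                for b in range(off, off + n_ring):
                    if use_cells:
                        bx = cell_of[b] // (ncs * ncs)
                        by = (cell_of[b] // ncs) % ncs
                        bz = cell_of[b] % ncs
                        for ox in range(-1, 2):
                            for oy in range(-1, 2):
                                for oz in range(-1, 2):
                                    cc = (
                                        ((bx + ox) % ncs) * ncs + ((by + oy) % ncs)
                                    ) * ncs + ((bz + oz) % ncs)
                                    c = head[cc]
                                    while c != -1:
                                        if not (off <= c < off + n_ring):
                                            r2o = _pair_dist2(pos, b, c, box)
                                            if r2o <= prune2:
                                                for d in range(3):
                                                    tmp[d] = pos[b, d] + dxv[d]
                                                r2n = _dist2_vec(tmp, pos[c], box)
                                                dE += _lj_rep(r2n, eps_rep, rcut2)
                                                dE -= _lj_rep(r2o, eps_rep, rcut2)
                                        c = nxt[c]
                            if dE > 1.0e20:
                                break
                    else:
                        for c in range(ntot):
                            if off <= c < off + n_ring:
                                continue
                            r2o = _pair_dist2(pos, b, c, box)
                            if r2o > prune2:
                                continue  # neither old nor new pair within cutoff
                            for d in range(3):
                                tmp[d] = pos[b, d] + dxv[d]
                            r2n = _dist2_vec(tmp, pos[c], box)
                            dE += _lj_rep(r2n, eps_rep, rcut2) - _lj_rep(r2o, eps_rep, rcut2)
                            if dE > 1.0e20:
                                break
                    if dE > 1.0e20:
                        break
                if dE <= 0.0 or np.random.random() < np.exp(-dE):
                    for b in range(off, off + n_ring):
                        for d in range(3):
                            pos[b, d] += dxv[d]
                        if use_cells:
                            _cell_update(b, pos, box, ncs, head, nxt, cell_of)
                    n_accept += 1
                continue

            # ----- crankshaft / tail rotation -----
            tail_move = False
            if closed:
                i = np.random.randint(n_ring)
                arc = 2 + np.random.randint(max_arc - 1)
                j = (i + arc) % n_ring
                nmv = arc - 1
                for k in range(nmv):
                    moved[k] = (i + 1 + k) % n_ring
            else:
                if np.random.random() < 0.4:
                    tail_move = True
                    # rotate a tail about an interior pivot
                    tail_len = 1 + np.random.randint(max_arc)
                    if np.random.random() < 0.5:
                        piv = tail_len  # beads 0..piv-1 move
                        if piv > n_ring - 2:
                            piv = n_ring - 2
                        nmv = piv
                        for k in range(nmv):
                            moved[k] = k
                        i = piv
                        j = piv
                    else:
                        piv = n_ring - 1 - tail_len
                        if piv < 1:
                            piv = 1
                        nmv = n_ring - 1 - piv
                        for k in range(nmv):
                            moved[k] = piv + 1 + k
                        i = piv
                        j = piv
                else:
                    arc = 2 + np.random.randint(max_arc - 1)
                    i = np.random.randint(n_ring - arc)
                    j = i + arc
                    nmv = arc - 1
                    for k in range(nmv):
                        moved[k] = i + 1 + k
            if nmv < 1:
                continue

            gi = off + i
            gj = off + j
            if tail_move:
                # random unit axis through the pivot bead
                while True:
                    for d in range(3):
                        axis[d] = np.random.normal()
                    an = _norm(axis)
                    if an > 1e-8:
                        break
                for d in range(3):
                    axis[d] /= an
                pivot = pos[gi]
            else:
                for d in range(3):
                    axis[d] = pos[gj, d] - pos[gi, d]
                an = _norm(axis)
                if an < 1e-9:
                    continue  # degenerate axis
                for d in range(3):
                    axis[d] /= an
                pivot = pos[gi]

            # displacement cap: max perpendicular distance of moved beads
            rperp_max = 0.0
            for k in range(nmv):
                gb = off + moved[k]
                for d in range(3):
                    tmp[d] = pos[gb, d] - pivot[d]
                par = _dot(tmp, axis)
                rp2 = _dot(tmp, tmp) - par * par
                if rp2 > rperp_max:
                    rperp_max = rp2
            rperp_max = np.sqrt(max(rperp_max, 0.0))
            cap = angle_cap
            if rperp_max > 1e-9 and d_max / rperp_max < cap:
                cap = d_max / rperp_max
            ang = cap * (2.0 * np.random.random() - 1.0)
            ca = np.cos(ang)
            sa = np.sin(ang)

            for k in range(nmv):
                gb = off + moved[k]
                for d in range(3):
                    tmp[d] = pos[gb, d] - pivot[d]
                _rotate(tmp, axis, ca, sa, newp[k])
                for d in range(3):
                    newp[k, d] += pivot[d]
                in_moved[gb] = 1

            dE = 0.0
            # bending terms change only at the pivot junctions
            if tail_move:
                p = i
                if 1 <= p <= n_ring - 2:
                    gp = off + p
                    # one neighbour of the pivot moved, the other did not
                    if moved[0] == 0:  # head tail moved: bead p-1 moved
                        kidx = nmv - 1  # moved index of bead p-1
                        dE += _bend_angle_energy(newp[kidx], pos[gp], pos[gp + 1], kappa)
                        dE -= _bend_angle_energy(pos[gp - 1], pos[gp], pos[gp + 1], kappa)
                    else:  # tail side moved: bead p+1 moved
                        dE += _bend_angle_energy(pos[gp - 1], pos[gp], newp[0], kappa)
                        dE -= _bend_angle_energy(pos[gp - 1], pos[gp], pos[gp + 1], kappa)
            else:
                if closed or i >= 1:
                    gprev = off + ((i - 1) % n_ring if closed else i - 1)
                    dE += _bend_angle_energy(pos[gprev], pos[gi], newp[0], kappa)
                    dE -= _bend_angle_energy(pos[gprev], pos[gi], pos[off + moved[0]], kappa)
                if closed or j <= n_ring - 2:
                    gnext = off + ((j + 1) % n_ring if closed else j + 1)
                    dE += _bend_angle_energy(newp[nmv - 1], pos[gj], pos[gnext], kappa)
                    dE -= _bend_angle_energy(pos[off + moved[nmv - 1]], pos[gj], pos[gnext], kappa)

            # excluded volume: moved beads vs everything outside {moved, pivots}
            # (a moved bead travels at most d_max, so pairs with old
            # distance > 1 + d_max stay outside the cutoff)
            prune2 = (1.0 + d_max) * (1.0 + d_max)
            if dE < 1.0e20:
                for k in range(nmv):
                    gb = off + moved[k]
                    if use_cells:
                        bx = cell_of[gb] // (ncs * ncs)
                        by = (cell_of[gb] // ncs) % ncs
                        bz = cell_of[gb] % ncs
                        for ox in range(-1, 2):
                            for oy in range(-1, 2):
                                for oz in range(-1, 2):
                                    cc = (
                                        ((bx + ox) % ncs) * ncs + ((by + oy) % ncs)
                                    ) * ncs + ((bz + oz) % ncs)
                                    c = head[cc]
                                    while c != -1:
                                        if not (
                                            in_moved[c] == 1 or c == gi or c == gj
                                        ):
                                            r2o = _pair_dist2(pos, gb, c, box)
                                            if r2o <= prune2:
                                                r2n = _dist2_vec(newp[k], pos[c], box)
                                                dE += _lj_rep(r2n, eps_rep, rcut2)
                                                dE -= _lj_rep(r2o, eps_rep, rcut2)
                                        c = nxt[c]
                            if dE > 1.0e20:
                                break
                    else:
                        for c in range(ntot):
                            if in_moved[c] == 1 or c == gi or c == gj:
                                continue
                            r2o = _pair_dist2(pos, gb, c, box)
                            if r2o > prune2:
                                continue
                            r2n = _dist2_vec(newp[k], pos[c], box)
                            dE += _lj_rep(r2n, eps_rep, rcut2) - _lj_rep(r2o, eps_rep, rcut2)
                            if dE > 1.0e20:
                                break
                    if dE > 1.0e20:
                        break

            # enhancer-promoter pair (same ring): changes only when exactly
            # one site moved (moved-to-moved and moved-to-pivot distances
            # are preserved by the rigid rotation)
            if ep_on and dE < 1.0e20:
                ge = off + ep_i
                gp2 = off + ep_j
                e_in = in_moved[ge] == 1
                p_in = in_moved[gp2] == 1
                if e_in != p_in:
                    if e_in:
                        gmv, gfx = ge, gp2
                    else:
                        gmv, gfx = gp2, ge
                    if gfx != gi and gfx != gj:
                        kidx = -1
                        for k in range(nmv):
                            if off + moved[k] == gmv:
                                kidx = k
                                break
                        ro = np.sqrt(_pair_dist2(pos, gmv, gfx, box))
                        rn = np.sqrt(_dist2_vec(newp[kidx], pos[gfx], box))
                        if ep_eps > 0.0:
                            dE += _ep_pair_energy(rn, ep_eps, ep_rcut, ep_shift)
                            dE -= _ep_pair_energy(ro, ep_eps, ep_rcut, ep_shift)
                        if bias_k > 0.0:
                            dE += 0.5 * bias_k * (rn - bias_d0) ** 2
                            dE -= 0.5 * bias_k * (ro - bias_d0) ** 2

            # writhe-coupled torsional energy (supercoiled rings only)
            dwr = 0.0
            if twist_coupling > 0.0 and not tail_move and dE < 1.0e20:
                # changed segments s in [i, i+arc-1]; all rotate rigidly,
                # so only changed-vs-unchanged pairs contribute
                arc_seg = j - i if not closed else (j - i) % n_ring
                for ks in range(arc_seg):
                    s = (i + ks) % n_ring
                    s1 = s
                    s2 = (s + 1) % n_ring
                    # old endpoints
                    if in_moved[off + s1] == 1:
                        k1 = (s1 - (i + 1)) % n_ring
                        a_new = newp[k1]
                    else:
                        a_new = pos[off + s1]
                    if in_moved[off + s2] == 1:
                        k2 = (s2 - (i + 1)) % n_ring
                        b_new = newp[k2]
                    else:
                        b_new = pos[off + s2]
                    for ss in range(n_ring):
                        inside = (ss - i) % n_ring < arc_seg
                        if inside:
                            continue
                        q1 = pos[off + ss]
                        q2 = pos[off + (ss + 1) % n_ring]
                        dwr += _omega(a_new, b_new, q1, q2)
                        dwr -= _omega(pos[off + s1], pos[off + s2], q1, q2)
                dwr *= 2.0
                t_old = delta_lk - wr[m]
                t_new = delta_lk - (wr[m] + dwr)
                dE += twist_coupling * (t_new * t_new - t_old * t_old)

            accept = False
            if dE < 1.0e20:
                if dE <= 0.0:
                    accept = True
                elif np.random.random() < np.exp(-dE):
                    accept = True
            if accept:
                for k in range(nmv):
                    gb = off + moved[k]
                    for d in range(3):
                        pos[gb, d] = newp[k, d]
                    if use_cells:
                        _cell_update(gb, pos, box, ncs, head, nxt, cell_of)
                wr[m] += dwr
                n_accept += 1
            for k in range(nmv):
                in_moved[off + moved[k]] = 0

        if twist_coupling > 0.0 and wr_refresh > 0 and (sweep + 1) % wr_refresh == 0:
            for mm in range(m_rings):
                wr[mm] = writhe_ring(pos[mm * n_ring : (mm + 1) * n_ring])

        if sample_every > 0 and (sweep + 1) % sample_every == 0 and isample < n_samples:
            for b in range(ntot):
                for d in range(3):
                    samples[isample, b, d] = pos[b, d]
            for mm in range(m_rings):
                wr_samples[isample, mm] = wr[mm]
            isample += 1

    return samples, wr_samples, n_accept, n_trial


# ---------------------------------------------------------------------------
# Brownian dynamics with material-frame torsion


@njit(cache=False)
def _transport(a, b, v, out):
    """Parallel-transport v by the minimal rotation taking unit a to unit b."""
    k = np.empty(3)
    _cross(a, b, k)
    s = _norm(k)
    c = _dot(a, b)
    if s < 1e-12:
        for d in range(3):
            out[d] = v[d] if c > 0.0 else -v[d]
        return
    for d in range(3):
        k[d] /= s
    _rotate(v, k, c, s, out)


@njit(cache=False)
def compute_phi(pos, mnorm, n_ring, m_rings, closed, phi):
    """Per-junction excess-twist angles from edge material frames.

    Junction k of a ring sits at bead k, between edges k-1 and k; its
    twist is the signed angle from the parallel-transported frame of edge
    k-1 to the frame of edge k, about the tangent of edge k.
    """
    t_prev = np.empty(3)
    t_cur = np.empty(3)
    mt = np.empty(3)
    crx = np.empty(3)
    for m in range(m_rings):
        off = m * n_ring
        n_edges = n_ring if closed else n_ring - 1
        k0 = 0 if closed else 1
        for k in range(k0, n_edges):
            e_prev = (k - 1) % n_ring
            # tangents of edges e_prev and k
            for d in range(3):
                t_prev[d] = pos[off + (e_prev + 1) % n_ring, d] - pos[off + e_prev, d]
                t_cur[d] = pos[off + (k + 1) % n_ring, d] - pos[off + k, d]
            np_ = _norm(t_prev)
            nc = _norm(t_cur)
            for d in range(3):
                t_prev[d] /= np_
                t_cur[d] /= nc
            _transport(t_prev, t_cur, mnorm[off + e_prev], mt)
            _cross(mt, mnorm[off + k], crx)
            sphi = _dot(crx, t_cur)
            cphi = _dot(mt, mnorm[off + k])
            phi[off + k] = np.arctan2(sphi, cphi)
        if not closed:
            phi[off] = 0.0


@njit(cache=False)
def _bd_forces(
    pos,
    phi,
    n_ring,
    m_rings,
    box,
    closed,
    kappa,
    eps_rep,
    k_bond,
    r0,
    k_twist,
    ep_i,
    ep_j,
    ep_eps,
    ep_rcut,
    F,
):
    ntot = n_ring * m_rings
    rcut2 = 1.0
    for b in range(ntot):
        for d in range(3):
            F[b, d] = 0.0
    e1 = np.empty(3)
    e2 = np.empty(3)
    kb = np.empty(3)
    energy = 0.0

    for m in range(m_rings):
        off = m * n_ring
        n_edges = n_ring if closed else n_ring - 1
        # bonds
        for k in range(n_edges):
            a = off + k
            b = off + (k + 1) % n_ring
            for d in range(3):
                e1[d] = pos[b, d] - pos[a, d]
            r = _norm(e1)
            fmag = k_bond * (r - r0) / r
            for d in range(3):
                F[a, d] += fmag * e1[d]
                F[b, d] -= fmag * e1[d]
            energy += 0.5 * k_bond * (r - r0) ** 2
        # bending + twist at junctions
        k0 = 0 if closed else 1
        kend = n_ring if closed else n_ring - 1
        for k in range(k0, kend):
            ia = off + (k - 1) % n_ring
            ib = off + k
            ic = off + (k + 1) % n_ring
            for d in range(3):
                e1[d] = pos[ib, d] - pos[ia, d]
                e2[d] = pos[ic, d] - pos[ib, d]
            l1 = _norm(e1)
            l2 = _norm(e2)
            inv1 = 1.0 / l1
            inv2 = 1.0 / l2
            ct = _dot(e1, e2) * inv1 * inv2
            # bending: E = kappa (1 - cos theta)
            # grad_e1 cos = (e2hat - cos * e1hat)/l1 ; grad_e2 similarly
            for d in range(3):
                g1 = (e2[d] * inv2 - ct * e1[d] * inv1) * inv1
                g2 = (e1[d] * inv1 - ct * e2[d] * inv2) * inv2
                # dE/dx = -kappa * dcos/dx
                F[ia, d] += -kappa * g1
                F[ib, d] += kappa * (g1 - g2)
                F[ic, d] += kappa * g2
            energy += kappa * (1.0 - ct)
            # twist: E = (k_twist/2) phi_k^2, holonomy gradient via the
            # curvature binormal (discrete-elastic-rod construction)
            if k_twist > 0.0:
                denom = l1 * l2 + _dot(e1, e2)
                if denom > 1e-12:
                    _cross(e1, e2, kb)
                    for d in range(3):
                        kb[d] *= 2.0 / denom
                    coef = k_twist * phi[ib]
                    for d in range(3):
                        ga = kb[d] * 0.5 * inv1   # d phi / d e1
                        gc = kb[d] * 0.5 * inv2   # d phi / d e2
                        F[ia, d] += coef * ga
                        F[ib, d] += coef * (gc - ga)
                        F[ic, d] += -coef * gc
                energy += 0.5 * k_twist * phi[ib] * phi[ib]
        # enhancer-promoter pair
        if ep_i >= 0 and ep_j >= 0 and ep_eps > 0.0:
            a = off + ep_i
            b = off + ep_j
            for d in range(3):
                e1[d] = pos[b, d] - pos[a, d]
            r = _norm(e1)
            if r < ep_rcut:
                inv6 = 1.0 / r**6
                fmag = 24.0 * ep_eps * (2.0 * inv6 * inv6 - inv6) / (r * r)
                for d in range(3):
                    F[a, d] -= fmag * e1[d]
                    F[b, d] += fmag * e1[d]
                inv6c = 1.0 / ep_rcut**6
                energy += 4.0 * ep_eps * (inv6 * inv6 - inv6) - 4.0 * ep_eps * (
                    inv6c * inv6c - inv6c
                )

    # excluded volume over all non-bonded pairs
    for a in range(ntot):
        ra = a % n_ring
        ma = a // n_ring
        for b in range(a + 1, ntot):
            if ma == b // n_ring:
                sep = b - a
                if sep == 1 or (closed and sep == n_ring - 1):
                    continue
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            if box > 0.0:
                dx -= box * np.round(dx / box)
                dy -= box * np.round(dy / box)
                dz -= box * np.round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut2 and r2 > 1e-12:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                fmag = 24.0 * eps_rep * (2.0 * inv6 * inv6 - inv6) * inv2
                F[a, 0] -= fmag * dx
                F[a, 1] -= fmag * dy
                F[a, 2] -= fmag * dz
                F[b, 0] += fmag * dx
                F[b, 1] += fmag * dy
                F[b, 2] += fmag * dz
                energy += 4.0 * eps_rep * (inv6 * inv6 - inv6)
    return energy


@njit(cache=False)
def bd_run(
    pos,
    mnorm,
    n_ring,
    m_rings,
    box,
    closed,
    kappa,
    eps_rep,
    k_bond,
    r0,
    k_twist,
    ep_i,
    ep_j,
    ep_eps,
    ep_rcut,
    dt,
    gamma,
    gamma_t,
    n_steps,
    sample_every,
    seed,
):
    """Overdamped Euler-Maruyama propagation with material-frame torsion.

    Per step: (1) forces (bond, bend, twist via the holonomy gradient,
    excluded volume, site pair) and position update at kT = 1; (2) frames
    parallel-transported onto the new tangents (this conserves Lk: any
    writhe change is absorbed as opposite twist); (3) torsional Langevin
    rotation of the frames about their tangents.

    Returns (sampled positions, sampled per-junction twist angles,
    sampled energies).  ``pos`` and ``mnorm`` are updated in place.
    """
    np.random.seed(seed)
    ntot = n_ring * m_rings
    n_samples = n_steps // sample_every if sample_every > 0 else 0
    s_pos = np.empty((n_samples, ntot, 3))
    s_phi = np.empty((n_samples, ntot))
    s_en = np.empty(n_samples)
    F = np.empty((ntot, 3))
    phi = np.zeros(ntot)
    newpos = np.empty((ntot, 3))
    t_old = np.empty(3)
    t_new = np.empty(3)
    mt = np.empty(3)
    sig = np.sqrt(2.0 * dt / gamma)
    sig_t = np.sqrt(2.0 * dt / gamma_t)
    max_disp2 = 0.25
    isample = 0

    for step in range(n_steps):
        if k_twist > 0.0 and closed:
            compute_phi(pos, mnorm, n_ring, m_rings, closed, phi)
        energy = _bd_forces(
            pos, phi, n_ring, m_rings, box, closed, kappa, eps_rep, k_bond, r0,
            k_twist, ep_i, ep_j, ep_eps, ep_rcut, F,
        )
        for b in range(ntot):
            d2 = 0.0
            for d in range(3):
                dx = dt / gamma * F[b, d] + sig * np.random.normal()
                newpos[b, d] = pos[b, d] + dx
                d2 += dx * dx
            if d2 > max_disp2:
                raise ValueError("BD instability: bead displacement exceeds 0.5 sigma")

        if k_twist > 0.0 and closed:
            # transport frames onto the new tangents
            for m in range(m_rings):
                off = m * n_ring
                n_edges = n_ring if closed else n_ring - 1
                for k in range(n_edges):
                    a = off + k
                    b = off + (k + 1) % n_ring
                    for d in range(3):
                        t_old[d] = pos[b, d] - pos[a, d]
                        t_new[d] = newpos[b, d] - newpos[a, d]
                    lo = _norm(t_old)
                    ln = _norm(t_new)
                    for d in range(3):
                        t_old[d] /= lo
                        t_new[d] /= ln
                    _transport(t_old, t_new, mnorm[a], mt)
                    # project exactly onto the plane normal to the new tangent
                    dp = _dot(mt, t_new)
                    for d in range(3):
                        mt[d] -= dp * t_new[d]
                    nm = _norm(mt)
                    for d in range(3):
                        mnorm[a, d] = mt[d] / nm

        for b in range(ntot):
            for d in range(3):
                pos[b, d] = newpos[b, d]

        if k_twist > 0.0 and closed:
            # torsional Langevin update of the frame angles
            compute_phi(pos, mnorm, n_ring, m_rings, closed, phi)
            for m in range(m_rings):
                off = m * n_ring
                for k in range(n_ring):
                    # frame of edge k couples to junctions k and k+1
                    tq = k_twist * (phi[off + (k + 1) % n_ring] - phi[off + k])
                    dalpha = dt / gamma_t * tq + sig_t * np.random.normal()
                    a = off + k
                    b = off + (k + 1) % n_ring
                    for d in range(3):
                        t_new[d] = pos[b, d] - pos[a, d]
                    ln = _norm(t_new)
                    for d in range(3):
                        t_new[d] /= ln
                    _rotate(mnorm[a], t_new, np.cos(dalpha), np.sin(dalpha), mt)
                    for d in range(3):
                        mnorm[a, d] = mt[d]

        if sample_every > 0 and (step + 1) % sample_every == 0 and isample < n_samples:
            if k_twist > 0.0 and closed:
                compute_phi(pos, mnorm, n_ring, m_rings, closed, phi)
            for b in range(ntot):
                for d in range(3):
                    s_pos[isample, b, d] = pos[b, d]
                s_phi[isample, b] = phi[b]
            s_en[isample] = energy
            isample += 1

    return s_pos, s_phi, s_en
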