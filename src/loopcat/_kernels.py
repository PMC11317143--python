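"""Numba-compiled inner loops: forces, the BAOAB Langevin integrator and
the fused production loop with bond-reconnection attempts.

Conventions shared by every kernel:

* bonded terms (springs, bending triplets) use minimum-image displacement
  vectors; bonded distances are always far below half the box, so this is
  identical to direct unwrapped geometry,
* non-bonded pairs use the minimum image and are excluded for directly
  bonded beads,
* pair interactions are tabulated per bead-type pair as
  (eps, sigma_ij, r_cut, shift) where shift = -U_LJ(r_cut), so every pair
  energy is exactly zero at and beyond its cutoff,
* non-bonded pairs are enumerated through a Verlet neighbour list with a
  safety skin, rebuilt (by cell binning) whenever any particle has moved
  more than half the skin; the evaluated interactions are identical to a
  full O(N^2) enumeration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1
STATUS_INTEGRATED = 2

DEFAULT_SKIN = 1.6
_PAIR_CAP = 128  # neighbour-list capacity per particle


@njit(cache=True, inline="always")
def _mi(d, box):
    if box > 0.0:
        return d - box * np.floor(d / box + 0.5)
    return d


@njit(cache=True, inline="always")
def _dist2(pos, box, i, j):
    dx = _mi(pos[j, 0] - pos[i, 0], box)
    dy = _mi(pos[j, 1] - pos[i, 1], box)
    dz = _mi(pos[j, 2] - pos[i, 2], box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _is_excluded(excl, i, j):
    for s in range(excl.shape[1]):
        if excl[i, s] == j:
            return True
        if excl[i, s] < 0:
            return False
    return False


@njit(cache=True, inline="always")
def _pair_e(pos, box, i, j, btype, eps_t, sig_t, rc_t, sh_t):
    """Shifted-truncated LJ energy of one specific pair."""
    ti = btype[i]
    tj = btype[j]
    rc = rc_t[ti, tj]
    r2 = _dist2(pos, box, i, j)
    if r2 >= rc * rc:
        return 0.0
    eps = eps_t[ti, tj]
    if eps == 0.0:
        return 0.0
    sig = sig_t[ti, tj]
    s2 = sig * sig / r2
    s6 = s2 * s2 * s2
    return 4.0 * eps * (s6 * s6 - s6) + sh_t[ti, tj]


@njit(cache=True, inline="always")
def _angle_e(pos, box, a, b, c, kappa):
    """Kratky-Porod energy of the triplet a-b-c."""
    t1x = _mi(pos[b, 0] - pos[a, 0], box)
    t1y = _mi(pos[b, 1] - pos[a, 1], box)
    t1z = _mi(pos[b, 2] - pos[a, 2], box)
    t2x = _mi(pos[c, 0] - pos[b, 0], box)
    t2y = _mi(pos[c, 1] - pos[b, 1], box)
    t2z = _mi(pos[c, 2] - pos[b, 2], box)
    n1 = np.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
    n2 = np.sqrt(t2x * t2x + t2y * t2y + t2z * t2z)
    cosq = (t1x * t2x + t1y * t2y + t1z * t2z) / (n1 * n2)
    if cosq > 1.0:
        cosq = 1.0
    elif cosq < -1.0:
        cosq = -1.0
    return kappa * (1.0 - cosq)


@njit(cache=True, fastmath=True)
def build_nlist(pos, box, btype, rc_t, skin, excl, pi, pj):
    """Cell-binned construction of the Verlet pair list.

    A pair (i, j) enters the list when its minimum-image distance is
    below rc_t[type_i, type_j] + skin.  Returns the pair count, or -1 on
    capacity overflow.
    """
    n = pos.shape[0]
    T = rc_t.shape[0]
    rcmax = 0.0
    for a in range(T):
        for b in range(T):
            if rc_t[a, b] > rcmax:
                rcmax = rc_t[a, b]
    rl = rcmax + skin
    count = 0
    nc = 0
    if box > 0.0 and rl > 0.0:
        nc = int(box / rl)
    cap = int(np.cbrt(4.0 * n)) + 1
    if nc > cap:
        nc = cap
    if nc < 3:
        ib = 1.0 / box if box > 0.0 else 0.0
        for i in range(1, n):
            ti = btype[i]
            for j in range(i):
                rc = rc_t[ti, btype[j]] + skin
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if box > 0.0:
                    dx -= box * np.floor(dx * ib + 0.5)
                    dy -= box * np.floor(dy * ib + 0.5)
                    dz -= box * np.floor(dz * ib + 0.5)
                if dx * dx + dy * dy + dz * dz < rc * rc:
                    if _is_excluded(excl, i, j):
                        continue
                    if count >= pi.shape[0]:
                        return -1
                    pi[count] = i
                    pj[count] = j
                    count += 1
        return count
    ib = 1.0 / box
    ncell3 = nc * nc * nc
    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cell = np.empty((n, 3), dtype=np.int64)
    inv = nc * ib
    for i in range(n):
        cx = int((pos[i, 0] - box * np.floor(pos[i, 0] * ib)) * inv)
        cy = int((pos[i, 1] - box * np.floor(pos[i, 1] * ib)) * inv)
        cz = int((pos[i, 2] - box * np.floor(pos[i, 2] * ib)) * inv)
        if cx >= nc:
            cx = nc - 1
        if cy >= nc:
            cy = nc - 1
        if cz >= nc:
            cz = nc - 1
        cell[i, 0] = cx
        cell[i, 1] = cy
        cell[i, 2] = cz
        idx = (cx * nc + cy) * nc + cz
        nxt[i] = head[idx]
        head[idx] = i
    for i in range(n):
        ti = btype[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for ox in range(-1, 2):
            cx = (cell[i, 0] + ox + nc) % nc
            for oy in range(-1, 2):
                cy = (cell[i, 1] + oy + nc) % nc
                for oz in range(-1, 2):
                    cz = (cell[i, 2] + oz + nc) % nc
                    j = head[(cx * nc + cy) * nc + cz]
                    while j >= 0:
                        if j < i:
                            rc = rc_t[ti, btype[j]] + skin
                            dx = xi - pos[j, 0]
                            dy = yi - pos[j, 1]
                            dz = zi - pos[j, 2]
                            dx -= box * np.floor(dx * ib + 0.5)
                            dy -= box * np.floor(dy * ib + 0.5)
                            dz -= box * np.floor(dz * ib + 0.5)
                            if dx * dx + dy * dy + dz * dz < rc * rc:
                                if not _is_excluded(excl, i, j):
                                    if count >= pi.shape[0]:
                                        return -1
                                    pi[count] = i
                                    pj[count] = j
                                    count += 1
                        j = nxt[j]
    return count


@njit(cache=True, fastmath=True)
def forces_energies(pos, box, bonds, bond_kind, bond_k, bond_r0,
                    angles, kappa, btype, eps_t, sig_t, rc_t, sh_t,
                    pi, pj, npairs, fcap, F):
    """Fill F with forces given the current neighbour list; returns
    (status, e_bond, e_closure, e_angle, e_pair)."""
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    e_bond = 0.0
    e_clos = 0.0
    e_angle = 0.0
    e_pair = 0.0

    # ---- bonds (unwrapped: a loop-closure spring must pull its anchors
    # together in real space, not toward a periodic image) --------------
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-10:
            return STATUS_UNSTABLE, e_bond, e_clos, e_angle, e_pair
        dr = r - bond_r0[b]
        e = bond_k[b] * dr * dr
        if bond_kind[b] == 0:
            e_bond += e
        else:
            e_clos += e
        f = -2.0 * bond_k[b] * dr / r
        F[j, 0] += f * dx
        F[j, 1] += f * dy
        F[j, 2] += f * dz
        F[i, 0] -= f * dx
        F[i, 1] -= f * dy
        F[i, 2] -= f * dz

    # ---- angles (unwrapped tangents, consistent with the bonds) -------
    for a in range(angles.shape[0]):
        ia = angles[a, 0]
        ib_ = angles[a, 1]
        ic = angles[a, 2]
        t1x = pos[ib_, 0] - pos[ia, 0]
        t1y = pos[ib_, 1] - pos[ia, 1]
        t1z = pos[ib_, 2] - pos[ia, 2]
        t2x = pos[ic, 0] - pos[ib_, 0]
        t2y = pos[ic, 1] - pos[ib_, 1]
        t2z = pos[ic, 2] - pos[ib_, 2]
        n1s = t1x * t1x + t1y * t1y + t1z * t1z
        n2s = t2x * t2x + t2y * t2y + t2z * t2z
        if n1s < 1e-20 or n2s < 1e-20:
            return STATUS_UNSTABLE, e_bond, e_clos, e_angle, e_pair
        n1 = np.sqrt(n1s)
        n2 = np.sqrt(n2s)
        inv12 = 1.0 / (n1 * n2)
        cosq = (t1x * t2x + t1y * t2y + t1z * t2z) * inv12
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        e_angle += kappa * (1.0 - cosq)
        # dc/dt1 = t2/(n1 n2) - c t1/n1^2 ; dc/dt2 = t1/(n1 n2) - c t2/n2^2
        g1x = t2x * inv12 - cosq * t1x / n1s
        g1y = t2y * inv12 - cosq * t1y / n1s
        g1z = t2z * inv12 - cosq * t1z / n1s
        g2x = t1x * inv12 - cosq * t2x / n2s
        g2y = t1y * inv12 - cosq * t2y / n2s
        g2z = t1z * inv12 - cosq * t2z / n2s
        # F_a = -kappa dc/dt1 ; F_c = +kappa dc/dt2 ; F_b = the balance
        F[ia, 0] -= kappa * g1x
        F[ia, 1] -= kappa * g1y
        F[ia, 2] -= kappa * g1z
        F[ic, 0] += kappa * g2x
        F[ic, 1] += kappa * g2y
        F[ic, 2] += kappa * g2z
        F[ib_, 0] += kappa * (g1x - g2x)
        F[ib_, 1] += kappa * (g1y - g2y)
        F[ib_, 2] += kappa * (g1z - g2z)

    # ---- non-bonded pairs from the neighbour list ---------------------
    ib = 1.0 / box if box > 0.0 else 0.0
    for m in range(npairs):
        i = pi[m]
        j = pj[m]
        ti = btype[i]
        tj = btype[j]
        rc = rc_t[ti, tj]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if box > 0.0:
            dx -= box * np.floor(dx * ib + 0.5)
            dy -= box * np.floor(dy * ib + 0.5)
            dz -= box * np.floor(dz * ib + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        eps = eps_t[ti, tj]
        if eps == 0.0:
            continue
        if r2 < 1e-12:
            if fcap > 0.0:
                r2 = 1e-12  # push-off phase: tolerate overlap, cap force
            else:
                return STATUS_UNSTABLE, e_bond, e_clos, e_angle, e_pair
        sig = sig_t[ti, tj]
        s2 = sig * sig / r2
        s6 = s2 * s2 * s2
        e_pair += 4.0 * eps * (s6 * s6 - s6) + sh_t[ti, tj]
        g = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        if fcap > 0.0:
            fmag = np.abs(g) * np.sqrt(r2)
            if fmag > fcap:
                g *= fcap / fmag
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz

    return STATUS_OK, e_bond, e_clos, e_angle, e_pair


@njit(cache=True)
def energy_oneshot(pos, box, bonds, bond_kind, bond_k, bond_r0,
                   angles, kappa, btype, eps_t, sig_t, rc_t, sh_t,
                   excl, fcap, F):
    """One-shot force/energy evaluation: build a zero-skin pair list and
    evaluate.  Identical to a full O(N^2) enumeration by construction."""
    n = pos.shape[0]
    pi = np.empty(_PAIR_CAP * n, dtype=np.int64)
    pj = np.empty(_PAIR_CAP * n, dtype=np.int64)
    cnt = build_nlist(pos, box, btype, rc_t, 0.0, excl, pi, pj)
    if cnt < 0:
        return STATUS_UNSTABLE, 0.0, 0.0, 0.0, 0.0
    return forces_energies(pos, box, bonds, bond_kind, bond_k, bond_r0,
                           angles, kappa, btype, eps_t, sig_t, rc_t, sh_t,
                           pi, pj, cnt, fcap, F)


@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return m


@njit(cache=True, fastmath=True)
def run_chunk(pos, vel, F, box, bonds, bond_kind, bond_k, bond_r0,
              angles, kappa, btype, eps_t, sig_t, rc_t, sh_t, excl,
              nsteps, dt, gamma, kT, fcap, seed,
              ramp_idx, ramp_k0, ramp_k1, ramp_offset, ramp_total):
    """Advance nsteps of BAOAB Langevin dynamics in place.

    ``ramp_idx`` lists bond indices whose spring constant is linearly
    interpolated from ramp_k0 to ramp_k1 as the global step counter
    (ramp_offset + local step) runs over [0, ramp_total - 1].

    Returns (status, steps_done, e_bond, e_closure, e_angle, e_pair).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    skin = DEFAULT_SKIN
    pi = np.empty(_PAIR_CAP * n, dtype=np.int64)
    pj = np.empty(_PAIR_CAP * n, dtype=np.int64)
    ref = pos.copy()
    npair = build_nlist(pos, box, btype, rc_t, skin, excl, pi, pj)
    if npair < 0:
        return STATUS_UNSTABLE, 0, 0.0, 0.0, 0.0, 0.0
    st, eb, ec, ea, ep = forces_energies(
        pos, box, bonds, bond_kind, bond_k, bond_r0, angles, kappa,
        btype, eps_t, sig_t, rc_t, sh_t, pi, pj, npair, fcap, F)
    if st != STATUS_OK:
        return st, 0, eb, ec, ea, ep
    half = 0.5 * dt
    for step in range(nsteps):
        if ramp_total > 1:
            frac = (ramp_offset + step) / (ramp_total - 1.0)
            if frac > 1.0:
                frac = 1.0
            kval = ramp_k0 + (ramp_k1 - ramp_k0) * frac
            for m in range(ramp_idx.shape[0]):
                bond_k[ramp_idx[m]] = kval
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.normal()
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if _max_disp2(pos, ref) > 0.25 * skin * skin:
            npair = build_nlist(pos, box, btype, rc_t, skin, excl, pi, pj)
            if npair < 0:
                return STATUS_UNSTABLE, step + 1, eb, ec, ea, ep
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        st, eb, ec, ea, ep = forces_energies(
            pos, box, bonds, bond_kind, bond_k, bond_r0, angles, kappa,
            btype, eps_t, sig_t, rc_t, sh_t, pi, pj, npair, fcap, F)
        if st != STATUS_OK:
            return st, step + 1, eb, ec, ea, ep
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
        if not np.isfinite(pos[0, 0]):
            return STATUS_UNSTABLE, step + 1, eb, ec, ea, ep
    return STATUS_OK, nsteps, eb, ec, ea, ep


@njit(cache=True, inline="always")
def _other_neighbour(neigh, x, y):
    if neigh[x, 0] == y:
        return neigh[x, 1]
    return neigh[x, 0]


@njit(cache=True)
def swap_delta_u(pos, box, i, i1, j, j1, neigh, kappa, k_harm, r0,
                 btype, eps_t, sig_t, rc_t, sh_t):
    """Local energy change of the reconnection that removes bonds
    (i, i1) and (j, j1) and creates (i, j) and (i1, j1).

    Only the interactions whose term set changes are evaluated: the four
    bond lengths, the bending triplets centred on the four endpoints,
    and the four pairs whose exclusion status flips.  Returns
    (delta_U, delta_U_angle).
    """
    # bonds
    d_new1 = np.sqrt(_dist2(pos, box, i, j))
    d_new2 = np.sqrt(_dist2(pos, box, i1, j1))
    d_old1 = np.sqrt(_dist2(pos, box, i, i1))
    d_old2 = np.sqrt(_dist2(pos, box, j, j1))
    du_bond = (k_harm * (d_new1 - r0) ** 2 + k_harm * (d_new2 - r0) ** 2
               - k_harm * (d_old1 - r0) ** 2 - k_harm * (d_old2 - r0) ** 2)

    # angles: triplets centred on i, i1, j, j1
    oi = _other_neighbour(neigh, i, i1)
    oi1 = _other_neighbour(neigh, i1, i)
    oj = _other_neighbour(neigh, j, j1)
    oj1 = _other_neighbour(neigh, j1, j)
    ua_before = 0.0
    if oi >= 0:
        ua_before += _angle_e(pos, box, oi, i, i1, kappa)
    if oi1 >= 0:
        ua_before += _angle_e(pos, box, i, i1, oi1, kappa)
    if oj >= 0:
        ua_before += _angle_e(pos, box, oj, j, j1, kappa)
    if oj1 >= 0:
        ua_before += _angle_e(pos, box, j, j1, oj1, kappa)
    ua_after = 0.0
    if oi >= 0:
        ua_after += _angle_e(pos, box, oi, i, j, kappa)
    if oi1 >= 0:
        ua_after += _angle_e(pos, box, oi1, i1, j1, kappa)
    if oj >= 0:
        ua_after += _angle_e(pos, box, oj, j, i, kappa)
    if oj1 >= 0:
        ua_after += _angle_e(pos, box, oj1, j1, i1, kappa)
    du_angle = ua_after - ua_before

    # pairs whose exclusion flips
    du_pair = (_pair_e(pos, box, i, i1, btype, eps_t, sig_t, rc_t, sh_t)
               + _pair_e(pos, box, j, j1, btype, eps_t, sig_t, rc_t, sh_t)
               - _pair_e(pos, box, i, j, btype, eps_t, sig_t, rc_t, sh_t)
               - _pair_e(pos, box, i1, j1, btype, eps_t, sig_t, rc_t, sh_t))

    return du_bond + du_angle + du_pair, du_angle


@njit(cache=True)
def scan_candidates(pos, box, sub_bonds, vir_bonds, vir_idx, Rc, out):
    """Fill ``out`` with (sub_bond_index, viral_bond_index) pairs whose
    beads admit a reconnection with both new-bond endpoints within Rc
    (in either of the two re-bonding orientations).  Returns the count.
    """
    rc2 = Rc * Rc
    # viral bounding sphere for a cheap pre-filter
    cx = 0.0
    cy = 0.0
    cz = 0.0
    nv = vir_idx.shape[0]
    for m in range(nv):
        v = vir_idx[m]
        cx += pos[v, 0]
        cy += pos[v, 1]
        cz += pos[v, 2]
    cx /= nv
    cy /= nv
    cz /= nv
    rad2 = 0.0
    for m in range(nv):
        v = vir_idx[m]
        dx = pos[v, 0] - cx
        dy = pos[v, 1] - cy
        dz = pos[v, 2] - cz
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > rad2:
            rad2 = d2
    reach = np.sqrt(rad2) + Rc + 0.5
    reach2 = reach * reach
    count = 0
    for sb in range(sub_bonds.shape[0]):
        i = sub_bonds[sb, 0]
        i1 = sub_bonds[sb, 1]
        dx = _mi(pos[i, 0] - cx, box)
        dy = _mi(pos[i, 1] - cy, box)
        dz = _mi(pos[i, 2] - cz, box)
        if dx * dx + dy * dy + dz * dz > reach2:
            dx = _mi(pos[i1, 0] - cx, box)
            dy = _mi(pos[i1, 1] - cy, box)
            dz = _mi(pos[i1, 2] - cz, box)
            if dx * dx + dy * dy + dz * dz > reach2:
                continue
        for vb in range(vir_bonds.shape[0]):
            j = vir_bonds[vb, 0]
            j1 = vir_bonds[vb, 1]
            okA = (_dist2(pos, box, i, j) < rc2
                   and _dist2(pos, box, i1, j1) < rc2)
            okB = (_dist2(pos, box, i, j1) < rc2
                   and _dist2(pos, box, i1, j) < rc2)
            if okA or okB:
                out[count, 0] = sb
                out[count, 1] = vb
                count += 1
    return count


@njit(cache=True)
def resolve_orientation(pos, box, i, i1, j, j1, Rc):
    """Pick the re-bonding orientation.

    Orientation A creates (i,j),(i1,j1); B creates (i,j1),(i1,j).  Among
    the orientations whose both new bonds are shorter than Rc, the one
    with the smaller summed new-bond length wins; exact ties fall to a
    coin flip.  Returns 0 for A, 1 for B, -1 if neither is admissible.
    """
    dA1 = np.sqrt(_dist2(pos, box, i, j))
    dA2 = np.sqrt(_dist2(pos, box, i1, j1))
    dB1 = np.sqrt(_dist2(pos, box, i, j1))
    dB2 = np.sqrt(_dist2(pos, box, i1, j))
    okA = dA1 < Rc and dA2 < Rc
    okB = dB1 < Rc and dB2 < Rc
    if okA and okB:
        sA = dA1 + dA2
        sB = dB1 + dB2
        if sA < sB:
            return 0
        if sB < sA:
            return 1
        return 0 if np.random.random() < 0.5 else 1
    if okA:
        return 0
    if okB:
        return 1
    return -1


@njit(cache=True, fastmath=True)
def run_production(pos, vel, F, box, bonds, bond_kind, bond_k, bond_r0,
                   angles, kappa, btype, eps_t, sig_t, rc_t, sh_t, excl,
                   nsteps, dt, gamma, kT, seed,
                   sub_bonds, vir_bonds, vir_idx, neigh,
                   Rc, attempt_every, bypass, k_harm, r0,
                   event_out):
    """Production dynamics with reconnection attempts every
    ``attempt_every`` steps.

    On the first accepted reconnection the kernel stops and fills
    ``event_out`` = [step, i, i1, j, j1, dU, dU_angle]; the topology
    mutation itself is applied by the caller.  Returns
    (status, steps_done) with status STATUS_INTEGRATED on success,
    STATUS_OK on timeout.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    skin = DEFAULT_SKIN
    pi = np.empty(_PAIR_CAP * n, dtype=np.int64)
    pj = np.empty(_PAIR_CAP * n, dtype=np.int64)
    ref = pos.copy()
    npair = build_nlist(pos, box, btype, rc_t, skin, excl, pi, pj)
    if npair < 0:
        return STATUS_UNSTABLE, 0
    cand = np.empty((sub_bonds.shape[0] * vir_bonds.shape[0], 2),
                    dtype=np.int64)
    st, eb, ec, ea, ep = forces_energies(
        pos, box, bonds, bond_kind, bond_k, bond_r0, angles, kappa,
        btype, eps_t, sig_t, rc_t, sh_t, pi, pj, npair, 0.0, F)
    if st != STATUS_OK:
        return st, 0
    half = 0.5 * dt
    for step in range(nsteps):
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.normal()
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if _max_disp2(pos, ref) > 0.25 * skin * skin:
            npair = build_nlist(pos, box, btype, rc_t, skin, excl, pi, pj)
            if npair < 0:
                return STATUS_UNSTABLE, step + 1
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        st, eb, ec, ea, ep = forces_energies(
            pos, box, bonds, bond_kind, bond_k, bond_r0, angles, kappa,
            btype, eps_t, sig_t, rc_t, sh_t, pi, pj, npair, 0.0, F)
        if st != STATUS_OK:
            return st, step + 1
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
        if not np.isfinite(pos[0, 0]):
            return STATUS_UNSTABLE, step + 1

        if (step + 1) % attempt_every != 0:
            continue
        ncand = scan_candidates(pos, box, sub_bonds, vir_bonds, vir_idx,
                                Rc, cand)
        if ncand == 0:
            continue
        # Fisher-Yates shuffle to remove index bias
        for m in range(ncand - 1, 0, -1):
            w = np.random.randint(0, m + 1)
            t0 = cand[m, 0]
            t1 = cand[m, 1]
            cand[m, 0] = cand[w, 0]
            cand[m, 1] = cand[w, 1]
            cand[w, 0] = t0
            cand[w, 1] = t1
        for m in range(ncand):
            sb = cand[m, 0]
            vb = cand[m, 1]
            i = sub_bonds[sb, 0]
            i1 = sub_bonds[sb, 1]
            j = vir_bonds[vb, 0]
            j1 = vir_bonds[vb, 1]
            orient = resolve_orientation(pos, box, i, i1, j, j1, Rc)
            if orient < 0:
                continue
            if orient == 1:
                j, j1 = j1, j
            dU, dUa = swap_delta_u(pos, box, i, i1, j, j1, neigh, kappa,
                                   k_harm, r0, btype, eps_t, sig_t,
                                   rc_t, sh_t)
            if bypass == 1 or dU < 0.0 or np.random.random() < np.exp(-dU):
                event_out[0] = float(step + 1)
                event_out[1] = float(i)
                event_out[2] = float(i1)
                event_out[3] = float(j)
                event_out[4] = float(j1)
                event_out[5] = dU
                event_out[6] = dUa
                return STATUS_INTEGRATED, step + 1
    return STATUS_OK, nsteps
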