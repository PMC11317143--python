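"""Independent brute-force oracles used across the test suite.

Everything here is written directly from the model definitions in pure
Python/NumPy, independent of the compiled kernels it checks.
"""

from __future__ import annotations

import numpy as np

from loopcat.units import BeadType, BondKind, derive_angles

WCA_CUT = 2.0 ** (1.0 / 6.0)


def mi(d, box):
    if box > 0:
        return d - box * np.floor(d / box + 0.5)
    return d


def brute_total_energy(system, topology, ff):
    """O(N^2) all-pairs + all-bonds + all-angles energy sum."""
    pos = system.positions
    box = system.box_side
    eps_t, sig_t, rc_t, sh_t = ff.tables()
    e_bond = e_clos = e_angle = e_pair = 0.0
    bonded = {(min(i, j), max(i, j)) for i, j, _ in topology.bonds()}
    topology.refresh()
    for b in range(len(topology.bond_pairs)):
        i, j = topology.bond_pairs[b]
        r = np.linalg.norm(pos[j] - pos[i])  # bonds are unwrapped
        e = topology.bond_k[b] * (r - topology.bond_r0[b]) ** 2
        if topology.bond_kind[b] == int(BondKind.BACKBONE):
            e_bond += e
        else:
            e_clos += e
    for a, b, c in derive_angles(topology):
        t1 = pos[b] - pos[a]
        t2 = pos[c] - pos[b]
        cosq = np.dot(t1, t2) / (np.linalg.norm(t1) * np.linalg.norm(t2))
        e_angle += ff.kappa * (1.0 - np.clip(cosq, -1, 1))
    n = system.n_particles
    bt = system.btype
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            r = np.linalg.norm(mi(pos[j] - pos[i], box))
            ti, tj = bt[i], bt[j]
            rc = rc_t[ti, tj]
            if r >= rc:
                continue
            eps, sig = eps_t[ti, tj], sig_t[ti, tj]
            if eps == 0:
                continue
            sr6 = (sig / r) ** 6
            e_pair += 4 * eps * (sr6**2 - sr6) + sh_t[ti, tj]
    return {"bond": e_bond, "closure": e_clos, "angle": e_angle,
            "pair": e_pair,
            "total": e_bond + e_clos + e_angle + e_pair}


def brute_candidates(system, topology, R_c):
    """Exhaustive O(B^2) scan for admissible inter-chain bond pairs."""
    from loopcat.units import Species
    pos = system.positions
    box = system.box_side
    sp = system.species
    bb = topology.backbone_bonds()
    subs = [tuple(b) for b in bb
            if sp[b[0]] == int(Species.DNA) and sp[b[1]] == int(Species.DNA)]
    virs = [tuple(b) for b in bb
            if sp[b[0]] == int(Species.VIRAL_DNA)
            and sp[b[1]] == int(Species.VIRAL_DNA)]
    out = []
    for (i, i1) in subs:
        for (j, j1) in virs:
            dA = (np.linalg.norm(mi(pos[j] - pos[i], box)) < R_c
                  and np.linalg.norm(mi(pos[j1] - pos[i1], box)) < R_c)
            dB = (np.linalg.norm(mi(pos[j1] - pos[i], box)) < R_c
                  and np.linalg.norm(mi(pos[j] - pos[i1], box)) < R_c)
            if dA or dB:
                out.append(((i, i1), (j, j1)))
    return out


def random_contact_system(rng, n_sub=8, n_vir=4, jitter=0.35, box=60.0):
    """Small random substrate + viral ring in guaranteed contact, for
    swap-energy oracle tests."""
    from loopcat.fixtures import make_contact_pose
    system, topo = make_contact_pose(n_sub, n_vir, gap=rng.uniform(0.3, 1.2),
                                     box=box)
    system.positions += rng.normal(0.0, jitter, system.positions.shape)
    return system, topo
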