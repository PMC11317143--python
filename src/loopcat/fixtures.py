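"""Deterministic small fixtures and statistical generators.

These build in well under a second each and are used both by the test
suite and by the ``loopcat fixtures`` CLI subcommand, e.g. the regular
polygon whose Kratky-Porod bending sum has the closed continuum limit
2 pi^2 l_p / contour.
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceFieldParams
from .moves import IntegrationEvent
from .units import BeadType, BondKind, ParticleSystem, Topology

__all__ = ["make_polygon_loop", "make_contact_pose",
           "sample_events_from_profile"]


def make_polygon_loop(n_beads: int, radius: float | None = None,
                      box: float = 1e4,
                      ff: ForceFieldParams | None = None):
    """Regular n-gon ring with unit-spaced beads.

    Its total bending energy is exactly n (l_p/sigma)(1 - cos(2 pi / n)),
    which tends to 2 pi^2 l_p / contour for large n.
    """
    if n_beads < 3:
        raise ValueError("a ring needs at least 3 beads")
    if ff is None:
        ff = ForceFieldParams()
    if radius is None:
        radius = 1.0 / (2.0 * np.sin(np.pi / n_beads))  # unit side
    theta = 2.0 * np.pi * np.arange(n_beads) / n_beads
    pos = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                    np.zeros(n_beads)], axis=1) + box / 2.0
    side = 2.0 * radius * np.sin(np.pi / n_beads)
    system = ParticleSystem(pos, np.zeros_like(pos),
                            np.full(n_beads, int(BeadType.DNA)),
                            np.zeros(n_beads, dtype=np.int64), box)
    topo = Topology(n_beads)
    for m in range(n_beads):
        topo.add_bond(m, (m + 1) % n_beads, BondKind.BACKBONE,
                      ff.k_harm, side)
    return system, topo


def make_contact_pose(n_substrate: int, n_viral: int, gap: float,
                      contact_bond: int | None = None, box: float = 1e3,
                      ff: ForceFieldParams | None = None):
    """Straight substrate along x plus a viral ring held at a controlled
    minimal distance ``gap`` above the midpoint of one substrate bond,
    guaranteeing a hand-enumerable candidate list."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if ff is None:
        ff = ForceFieldParams()
    step = ff.r0
    sub = np.zeros((n_substrate, 3))
    sub[:, 0] = step * np.arange(n_substrate)
    sub += box / 2.0
    if contact_bond is None:
        contact_bond = (n_substrate - 1) // 2
    mid = 0.5 * (sub[contact_bond] + sub[contact_bond + 1])
    R = step / (2.0 * np.sin(np.pi / n_viral))
    theta = 2.0 * np.pi * np.arange(n_viral) / n_viral
    # ring in the xz-plane, centred in x over the bond midpoint, lowest
    # bead exactly `gap` above it
    ring = np.stack([R * np.sin(theta), np.zeros(n_viral),
                     R * (1.0 - np.cos(theta))], axis=1)
    ring[:, 0] += mid[0]
    ring[:, 1] = mid[1]
    ring[:, 2] += mid[2] + gap - ring[:, 2].min()
    pos = np.vstack([sub, ring])
    btype = np.concatenate([np.full(n_substrate, int(BeadType.DNA)),
                            np.full(n_viral, int(BeadType.VIRAL))])
    chain = np.concatenate([np.zeros(n_substrate, dtype=np.int64),
                            np.ones(n_viral, dtype=np.int64)])
    system = ParticleSystem(pos, np.zeros_like(pos), btype, chain, box)
    topo = Topology(n_substrate + n_viral)
    for i in range(n_substrate - 1):
        topo.add_bond(i, i + 1, BondKind.BACKBONE, ff.k_harm, ff.r0)
    for m in range(n_viral):
        topo.add_bond(n_substrate + m, n_substrate + (m + 1) % n_viral,
                      BondKind.BACKBONE, ff.k_harm, ff.r0)
    return system, topo


def sample_events_from_profile(p_x: np.ndarray, n: int,
                               rng: np.random.Generator) -> list[IntegrationEvent]:
    """Multinomial sampler of integration events from a site profile,
    for testing the histogram/statistics pipeline without dynamics."""
    p_x = np.asarray(p_x, dtype=float)
    if abs(p_x.sum() - 1.0) > 1e-9 or np.any(p_x < 0):
        raise ValueError("p_x must be a normalized probability vector")
    counts = rng.multinomial(n, p_x)
    events = []
    for site, c in enumerate(counts):
        events.extend(IntegrationEvent(step=0, site=site, in_loop=False,
                                       delta_U=0.0, delta_U_angle=0.0)
                      for _ in range(c))
    return events
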