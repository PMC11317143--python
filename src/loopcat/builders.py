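"""Synthetic-configuration builders for every simulated experiment:
single-loop and multi-loop naked-DNA substrates, chromatinized fibres
with nucleosome core particles, the circular viral element, and the
facilitated-diffusion variant.

All builders are deterministic given (spec, seed), initialize the
substrate as a self-avoiding-adjusted random walk with fixed bond step
1.1 sigma, and place the viral ring uniformly in the box without
overlaps.  The default box gives a bead volume fraction of about 1%
(dilute); note that the loop-finding rate scales like loop-length/volume,
so absolute integration rates are box dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceFieldParams
from .units import (BeadType, BondKind, ParticleSystem, Topology,
                    TopologyError)

__all__ = [
    "LoopSpec",
    "ChromatinSpec",
    "build_single_loop_system",
    "build_multiloop_system",
    "build_chromatin_system",
    "enable_facilitated_diffusion",
    "default_box_side",
    "DEFAULT_VIRAL_LEN",
]

# viral ring default: 20 beads ~ 147 bp, the nucleosomal-block scale
DEFAULT_VIRAL_LEN = 20
STEP = 1.1           # random-walk / ring bond step, sigma
MIN_SEP = 0.8        # overlap threshold at placement, sigma


@dataclass(frozen=True)
class LoopSpec:
    """A loop stabilized by a harmonic bridge between two anchors."""

    anchor_lo: int
    anchor_hi: int
    spring_k_final: float = 20.0

    def __post_init__(self) -> None:
        if not (0 <= self.anchor_lo < self.anchor_hi):
            raise ValueError("need 0 <= anchor_lo < anchor_hi")
        if self.length_beads < 3:
            raise ValueError("loop must span at least 3 beads")

    @property
    def length_beads(self) -> int:
        return self.anchor_hi - self.anchor_lo


@dataclass(frozen=True)
class ChromatinSpec:
    """Layout of a chromatinized fibre: nucleosomal-DNA blocks separated
    by linkers, plus free NCP spheres that self-assemble onto the blocks."""

    n_ncp: int = 30
    block_beads: int = 20     # nucleosomal DNA per block (~147 bp)
    linker_beads: int = 10    # linker DNA (~74 bp)
    ncp_diameter: float = 3.0
    ncp_dna_eps: float = 4.0
    loop_region: tuple[LoopSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_ncp < 1 or self.block_beads < 1 or self.linker_beads < 0:
            raise ValueError("infeasible chromatin spec")

    @property
    def n_dna_beads(self) -> int:
        return self.linker_beads + self.n_ncp * (self.block_beads
                                                 + self.linker_beads)


def default_box_side(n_beads: int, volume_fraction: float = 0.01,
                     ncp_count: int = 0, ncp_diameter: float = 3.0) -> float:
    """Box side giving the requested bead volume fraction."""
    vol = n_beads * np.pi / 6.0 + ncp_count * np.pi / 6.0 * ncp_diameter**3
    return float((vol / volume_fraction) ** (1.0 / 3.0))


def _kp_cos(rng: np.random.Generator, kappa: float) -> float:
    """Exact draw of cos(theta) from the Kratky-Porod Boltzmann weight
    exp(kappa cos theta) on [-1, 1]."""
    u = rng.random()
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def _rotate_towards(t: np.ndarray, cos_theta: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit vector at angle arccos(cos_theta) from t, uniform azimuth."""
    perp = np.cross(t, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta**2))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    out = (cos_theta * t
           + sin_theta * (np.cos(phi) * perp
                          + np.sin(phi) * np.cross(t, perp)))
    return out / np.linalg.norm(out)


def _random_walk(n: int, rng: np.random.Generator, start: np.ndarray,
                 loops=(), persistence: float = 20.0,
                 window: int = 40, tries: int = 30) -> np.ndarray:
    """Fixed-step persistent (worm-like) random walk with loops
    pre-folded as regular polygons.

    Step directions carry the chain's own persistence so fresh systems
    start near conformational equilibrium; looped segments are laid out
    as closed polygons in a random plane, so their closure pairs start
    at bonding distance and the anchor springs only have to hold them.
    Steps landing within MIN_SEP of the last ``window`` beads are
    re-drawn (best effort; the push-off phase removes residual overlap).
    """
    pos = np.empty((n, 3))
    pos[0] = start
    t = rng.normal(size=3)
    t /= np.linalg.norm(t)
    loop_start = {lp.anchor_lo: lp.anchor_hi for lp in loops}
    i = 1
    while i < n:
        if (i - 1) in loop_start and loop_start[i - 1] < n:
            hi = loop_start[i - 1]
            n_side = hi - (i - 1) + 1     # polygon sides incl. closure
            R = STEP / (2.0 * np.sin(np.pi / n_side))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            u = np.cross(axis, rng.normal(size=3))
            u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            centre = pos[i - 1] + R * u
            for k in range(1, n_side):
                ang = 2.0 * np.pi * k / n_side
                pos[i - 1 + k] = (centre
                                  - R * (np.cos(ang) * u - np.sin(ang) * v))
            t = pos[hi] - pos[hi - 1]
            t /= np.linalg.norm(t)
            i = hi + 1
            continue
        best = None
        for _ in range(tries):
            cand_t = _rotate_towards(t, _kp_cos(rng, persistence), rng)
            cand = pos[i - 1] + STEP * cand_t
            lo = max(0, i - window)
            d2 = (np.sum((pos[lo:i - 1] - cand) ** 2, axis=1)
                  if i - 1 > lo else np.empty(0))
            best = (cand, cand_t)
            if d2.size == 0 or d2.min() >= MIN_SEP**2:
                break
        pos[i], t = best
        i += 1
    return pos


def _ring_positions(m: int, rng: np.random.Generator,
                    center: np.ndarray) -> np.ndarray:
    """Regular m-gon of side STEP with a random orientation."""
    R = STEP / (2.0 * np.sin(np.pi / m))
    theta = 2.0 * np.pi * np.arange(m) / m
    ring = np.stack([R * np.cos(theta), R * np.sin(theta),
                     np.zeros(m)], axis=1)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return ring @ q.T + center


def _place_ring(m: int, other: np.ndarray, box: float,
                rng: np.random.Generator, max_tries: int = 2000) -> np.ndarray:
    for _ in range(max_tries):
        center = rng.uniform(0.0, box, size=3)
        ring = _ring_positions(m, rng, center)
        d = _min_image_dists(ring, other, box)
        if d.min() >= MIN_SEP:
            return ring
    raise ValueError("box too small: could not place viral ring "
                     "without overlap")


def _min_image_dists(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.floor(d / box + 0.5)
    return np.sqrt(np.sum(d * d, axis=2)).ravel()


def _assemble(sub_pos, sub_types, loops, viral_len, box, rng,
              ff: ForceFieldParams, extra_pos=None, extra_types=None):
    n_sub = len(sub_pos)
    parts = [sub_pos]
    types = [np.asarray(sub_types, dtype=np.int64)]
    chains = [np.zeros(n_sub, dtype=np.int64)]
    if viral_len:
        ring = _place_ring(viral_len, sub_pos, box, rng)
        parts.append(ring)
        types.append(np.full(viral_len, int(BeadType.VIRAL), dtype=np.int64))
        chains.append(np.ones(viral_len, dtype=np.int64))
    if extra_pos is not None:
        parts.append(extra_pos)
        types.append(extra_types)
        chains.append(np.arange(len(extra_pos), dtype=np.int64) + 2)
    positions = np.vstack(parts)
    btype = np.concatenate(types)
    chain_id = np.concatenate(chains)
    system = ParticleSystem(positions, np.zeros_like(positions),
                            btype, chain_id, box)
    topo = Topology(len(positions))
    for i in range(n_sub - 1):
        topo.add_bond(i, i + 1, BondKind.BACKBONE, ff.k_harm, ff.r0)
    if viral_len:
        for m in range(viral_len):
            topo.add_bond(n_sub + m, n_sub + (m + 1) % viral_len,
                          BondKind.BACKBONE, ff.k_harm, ff.r0)
    for lp in loops:
        if lp.anchor_hi >= n_sub:
            raise ValueError("loop extends beyond the substrate")
        # added at stiffness 0; ramped to spring_k_final during equilibration
        topo.add_bond(lp.anchor_lo, lp.anchor_hi, BondKind.LOOP_CLOSURE,
                      0.0, ff.r0)
    return system, topo


def build_single_loop_system(N: int, loop: LoopSpec | None,
                             viral_len: int = DEFAULT_VIRAL_LEN,
                             box: float | None = None,
                             rng: np.random.Generator | None = None,
                             ff: ForceFieldParams | None = None):
    """Linear substrate of N beads with an optional single stabilized
    loop, plus a circular viral element.  ``loop=None`` builds the
    loop-free null substrate."""
    if rng is None:
        rng = np.random.default_rng(0)
    if ff is None:
        ff = ForceFieldParams()
    if box is None:
        box = default_box_side(N + viral_len)
    start = np.full(3, box / 2.0)
    loops = (loop,) if loop is not None else ()
    sub = _random_walk(N, rng, start, loops=loops, persistence=ff.l_p)
    types = np.full(N, int(BeadType.DNA))
    return _assemble(sub, types, loops, viral_len, box, rng, ff)


def multiloop_anchors(N: int, n_loops: int, loop_len: int,
                      mode: str, gap_beads: int = 2) -> list[LoopSpec]:
    """Deterministic anchor layout.

    sparse: loop starts evenly spaced over [0, N-1-loop_len];
    clustered: loops packed contiguously (gap_beads apart) in the chain
    centre.  A single loop gives the identical central layout in both
    modes.
    """
    if mode not in ("sparse", "clustered"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    if n_loops == 1:
        start = (N - 1 - loop_len) // 2
        if start < 0:
            raise ValueError("infeasible packing")
        return [LoopSpec(start, start + loop_len)]
    if mode == "sparse":
        span = N - 1 - loop_len
        if n_loops * loop_len > span:
            raise ValueError("infeasible packing")
        # cell-centred even spacing: loops sit in the chain interior,
        # where they act as flexibility kinks, not at the ends
        starts = [round((2 * k + 1) * span / (2 * n_loops))
                  for k in range(n_loops)]
    else:
        total = n_loops * loop_len + (n_loops - 1) * gap_beads
        s0 = (N - 1 - total) // 2
        if s0 < 0:
            raise ValueError("infeasible packing")
        starts = [s0 + k * (loop_len + gap_beads) for k in range(n_loops)]
    specs = [LoopSpec(s, s + loop_len) for s in starts]
    for a, b in zip(specs, specs[1:]):
        if b.anchor_lo < a.anchor_hi:
            raise ValueError("infeasible packing: overlapping loops")
    return specs


def build_multiloop_system(N: int, n_loops: int, loop_len: int,
                           mode: str, gap_beads: int = 2,
                           viral_len: int = DEFAULT_VIRAL_LEN,
                           box: float | None = None,
                           rng: np.random.Generator | None = None,
                           ff: ForceFieldParams | None = None):
    """Substrate with n_loops equal loops in a sparse or clustered 1D
    arrangement; the two modes differ only in anchor placement."""
    if rng is None:
        rng = np.random.default_rng(0)
    if ff is None:
        ff = ForceFieldParams()
    if box is None:
        box = default_box_side(N + viral_len)
    loops = multiloop_anchors(N, n_loops, loop_len, mode, gap_beads)
    start = np.full(3, box / 2.0)
    sub = _random_walk(N, rng, start, loops=loops, persistence=ff.l_p)
    types = np.full(N, int(BeadType.DNA))
    system, topo = _assemble(sub, types, loops, viral_len, box, rng, ff)
    return system, topo, loops


def build_chromatin_system(spec: ChromatinSpec,
                           viral_len: int = DEFAULT_VIRAL_LEN,
                           box: float | None = None,
                           rng: np.random.Generator | None = None,
                           ff: ForceFieldParams | None = None):
    """Chromatinized fibre: DNA with species-tagged nucleosomal blocks
    alternating with linkers, free NCP spheres attracted only to the
    blocks, and an optional looped region."""
    if rng is None:
        rng = np.random.default_rng(0)
    if ff is None:
        ff = ForceFieldParams(ncp_diameter=spec.ncp_diameter,
                              eps_attr=spec.ncp_dna_eps)
    N = spec.n_dna_beads
    if box is None:
        box = default_box_side(N + viral_len, ncp_count=spec.n_ncp,
                               ncp_diameter=spec.ncp_diameter)
    types = np.full(N, int(BeadType.DNA))
    pos_cursor = spec.linker_beads
    for _ in range(spec.n_ncp):
        types[pos_cursor:pos_cursor + spec.block_beads] = int(BeadType.NUC_DNA)
        pos_cursor += spec.block_beads + spec.linker_beads
    start = np.full(3, box / 2.0)
    sub = _random_walk(N, rng, start, loops=spec.loop_region,
                       persistence=ff.l_p)
    # NCPs: random non-overlapping placement
    ncp_pos = []
    placed = sub
    for _ in range(spec.n_ncp):
        for _ in range(500):
            c = rng.uniform(0.0, box, size=3)
            d = _min_image_dists(c[None, :], placed, box)
            ok = d.min() >= MIN_SEP * 0.5 * (1.0 + spec.ncp_diameter)
            if ok and ncp_pos:
                dn = _min_image_dists(c[None, :], np.array(ncp_pos), box)
                ok = dn.min() >= MIN_SEP * spec.ncp_diameter
            if ok:
                ncp_pos.append(c)
                break
        else:
            raise ValueError("box too small: could not place NCPs")
    ncp_pos = np.array(ncp_pos)
    ncp_types = np.full(spec.n_ncp, int(BeadType.NCP), dtype=np.int64)
    system, topo = _assemble(sub, types, spec.loop_region, viral_len, box,
                             rng, ff, extra_pos=ncp_pos,
                             extra_types=ncp_types)
    return system, topo


def enable_facilitated_diffusion(system: ParticleSystem,
                                 bead: int | None = None) -> ParticleSystem:
    """Designate exactly one viral bead as the sticky intasome-like bead
    (attractive toward all substrate DNA).  Idempotent."""
    viral = np.nonzero((system.btype == int(BeadType.VIRAL))
                       | (system.btype == int(BeadType.VIRAL_STICKY)))[0]
    if len(viral) == 0:
        raise ValueError("system has no viral chain")
    if np.any(system.btype == int(BeadType.VIRAL_STICKY)):
        return system
    if bead is None:
        bead = int(viral[0])
    if system.btype[bead] != int(BeadType.VIRAL):
        raise ValueError(f"bead {bead} is not a viral bead")
    system.btype[bead] = int(BeadType.VIRAL_STICKY)
    return system
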