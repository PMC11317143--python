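"""Inter-chain bond-reconnection ("double-bridging") moves.

Integration of the circular viral polymer into the linear substrate is
modelled as a bond swap: a substrate backbone bond (i, i+1) and a viral
ring bond (j, j+1) are removed and two inter-chain bonds are created,
splicing the opened ring into the substrate as a single linear chain.
Candidates are bond pairs whose beads are mutually closer than the
capture radius R_c; only inter-chain swaps are allowed (self-reconnection
is forbidden) and loop-closure springs never participate.

Each proposal is weighted by a Metropolis test on the full local energy
change (bond stretching, bending and the pair interactions whose
exclusion status flips); the non-equilibrium "bypass" mode accepts every
geometrically admissible proposal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams
from .units import BondKind, ParticleSystem, Species, Topology

__all__ = [
    "MoveParams",
    "IntegrationEvent",
    "find_candidates",
    "propose_swap",
    "apply_swap",
    "metropolis_accept",
    "acceptance_probability",
    "attempt_sweep",
]


@dataclass
class MoveParams:
    R_c: float = 2.0              # capture radius, sigma
    attempt_every: int = 1        # steps between attempt sweeps
    mode: str = "equilibrium"     # "equilibrium" | "bypass"
    allow_intra: bool = False     # fixed False: inter-chain only
    halt_on_integration: bool = True

    def __post_init__(self) -> None:
        if self.R_c <= 0:
            raise ValueError("R_c must be positive")
        if self.attempt_every < 1:
            raise ValueError("attempt_every must be >= 1")
        if self.mode not in ("equilibrium", "bypass"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.allow_intra:
            raise ValueError("intra-chain reconnections are not supported")


@dataclass
class IntegrationEvent:
    """One recorded integration: when, where, and at what energy cost."""

    step: int              # timestep index of the accepted swap
    site: int              # substrate bead index on the low side of the broken bond
    in_loop: bool
    delta_U: float         # full accepted energy change, kBT
    delta_U_angle: float   # angular component, kBT


def _chain_bonds(system: ParticleSystem, topology: Topology,
                 species: Species) -> np.ndarray:
    """Backbone bonds both of whose beads belong to the given species."""
    topology.refresh()
    sp = system.species
    bb = topology.backbone_bonds()
    mask = (sp[bb[:, 0]] == int(species)) & (sp[bb[:, 1]] == int(species))
    return bb[mask]


def find_candidates(system: ParticleSystem, topology: Topology,
                    move_params: MoveParams) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All (substrate bond, viral bond) pairs admitting a swap whose new
    bonds' endpoints are both within R_c, in either orientation.

    Loop-closure bonds and intra-chain pairs are never candidates.
    """
    sub = _chain_bonds(system, topology, Species.DNA)
    vir = _chain_bonds(system, topology, Species.VIRAL_DNA)
    if len(sub) == 0 or len(vir) == 0:
        return []
    vir_idx = np.unique(vir)
    out = np.empty((len(sub) * len(vir), 2), dtype=np.int64)
    n = _kernels.scan_candidates(system.positions, system.box_side,
                                 sub, vir, vir_idx, move_params.R_c, out)
    return [(tuple(sub[out[m, 0]]), tuple(vir[out[m, 1]]))
            for m in range(n)]


def propose_swap(candidate, system: ParticleSystem, topology: Topology,
                 ff_params: ForceFieldParams,
                 rng: np.random.Generator | None = None,
                 R_c: float = 2.0):
    """Resolve the orientation of a candidate and compute its local
    energy change.

    Returns (new_topology, delta_U, delta_U_angle, resolved) where
    ``resolved`` = (i, i1, j, j1): removed bonds (i, i1) and (j, j1),
    created bonds (i, j) and (i1, j1).  The orientation minimizing the
    summed new-bond length among the admissible ones is chosen; ties
    break by coin flip.  Raises ValueError for an inadmissible candidate.
    """
    (i, i1), (j, j1) = candidate
    if rng is not None:
        np.random.seed(int(rng.integers(1, 2**31 - 1)))
    orient = _kernels.resolve_orientation(
        system.positions, system.box_side, i, i1, j, j1, float(R_c))
    if orient < 0:
        raise ValueError("candidate does not admit a swap within R_c")
    if orient == 1:
        j, j1 = j1, j
    topology.refresh()
    eps, sig, rc, sh = ff_params.tables()
    dU, dUa = _kernels.swap_delta_u(
        system.positions, system.box_side, i, i1, j, j1,
        topology.neighbours, ff_params.kappa, ff_params.k_harm,
        ff_params.r0, system.btype, eps, sig, rc, sh)
    new_topology = topology.copy()
    _do_swap(new_topology, i, i1, j, j1, ff_params)
    _audit_swap(system, new_topology, (i, i1, j, j1))
    return new_topology, float(dU), float(dUa), (i, i1, j, j1)


def _do_swap(topology: Topology, i: int, i1: int, j: int, j1: int,
             ff_params: ForceFieldParams) -> None:
    topology.remove_bond(i, i1)
    topology.remove_bond(j, j1)
    topology.add_bond(i, j, BondKind.BACKBONE, ff_params.k_harm, ff_params.r0)
    topology.add_bond(i1, j1, BondKind.BACKBONE, ff_params.k_harm, ff_params.r0)


def apply_swap(system: ParticleSystem, topology: Topology,
               resolved: tuple[int, int, int, int],
               ff_params: ForceFieldParams) -> None:
    """Mutate the topology with an accepted swap, merge the chain ids and
    remap the viral chain by the image vector of the contact so the new
    bonds are short in unwrapped coordinates."""
    i, i1, j, j1 = resolved
    _audit_swap_pre(system, resolved)
    box = system.box_side
    vir_mask = system.chain_id == system.chain_id[j]
    shift = box * np.floor((system.positions[j] - system.positions[i]) / box + 0.5)
    system.positions[vir_mask] -= shift
    _do_swap(topology, i, i1, j, j1, ff_params)
    system.chain_id[vir_mask] = system.chain_id[i]
    _audit_swap(system, topology, resolved)


def _audit_swap_pre(system: ParticleSystem, resolved) -> None:
    i, i1, j, j1 = resolved
    if system.chain_id[i] == system.chain_id[j]:
        raise RuntimeError("audit failure: intra-chain reconnection proposed")


def _audit_swap(system: ParticleSystem, topology: Topology, resolved) -> None:
    """Degree-and-connectivity audit: the swap must not disconnect the
    system or create a bead of backbone degree 3."""
    topology.refresh()  # raises TopologyError on degree > 2


def acceptance_probability(delta_U: float, mode: str = "equilibrium") -> float:
    """Metropolis acceptance probability: exactly 1 for delta_U < 0,
    exp(-delta_U) otherwise; bypass mode always accepts."""
    if not math.isfinite(delta_U):
        raise ValueError("delta_U must be finite")
    if mode == "bypass":
        return 1.0
    if delta_U < 0.0:
        return 1.0
    return math.exp(-delta_U)


def metropolis_accept(delta_U: float, mode: str = "equilibrium",
                      rng: np.random.Generator | None = None) -> bool:
    p = acceptance_probability(delta_U, mode)
    if p >= 1.0:
        return True
    if rng is None:
        rng = np.random.default_rng()
    return bool(rng.random() < p)


def attempt_sweep(system: ParticleSystem, topology: Topology,
                  move_params: MoveParams, ff_params: ForceFieldParams,
                  rng: np.random.Generator, *, step: int = 0,
                  loops=None) -> IntegrationEvent | None:
    """One attempt sweep: shuffle the candidate list and try swaps until
    one is accepted or the list is exhausted.

    On acceptance the topology and chain ids are mutated in place and an
    :class:`IntegrationEvent` is returned (site = substrate bead index on
    the low-index side of the broken substrate bond).
    """
    candidates = find_candidates(system, topology, move_params)
    if not candidates:
        return None
    order = rng.permutation(len(candidates))
    for m in order:
        cand = candidates[m]
        try:
            _, dU, dUa, resolved = propose_swap(
                cand, system, topology, ff_params, rng=rng,
                R_c=move_params.R_c)
        except ValueError:
            continue
        if metropolis_accept(dU, move_params.mode, rng):
            i, i1, j, j1 = resolved
            apply_swap(system, topology, resolved, ff_params)
            site = min(i, i1)
            in_loop = _site_in_loops(site, loops)
            return IntegrationEvent(step=step, site=site, in_loop=in_loop,
                                    delta_U=dU, delta_U_angle=dUa)
    return None


def _site_in_loops(site: int, loops) -> bool:
    if not loops:
        return False
    for lp in loops:
        if lp.anchor_lo <= site < lp.anchor_hi:
            return True
    return False
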