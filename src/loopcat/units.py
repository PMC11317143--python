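"""Reduced-unit system and core state containers.

The simulation works in reduced units: one bead diameter sigma as the
length unit, the thermal energy k_B*T as the energy unit, and the Brownian
time tau_Br (the time for a bead to diffuse its own diameter) as the time
unit.  With mass m = 1 and friction gamma = 1 the diffusion constant is
D = k_B*T/gamma = 1 and tau_Br = sigma^2/D = 1 holds identically.

One bead coarse-grains 7.35 bp of B-DNA (sigma = 2.5 nm at a helical rise
of 0.34 nm/bp).  All bead <-> base-pair conversions go through
:class:`UnitSystem` so the mapping lives in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BeadType",
    "Species",
    "UnitSystem",
    "ParticleSystem",
    "Topology",
    "BondKind",
    "bp_to_beads",
    "beads_to_bp",
    "derive_angles",
    "TopologyError",
]

N_TYPES = 5


class BeadType(IntEnum):
    """Interaction type of a bead.

    The species (DNA / viral DNA / nucleosome core particle) is coarser
    than the interaction type: nucleosomal-block DNA attracts NCPs while
    plain substrate DNA does not, and in the facilitated-diffusion variant
    a single viral bead is sticky toward the substrate.
    """

    DNA = 0          # plain substrate DNA
    NUC_DNA = 1      # nucleosomal-block DNA (attracts NCPs)
    VIRAL = 2        # viral/transposon DNA
    VIRAL_STICKY = 3 # the one intasome-like bead in the fd variant
    NCP = 4          # nucleosome core particle (3 sigma sphere)


class Species(IntEnum):
    DNA = 0
    VIRAL_DNA = 1
    NCP = 2


_SPECIES_OF_TYPE = {
    BeadType.DNA: Species.DNA,
    BeadType.NUC_DNA: Species.DNA,
    BeadType.VIRAL: Species.VIRAL_DNA,
    BeadType.VIRAL_STICKY: Species.VIRAL_DNA,
    BeadType.NCP: Species.NCP,
}


class BondKind(IntEnum):
    BACKBONE = 0
    LOOP_CLOSURE = 1


class TopologyError(ValueError):
    """Raised when a topology violates its structural invariants."""


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit definitions and the bead <-> bp mapping.

    Parameters
    ----------
    sigma_nm : bead diameter in nanometres.
    bp_per_bead : base pairs coarse-grained into one bead.
    bp_rise_nm : helical rise per base pair; only used to check that
        ``bp_per_bead`` is consistent with ``sigma_nm``.
    """

    sigma_nm: float = 2.5
    bp_per_bead: float = 7.35
    bp_rise_nm: float = 0.34
    kBT: float = 1.0
    tau_Br: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("sigma_nm must be positive")
        derived = self.sigma_nm / self.bp_rise_nm
        if abs(derived - self.bp_per_bead) > 0.01:
            raise ValueError(
                f"bp_per_bead={self.bp_per_bead} inconsistent with "
                f"sigma_nm/bp_rise_nm={derived:.4f}"
            )


DEFAULT_UNITS = UnitSystem()


def bp_to_beads(length_bp: float, units: UnitSystem = DEFAULT_UNITS) -> int:
    """Convert a contour length in bp to a bead count (nearest integer,
    ties to even)."""
    if length_bp < 0:
        raise ValueError(f"length_bp must be >= 0, got {length_bp}")
    return int(round(length_bp / units.bp_per_bead))


def beads_to_bp(n_beads: float, units: UnitSystem = DEFAULT_UNITS) -> float:
    """Convert a bead count to base pairs."""
    if n_beads < 0:
        raise ValueError(f"n_beads must be >= 0, got {n_beads}")
    return n_beads * units.bp_per_bead


@dataclass
class ParticleSystem:
    """Positions, velocities and identity of every particle.

    Coordinates are kept unwrapped; periodic wrapping is applied only when
    computing pair distances (minimum image), so tangent vectors and radii
    of gyration can be read straight off the coordinates.
    """

    positions: np.ndarray          # (N, 3) float64, sigma units
    velocities: np.ndarray         # (N, 3) float64
    btype: np.ndarray              # (N,) int64, BeadType values
    chain_id: np.ndarray           # (N,) int64
    box_side: float                # sigma units; > 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.btype = np.ascontiguousarray(self.btype, dtype=np.int64)
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if self.positions.shape != (self.n_particles, 3):
            raise ValueError("positions must be (N, 3)")

    @property
    def n_particles(self) -> int:
        return len(self.btype)

    @property
    def species(self) -> np.ndarray:
        out = np.empty(self.n_particles, dtype=np.int64)
        for t, s in _SPECIES_OF_TYPE.items():
            out[self.btype == int(t)] = int(s)
        return out

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(), self.velocities.copy(),
            self.btype.copy(), self.chain_id.copy(), self.box_side,
        )


class Topology:
    """Bond list with kind tags and the derived bending triplets.

    Backbone bonds define connectivity and generate the angle triplets;
    loop-closure springs mimic a protein bridge, never create angle terms
    and are excluded from reconnection moves.
    """

    def __init__(self, n_particles: int):
        self.n_particles = int(n_particles)
        self._pairs: list[tuple[int, int]] = []
        self._kind: list[int] = []
        self._k: list[float] = []
        self._r0: list[float] = []
        self._stale = True

    # -- construction ---------------------------------------------------
    def add_bond(self, i: int, j: int, kind: BondKind = BondKind.BACKBONE,
                 k: float = 20.0, r0: float = 1.1) -> None:
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        if i == j:
            raise TopologyError("self-bond")
        if not (0 <= i < self.n_particles and 0 <= j < self.n_particles):
            raise TopologyError(f"bond ({i},{j}) out of range")
        if (i, j) in self._pairs:
            raise TopologyError(f"duplicate bond ({i},{j})")
        self._pairs.append((i, j))
        self._kind.append(int(kind))
        self._k.append(float(k))
        self._r0.append(float(r0))
        self._stale = True

    def remove_bond(self, i: int, j: int) -> None:
        key = (int(i), int(j)) if i < j else (int(j), int(i))
        try:
            idx = self._pairs.index(key)
        except ValueError:
            raise TopologyError(f"no bond {key}") from None
        for lst in (self._pairs, self._kind, self._k, self._r0):
            del lst[idx]
        self._stale = True

    def has_bond(self, i: int, j: int) -> bool:
        key = (int(i), int(j)) if i < j else (int(j), int(i))
        return key in self._pairs

    # -- array views ----------------------------------------------------
    def _compile(self) -> None:
        nb = len(self._pairs)
        self.bond_pairs = np.array(self._pairs, dtype=np.int64).reshape(nb, 2)
        self.bond_kind = np.array(self._kind, dtype=np.int64)
        self.bond_k = np.array(self._k, dtype=np.float64)
        self.bond_r0 = np.array(self._r0, dtype=np.float64)
        self.angles = derive_angles(self)
        # backbone neighbour map (N, 2), -1 fill
        self.neighbours = _backbone_neighbours(self)
        # exclusion list: every bonded pair, any kind; max 3 partners
        excl = np.full((self.n_particles, 4), -1, dtype=np.int64)
        cnt = np.zeros(self.n_particles, dtype=np.int64)
        for (i, j) in self._pairs:
            for a, b in ((i, j), (j, i)):
                if cnt[a] >= excl.shape[1]:
                    raise TopologyError(f"bead {a} has too many bonds")
                excl[a, cnt[a]] = b
                cnt[a] += 1
        self.exclusions = excl
        self._stale = False

    def __getattr__(self, name):
        if name in {"bond_pairs", "bond_kind", "bond_k", "bond_r0",
                    "angles", "neighbours", "exclusions"}:
            self._compile()
            return object.__getattribute__(self, name)
        raise AttributeError(name)

    def invalidate(self) -> None:
        self._stale = True

    def refresh(self) -> None:
        if self._stale:
            self._compile()

    @property
    def n_bonds(self) -> int:
        return len(self._pairs)

    def bonds(self) -> list[tuple[int, int, BondKind]]:
        return [(i, j, BondKind(k)) for (i, j), k in zip(self._pairs, self._kind)]

    def backbone_bonds(self) -> np.ndarray:
        self.refresh()
        mask = self.bond_kind == int(BondKind.BACKBONE)
        return self.bond_pairs[mask]

    def closure_bond_indices(self) -> np.ndarray:
        self.refresh()
        return np.nonzero(self.bond_kind == int(BondKind.LOOP_CLOSURE))[0]

    def set_bond_k(self, idx: int, k: float) -> None:
        self._k[idx] = float(k)
        self._stale = True

    def copy(self) -> "Topology":
        t = Topology(self.n_particles)
        t._pairs = list(self._pairs)
        t._kind = list(self._kind)
        t._k = list(self._k)
        t._r0 = list(self._r0)
        return t

    def connected_components(self) -> list[set[int]]:
        """Connected components of the backbone-bond graph (isolated
        particles count as singletons)."""
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_particles)}
        for (i, j), k in zip(self._pairs, self._kind):
            if k == int(BondKind.BACKBONE):
                adj[i].append(j)
                adj[j].append(i)
        seen: set[int] = set()
        comps = []
        for s in range(self.n_particles):
            if s in seen:
                continue
            stack, comp = [s], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(v for v in adj[u] if v not in comp)
            seen |= comp
            comps.append(comp)
        return comps


def _backbone_neighbours(topology: Topology) -> np.ndarray:
    n = topology.n_particles
    neigh = np.full((n, 2), -1, dtype=np.int64)
    deg = np.zeros(n, dtype=np.int64)
    for (i, j), kind in zip(topology._pairs, topology._kind):
        if kind != int(BondKind.BACKBONE):
            continue
        for a, b in ((i, j), (j, i)):
            if deg[a] >= 2:
                raise TopologyError(f"bead {a} has backbone degree > 2")
            neigh[a, deg[a]] = b
            deg[a] += 1
    return neigh


def derive_angles(topology: Topology) -> np.ndarray:
    """Every ordered triple (i, j, k) of consecutively backbone-bonded
    beads, i.e. the length-3 bonded paths.  Loop-closure bonds never enter.

    Triples are emitted once, normalized so that i < k.
    """
    neigh = _backbone_neighbours(topology)
    out = []
    for b in range(topology.n_particles):
        n0, n1 = neigh[b]
        if n0 >= 0 and n1 >= 0:
            lo, hi = (n0, n1) if n0 < n1 else (n1, n0)
            out.append((lo, b, hi))
    if not out:
        return np.empty((0, 3), dtype=np.int64)
    return np.array(out, dtype=np.int64)
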