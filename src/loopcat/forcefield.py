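"""Bonded and non-bonded potentials of the bead-spring DNA model.

Three bonded/non-bonded contributions act on every bead:

* a stiff harmonic spring ``U = k_harm (r - r0)^2`` between consecutive
  beads (the literal spring-constant convention, no 1/2 prefactor),
* a Kratky-Porod bending term ``U = (l_p/sigma)(1 - cos theta)`` on every
  triplet of consecutive beads, parameterized by the persistence length,
* a truncated-and-shifted Lennard-Jones pair potential: purely repulsive
  (WCA, cutoff 2^(1/6) sigma_ij) between most bead pairs, or attractive
  with depth ``eps_attr`` and cutoff ``rc_attr * sigma_ij`` for the
  designated pairs (NCP with nucleosomal DNA; the sticky viral bead with
  substrate DNA in the facilitated-diffusion variant).

Contact distances mix arithmetically, sigma_ij = (sigma_i + sigma_j)/2,
with the nucleosome core particle a 3 sigma sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .units import BeadType, N_TYPES, ParticleSystem, Topology

__all__ = [
    "ForceFieldParams",
    "bond_energy",
    "bending_energy",
    "pair_energy",
    "total_energy",
    "forces",
    "angular_energy",
    "SingularOverlapError",
    "InstabilityError",
]

WCA_CUT = 2.0 ** (1.0 / 6.0)


class SingularOverlapError(FloatingPointError):
    """Two interacting particles at (numerically) zero separation."""


class InstabilityError(RuntimeError):
    """The integrator produced a non-finite or degenerate configuration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"numerical instability at step {step}")


def _lj(r: float, eps: float, sigma: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


@dataclass
class ForceFieldParams:
    """All force-field constants, in reduced units.

    ``pair_matrix`` overrides are expressed through the per-type tables
    built by :meth:`tables`; entries follow the bead types in
    :class:`~loopcat.units.BeadType`.
    """

    k_harm: float = 20.0      # bond stiffness, kBT/sigma^2
    r0: float = 1.1           # equilibrium bond length, sigma
    l_p: float = 20.0         # persistence length, sigma
    eps_rep: float = 1.0      # repulsive (WCA) depth, kBT
    eps_attr: float = 4.0     # attractive depth, kBT
    rc_attr: float = 1.8      # attraction cutoff in units of sigma_ij
    ncp_diameter: float = 3.0 # NCP sphere size, sigma

    def __post_init__(self) -> None:
        for name in ("k_harm", "l_p", "eps_rep", "eps_attr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rc_attr <= WCA_CUT:
            raise ValueError("rc_attr must exceed 2^(1/6)")

    @property
    def kappa(self) -> float:
        """Bending prefactor l_p/sigma in kBT."""
        return self.l_p

    def type_diameter(self, t: int) -> float:
        return self.ncp_diameter if t == int(BeadType.NCP) else 1.0

    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-type-pair (eps, sigma_ij, r_cut, shift) tables.

        Attractive pairs: nucleosomal DNA with NCP, and the sticky viral
        bead with both substrate DNA types.  Everything else is WCA
        repulsion at depth ``eps_rep``.
        """
        T = N_TYPES
        eps = np.full((T, T), self.eps_rep, dtype=np.float64)
        sig = np.empty((T, T), dtype=np.float64)
        rc = np.empty((T, T), dtype=np.float64)
        attractive = {
            (int(BeadType.NUC_DNA), int(BeadType.NCP)),
            (int(BeadType.VIRAL_STICKY), int(BeadType.DNA)),
            (int(BeadType.VIRAL_STICKY), int(BeadType.NUC_DNA)),
        }
        for a in range(T):
            for b in range(T):
                s = 0.5 * (self.type_diameter(a) + self.type_diameter(b))
                sig[a, b] = s
                key = (a, b) if a <= b else (b, a)
                if key in attractive or (key[1], key[0]) in attractive:
                    eps[a, b] = self.eps_attr
                    rc[a, b] = self.rc_attr * s
                else:
                    rc[a, b] = WCA_CUT * s
        shift = np.empty((T, T), dtype=np.float64)
        for a in range(T):
            for b in range(T):
                if eps[a, b] == 0.0:
                    shift[a, b] = 0.0
                else:
                    shift[a, b] = -_lj(rc[a, b], eps[a, b], sig[a, b])
        return eps, sig, rc, shift

    @property
    def rc_max(self) -> float:
        _, _, rc, _ = self.tables()
        return float(rc.max())


def bond_energy(r: float, params: ForceFieldParams) -> float:
    """Harmonic bond energy ``k_harm (r - r0)^2`` in kBT."""
    if r < 0:
        raise ValueError("separation must be >= 0")
    return params.k_harm * (r - params.r0) ** 2


def bending_energy(t1: np.ndarray, t2: np.ndarray,
                   params: ForceFieldParams) -> float:
    """Kratky-Porod energy of the angle between tangents t1 and t2."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n1 = float(np.linalg.norm(t1))
    n2 = float(np.linalg.norm(t2))
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("degenerate geometry: zero-length tangent")
    c = float(np.dot(t1, t2)) / (n1 * n2)
    c = max(-1.0, min(1.0, c))
    return params.kappa * (1.0 - c)


def pair_energy(r: float, kind: str = "repulsive",
                params: ForceFieldParams | None = None,
                sigma_ij: float = 1.0) -> float:
    """Shifted-truncated LJ pair energy at separation r.

    ``kind`` is "repulsive" (WCA, zero at and beyond 2^(1/6) sigma_ij)
    or "attractive" (zero at and beyond rc_attr * sigma_ij).
    """
    if params is None:
        params = ForceFieldParams()
    if r <= 0:
        raise SingularOverlapError("pair separation must be positive")
    if kind == "repulsive":
        eps, cut = params.eps_rep, WCA_CUT * sigma_ij
    elif kind == "attractive":
        eps, cut = params.eps_attr, params.rc_attr * sigma_ij
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    if r >= cut or eps == 0.0:
        return 0.0
    return _lj(r, eps, sigma_ij) - _lj(cut, eps, sigma_ij)


def _kernel_args(system: ParticleSystem, topology: Topology,
                 params: ForceFieldParams):
    topology.refresh()
    eps, sig, rc, sh = params.tables()
    return (system.positions, system.box_side, topology.bond_pairs,
            topology.bond_kind, topology.bond_k, topology.bond_r0,
            topology.angles, params.kappa, system.btype,
            eps, sig, rc, sh, topology.exclusions)


def total_energy(system: ParticleSystem, topology: Topology,
                 params: ForceFieldParams) -> dict[str, float]:
    """Per-term potential-energy breakdown {bond, angle, pair, closure}."""
    args = _kernel_args(system, topology, params)
    F = np.zeros_like(system.positions)
    status, eb, ec, ea, ep = _kernels.energy_oneshot(*args, 0.0, F)
    if status != _kernels.STATUS_OK:
        raise SingularOverlapError("overlapping or degenerate configuration")
    return {"bond": eb, "angle": ea, "pair": ep, "closure": ec,
            "total": eb + ea + ep + ec}


def forces(system: ParticleSystem, topology: Topology,
           params: ForceFieldParams) -> np.ndarray:
    """Analytic force on every particle, (N, 3) in kBT/sigma."""
    args = _kernel_args(system, topology, params)
    F = np.zeros_like(system.positions)
    status, *_ = _kernels.energy_oneshot(*args, 0.0, F)
    if status != _kernels.STATUS_OK:
        raise SingularOverlapError("overlapping or degenerate configuration")
    return F


def angular_energy(positions: np.ndarray, angles: np.ndarray,
                   params: ForceFieldParams, box: float = 0.0) -> float:
    """Total Kratky-Porod energy of a frame given its angle triplets
    (tangents taken on unwrapped coordinates, as in the dynamics)."""
    total = 0.0
    for a, b, c in angles:
        total += _kernels._angle_e(positions, 0.0, a, b, c, params.kappa)
    return total
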