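"""Langevin dynamics: BAOAB integration, equilibration with loop-spring
ramping, and trajectory sampling.

The integrator is the BAOAB splitting of the Langevin equation (velocity
Verlet plus an Ornstein-Uhlenbeck kick on the velocities), which reduces
exactly to velocity Verlet at gamma = 0 and satisfies the discrete
fluctuation-dissipation relation so that long runs sample the Boltzmann
distribution at the requested temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams, InstabilityError, _kernel_args
from .units import ParticleSystem, Topology

__all__ = ["LangevinParams", "step", "run", "equilibrate", "sample_frames",
           "maxwell_velocities"]

_SEED_MOD = 2**31 - 1


@dataclass
class LangevinParams:
    dt: float = 0.01          # timestep, tau_Br
    gamma: float = 1.0        # friction per particle
    temperature: float = 1.0  # kBT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0 or self.temperature < 0:
            raise ValueError("gamma and temperature must be >= 0")


def maxwell_velocities(n: int, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    if temperature == 0:
        return np.zeros((n, 3))
    return rng.normal(0.0, np.sqrt(temperature), size=(n, 3))


def _chunk_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, _SEED_MOD))


_NO_RAMP = (np.empty(0, dtype=np.int64), 0.0, 0.0, 0, 0)


def run(system: ParticleSystem, topology: Topology,
        ff_params: ForceFieldParams, lv_params: LangevinParams,
        n_steps: int, *, fcap: float = 0.0,
        rng: np.random.Generator | None = None,
        ramp: tuple | None = None) -> dict[str, float]:
    """Advance the system n_steps in place; returns the final per-term
    potential energies."""
    if rng is None:
        rng = np.random.default_rng(lv_params.seed)
    args = _kernel_args(system, topology, ff_params)
    F = np.zeros_like(system.positions)
    status, done, eb, ec, ea, ep = _kernels.run_chunk(
        args[0], system.velocities, F, *args[1:],
        int(n_steps), lv_params.dt, lv_params.gamma,
        lv_params.temperature, fcap, _chunk_seed(rng),
        *(ramp if ramp is not None else _NO_RAMP))
    if status != _kernels.STATUS_OK:
        raise InstabilityError(int(done))
    return {"bond": eb, "closure": ec, "angle": ea, "pair": ep}


def step(system: ParticleSystem, topology: Topology,
         ff_params: ForceFieldParams, lv_params: LangevinParams,
         rng: np.random.Generator | None = None) -> ParticleSystem:
    """One BAOAB step; deterministic given (state, rng state)."""
    run(system, topology, ff_params, lv_params, 1, rng=rng)
    return system


def equilibrate(system: ParticleSystem, topology: Topology,
                ff_params: ForceFieldParams, lv_params: LangevinParams,
                n_equil: int = 300_000, *, n_push: int = 2_000,
                push_fcap: float = 50.0, ramp_k: tuple[float, float] = (1.0, 20.0),
                rng: np.random.Generator | None = None) -> ParticleSystem:
    """Relax a freshly built system: a capped-force push-off removes
    random-walk overlaps, then ``n_equil`` steps during which every
    loop-closure spring is linearly ramped from ramp_k[0] to ramp_k[1]
    kBT/sigma^2.  No reconnection moves run here.
    """
    if rng is None:
        rng = np.random.default_rng(lv_params.seed)
    closure_idx = topology.closure_bond_indices()
    for idx in closure_idx:
        topology.set_bond_k(int(idx), 0.0)
    if n_push > 0:
        run(system, topology, ff_params, lv_params, n_push,
            fcap=push_fcap, rng=rng)
    if n_equil > 0:
        ramp = (closure_idx.astype(np.int64), float(ramp_k[0]),
                float(ramp_k[1]), 0, int(n_equil))
        run(system, topology, ff_params, lv_params, n_equil,
            rng=rng, ramp=ramp)
        # the kernel mutates the compiled bond_k view; persist the final
        # value in the Topology source of truth
        for idx in closure_idx:
            topology.set_bond_k(int(idx), float(ramp_k[1]))
    return system


def sample_frames(system: ParticleSystem, topology: Topology,
                  ff_params: ForceFieldParams, lv_params: LangevinParams,
                  n_frames: int, stride: int, *,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Run and collect ``n_frames`` position snapshots every ``stride``
    steps; returns an (n_frames, N, 3) array of unwrapped coordinates."""
    if rng is None:
        rng = np.random.default_rng(lv_params.seed)
    frames = np.empty((n_frames, system.n_particles, 3))
    for f in range(n_frames):
        run(system, topology, ff_params, lv_params, stride, rng=rng)
        frames[f] = system.positions
    return frames
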