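"""Replica-campaign orchestration.

A campaign runs many independent replicas of the same experiment: build
a fresh system, equilibrate it with the loop springs ramping 1 -> 20
kBT/sigma^2 (no reconnection moves), then run production dynamics with
reconnection attempts until the first integration or the step cap.
Replica seeds are base_seed + replica index, replicas share nothing, and
aggregation is independent of execution order.

Full-scale presets (1500 replicas, 1e7-step cap) are cluster-scale;
the named presets here are scaled-down desk recipes for each experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels, builders, io, moves, observables
from .dynamics import LangevinParams, equilibrate, maxwell_velocities
from .forcefield import ForceFieldParams, InstabilityError, _kernel_args
from .moves import IntegrationEvent, MoveParams, apply_swap
from .units import BeadType, ParticleSystem, Species, Topology, beads_to_bp

__all__ = ["CampaignSpec", "ReplicaResult", "run_replica", "run_campaign",
           "events_from_frame", "PRESETS"]

_SEED_MOD = 2**31 - 1


@dataclass
class CampaignSpec:
    """Everything needed to reproduce a campaign."""

    system: dict                  # builder kind + kwargs
    n_replicas: int = 100
    n_equil: int = 300_000
    n_max: int = 1_000_000        # production step cap (paper scale: 1e7)
    n_push: int = 2_000
    base_seed: int = 0
    mode: str = "equilibrium"     # or "bypass"
    attempt_every: int = 1
    R_c: float = 2.0
    dt: float = 0.01
    gamma: float = 1.0
    fd: bool = False              # facilitated-diffusion variant
    out_dir: str | None = None
    bondlist_every: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.n_max < 0 or self.n_equil < 0:
            raise ValueError("step counts must be >= 0")
        if self.mode not in ("equilibrium", "bypass"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReplicaResult:
    row: dict                    # event-log row
    rg_substrate: float          # substrate R_g at end of equilibration
    event: IntegrationEvent | None
    system: ParticleSystem | None = None   # final state (audits/output)
    topology: Topology | None = None


def _build(spec: CampaignSpec, rng: np.random.Generator):
    cfg = dict(spec.system)
    kind = cfg.pop("kind")
    ff = ForceFieldParams(**cfg.pop("forcefield", {}))
    loops: list = []
    if kind == "single_loop":
        loop_len = cfg.pop("loop_len", None)
        N = cfg.pop("N")
        if loop_len:
            start = (N - 1 - loop_len) // 2
            loop = builders.LoopSpec(start, start + loop_len)
            loops = [loop]
        else:
            loop = None
        system, topo = builders.build_single_loop_system(
            N, loop, rng=rng, ff=ff, **cfg)
    elif kind == "multiloop":
        system, topo, loops = builders.build_multiloop_system(
            rng=rng, ff=ff, **cfg)
    elif kind == "chromatin":
        cspec = builders.ChromatinSpec(**cfg.pop("chromatin", {}))
        loops = list(cspec.loop_region)
        system, topo = builders.build_chromatin_system(
            cspec, rng=rng, ff=ff, **cfg)
    else:
        raise ValueError(f"unknown system kind {kind!r}")
    if spec.fd:
        builders.enable_facilitated_diffusion(system)
    return system, topo, loops, ff


def run_replica(spec: CampaignSpec, replica_index: int) -> ReplicaResult:
    """One replica: build -> equilibrate (moves off) -> production with
    reconnection attempts -> halt at first integration or the step cap."""
    seed = (spec.base_seed + replica_index) % _SEED_MOD
    rng = np.random.default_rng(seed)
    row = {"replica": replica_index, "seed": seed, "step": -1,
           "site_bead": -1, "site_bp": float("nan"), "in_loop": False,
           "delta_U": float("nan"), "delta_U_angle": float("nan"),
           "outcome": "failed"}
    try:
        system, topo, loops, ff = _build(spec, rng)
        lv = LangevinParams(dt=spec.dt, gamma=spec.gamma, seed=seed)
        system.velocities[:] = maxwell_velocities(
            system.n_particles, lv.temperature, rng)
        equilibrate(system, topo, ff, lv, n_equil=spec.n_equil,
                    n_push=spec.n_push, rng=rng)
        sub = np.nonzero(system.species == int(Species.DNA))[0]
        rg = observables.radius_of_gyration(
            system, (int(sub.min()), int(sub.max()) + 1))
        event = _production(system, topo, ff, lv, spec, loops, rng)
    except (InstabilityError, ValueError) as exc:
        row["outcome"] = f"failed:{type(exc).__name__}"
        return ReplicaResult(row, float("nan"), None)
    if event is None:
        row.update(step=spec.n_max, outcome="timeout")
    else:
        row.update(step=event.step, site_bead=event.site,
                   site_bp=beads_to_bp(event.site),
                   in_loop=event.in_loop, delta_U=event.delta_U,
                   delta_U_angle=event.delta_U_angle,
                   outcome="integrated")
        _audit_post_integration(system, topo)
    return ReplicaResult(row, rg, event, system, topo)


def _production(system, topo, ff, lv, spec: CampaignSpec, loops,
                rng: np.random.Generator) -> IntegrationEvent | None:
    if spec.n_max == 0:
        return None
    args = _kernel_args(system, topo, ff)
    F = np.zeros_like(system.positions)
    sp = system.species
    bb = topo.backbone_bonds()
    sub_mask = (sp[bb[:, 0]] == int(Species.DNA)) \
        & (sp[bb[:, 1]] == int(Species.DNA))
    vir_mask = (sp[bb[:, 0]] == int(Species.VIRAL_DNA)) \
        & (sp[bb[:, 1]] == int(Species.VIRAL_DNA))
    sub_bonds = np.ascontiguousarray(bb[sub_mask])
    vir_bonds = np.ascontiguousarray(bb[vir_mask])
    vir_idx = np.unique(vir_bonds)
    event_out = np.zeros(7)
    status, done = _kernels.run_production(
        args[0], system.velocities, F, *args[1:],
        int(spec.n_max), lv.dt, lv.gamma, lv.temperature,
        int(rng.integers(1, _SEED_MOD)),
        sub_bonds, vir_bonds, vir_idx, topo.neighbours,
        spec.R_c, int(spec.attempt_every),
        1 if spec.mode == "bypass" else 0, ff.k_harm, ff.r0, event_out)
    if status == _kernels.STATUS_UNSTABLE:
        raise InstabilityError(int(done))
    if status != _kernels.STATUS_INTEGRATED:
        return None
    step, i, i1, j, j1 = (int(event_out[0]), int(event_out[1]),
                          int(event_out[2]), int(event_out[3]),
                          int(event_out[4]))
    apply_swap(system, topo, (i, i1, j, j1), ff)
    site = min(i, i1)
    return IntegrationEvent(step=step, site=site,
                            in_loop=moves._site_in_loops(site, loops),
                            delta_U=float(event_out[5]),
                            delta_U_angle=float(event_out[6]))


def _audit_post_integration(system: ParticleSystem, topo: Topology) -> None:
    """Topological conservation audit: after integration the union chain
    must be one linear chain holding every DNA and viral bead."""
    dna_like = np.isin(system.btype, [int(BeadType.DNA),
                                      int(BeadType.NUC_DNA),
                                      int(BeadType.VIRAL),
                                      int(BeadType.VIRAL_STICKY)])
    n_chain = int(dna_like.sum())
    comps = [c for c in topo.connected_components() if len(c) > 1]
    if len(comps) != 1 or len(comps[0]) != n_chain:
        raise RuntimeError("audit failure: integrated system is not a "
                           "single linear chain")
    neigh = topo.neighbours
    n_ends = int(np.sum((neigh[np.nonzero(dna_like)[0]] < 0).sum(axis=1) == 1))
    if n_ends != 2:
        raise RuntimeError("audit failure: integrated chain is not linear")


def run_campaign(spec: CampaignSpec) -> pd.DataFrame:
    """Run every replica serially and return the tidy event table; also
    writes the event log and aggregate profile when out_dir is set.

    The aggregate is a plain concatenation of independent replica rows,
    so it is invariant under execution order and parallelism width.
    """
    results = [run_replica(spec, k) for k in range(spec.n_replicas)]
    df = pd.DataFrame([r.row for r in results],
                      columns=io.EVENT_COLUMNS)
    df["rg_substrate"] = [r.rg_substrate for r in results]
    df.attrs["config_hash"] = io.config_hash(spec.to_dict())
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_events(df, out / "events.tsv")
        for r in results:
            if r.system is None:
                continue
            k = r.row["replica"]
            io.write_xyz(out / f"replica_{k:04d}_final.xyz", r.system,
                         comment=f"replica {k} {r.row['outcome']}")
            io.write_bondlist(out / f"replica_{k:04d}_bonds.tsv",
                              r.topology, frame=r.row["step"])
    return df


def events_from_frame(df: pd.DataFrame, loops=None) -> list[IntegrationEvent]:
    """Reconstruct IntegrationEvent objects from an event table
    (integrated rows only)."""
    sub = df[df["outcome"] == "integrated"]
    out = []
    for _, r in sub.iterrows():
        site = int(r["site_bead"])
        in_loop = bool(r["in_loop"]) if loops is None \
            else moves._site_in_loops(site, loops)
        out.append(IntegrationEvent(step=int(r["step"]), site=site,
                                    in_loop=in_loop,
                                    delta_U=float(r["delta_U"]),
                                    delta_U_angle=float(r["delta_U_angle"])))
    return out


def _preset_uniform_null(**over) -> CampaignSpec:
    base = dict(system={"kind": "single_loop", "N": 100, "loop_len": 0,
                        "viral_len": 20, "box": 14.0},
                n_replicas=500, n_equil=10_000, n_push=2_000,
                n_max=150_000, mode="bypass", attempt_every=2)
    base.update(over)
    return CampaignSpec(**base)


def _preset_single_loop(loop_len_beads: int = 11, **over) -> CampaignSpec:
    base = dict(system={"kind": "single_loop", "N": 100,
                        "loop_len": loop_len_beads, "viral_len": 20,
                        "box": 14.0},
                n_replicas=100, n_equil=20_000, n_push=2_000,
                n_max=200_000, mode="equilibrium", attempt_every=2)
    base.update(over)
    return CampaignSpec(**base)


def _preset_multiloop(mode_1d: str = "sparse", **over) -> CampaignSpec:
    base = dict(system={"kind": "multiloop", "N": 300, "n_loops": 5,
                        "loop_len": 11, "mode": mode_1d, "viral_len": 20,
                        "box": 22.0},
                n_replicas=60, n_equil=40_000, n_push=2_000,
                n_max=100_000, mode="bypass", attempt_every=2)
    base.update(over)
    return CampaignSpec(**base)


def _preset_chromatin(loop_len_beads: int = 11, **over) -> CampaignSpec:
    base = dict(system={"kind": "chromatin",
                        "chromatin": {"n_ncp": 6, "block_beads": 20,
                                      "linker_beads": 10},
                        "viral_len": 20},
                n_replicas=30, n_equil=50_000, n_push=2_000,
                n_max=100_000, mode="equilibrium", attempt_every=2)
    base.update(over)
    return CampaignSpec(**base)


PRESETS = {
    "uniform_null": _preset_uniform_null,
    "single_loop": _preset_single_loop,
    "multiloop": _preset_multiloop,
    "chromatin": _preset_chromatin,
}
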