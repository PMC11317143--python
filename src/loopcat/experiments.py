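"""Desk-scale experiment recipes.

Each function here reproduces one of the simulator's headline
measurements at a problem size that runs in minutes on one CPU:

* :func:`measure_persistence_length` — tangent-correlation decay of a
  free chain, pooled over independent replicas (slow bending modes make
  single-chain estimates noisy),
* :func:`loop_length_sweep` — equilibrium integration campaigns over a
  set of loop lengths, yielding in-loop statistics for the catalysis
  analysis and the f_in(ell) fit,
* :func:`sparse_vs_clustered` — paired bypass campaigns comparing the
  two 1D loop arrangements.

The scaled-down conditions (replica counts, step caps, box sides) are
deliberate desk-scale choices; full campaigns (>1000 replicas, 1e7-step
caps) are cluster work.
"""

from __future__ import annotations

import numpy as np

from .builders import build_single_loop_system
from .campaign import CampaignSpec, events_from_frame, run_campaign
from .dynamics import LangevinParams, equilibrate, maxwell_velocities, sample_frames
from .forcefield import ForceFieldParams
from .observables import LoopStats, loop_stats, tangent_correlation
from .units import beads_to_bp

__all__ = ["measure_persistence_length", "loop_length_sweep",
           "sparse_vs_clustered"]

_SEED_MOD = 2**31 - 1


def measure_persistence_length(seed: int, n_chains: int = 6,
                               n_beads: int = 100, n_equil: int = 800_000,
                               n_frames: int = 200, stride: int = 2_500,
                               s_max: int = 20) -> float:
    """Persistence length (sigma) of a free chain from the pooled
    tangent-correlation decay over independent replicas.

    Each replica is a free linear chain (no loop, no viral element)
    equilibrated for ``n_equil`` steps, then sampled every ``stride``
    steps.  Correlations are pooled over replicas and fitted
    log-linearly over s in [1, s_max] with inverse-variance weights from
    the replica spread: the large-s tail is dominated by slowly relaxing
    long-wavelength bending modes and carries most of the sampling
    noise, so an unweighted fit would be needlessly unstable.
    """
    ff = ForceFieldParams()
    corrs = np.empty((n_chains, s_max))
    for c in range(n_chains):
        rng = np.random.default_rng((seed + c) % _SEED_MOD)
        system, topo = build_single_loop_system(
            n_beads, None, viral_len=0, box=200.0, rng=rng)
        lv = LangevinParams(seed=(seed + c) % _SEED_MOD)
        system.velocities[:] = maxwell_velocities(
            system.n_particles, lv.temperature, rng)
        equilibrate(system, topo, ff, lv, n_equil=n_equil, rng=rng)
        frames = sample_frames(system, topo, ff, lv, n_frames=n_frames,
                               stride=stride, rng=rng)
        corrs[c] = tangent_correlation(frames, s_max)
    corr = corrs.mean(axis=0)
    sem = corrs.std(axis=0, ddof=1) / np.sqrt(n_chains)
    s = np.arange(1, s_max + 1, dtype=float)
    # var(log corr) ~ (sem/corr)^2; polyfit weights are 1/sd
    w = corr / np.maximum(sem, 1e-6)
    slope, _ = np.polyfit(s, np.log(corr), 1, w=w)
    return float(-1.0 / slope)


def _loop_campaign(loop_len: int, seed: int, n_replicas: int,
                   mode: str, n_max: int, box: float) -> CampaignSpec:
    return CampaignSpec(
        system={"kind": "single_loop", "N": 100, "loop_len": loop_len,
                "viral_len": 20, "box": box},
        n_replicas=n_replicas, n_equil=15_000, n_push=2_000,
        n_max=n_max, mode=mode, attempt_every=1, base_seed=seed)


def loop_length_sweep(seed: int, loop_lens=(11, 21, 41),
                      n_replicas: int = 70, mode: str = "equilibrium",
                      n_max: int = 100_000, box: float = 8.0) -> dict:
    """Equilibrium (or bypass) campaigns over several loop lengths on a
    100-bead substrate; returns per-length LoopStats and the tidy rows.

    The small box keeps the viral element in frequent contact with the
    substrate so that the 3D search is not rate limiting at desk scale;
    what remains is the energetic (Metropolis) site selection the loop
    catalysis acts on.
    """
    out = {"loop_len": [], "stats": [], "frames": []}
    for k, ell in enumerate(loop_lens):
        spec = _loop_campaign(ell, seed + 10_000 * k, n_replicas, mode,
                              n_max, box)
        df = run_campaign(spec)
        start = (100 - 1 - ell) // 2
        from .builders import LoopSpec
        loops = [LoopSpec(start, start + ell)]
        events = events_from_frame(df, loops)
        out["loop_len"].append(ell)
        out["stats"].append(loop_stats(events, loops, 100))
        out["frames"].append(df)
    return out


def sweep_to_fin_table(sweep: dict):
    """Convert a loop-length sweep to (ell_bp, f_in, n_events) arrays for
    the theory fit."""
    ell_bp = np.array([beads_to_bp(l) for l in sweep["loop_len"]])
    f_in = np.array([s.f_in for s in sweep["stats"]])
    n = np.array([s.I_tot for s in sweep["stats"]])
    return ell_bp, f_in, n


def sparse_vs_clustered(seed: int, N: int = 300, n_loops: int = 5,
                        loop_len: int = 11, n_replicas: int = 55,
                        n_equil: int = 30_000, n_max: int = 60_000,
                        box: float = 18.0, n_rg_extra: int = 150,
                        rg_equil: int = 8_000) -> dict:
    """Paired bypass campaigns with identical loop count and length but
    sparse versus clustered 1D arrangement.

    Returns per-arm event tables, in-loop statistics and per-replica
    substrate radii of gyration (taken at the end of equilibration).
    The conformational comparison does not need the viral element or
    the reconnection machinery, so the R_g sample is enlarged with
    ``n_rg_extra`` cheap substrate-only replicas per arm (the builders
    initialize at conformational equilibrium, so a short relaxation
    suffices); the loop-arrangement effect on R_g is modest and needs
    a few hundred samples per arm to resolve.
    """
    from .builders import build_multiloop_system, multiloop_anchors

    ff = ForceFieldParams()
    out = {}
    for arm_i, arm in enumerate(("sparse", "clustered")):
        spec = CampaignSpec(
            system={"kind": "multiloop", "N": N, "n_loops": n_loops,
                    "loop_len": loop_len, "mode": arm, "viral_len": 20,
                    "box": box},
            n_replicas=n_replicas, n_equil=n_equil, n_push=2_000,
            n_max=n_max, mode="bypass", attempt_every=2,
            base_seed=seed + arm_i * 500_000)
        df = run_campaign(spec)
        loops = multiloop_anchors(N, n_loops, loop_len, arm)
        events = events_from_frame(df, loops)
        rg = list(df.loc[df["outcome"] != "failed",
                         "rg_substrate"].to_numpy())
        for k in range(n_rg_extra):
            rng = np.random.default_rng(
                (seed + 900_000 + arm_i * 500_000 + k) % _SEED_MOD)
            system, topo, _ = build_multiloop_system(
                N, n_loops, loop_len, arm, viral_len=0, box=box, rng=rng)
            lv = LangevinParams(seed=(seed + 900_000 + arm_i * 500_000
                                      + k) % _SEED_MOD)
            system.velocities[:] = maxwell_velocities(
                system.n_particles, lv.temperature, rng)
            equilibrate(system, topo, ff, lv, n_equil=rg_equil,
                        n_push=1_000, rng=rng)
            from .observables import radius_of_gyration
            rg.append(radius_of_gyration(system, (0, N)))
        out[arm] = {
            "frame": df,
            "stats": loop_stats(events, loops, N),
            "rg": np.asarray(rg),
        }
    return out
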