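"""Measured quantities: integration-site distributions, in-loop
statistics, radius of gyration, persistence length, proximity fraction,
angular-energy traces and distribution comparisons.

The in-loop statistics follow the per-bead convention
``p_in = I_in / (l * I_tot)`` with the random reference ``p_rand = 1/N``
and the in-loop fraction ``f_in = p_in * l``.  Loop membership uses the
half-open bead interval [anchor_lo, anchor_hi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .forcefield import ForceFieldParams, angular_energy
from .moves import IntegrationEvent
from .units import ParticleSystem

__all__ = [
    "IntegrationProfile",
    "LoopStats",
    "integration_histogram",
    "loop_stats",
    "radius_of_gyration",
    "PersistenceFit",
    "fit_persistence_length",
    "tangent_correlation",
    "proximity_fraction",
    "angular_energy_trace",
    "compare_rg",
]


@dataclass
class IntegrationProfile:
    counts: np.ndarray     # per-substrate-bead event counts
    p_x: np.ndarray | None # normalized probability per bead (None if empty)
    n_events: int
    p_rand: float          # 1/N reference


@dataclass
class LoopStats:
    I_in: int
    I_tot: int
    ell_beads: int         # total looped contour, beads
    N: int
    p_in: float            # per-bead in-loop probability
    f_in: float            # fraction of integrations inside loops


def integration_histogram(events: Iterable[IntegrationEvent],
                          N: int) -> IntegrationProfile:
    counts = np.zeros(N, dtype=np.int64)
    n = 0
    for ev in events:
        if not (0 <= ev.site < N):
            raise ValueError(f"site {ev.site} out of range [0, {N})")
        counts[ev.site] += 1
        n += 1
    p_x = counts / n if n > 0 else None
    return IntegrationProfile(counts=counts, p_x=p_x, n_events=n,
                              p_rand=1.0 / N)


def loop_stats(events: Iterable[IntegrationEvent], loops: Sequence,
               N: int) -> LoopStats:
    """In-loop statistics aggregated over all loops; loops must not
    overlap and must lie within the substrate."""
    iv = sorted((lp.anchor_lo, lp.anchor_hi) for lp in loops)
    for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
        if b0 < a1:
            raise ValueError("overlapping loops")
    if iv and iv[-1][1] > N:
        raise ValueError("loop outside substrate")
    ell = sum(hi - lo for lo, hi in iv)
    I_in = 0
    I_tot = 0
    for ev in events:
        I_tot += 1
        if any(lo <= ev.site < hi for lo, hi in iv):
            I_in += 1
    if I_tot == 0 or ell == 0:
        return LoopStats(I_in, I_tot, ell, N, math.nan, math.nan)
    p_in = I_in / (ell * I_tot)
    return LoopStats(I_in, I_tot, ell, N, p_in, p_in * ell)


def radius_of_gyration(system_or_positions, bead_range=None) -> float:
    """Root-mean-square distance from the centre of mass of the selected
    bead range, on unwrapped coordinates."""
    pos = (system_or_positions.positions
           if isinstance(system_or_positions, ParticleSystem)
           else np.asarray(system_or_positions, dtype=float))
    if bead_range is not None:
        lo, hi = bead_range
        pos = pos[lo:hi]
    if len(pos) == 0:
        raise ValueError("empty bead range")
    com = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=1))))


def tangent_correlation(frames: np.ndarray, s_max: int) -> np.ndarray:
    """Mean normalized tangent-tangent correlation <t_i . t_{i+s}> over
    beads and frames, for s = 1 .. s_max."""
    frames = np.asarray(frames, dtype=float)
    t = np.diff(frames, axis=1)
    t /= np.linalg.norm(t, axis=2, keepdims=True)
    corr = np.empty(s_max)
    for s in range(1, s_max + 1):
        corr[s - 1] = np.mean(np.sum(t[:, :-s] * t[:, s:], axis=2))
    return corr


@dataclass
class PersistenceFit:
    l_p: float        # decay length in sigma (inf for a rigid rod)
    slope: float
    corr: np.ndarray
    ok: bool


def fit_persistence_length(frames: np.ndarray, s_max: int = 20,
                           rigid_tol: float = 1e-4) -> PersistenceFit:
    """Fit <t_i . t_{i+s}> = exp(-s sigma / l_p) by log-linear regression
    over s in [1, s_max].

    The fit window is capped at about one persistence length to avoid
    excluded-volume swelling bias.  Non-positive correlations at small s
    flag a failed fit; a flat correlation (rigid rod) returns l_p = inf.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (frames, beads, 3) trajectory, >= 2 frames")
    s_max = min(s_max, frames.shape[1] - 2)
    corr = tangent_correlation(frames, s_max)
    if np.any(corr <= 0):
        return PersistenceFit(math.nan, math.nan, corr, ok=False)
    s = np.arange(1, s_max + 1, dtype=float)
    slope, _ = np.polyfit(s, np.log(corr), 1)
    if slope >= -rigid_tol:
        return PersistenceFit(math.inf, slope, corr, ok=True)
    return PersistenceFit(-1.0 / slope, slope, corr, ok=True)


def proximity_fraction(frames: np.ndarray, loop_beads: np.ndarray,
                       viral_beads: np.ndarray, R: float = 2.0,
                       box: float = 0.0) -> float:
    """Fraction of frames with any viral-loop bead pair within R
    (minimum image when box > 0)."""
    if R <= 0:
        raise ValueError("R must be positive")
    loop_beads = np.asarray(loop_beads, dtype=int)
    viral_beads = np.asarray(viral_beads, dtype=int)
    hits = 0
    for frame in frames:
        d = frame[loop_beads, None, :] - frame[None, viral_beads, :]
        if box > 0:
            d -= box * np.floor(d / box + 0.5)
        if np.any(np.sum(d * d, axis=2) < R * R):
            hits += 1
    return hits / len(frames)


def angular_energy_trace(frames: np.ndarray, angle_sets,
                         params: ForceFieldParams,
                         box: float = 0.0) -> np.ndarray:
    """Total Kratky-Porod energy per frame.

    ``angle_sets`` is either one (na, 3) triplet array used for every
    frame or a sequence of per-frame arrays (topology history around an
    integration event).
    """
    frames = np.asarray(frames, dtype=float)
    per_frame = not (isinstance(angle_sets, np.ndarray)
                     and angle_sets.ndim == 2)
    out = np.empty(len(frames))
    for f, frame in enumerate(frames):
        ang = angle_sets[f] if per_frame else angle_sets
        out[f] = angular_energy(frame, ang, params, box)
    return out


def compare_rg(samples_a: np.ndarray, samples_b: np.ndarray,
               min_n: int = 20) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) comparison of two R_g samples;
    rank-based because R_g distributions are skewed."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"need >= {min_n} samples per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
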