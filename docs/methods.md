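# Methods

## Model and units

The simulator works in reduced units: bead diameter sigma (= 2.5 nm =
7.35 bp of B-DNA at 0.34 nm/bp), thermal energy kBT, and Brownian time
tau_Br = sigma^2/D.  With m = 1 and gamma = 1 the diffusion constant is
D = kBT/gamma = 1, so tau_Br = 1 identically.  The persistence length is
l_p = 20 sigma; note that 20 x 2.5 nm = 50 nm, slightly below the 55 nm
sometimes quoted for this bead size — the implementation is defined by
l_p = 20 sigma and the nanometre value is derived, not input.

Bonded terms: harmonic springs U = k_harm (r - r0)^2 (k_harm = 20
kBT/sigma^2, r0 = 1.1 sigma; literal spring-constant convention, no 1/2)
between consecutive beads, and a Kratky–Porod bending energy
(l_p/sigma)(1 - cos theta) on every triplet of consecutively bonded
beads.  Non-bonded pairs interact through a truncated-and-shifted
Lennard-Jones potential that is exactly zero at and beyond its cutoff:
WCA repulsion (depth eps_rep = 1 kBT, cutoff 2^(1/6) sigma_ij) between
almost all pairs, and an attractive variant (depth 4 kBT, cutoff
1.8 sigma_ij) for nucleosome-core-particle/nucleosomal-DNA pairs and,
in the facilitated-diffusion variant, for the single sticky viral bead
against substrate DNA.  Contact distances mix arithmetically; the NCP is
a 3 sigma sphere, so sigma_ij = 2 sigma against DNA (the mixed
attraction cutoff 1.8 x 2 sigma is a geometric-consistency choice; the
NCP size and depth are inputs, the mixed cutoff is not).  eps_rep is a
free default: the athermal-solvent convention of 1 kBT.  Directly
bonded pairs (including loop-closure pairs) are excluded from the pair
sum.  There are no torsional/twist degrees of freedom and no
sequence-dependent elasticity.

Coordinates are unwrapped and the minimum image convention is applied
only to non-bonded pair distances.  Bonds and bending tangents use raw
Euclidean displacements — this matters: a loop-closure spring evaluated
through the minimum image would let the loop "close" through a periodic
image of its anchor, winding the segment around the box instead of
bending it, and the stored elastic energy that drives loop catalysis
would vanish.  Radii of gyration and loop geometry likewise come from
plain unwrapped coordinates.

## Dynamics

The Langevin equation is integrated with the BAOAB splitting of
velocity Verlet at dt = 0.01 tau_Br: two half-kicks and two half-drifts
around an exact Ornstein–Uhlenbeck velocity update
v <- c1 v + sqrt(kBT (1 - c1^2)) xi with c1 = exp(-gamma dt).  This is
the discrete realization of the white-noise correlator
<dF dF'> = 2 kBT gamma delta(t - t'); at gamma = 0 the scheme reduces
exactly to velocity Verlet (the energy-conservation tests rely on
this).  Each replica draws all randomness from one seeded stream
(base_seed + replica index), so trajectories are bit-reproducible for a
fixed build.  Numerical instability (non-finite coordinates or a
collapsed bond/tangent) aborts the replica with the failing step index;
nothing is silently clamped.

Fresh systems start from a self-avoiding-adjusted *persistent* random
walk with fixed 1.1 sigma steps: step directions are drawn from the
exact Kratky-Porod Boltzmann weight at the chain's own l_p, and looped
segments are pre-folded as closed regular polygons in random planes so
their closure pairs start at bonding distance.  Starting at
conformational equilibrium matters: from a direction-uncorrelated walk
a few-hundred-bead semiflexible chain needs on the order of its Rouse
time (~1e5-1e6 steps) before large-scale observables are meaningful,
which desk-scale replica counts cannot afford.  Viral rings are regular
polygons placed without overlap.  A short push-off phase with pair
forces capped at 50 kBT/sigma removes residual overlaps (including
periodic-image overlaps of an extended chain in a small box), after
which the main equilibration runs with loop-closure springs ramped
linearly from 1 to 20 kBT/sigma^2 (the ramp shape is a choice; only its
endpoints are model inputs).

Sparse multi-loop layouts use cell-centred even spacing so every loop
sits in the chain interior: an end-anchored loop acts like a chain end
rather than a flexibility kink and would dilute the sparse-vs-clustered
comparison.

Non-bonded pairs are enumerated through a Verlet neighbour list with a
1.6 sigma skin, rebuilt by cell binning whenever any particle has moved
more than half the skin since the last build.  The enumerated
interactions are provably identical to a full O(N^2) scan (tested), the
list is purely an optimization.

## Integration moves

Reconnection candidates are (substrate bond, viral-ring bond) pairs for
which at least one of the two re-bonding orientations puts both new
bonds below R_c = 2 sigma; loop-closure springs and intra-chain pairs
are never candidates.  Of the two orientations the one with the smaller
summed new-bond length is proposed (exact ties: coin flip) — the
alternative proposal would stretch bonds close to R_c and be rejected
almost surely, so this mirrors the distance test of reference bond-swap
implementations.  The energy change is computed locally over exactly the
terms whose membership changes (4 bonds, up to 8 bending triplets
centred on the endpoints, 4 pair exclusions) and equals the full-system
U(after) - U(before) to 1e-8 relative (tested against recomputation).
Acceptance is Metropolis (1 if dU < 0, e^{-dU} otherwise) or forced in
bypass mode.  Candidate order is shuffled every sweep to remove index
bias.  After the first accepted integration the replica halts and the
topology is frozen — the observable is first-event statistics, excision
or multiple insertions are out of scope.  Every accepted move is
audited: species/bond counts conserved, resulting union chain linear
with N + l_viral beads, never an intra-chain reconnection.

The integration site is recorded as the substrate bead index on the
low-index side of the broken substrate bond; loop membership uses the
half-open anchor interval [anchor_lo, anchor_hi).

## Observables and theory

In-loop statistics follow p_in = I_in/(ell I_tot), f_in = p_in ell,
against the random reference p_rand = 1/N.  R_g comparisons use the
two-sided Mann–Whitney rank-sum test (R_g distributions are skewed).
The proximity fraction defaults to radius R_c = 2 sigma.  The
persistence-length estimator fits log <t_i . t_{i+s}> linearly over
s in [1, 20] (capped near l_p to avoid excluded-volume swelling bias);
because the large-s tail is dominated by slowly relaxing
long-wavelength bending modes, the production estimator pools
correlations over independent replicas and weights the fit by the
inverse replica-to-replica variance.  A flat correlation returns
l_p = infinity (rigid rod); non-positive correlations flag a failed fit.

Theory-side lengths are all in base pairs.  The loop elastic energy is
shape_factor x l_p / ell with shape_factor = 2 pi^2 for a circle (the
discrete polygon sum converges to this, which doubles as a cross-check
between the force field and the theory).  The angular energy released
by in-loop integration is modelled as a/(ell + l_viral) - b/ell and the
in-loop fraction as
f_in = ell W / (ell W + (N - ell)), W = exp(-a/(ell+l_viral) + b/ell);
loop-length-independent prefactors are dropped.  Fits use multi-start
nonlinear least squares with (a, b) free and l_viral a known input
(default 147 bp = the 20-bead builder default; the viral contour is
never a fitted parameter).

## Genomic intervals

BED input is 0-based half-open.  Nearest-neighbour distances are
edge-to-edge gaps (overlap = 0) to the closest element on the same
chromosome; with nested intervals the left neighbour is found through a
prefix maximum of interval ends, which matches the O(n^2) oracle.
Midpoint distances are deliberately not the default: "closer than 1 kb"
phrasing for enhancer–promoter pairs reads as gap distance.  The
synthetic generator draws inter-element gaps from a mixture of
exponential (uniform placement) and short gamma gaps, with the mixture
weight tuning the short-distance tail.  Published figures for fractions
of regulatory elements below 500 bp / 1 kb are database-version
dependent and are therefore reproduced qualitatively by the generator,
not asserted against a particular export.

## Scaled-down study conditions

Full campaigns (>1000 replicas, 1e7-step caps, dilute boxes) are
cluster-scale.  The desk-scale recipes in `loopcat.experiments` and the
test suite use:

* persistence length: 6 free 100-bead chains, 8e5-step equilibration,
  200 frames every 2500 steps each;
* random-integration null: 500 bypass replicas, loop-free 100-bead
  substrate, box 10 sigma, 1.5e5-step cap;
* loop-length sweep: 70 equilibrium replicas per length (11, 21, 41
  beads), box 8 sigma, 1e5-step cap.  The small box keeps the viral
  element in frequent contact so the 3D search is not rate limiting;
  what remains is the energetic site selection that loop catalysis acts
  on.  Absolute integration rates are box dependent (the loop-finding
  probability scales like ell/V), so only ratios and orderings are
  interpreted;
* sparse vs clustered: 55 bypass replicas per arm, 5 loops of 11 beads
  on a 300-bead substrate, box 18 sigma.  The loop-arrangement effect
  on substrate R_g is modest at this size (about a quarter of the
  replica-to-replica spread), so the R_g sample is enlarged with 180
  substrate-only equilibration replicas per arm — the conformational
  observable needs neither the viral element nor the move engine.

One desk-scale caveat: in the crowded boxes used here the bypass
(non-equilibrium) mode shows no in-loop enhancement — a tight loop's
advantage in bypass mode is its locally dense 3D target for the
diffusive search, which a box where everything is permanently in
contact removes; only steric burial remains.  The equilibrium-mode
catalysis (an energetic effect) and the bypass-mode uniformity and
arrangement orderings are the desk-scale surfaces.

What passing these scaled-down campaigns shows: the direction and
rough magnitude of the full-scale effects (short-loop enhancement,
decay to 1/N, arrangement ordering) under the same force field and move
set.  What it does not show: converged full-scale values of (a, b) or
of absolute integration rates, which require cluster campaigns; and any
feature of real chromatin beyond the model (electrostatics, histone
tails, chaperone proteins, torsion are all absent).

## Degenerate inputs and tie-breaks

Zero-length loops are represented as "no loop"; loops must span at
least 3 beads.  A candidate exactly at R_c is outside the (strict)
capture radius.  bp/bead conversions round half to even.  Empty event
lists yield an undefined (None) probability profile rather than NaNs.
Overlapping loops are rejected wherever loop membership is computed.
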