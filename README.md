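# loopcat

Coarse-grained molecular-dynamics simulation of DNA-element integration
(viral DNA, transposons) into looped DNA and chromatin substrates, with
the analytic theory describing why short loops act as *geometric
catalysts* for integration, and the genomic interval analysis that
quantifies how common short potential loops are between regulatory
elements.

It is aimed at biophysicists studying integration site selection: it
answers questions like *how does the length and 1D arrangement of DNA
loops bias where a retroviral element inserts?* entirely in silico, with
replica campaigns small enough for a laptop.

## Model

DNA is a semi-flexible bead-spring chain (one bead = sigma = 2.5 nm =
7.35 bp) evolved by the Langevin equation

    m r_i'' = -grad U_i - gamma r_i' + dF_i,   <dF dF> = 2 kBT gamma,

integrated with a BAOAB velocity-Verlet scheme at dt = 0.01 tau_Br.
The potential has three parts:

* harmonic bonds `U = k_harm (r - r0)^2` with k_harm = 20 kBT/sigma^2,
  r0 = 1.1 sigma;
* Kratky–Porod bending `U = (l_p/sigma)(1 - cos theta)` over consecutive
  bead triplets, l_p = 20 sigma;
* truncated-and-shifted Lennard-Jones pairs: WCA repulsion everywhere,
  plus eps = 4 kBT attraction (cutoff 1.8 sigma_ij) for the designated
  pairs (nucleosome core particle with nucleosomal DNA; the single
  "intasome" bead with substrate DNA in the facilitated-diffusion
  variant).

Integration is an inter-chain **bond-swap (double-bridging) move**: when
a substrate bond and a bond of the circular viral element have both
endpoints within R_c = 2 sigma, the two bonds may be exchanged, splicing
the opened ring into the substrate.  Proposals pass a Metropolis test on
the full local energy change (probability 1 if dU < 0, e^{-dU} else); a
non-equilibrium *bypass* mode accepts every admissible proposal.
Loops are stabilized by harmonic bridges ramped from 1 to 20
kBT/sigma^2 during equilibration.

Short loops store bending energy `F/kBT = eps_shape l_p / ell`; splicing
a viral ring of contour `l_viral` into a loop lengthens it, releasing

    dU_angle/kBT ≈ a/(ell + l_viral) - b/ell.

Balancing this Boltzmann weight against the probability of *finding* the
loop gives the in-loop fraction of integrations

    f_in(ell) = ell e^{-a/(ell+l_viral)+b/ell} / (ell e^{...} + (N - ell)),

which the package fits to campaign data with (a, b) free.

## Worked example

Run a scaled-down equilibrium campaign with an 80 bp (11-bead) loop in a
735 bp (100-bead) substrate, then compare the in-loop statistics with
the random expectation:

```python
import numpy as np
from loopcat.campaign import CampaignSpec, run_campaign, events_from_frame
from loopcat.builders import LoopSpec
from loopcat.observables import loop_stats

spec = CampaignSpec(
    system={"kind": "single_loop", "N": 100, "loop_len": 11,
            "viral_len": 20, "box": 8.0},
    n_replicas=40, n_equil=15_000, n_max=100_000,
    mode="equilibrium", base_seed=777)
df = run_campaign(spec)
loops = [LoopSpec(44, 55)]
st = loop_stats(events_from_frame(df, loops), loops, 100)
print(f"integrated {st.I_tot}/40 replicas; "
      f"f_in = {st.f_in:.2f}, p_in = {st.p_in:.4f} vs p_rand = 0.01")
```

Output (seed 777):

```
integrated 30/40 replicas; f_in = 0.70, p_in = 0.0636 vs p_rand = 0.01
```

The 11-bead loop covers 11% of the substrate but catches 70% of the
integrations — a per-bead integration probability six times the random
1/N, the geometric-catalysis signature.  Sweeping the loop length
(`loopcat.experiments.loop_length_sweep`) shows the enhancement decaying
back to 1/N for long loops, and `loopcat.theory.fit_fin` extracts the
length constants (a, b) from the resulting f_in table.

A command-line surface wraps the same machinery:

```bash
loopcat run campaign.yaml --seed 1 --out results/
loopcat fit results/fin_table.tsv --n-bp 735
loopcat regdist elements.bed          # nearest-neighbour 1D distances
loopcat fixtures polygon --n 20       # dump a deterministic fixture
```

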