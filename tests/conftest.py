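"""Shared expensive campaign fixtures.

The replica campaigns below are session scoped: several acceptance-level
checks (site-distribution statistics, loop-catalysis ordering, topology
conservation audits) read different aspects of the same runs.
"""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def uniform_null_campaign():
    """Bypass-mode campaign on a loop-free 100-bead substrate: the
    random-integration null model."""
    from loopcat.campaign import CampaignSpec, run_campaign

    spec = CampaignSpec(
        system={"kind": "single_loop", "N": 100, "loop_len": 0,
                "viral_len": 20, "box": 10.0},
        n_replicas=500, n_equil=6_000, n_push=2_000, n_max=150_000,
        mode="bypass", attempt_every=2, base_seed=12345)
    return run_campaign(spec)


@pytest.fixture(scope="session")
def loop_sweep():
    """Equilibrium campaigns over three loop lengths (11, 21, 41 beads)
    on the 100-bead substrate."""
    from loopcat.experiments import loop_length_sweep

    return loop_length_sweep(seed=777, loop_lens=(11, 21, 41),
                             n_replicas=40, n_max=80_000, box=8.0)


@pytest.fixture(scope="session")
def sparse_clustered():
    """Paired bypass campaigns: 5 loops of 11 beads on a 300-bead
    substrate, sparse versus clustered."""
    from loopcat.experiments import sparse_vs_clustered

    return sparse_vs_clustered(seed=555, n_replicas=55)
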