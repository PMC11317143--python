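import numpy as np
import pytest

from loopcat.builders import (ChromatinSpec, LoopSpec,
                              build_chromatin_system,
                              build_multiloop_system,
                              build_single_loop_system,
                              enable_facilitated_diffusion,
                              multiloop_anchors)
from loopcat.forcefield import ForceFieldParams
from loopcat.units import BeadType, BondKind, Species

FF = ForceFieldParams()


def _bond_lengths(system, topo, kind=BondKind.BACKBONE):
    out = []
    for i, j, k in topo.bonds():
        if k == kind:
            out.append(np.linalg.norm(system.positions[j]
                                      - system.positions[i]))
    return np.array(out)


class TestSingleLoop:
    def test_geometry_of_80bp_experiment(self):
        rng = np.random.default_rng(0)
        system, topo = build_single_loop_system(
            100, LoopSpec(44, 55), viral_len=20, rng=rng)
        assert system.n_particles == 120
        assert (system.species == int(Species.DNA)).sum() == 100
        assert (system.species == int(Species.VIRAL_DNA)).sum() == 20
        closure = topo.closure_bond_indices()
        assert len(closure) == 1
        assert set(map(tuple, topo.bond_pairs[closure])) == {(44, 55)}

    def test_loop_spanning_whole_chain_accepted(self):
        rng = np.random.default_rng(1)
        system, topo = build_single_loop_system(
            30, LoopSpec(0, 29), viral_len=5, rng=rng)
        assert len(topo.closure_bond_indices()) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_random_walk_bond_lengths_in_range(self, seed):
        rng = np.random.default_rng(seed)
        system, topo = build_single_loop_system(
            60, None, viral_len=10, rng=rng)
        lens = _bond_lengths(system, topo)
        assert lens.min() >= 0.8 and lens.max() <= 1.4

    def test_loop_longer_than_substrate_rejected(self):
        with pytest.raises(ValueError):
            build_single_loop_system(20, LoopSpec(0, 25), viral_len=5,
                                     rng=np.random.default_rng(0))

    def test_deterministic_given_seed(self):
        a, _ = build_single_loop_system(40, LoopSpec(10, 21), viral_len=8,
                                        rng=np.random.default_rng(9))
        b, _ = build_single_loop_system(40, LoopSpec(10, 21), viral_len=8,
                                        rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_no_hard_overlaps_after_placement(self):
        """Real-space self-overlaps are avoided at build time (periodic
        image overlaps are the push-off phase's job)."""
        rng = np.random.default_rng(4)
        system, topo = build_single_loop_system(80, None, viral_len=20,
                                                rng=rng, box=12.0)
        pos = system.positions
        bonded = {(min(i, j), max(i, j)) for i, j, _ in topo.bonds()}
        n = system.n_particles
        dmin = 10.0
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded:
                    continue
                dmin = min(dmin, np.linalg.norm(pos[j] - pos[i]))
        assert dmin >= 0.5  # best-effort placement; push-off removes the rest


class TestMultiloop:
    def test_hand_computed_sparse_layout(self):
        # N=60, 3 loops of 5, cell-centred: starts at
        # (2k+1)*(59-5)/6 = 9, 27, 45
        specs = multiloop_anchors(60, 3, 5, "sparse")
        assert [(s.anchor_lo, s.anchor_hi) for s in specs] == \
            [(9, 14), (27, 32), (45, 50)]

    def test_hand_computed_clustered_layout(self):
        # span = 3*5 + 2*2 = 19, start0 = (59-19)//2 = 20
        specs = multiloop_anchors(60, 3, 5, "clustered")
        assert [(s.anchor_lo, s.anchor_hi) for s in specs] == \
            [(20, 25), (27, 32), (34, 39)]

    def test_same_total_looped_contour(self):
        for n_loops, loop_len in [(3, 5), (5, 11)]:
            sparse = multiloop_anchors(300, n_loops, loop_len, "sparse")
            clustered = multiloop_anchors(300, n_loops, loop_len,
                                          "clustered")
            assert sum(s.length_beads for s in sparse) == \
                sum(s.length_beads for s in clustered)

    def test_single_loop_modes_identical(self):
        a = multiloop_anchors(100, 1, 11, "sparse")
        b = multiloop_anchors(100, 1, 11, "clustered")
        assert [(s.anchor_lo, s.anchor_hi) for s in a] == \
            [(s.anchor_lo, s.anchor_hi) for s in b]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            multiloop_anchors(30, 5, 11, "clustered")

    def test_builds_differ_only_in_anchor_placement(self):
        """The two modes share bead counts, species and connectivity;
        their loop specs differ only in where the anchors sit."""
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(5)
        sa, ta, la = build_multiloop_system(120, 3, 7, "sparse",
                                            viral_len=10, rng=rng_a)
        sb, tb, lb = build_multiloop_system(120, 3, 7, "clustered",
                                            viral_len=10, rng=rng_b)
        assert sa.n_particles == sb.n_particles
        np.testing.assert_array_equal(sa.btype, sb.btype)
        backbone_a = {tuple(b) for b in ta.backbone_bonds()}
        backbone_b = {tuple(b) for b in tb.backbone_bonds()}
        assert backbone_a == backbone_b
        assert [s.length_beads for s in la] == [s.length_beads for s in lb]
        assert [s.anchor_lo for s in la] != [s.anchor_lo for s in lb]


class TestChromatin:
    def test_default_layout_counts(self):
        spec = ChromatinSpec()
        assert spec.n_ncp == 30
        assert spec.block_beads == 20
        assert spec.linker_beads == 10
        assert spec.n_dna_beads == 910

    def test_species_pattern(self):
        spec = ChromatinSpec(n_ncp=3)
        rng = np.random.default_rng(0)
        system, topo = build_chromatin_system(spec, viral_len=5, rng=rng)
        bt = system.btype
        ndna = spec.n_dna_beads
        assert (bt[:10] == int(BeadType.DNA)).all()           # leading linker
        assert (bt[10:30] == int(BeadType.NUC_DNA)).all()     # first block
        assert (bt[30:40] == int(BeadType.DNA)).all()         # linker
        assert (bt == int(BeadType.NCP)).sum() == 3
        assert (system.species == int(Species.NCP)).sum() == 3
        # NCPs are unbonded free particles
        assert (topo.neighbours[ndna + 5:] == -1).all()

    def test_ncp_self_assembly_with_and_without_attraction(self):
        """With eps = 4 kBT the NCPs wrap nucleosomal DNA (many block
        beads in contact); with eps = 0 they do not."""
        from loopcat.dynamics import LangevinParams, equilibrate, \
            maxwell_velocities
        counts = {}
        for eps in (4.0, 0.0):
            spec = ChromatinSpec(n_ncp=4, ncp_dna_eps=eps)
            rng = np.random.default_rng(21)
            ff = ForceFieldParams()
            system, topo = build_chromatin_system(spec, viral_len=0,
                                                  rng=rng, box=14.0)
            if eps == 0.0:
                # attraction off: retag nucleosomal DNA as plain DNA
                system.btype[system.btype == int(BeadType.NUC_DNA)] = \
                    int(BeadType.DNA)
            lv = LangevinParams(seed=21)
            system.velocities[:] = maxwell_velocities(
                system.n_particles, 1.0, rng)
            equilibrate(system, topo, ff, lv, n_equil=30_000,
                        n_push=2_000, rng=rng)
            ncp_idx = np.nonzero(system.btype == int(BeadType.NCP))[0]
            blocks = np.nonzero((system.btype == int(BeadType.NUC_DNA))
                                | (system.btype == int(BeadType.DNA)))[0]
            # count nucleosomal-scale DNA beads within the wrapping shell
            from helpers import mi
            per_ncp = []
            for h in ncp_idx:
                d = np.linalg.norm(
                    mi(system.positions[blocks] - system.positions[h],
                       system.box_side), axis=1)
                per_ncp.append((d < 1.8 * 2.0).sum())
            counts[eps] = np.array(per_ncp)
        assert np.median(counts[4.0]) >= 10     # wrapped
        assert counts[4.0].mean() > counts[0.0].mean() + 5


class TestFacilitatedDiffusion:
    def _system(self):
        rng = np.random.default_rng(2)
        return build_single_loop_system(30, None, viral_len=8, rng=rng)

    def test_single_sticky_bead(self):
        system, _ = self._system()
        enable_facilitated_diffusion(system)
        assert (system.btype == int(BeadType.VIRAL_STICKY)).sum() == 1
        assert (system.btype == int(BeadType.VIRAL)).sum() == 7

    def test_idempotent(self):
        system, _ = self._system()
        enable_facilitated_diffusion(system)
        enable_facilitated_diffusion(system)
        assert (system.btype == int(BeadType.VIRAL_STICKY)).sum() == 1

    def test_pair_table_attraction_only_for_sticky_bead(self):
        eps, sig, rc, _ = FF.tables()
        sticky, plain = int(BeadType.VIRAL_STICKY), int(BeadType.VIRAL)
        dna = int(BeadType.DNA)
        assert eps[sticky, dna] == FF.eps_attr
        assert rc[sticky, dna] == pytest.approx(FF.rc_attr)
        assert eps[plain, dna] == FF.eps_rep
        assert rc[plain, dna] == pytest.approx(2 ** (1 / 6))

    def test_zero_attraction_reduces_to_repulsive_model(self):
        ff0 = ForceFieldParams(eps_attr=0.0, rc_attr=1.8)
        eps, _, _, sh = ff0.tables()
        sticky, dna = int(BeadType.VIRAL_STICKY), int(BeadType.DNA)
        assert eps[sticky, dna] == 0.0
        assert sh[sticky, dna] == 0.0

    def test_requires_viral_chain(self):
        system, _ = build_single_loop_system(
            10, None, viral_len=0, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            enable_facilitated_diffusion(system)
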