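import numpy as np
import pytest
from scipy import stats

from loopcat.builders import LoopSpec
from loopcat.fixtures import sample_events_from_profile
from loopcat.forcefield import ForceFieldParams
from loopcat.moves import IntegrationEvent
from loopcat.observables import (angular_energy_trace, compare_rg,
                                 fit_persistence_length,
                                 integration_histogram, loop_stats,
                                 proximity_fraction, radius_of_gyration,
                                 tangent_correlation)

FF = ForceFieldParams()


def _ev(site):
    return IntegrationEvent(step=0, site=site, in_loop=False,
                            delta_U=0.0, delta_U_angle=0.0)


class TestIntegrationHistogram:
    def test_single_event(self):
        prof = integration_histogram([_ev(5)], 10)
        assert prof.p_x[5] == 1.0
        assert prof.counts.sum() == 1
        assert prof.p_rand == pytest.approx(0.1)

    def test_empty_event_list(self):
        prof = integration_histogram([], 10)
        assert prof.p_x is None
        assert prof.counts.sum() == 0

    def test_out_of_range_site(self):
        with pytest.raises(ValueError):
            integration_histogram([_ev(10)], 10)

    def test_uniform_sampler_passes_gof(self):
        rng = np.random.default_rng(0)
        N = 50
        events = sample_events_from_profile(np.full(N, 1 / N), 5000, rng)
        prof = integration_histogram(events, N)
        p = stats.chisquare(prof.counts).pvalue
        assert p > 0.01

    def test_delta_profile(self):
        rng = np.random.default_rng(1)
        p_x = np.zeros(20)
        p_x[7] = 1.0
        events = sample_events_from_profile(p_x, 100, rng)
        assert all(ev.site == 7 for ev in events)


class TestLoopStats:
    def test_all_events_inside(self):
        loops = [LoopSpec(10, 21)]
        events = [_ev(s) for s in range(10, 21)]
        st = loop_stats(events, loops, 100)
        assert st.f_in == pytest.approx(1.0)
        assert st.p_in == pytest.approx(1.0 / 11)

    def test_manual_count(self):
        loops = [LoopSpec(5, 10), LoopSpec(20, 25)]
        sites = [0, 5, 9, 10, 15, 20, 24, 25, 40, 7]  # 5 inside
        st = loop_stats([_ev(s) for s in sites], loops, 50)
        assert st.I_in == 5 and st.I_tot == 10
        assert st.f_in == pytest.approx(0.5)
        assert st.p_in == pytest.approx(0.5 / 10)

    def test_half_open_membership(self):
        loops = [LoopSpec(10, 20)]
        st = loop_stats([_ev(10), _ev(19), _ev(20)], loops, 50)
        assert st.I_in == 2

    def test_random_events_match_contour_fraction(self):
        rng = np.random.default_rng(2)
        N, loops = 100, [LoopSpec(30, 50)]
        events = sample_events_from_profile(np.full(N, 1 / N), 20_000, rng)
        st = loop_stats(events, loops, N)
        assert st.f_in == pytest.approx(20 / 100, abs=0.01)

    def test_in_and_out_fractions_sum_to_one(self):
        loops = [LoopSpec(3, 8)]
        events = [_ev(s) for s in [1, 4, 6, 9]]
        st = loop_stats(events, loops, 20)
        f_out = (st.I_tot - st.I_in) / st.I_tot
        assert st.f_in + f_out == 1.0

    def test_overlapping_loops_rejected(self):
        with pytest.raises(ValueError):
            loop_stats([_ev(1)], [LoopSpec(0, 10), LoopSpec(5, 15)], 50)


class TestRadiusOfGyration:
    def test_coincident_beads(self):
        pos = np.ones((5, 3))
        assert radius_of_gyration(pos) == 0.0

    def test_two_beads(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(pos) == pytest.approx(1.5)

    def test_direct_formula(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(40, 3))
        com = pos.mean(0)
        ref = np.sqrt(np.mean(np.sum((pos - com)**2, axis=1)))
        assert radius_of_gyration(pos) == pytest.approx(ref)

    def test_translation_rotation_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.normal(size=(30, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pos @ q.T + np.array([5.0, -2.0, 11.0])
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(pos))

    def test_empty_range(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((10, 3)), (4, 4))


def _wlc_frames(n_frames, n_beads, lp, rng):
    """Synthetic worm-like-chain frames with known tangent decay."""
    frames = np.zeros((n_frames, n_beads, 3))
    cos_mean = np.exp(-1.0 / lp)
    for f in range(n_frames):
        t = np.array([0.0, 0, 1.0])
        pos = np.zeros((n_beads, 3))
        for i in range(1, n_beads):
            # sample polar angle with <cos> = exp(-1/lp) (small-angle
            # gaussian approximation, adequate for lp >~ 2)
            theta = np.abs(rng.normal(0, np.sqrt(2 * (1 - cos_mean))))
            phi = rng.uniform(0, 2 * np.pi)
            # rotate t by theta about a random perpendicular axis
            perp = np.cross(t, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            t = (np.cos(theta) * t + np.sin(theta)
                 * (np.cos(phi) * perp + np.sin(phi) * np.cross(t, perp)))
            t /= np.linalg.norm(t)
            pos[i] = pos[i - 1] + t
        frames[f] = pos
    return frames


class TestPersistenceFit:
    def test_rigid_rod_flags_infinity(self):
        pos = np.zeros((5, 30, 3))
        pos[:, :, 0] = np.arange(30)
        fit = fit_persistence_length(pos)
        assert fit.l_p == np.inf and fit.ok

    def test_recovers_known_wlc_decay(self):
        rng = np.random.default_rng(5)
        for lp in (5.0, 12.0):
            frames = _wlc_frames(300, 60, lp, rng)
            fit = fit_persistence_length(frames, s_max=int(lp))
            assert fit.ok
            assert fit.l_p == pytest.approx(lp, rel=0.15)

    def test_uncorrelated_walk_flags_failure(self):
        rng = np.random.default_rng(6)
        steps = rng.normal(size=(50, 40, 3))
        frames = np.cumsum(steps, axis=1)
        fit = fit_persistence_length(frames, s_max=10)
        # freely-jointed tangents: correlation ~ 0, log-fit impossible
        assert (not fit.ok) or fit.l_p < 2.0


class TestProximityFraction:
    def test_far_apart_zero(self):
        frames = np.zeros((10, 6, 3))
        frames[:, 3:, 0] = 50.0
        assert proximity_fraction(frames, [0, 1, 2], [3, 4, 5]) == 0.0

    def test_glued_one(self):
        frames = np.zeros((10, 6, 3))
        frames[:, 3:, 0] = 0.5
        assert proximity_fraction(frames, [0, 1, 2], [3, 4, 5]) == 1.0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            proximity_fraction(np.zeros((2, 4, 3)), [0], [1], R=0.0)


class TestAngularEnergyTrace:
    def test_straight_chain_zero_trace(self):
        frames = np.zeros((4, 10, 3))
        frames[:, :, 0] = 1.1 * np.arange(10)
        angles = np.array([[i, i + 1, i + 2] for i in range(8)])
        trace = angular_energy_trace(frames, angles, FF)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_matches_total_energy_angle_term(self):
        from loopcat.forcefield import total_energy
        from helpers import random_contact_system
        rng = np.random.default_rng(7)
        system, topo = random_contact_system(rng)
        topo.refresh()
        trace = angular_energy_trace(system.positions[None, :, :],
                                     topo.angles, FF,
                                     box=system.box_side)
        ref = total_energy(system, topo, FF)["angle"]
        assert trace[0] == pytest.approx(ref, rel=1e-10)


class TestCompareRg:
    def test_identical_samples_high_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(10, 1, 50)
        _, p = compare_rg(a, a.copy())
        assert p > 0.9

    def test_shifted_normals_significant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(10, 1, 50)
        b = rng.normal(12, 1, 50)  # 2 pooled SD shift
        _, p = compare_rg(a, b)
        assert p < 0.001

    def test_insufficient_samples(self):
        with pytest.raises(ValueError):
            compare_rg(np.ones(5), np.ones(50))
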