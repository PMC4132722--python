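"""Synthetic polysome generator: geometry, rendering, wedge, ground truth."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polytomo import (GeneratorConfig, Pose, apply_missing_wedge, max_spacer_nm,
                      render_tomogram, sample_polysome, simulate_condition)
from polytomo.polysomes import PolysomeGroup
from polytomo.ribosome import body_landmarks
from polytomo.simulate import TOPOLOGIES, CIRCULAR_TOPOLOGIES, GenerationError
from polytomo.trace import TraceConfig, candidate_links, solve_path


def _link_spacers(poses, order, closed):
    lm = body_landmarks()
    exits = np.array([p.matrix @ lm["mrna_exit"] + p.position for p in poses])
    entries = np.array([p.matrix @ lm["mrna_entry"] + p.position for p in poses])
    pairs = list(zip(order[:-1], order[1:])) + ([(order[-1], order[0])] if closed else [])
    return [float(np.linalg.norm(entries[j] - exits[i])) for i, j in pairs]


class TestSamplePolysome:
    def test_hexamer_ring_closes_with_feasible_links(self, rng):
        cfg = GeneratorConfig(orientation_jitter_deg=0.0)
        poses, order, closed = sample_polysome("circular_ring", 6, cfg, rng,
                                               occupancy_nt=120.0)
        assert closed and len(poses) == 6
        cap = max_spacer_nm(120.0)
        assert all(s <= cap for s in _link_spacers(poses, order, closed))

    def test_singleton_is_open_with_no_links(self, rng):
        cfg = GeneratorConfig()
        poses, order, closed = sample_polysome("linear_single_row", 1, cfg, rng)
        assert len(poses) == 1 and order == [0] and not closed

    def test_hexamer_ring_radius_chord_formula(self, rng):
        """Ring radius follows d / (2 sin(pi/n)) for chord d = 27 nm."""
        cfg = GeneratorConfig(orientation_jitter_deg=0.0)
        poses, _, _ = sample_polysome("circular_ring", 6, cfg, rng,
                                      occupancy_nt=140.0)
        radii = np.linalg.norm([p.position for p in poses], axis=1)
        np.testing.assert_allclose(radii, 27.0 / (2 * np.sin(np.pi / 6)), atol=1e-9)

    @pytest.mark.parametrize("topology", TOPOLOGIES)
    def test_spacer_cap_respected_under_jitter(self, topology, rng):
        cfg = GeneratorConfig(orientation_jitter_deg=5.0)
        for n in (4, 6, 8):
            occupancy = float(rng.uniform(100, 140))
            poses, order, closed = sample_polysome(topology, n, cfg, rng,
                                                   occupancy_nt=occupancy)
            cap = max_spacer_nm(occupancy)
            assert max(_link_spacers(poses, order, closed)) <= cap

    def test_infeasible_occupancy_raises(self, rng):
        cfg = GeneratorConfig(orientation_jitter_deg=0.0)
        with pytest.raises(GenerationError):
            # 40 nt budget leaves a 3.4 nm spacer: nothing fits
            sample_polysome("circular_ring", 6, cfg, rng, occupancy_nt=40.0)

    def test_out_of_range_size_refused(self, rng):
        with pytest.raises(GenerationError):
            sample_polysome("circular_ring", 13, GeneratorConfig(), rng)


class TestRenderTomogram:
    def test_empty_pose_list_gives_zero_mean_noise(self, ref_coarse, rng):
        cfg = GeneratorConfig(box_edge=32, snr=1.0)
        tomo = render_tomogram([], ref_coarse, cfg, rng, box_edge=32)
        assert abs(tomo.density.mean()) < 0.02
        assert tomo.density.std() > 0

    def test_identity_pose_embeds_reference_exactly(self, ref_coarse, rng):
        cfg = GeneratorConfig(box_edge=32, snr=np.inf)
        # 31 nm puts the (even-box) reference grid exactly on canvas voxels,
        # so the embedding involves no interpolation at all
        pose = Pose("p0", np.full(3, 31.0), Rotation.identity())
        tomo = render_tomogram([pose], ref_coarse, cfg, rng, box_edge=32)
        sub = tomo.density[4:28, 4:28, 4:28]
        np.testing.assert_allclose(sub, ref_coarse.density, atol=1e-5)

    def test_superposition_of_separated_particles(self, ref_coarse, rng):
        """Rendering is linear: two non-overlapping particles integrate to
        twice the reference integral."""
        cfg = GeneratorConfig(box_edge=48, snr=np.inf)
        poses = [Pose("a", np.array([30.0, 30.0, 30.0]), Rotation.identity()),
                 Pose("b", np.array([66.0, 66.0, 66.0]), Rotation.identity())]
        tomo = render_tomogram(poses, ref_coarse, cfg, rng, box_edge=48)
        expected = 2.0 * float(ref_coarse.density.sum())
        assert tomo.density.sum() == pytest.approx(expected, rel=1e-6)

    def test_crowded_particles_warn_but_render(self, ref_coarse, rng):
        cfg = GeneratorConfig(box_edge=48, snr=np.inf)
        poses = [Pose("a", np.array([40.0, 48.0, 48.0]), Rotation.identity()),
                 Pose("b", np.array([58.0, 48.0, 48.0]), Rotation.identity())]
        with pytest.warns(UserWarning, match="crowded"):
            render_tomogram(poses, ref_coarse, cfg, rng, box_edge=48)

    def test_pose_outside_margin_raises(self, ref_coarse, rng):
        cfg = GeneratorConfig(box_edge=32, snr=np.inf)
        pose = Pose("p0", np.array([2.0, 32.0, 32.0]), Rotation.identity())
        with pytest.raises(GenerationError):
            render_tomogram([pose], ref_coarse, cfg, rng, box_edge=32)


class TestMissingWedge:
    def test_full_tilt_range_is_identity(self, rng):
        vol = rng.normal(size=(24, 24, 24))
        np.testing.assert_allclose(apply_missing_wedge(vol, 90.0), vol, atol=1e-10)

    def test_zeroed_fraction_matches_wedge_angle(self, rng):
        """At +-66 deg the unsampled wedge holds (90-66)/90 of the in-plane
        angular measure."""
        vol = rng.normal(size=(32, 32, 32))
        out = apply_missing_wedge(vol, 66.0)
        spec = np.fft.fftn(out)
        zeroed = np.abs(spec) < 1e-9
        # angular measure: count within the inscribed disc of the (kx, kz)
        # plane, where the angle is sampled uniformly
        f = np.fft.fftfreq(32)
        kx, _, kz = np.meshgrid(f, f, f, indexing="ij")
        disc = (kx**2 + kz**2 <= 0.25) & (kx**2 + kz**2 > 0.01)
        frac = float(zeroed[disc].mean())
        assert frac == pytest.approx((90 - 66) / 90, abs=0.03)

    def test_output_is_real_and_idempotent(self, rng):
        vol = rng.normal(size=(24, 24, 24))
        once = apply_missing_wedge(vol, 66.0)
        assert np.isrealobj(once)
        np.testing.assert_allclose(apply_missing_wedge(once, 66.0), once,
                                   atol=1e-10)

    def test_invalid_angle_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_missing_wedge(np.zeros((8, 8, 8)), 0.0)


class TestSimulateCondition:
    def test_degenerate_mixture_all_circular(self):
        cfg = GeneratorConfig(n_polysomes=20, seed=5,
                              topology_mixture={"circular_ring": 1.0},
                              size_distribution={5: 0.5, 6: 0.5})
        _, gt = simulate_condition(cfg, render=False)
        assert all(lab in CIRCULAR_TOPOLOGIES for lab in gt.topology_label.values())
        assert all(gt.closed.values())

    def test_same_seed_reproduces_pose_table(self):
        cfg = GeneratorConfig(n_polysomes=15, seed=7)
        _, gt1 = simulate_condition(cfg, render=False)
        _, gt2 = simulate_condition(cfg, render=False)
        t1, t2 = gt1.to_table(), gt2.to_table()
        assert t1.equals(t2)

    def test_iid_mixture_within_binomial_error(self):
        """With iid topology draws the empirical circular fraction converges
        to the configured mixture (3 binomial SDs at n=400)."""
        cfg = GeneratorConfig(
            n_polysomes=400, seed=11, stratified_mixture=False,
            topology_mixture={"circular_ring": 0.5, "linear_single_row": 0.5},
            size_distribution={4: 0.5, 5: 0.5})
        _, gt = simulate_condition(cfg, render=False)
        frac = np.mean([lab in CIRCULAR_TOPOLOGIES
                        for lab in gt.topology_label.values()])
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 400)

    def test_ground_truth_invariants(self):
        cfg = GeneratorConfig(n_polysomes=30, seed=3)
        _, gt = simulate_condition(cfg, render=False)
        gt.validate()
        seen = [pid for seq in gt.mrna_order.values() for pid in seq]
        assert sorted(seen) == sorted(gt.membership)
        for poly, seq in gt.mrna_order.items():
            expected = len(seq) if gt.closed[poly] else len(seq) - 1
            assert gt.n_links(poly) == max(expected, 0)

    def test_ground_truth_self_consistency_with_tracer(self):
        """Path inference on jitter-free generated poses reproduces the
        generated 5'->3' order for every polysome."""
        cfg = GeneratorConfig(n_polysomes=12, seed=21, orientation_jitter_deg=0.0,
                              size_distribution={n: 0.25 for n in (4, 5, 6, 7)})
        _, gt = simulate_condition(cfg, render=False)
        tcfg = TraceConfig()
        for poly, seq in gt.mrna_order.items():
            poses = [p for p in gt.poses if gt.membership[p.particle_id] == poly]
            group = PolysomeGroup(poly, [p.particle_id for p in poses], poses)
            path = solve_path(group, candidate_links(group, None, tcfg), tcfg)
            assert path.feasible and path.closed == gt.closed[poly]
            got = path.order
            if path.closed:
                k = got.index(seq[0])
                got = got[k:] + got[:k]
            assert got == seq
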