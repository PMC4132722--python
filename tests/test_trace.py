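"""mRNA path inference: link scoring, exact path search, topology labels."""
import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polytomo import (GeneratorConfig, Pose, TraceConfig, candidate_links,
                      classify_topology, sample_polysome, solve_path,
                      transform_pose)
from polytomo.polysomes import PolysomeGroup
from polytomo.ribosome import body_landmarks
from polytomo.simulate import TOPOLOGIES, _effective_topology
from polytomo.trace import _dp_best, _enumerate_best, trace_polysome


def _group_for(topology, n, rng, jitter=0.0, occupancy=120.0):
    cfg = GeneratorConfig(orientation_jitter_deg=jitter)
    poses, order, closed = sample_polysome(topology, n, cfg, rng,
                                           occupancy_nt=occupancy)
    group = PolysomeGroup("g", [p.particle_id for p in poses], poses)
    return group, order, closed


def _brute_force(cost, closed):
    """Independent itertools enumeration of the minimum feasible route."""
    n = cost.shape[0]
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(n)):
        if closed and perm[0] != 0:
            continue
        total = sum(cost[a, b] for a, b in zip(perm, perm[1:]))
        if closed:
            total += cost[perm[-1], perm[0]]
        if total < best_cost:
            best, best_cost = list(perm), total
    return best, best_cost


class TestCandidateLinks:
    def test_coincident_sites_give_zero_feasible_spacer(self):
        lm = body_landmarks()
        rot = Rotation.identity()
        a = Pose("a", np.zeros(3), rot)
        # place b so that b's entry lands exactly on a's exit
        b = Pose("b", lm["mrna_exit"] - lm["mrna_entry"], rot)
        group = PolysomeGroup("g", ["a", "b"], [a, b])
        links = {(l.from_particle, l.to_particle): l
                 for l in candidate_links(group, None, TraceConfig())}
        ab = links[("a", "b")]
        assert ab.spacer_nm == pytest.approx(0.0, abs=1e-9)
        assert ab.feasible

    def test_occupancy_budget_arithmetic(self):
        """140 nt occupancy minus a 30 nt footprint at 0.34 nm/nt caps the
        spacer at 37.4 nm, so a 40 nm link is infeasible."""
        cfg = TraceConfig(occupancy_nt=140.0)
        assert cfg.max_spacer_nm(6) == pytest.approx(37.4)
        rot = Rotation.identity()
        lm = body_landmarks()
        offset = lm["mrna_exit"] - lm["mrna_entry"]
        a = Pose("a", np.zeros(3), rot)
        b = Pose("b", offset + np.array([40.0, 0.0, 0.0]), rot)
        group = PolysomeGroup("g", ["a", "b"], [a, b])
        links = {(l.from_particle, l.to_particle): l
                 for l in candidate_links(group, None, cfg)}
        assert links[("a", "b")].spacer_nm == pytest.approx(40.0)
        assert not links[("a", "b")].feasible

    def test_spacer_equals_euclidean_landmark_distance(self, rng):
        lm = body_landmarks()
        poses = [Pose(f"p{i}", rng.uniform(-40, 40, 3), Rotation.random(rng=rng))
                 for i in range(4)]
        group = PolysomeGroup("g", [p.particle_id for p in poses], poses)
        links = candidate_links(group, None, TraceConfig())
        by_pair = {(l.from_particle, l.to_particle): l.spacer_nm for l in links}
        for i, j in itertools.permutations(range(4), 2):
            exit_w = poses[i].matrix @ lm["mrna_exit"] + poses[i].position
            entry_w = poses[j].matrix @ lm["mrna_entry"] + poses[j].position
            expected = np.linalg.norm(entry_w - exit_w)
            assert by_pair[(f"p{i}", f"p{j}")] == pytest.approx(expected, abs=1e-9)

    def test_missing_pose_raises(self):
        pose = Pose("a", np.zeros(3), Rotation.identity())
        pose.rotation = None
        group = PolysomeGroup("g", ["a"], [pose])
        with pytest.raises(ValueError, match="a"):
            candidate_links(group, None, TraceConfig())


class TestSolvePath:
    def test_two_members_forced_link(self, rng):
        group, order, _ = _group_for("linear_single_row", 2, rng)
        links = candidate_links(group, None, TraceConfig())
        path = solve_path(group, links, TraceConfig())
        assert path.feasible and not path.closed
        assert path.order == ["p0", "p1"]
        feasible = [l for l in links if l.feasible]
        assert path.total_cost == pytest.approx(min(l.spacer_nm for l in feasible))

    def test_hexamer_ring_recovered_as_closed_cycle(self, rng):
        group, order, _ = _group_for("circular_ring", 6, rng)
        path = solve_path(group, candidate_links(group, None, TraceConfig()),
                          TraceConfig())
        assert path.closed and path.unique
        got = [int(p[1:]) for p in path.order]
        k = got.index(0)
        assert got[k:] + got[:k] == list(range(6))

    @pytest.mark.parametrize("closed", [False, True])
    def test_enumeration_matches_independent_brute_force(self, closed, rng):
        """Random feasible cost matrices, n = 7: the solver's optimum equals
        a second, independently coded full enumeration."""
        for _ in range(5):
            cost = rng.uniform(5, 40, size=(7, 7))
            cost[rng.random((7, 7)) < 0.2] = np.inf
            np.fill_diagonal(cost, np.inf)
            order, total, _ = _enumerate_best(cost, closed, lambda o: False)
            oracle_order, oracle_total = _brute_force(cost, closed)
            if not np.isfinite(oracle_total):
                assert order is None
            else:
                assert total == pytest.approx(oracle_total)

    @pytest.mark.parametrize("closed", [False, True])
    def test_held_karp_matches_enumeration(self, closed, rng):
        for _ in range(3):
            cost = rng.uniform(5, 40, size=(8, 8))
            cost[rng.random((8, 8)) < 0.15] = np.inf
            np.fill_diagonal(cost, np.inf)
            _, total_dp, _ = _dp_best(cost, closed, lambda o: False)
            _, total_en, _ = _enumerate_best(cost, closed, lambda o: False)
            assert total_dp == pytest.approx(total_en)

    def test_conservation_of_link_costs(self, rng):
        for topo in ("circular_ring", "helical"):
            group, _, _ = _group_for(topo, 6, rng, jitter=5.0)
            path = solve_path(group, candidate_links(group, None, TraceConfig()),
                              TraceConfig())
            assert sum(path.link_costs) == pytest.approx(path.total_cost, abs=1e-9)

    def test_tightening_budget_never_creates_feasibility(self, rng):
        """Monotonicity: if no feasible route exists at some spacer budget,
        none exists at any tighter budget."""
        group, _, _ = _group_for("linear_single_row", 5, rng)
        feasible_at = {}
        for occupancy in (40.0, 60.0, 80.0, 100.0, 140.0):
            cfg = TraceConfig(occupancy_nt=occupancy)
            path = solve_path(group, candidate_links(group, None, cfg), cfg)
            feasible_at[occupancy] = path.feasible
        budgets = sorted(feasible_at)
        for lo, hi in zip(budgets, budgets[1:]):
            assert not (feasible_at[lo] and not feasible_at[hi])

    def test_oversized_group_refused(self, rng):
        poses = [Pose(f"p{i}", np.array([30.0 * i, 0, 0]), Rotation.identity())
                 for i in range(13)]
        group = PolysomeGroup("g", [p.particle_id for p in poses], poses)
        with pytest.raises(ValueError):
            solve_path(group, [], TraceConfig())

    def test_isolated_particles_unroutable(self, rng):
        poses = [Pose(f"p{i}", np.array([200.0 * i, 0, 0]), Rotation.identity())
                 for i in range(4)]
        group = PolysomeGroup("g", [p.particle_id for p in poses], poses)
        path = solve_path(group, candidate_links(group, None, TraceConfig()),
                          TraceConfig())
        assert not path.feasible and path.order is None
        assert classify_topology(group, path, TraceConfig()) == "unassigned"


class TestClassifyTopology:
    def test_noiseless_ring_hexamer_is_circular_ring(self, rng):
        group, _, _ = _group_for("circular_ring", 6, rng)
        cfg = TraceConfig()
        path = solve_path(group, candidate_links(group, None, cfg), cfg)
        assert classify_topology(group, path, cfg) == "circular_ring"

    def test_trisome_never_assigned(self, rng):
        group, _, _ = _group_for("circular_ring", 3, rng)
        cfg = TraceConfig()
        path = solve_path(group, candidate_links(group, None, cfg), cfg)
        assert classify_topology(group, path, cfg) == "unassigned"

    def test_serpentine_heptamer_is_linear_double_row(self, rng):
        group, _, _ = _group_for("linear_double_row", 7, rng)
        cfg = TraceConfig()
        path = solve_path(group, candidate_links(group, None, cfg), cfg)
        assert not path.closed
        assert classify_topology(group, path, cfg) == "linear_double_row"

    @pytest.mark.parametrize("topology", TOPOLOGIES)
    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_perfect_classification_on_noiseless_polysomes(self, topology, n, rng):
        """Every generated topology at n >= 4 is labelled exactly, without
        noise or jitter, including under a random rigid transform."""
        group, order, closed = _group_for(topology, n, rng)
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-200, 200, 3)
        moved = [transform_pose(p, rot, shift) for p in group.poses]
        group = PolysomeGroup("g", group.particle_ids, moved)
        cfg = TraceConfig()
        path = solve_path(group, candidate_links(group, None, cfg), cfg)
        assert path.closed == closed
        assert classify_topology(group, path, cfg) == _effective_topology(topology, n)

    def test_pipeline_invariant_under_relabelling_and_rigid_motion(self, rng):
        group, _, _ = _group_for("circular_double_row", 8, rng, jitter=3.0)
        cfg = TraceConfig()
        row = trace_polysome(group, None, cfg)
        # relabel particles and move the whole polysome
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-100, 100, 3)
        perm = rng.permutation(len(group))
        poses = []
        for new_idx, old_idx in enumerate(perm):
            p = transform_pose(group.poses[old_idx], rot, shift)
            p.particle_id = f"q{new_idx}"
            poses.append(p)
        regrouped = PolysomeGroup("g2", [p.particle_id for p in poses], poses)
        row2 = trace_polysome(regrouped, None, cfg)
        assert row2["label"] == row["label"]
        assert row2["closed"] == row["closed"]
        assert row2["total_cost_nm"] == pytest.approx(row["total_cost_nm"], abs=1e-6)
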