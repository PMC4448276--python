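"""Morphometrics: divergence angles, collisions, bead distance, kinematics."""

import math

import numpy as np
import pandas as pd
import pytest

from selfavoid.core import Element, TubuleTree
from selfavoid.morphometrics import (
    angles_by_generation,
    closest_approach_to_disc,
    closing_speed_table,
    detect_collisions,
    divergence_angle,
    tip_speeds,
    validate_track_table,
)
from tests.conftest import build_tree


def track(tip_id, points, times=None):
    times = times if times is not None else list(range(len(points)))
    return pd.DataFrame(
        {"time_h": times, "tip_id": tip_id,
         "x": [p[0] for p in points], "y": [p[1] for p in points]}
    )


class TestDivergenceAngle:
    def test_orthogonal_diagonals_give_90(self, vee_tree):
        assert divergence_angle(vee_tree, (10, 4), L=6) == pytest.approx(90.0)

    def test_parallel_daughters_give_0(self):
        # two straight daughters along the same direction (synthetic
        # degenerate tree; legal as pure topology)
        trunk = [(10, y) for y in range(3)]
        d1 = [(10, 3 + i) for i in range(1, 6)]
        d2 = [(11, 2 + i) for i in range(1, 6)]
        tree = build_tree((trunk, [(2, d1), (2, d2)]))
        ang = divergence_angle(tree, (10, 2), L=4)
        assert ang < 16  # nearly parallel given 1-cell lateral offset

    def test_opposite_daughters_give_180(self):
        trunk = [(10, y) for y in range(3)]
        d1 = [(10 + i, 2) for i in range(1, 6)]
        d2 = [(10 - i, 2) for i in range(1, 6)]
        tree = build_tree((trunk, [(2, d1), (2, d2)]))
        assert divergence_angle(tree, (10, 2), L=4) == pytest.approx(180.0)

    def test_curved_daughter_matches_hand_oracle(self):
        # daughter A: 4 diagonal then 3 east; daughter B straight west.
        # walk stops at the first cell with arc >= 7: A reaches (16, 5) at
        # arc 4*sqrt(2)+2 ~ 7.66 -> vector (6, 4); B stops at (5, 1): (-5, 0)
        trunk = [(10, 0), (10, 1)]
        a = [(11, 2), (12, 3), (13, 4), (14, 5), (15, 5), (16, 5), (17, 5)]
        b = [(9, 1), (8, 1), (7, 1), (6, 1), (5, 1), (4, 1)]
        tree = build_tree((trunk, [(1, a), (1, b)]))
        expected = math.degrees(
            math.acos(np.dot([6, 4], [-5, 0]) / (math.hypot(6, 4) * 5.0))
        )
        assert divergence_angle(tree, (10, 1), L=7) == pytest.approx(
            expected, abs=1e-9
        )

    def test_requires_exactly_two_daughters(self, vee_tree):
        with pytest.raises(ValueError):
            divergence_angle(vee_tree, (10, 0), L=5)  # root: 1 child
        with pytest.raises(ValueError):
            divergence_angle(vee_tree, (99, 99), L=5)  # not in tree

    def test_daughter_swap_symmetric(self, vee_tree):
        # reverse element order of the two daughter chains
        ang1 = divergence_angle(vee_tree, (10, 4), L=6)
        trunk = [(10, y) for y in range(5)]
        right = [(10 + i, 4 + i) for i in range(1, 8)]
        left = [(10 - i, 4 + i) for i in range(1, 8)]
        swapped = build_tree((trunk, [(4, left), (4, right)]))
        assert divergence_angle(swapped, (10, 4), L=6) == pytest.approx(ang1)

    def test_quarter_turn_rotation_invariant(self, vee_tree):
        rot = TubuleTree(tree_id=0)
        for e in vee_tree.elements:
            x, y = e.cell
            rot.elements.append(Element((-y, x), e.kind, e.parent,
                                        e.generation, e.birth_step))
        assert divergence_angle(rot, (-4, 10), L=6) == pytest.approx(
            divergence_angle(vee_tree, (10, 4), L=6), abs=0.5
        )


class TestAnglesByGeneration:
    def test_single_bifurcation_single_record(self, vee_tree):
        table, recs = angles_by_generation(vee_tree, L=6)
        assert set(table) == {1}
        assert len(recs) == 1
        assert recs[0].branch_point == (10, 4)

    def test_generation_labels_follow_daughters(self):
        trunk = [(50, y) for y in range(4)]
        tree = build_tree((trunk, []))
        # gen-1 daughters, one of which branches again (gen 2)
        r = [(51 + i, 3 + i) for i in range(5)]
        l = [(49 - i, 3 + i) for i in range(5)]
        tree = build_tree((trunk, [(3, r), (3, l)]))
        for e in tree.elements[4:]:
            e.generation = 1
        rr = [(56 + i, 8) for i in range(4)]
        rl = [(54 - i, 8) for i in range(4)]
        for chain in (rr, rl):
            idx = 8  # last cell of r
            for cell in chain:
                tree.elements.append(Element(cell, "stalk", idx, 2, 0))
                idx = len(tree.elements) - 1
        table, _ = angles_by_generation(tree, L=3)
        assert set(table) == {1, 2}
        assert len(table[1]) == 1 and len(table[2]) == 1


class TestCollisions:
    def two_trees(self, gap):
        a = build_tree(([(10, y) for y in range(5)], []))
        b = build_tree(([(10 + gap, y) for y in range(5)], []))
        b.tree_id = 1
        return [a, b]

    def test_contact_at_threshold(self):
        events, verdict = detect_collisions(self.two_trees(1), 1)
        assert verdict
        assert all(e.type == "inter_tree" for e in events)
        assert {tid for e in events for tid in e.tree_ids} == {0, 1}

    def test_no_contact_beyond_threshold(self):
        events, verdict = detect_collisions(self.two_trees(2), 1)
        assert not verdict and not events

    def test_verdict_monotone_in_threshold(self):
        trees = self.two_trees(2)
        none, v1 = detect_collisions(trees, 1)
        some, v2 = detect_collisions(trees, 2)
        assert not v1 and v2
        assert len(some) >= len(none)

    def test_hairpin_self_loop(self):
        # a tubule that runs up, turns, and comes back beside itself
        up = [(10, y) for y in range(9)]
        over = [(11, 8)]
        down = [(11, 7 - i) for i in range(8)]
        tree = build_tree((up + over + down, []))
        events, verdict = detect_collisions([tree], 1,
                                            self_loop_path_cutoff=10)
        assert verdict
        assert {e.type for e in events} == {"self_loop"}

    def test_parent_child_adjacency_is_not_a_loop(self, vee_tree):
        events, verdict = detect_collisions([vee_tree], 1)
        assert not verdict


class TestBeadDistance:
    def test_single_cell_geometry(self):
        tree = build_tree(([(10, 10)], []))
        assert closest_approach_to_disc(tree, (10, 20), 4.0) == pytest.approx(6.0)

    def test_inside_disc_is_zero(self):
        tree = build_tree(([(10, 10)], []))
        assert closest_approach_to_disc(tree, (11, 11), 4.0) == 0.0

    def test_matches_exhaustive_minimum(self, vee_tree):
        center, radius = (20.0, 3.0), 2.5
        brute = min(
            max(0.0, math.hypot(x - center[0], y - center[1]) - radius)
            for x, y in vee_tree.cells()
        )
        assert closest_approach_to_disc(vee_tree, center, radius) == pytest.approx(brute)

    def test_radius_validated(self, vee_tree):
        with pytest.raises(ValueError):
            closest_approach_to_disc(vee_tree, (0, 0), 0.0)


class TestTipSpeeds:
    def test_three_four_five_triangle(self):
        t = track("a", [(0, 0), (3, 4)])
        out = tip_speeds(t, stride=1)
        assert out.speed.tolist() == [5.0]

    def test_stationary_tip(self):
        t = track("a", [(2, 2)] * 4)
        assert tip_speeds(t, stride=1).speed.tolist() == [0.0, 0.0, 0.0]

    def test_unequal_intervals_hand_check(self):
        t = track("a", [(0, 0), (0, 6), (8, 6)], times=[0.0, 2.0, 3.0])
        out = tip_speeds(t, stride=1)
        assert out.speed.tolist() == pytest.approx([3.0, 8.0])

    def test_stride_samples_frame_pairs(self):
        pts = [(i, 0) for i in range(11)]
        out = tip_speeds(track("a", pts), stride=5)
        # frame pairs (0,1), (5,6), (10,-) -> last has no successor
        assert out.time_h.tolist() == [0.0, 5.0]

    def test_duplicate_times_rejected(self):
        # out-of-order rows are re-sorted, but coincident timestamps can
        # never form a strictly increasing track
        t = track("a", [(0, 0), (1, 0), (2, 0)], times=[0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            tip_speeds(t, stride=1)


class TestClosingSpeed:
    def test_approach_positive_by_convention(self):
        a = track("a", [(0, 0), (0, 0)])
        b = track("b", [(10, 0), (7, 0)])
        out = closing_speed_table(a, b)
        assert out.separation.tolist() == [10.0]
        assert out.closing_speed.tolist() == [3.0]
        assert out.raw_velocity.tolist() == [-3.0]

    def test_static_pair_zero(self):
        a = track("a", [(0, 0)] * 3)
        b = track("b", [(5, 5)] * 3)
        out = closing_speed_table(a, b)
        assert out.closing_speed.tolist() == [0.0, 0.0]

    def test_pythagoras_oracle(self):
        a = track("a", [(0, 0), (0, 0)])
        b = track("b", [(30, 40), (27, 36)])
        out = closing_speed_table(a, b)
        assert out.separation.tolist() == [50.0]
        assert out.closing_speed.tolist() == [5.0]

    def test_head_on_equals_tip_speed(self):
        mover = [(20 - 2 * i, 0) for i in range(6)]
        a = track("a", [(0, 0)] * 6)
        b = track("b", mover)
        cs = closing_speed_table(a, b).closing_speed
        sp = tip_speeds(track("b", mover), stride=1).speed
        assert cs.tolist() == pytest.approx(sp.tolist())

    def test_mismatched_times_rejected(self):
        a = track("a", [(0, 0), (0, 0)], times=[0.0, 1.0])
        b = track("b", [(9, 0), (8, 0)], times=[0.0, 1.5])
        with pytest.raises(ValueError):
            closing_speed_table(a, b)

    def test_track_validation(self):
        bad = pd.DataFrame({"time_h": [0], "x": [1], "y": [2]})
        with pytest.raises(ValueError):
            validate_track_table(bad)
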