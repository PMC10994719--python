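"""Occupancy grid and Euclidean/topological distance computation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from xlinkval.distances import (
    AnchorAtom,
    DistanceError,
    OccupancyGrid,
    anchor_atom,
    build_occupancy_grid,
    euclidean_distance,
    grid_shortest_path,
    segment_is_free,
    topological_distance,
)
from xlinkval.fixtures import make_helix_chain
from xlinkval.io import Atom, Chain, Residue, RunConfig, StructureModel

from conftest import dijkstra_grid_distance

SQRT3 = math.sqrt(3.0)


def point_anchor(x, y, z, chain="A"):
    return AnchorAtom(chain, 1, "", "CB", x, y, z)


def empty_grid(shape=(20, 20, 20), spacing=1.0):
    return OccupancyGrid(origin=np.zeros(3), spacing=spacing,
                         blocked=np.zeros(shape, dtype=bool))


class TestAnchorAtom:
    def residue(self, name, atom_names):
        atoms = tuple(Atom(a, "C", float(i), 0.0, 0.0) for i, a in enumerate(atom_names))
        return Residue(1, "", name, atoms)

    def structure(self, res):
        return StructureModel("s", "experimental", 2.0, [Chain("A", [res])])

    def test_beta_carbon_preferred(self):
        st = self.structure(self.residue("ALA", ["N", "CA", "CB"]))
        assert anchor_atom(st, "A", (1, "")).atom_name == "CB"

    def test_glycine_uses_alpha_carbon(self):
        st = self.structure(self.residue("GLY", ["N", "CA"]))
        assert anchor_atom(st, "A", (1, "")).atom_name == "CA"

    def test_backbone_only_residue_is_error(self):
        st = self.structure(self.residue("ALA", ["N"]))
        with pytest.raises(DistanceError):
            anchor_atom(st, "A", (1, ""))

    def test_alpha_mode_forces_ca(self):
        st = self.structure(self.residue("ALA", ["N", "CA", "CB"]))
        assert anchor_atom(st, "A", (1, ""), mode="ca").atom_name == "CA"


class TestEuclidean:
    def test_identical_points(self):
        a = point_anchor(1, 2, 3)
        assert euclidean_distance(a, a) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance(point_anchor(0, 0, 0), point_anchor(3, 4, 0)) == 5.0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p, q = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
            expected = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
            assert euclidean_distance(point_anchor(*p), point_anchor(*q)) == pytest.approx(expected)


class TestOccupancyGrid:
    def test_single_atom_blocks_exactly_inflated_sphere(self):
        cfg = RunConfig(grid_padding=6.0, clearance_radius=0.0)
        st = StructureModel(
            "s", "experimental", 2.0,
            [Chain("A", [Residue(1, "", "ALA",
                                 (Atom("CA", "C", 0.0, 0.0, 0.0),))])],
        )
        grid = build_occupancy_grid(st, [], cfg)
        r = 1.7 + cfg.probe_radius  # carbon vdW + probe
        idx = np.argwhere(np.ones_like(grid.blocked))
        centers = grid.origin + (idx + 0.5) * grid.spacing
        inside = np.linalg.norm(centers, axis=1) <= r
        assert np.array_equal(grid.blocked.ravel(), inside)

    def test_endpoint_clearance_carves_free_voxels(self):
        cfg = RunConfig(grid_padding=6.0)
        chain = make_helix_chain(10, "A" * 10, "A")
        st = StructureModel("s", "experimental", 2.0, [chain])
        ca5 = chain.residues[4].atom("CA")
        grid = build_occupancy_grid(st, [np.array(ca5.pos)], cfg)
        v = grid.voxel_of(ca5.pos)
        assert not grid.is_blocked(v)

    def test_no_atoms_means_no_blocked_voxels(self):
        cfg = RunConfig(grid_padding=5.0)
        st = StructureModel(
            "s", "experimental", 2.0,
            [Chain("A", [Residue(1, "", "ALA",
                                 (Atom("CA", "C", 0.0, 0.0, 0.0),))])],
        )
        grid = build_occupancy_grid(st, [], cfg, chain_ids=set())  # exclude all
        assert not grid.blocked.any()


class TestTopologicalDistance:
    def test_free_space_equals_euclidean(self):
        grid = empty_grid()
        a, b = point_anchor(2.5, 2.5, 2.5), point_anchor(12.5, 9.5, 4.5)
        d, capped = topological_distance(grid, a, b)
        assert not capped
        assert d == pytest.approx(euclidean_distance(a, b))

    def test_wall_with_gap_matches_independent_dijkstra(self):
        blocked = np.zeros((21, 21, 21), dtype=bool)
        blocked[10, :, :] = True
        blocked[10, 15, 15] = False  # one off-center gap
        grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
        start, goal = (3, 5, 5), (17, 5, 5)
        ours, capped = grid_shortest_path(grid, start, goal)
        oracle = dijkstra_grid_distance(blocked, 1.0, start, goal)
        assert not capped
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_closed_box_is_unreachable(self):
        blocked = np.zeros((15, 15, 15), dtype=bool)
        blocked[4:11, 4:11, 4:11] = True
        blocked[5:10, 5:10, 5:10] = False  # hollow interior
        grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
        inside = point_anchor(7.5, 7.5, 7.5)
        outside = point_anchor(1.5, 1.5, 1.5)
        d, capped = topological_distance(grid, inside, outside)
        assert d is None
        assert not capped  # exhausted, not abandoned

    def test_cap_abandons_long_searches(self):
        blocked = np.zeros((30, 9, 9), dtype=bool)
        blocked[15, :, :] = True  # full wall, no gap
        grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
        d, capped = grid_shortest_path(grid, (2, 4, 4), (27, 4, 4), cap=30.0)
        assert d is None
        assert capped

    def test_endpoint_outside_grid_is_error(self):
        grid = empty_grid((5, 5, 5))
        with pytest.raises(DistanceError):
            topological_distance(grid, point_anchor(2, 2, 2), point_anchor(50, 2, 2))

    def test_straight_segment_detects_obstacles(self):
        blocked = np.zeros((11, 11, 11), dtype=bool)
        blocked[5, 5, 5] = True
        grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
        assert not segment_is_free(grid, (0.5, 5.5, 5.5), (10.5, 5.5, 5.5))
        assert segment_is_free(grid, (0.5, 1.5, 1.5), (10.5, 1.5, 1.5))


def random_obstacle_grid(rng, shape=(14, 14, 14), fill=0.15):
    blocked = rng.random(shape) < fill
    return blocked


class TestInvariants:
    def test_symmetry_on_random_grids(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 50:
            blocked = random_obstacle_grid(rng)
            grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
            s = tuple(rng.integers(0, 14, 3))
            g = tuple(rng.integers(0, 14, 3))
            if blocked[s] or blocked[g]:
                continue
            d1, _ = grid_shortest_path(grid, s, g)
            d2, _ = grid_shortest_path(grid, g, s)
            if d1 is None:
                assert d2 is None
            else:
                assert d1 == pytest.approx(d2, abs=1e-9)
            checked += 1

    def test_lower_bound_against_euclidean(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 50:
            blocked = random_obstacle_grid(rng)
            grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
            pa = rng.uniform(0.5, 13.5, 3)
            pb = rng.uniform(0.5, 13.5, 3)
            a, b = point_anchor(*pa), point_anchor(*pb)
            if blocked[grid.voxel_of(pa)] or blocked[grid.voxel_of(pb)]:
                continue
            d, _ = topological_distance(grid, a, b)
            if d is not None:
                assert d >= euclidean_distance(a, b) - grid.spacing * SQRT3 - 1e-9
            checked += 1

    def test_adding_obstacles_never_shortens_paths(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            blocked = random_obstacle_grid(rng, fill=0.10)
            more = blocked | (rng.random(blocked.shape) < 0.10)
            s, g = (1, 1, 1), (12, 12, 12)
            if blocked[s] or blocked[g] or more[s] or more[g]:
                continue
            grid1 = OccupancyGrid(np.zeros(3), 1.0, blocked)
            grid2 = OccupancyGrid(np.zeros(3), 1.0, more)
            d1, _ = grid_shortest_path(grid1, s, g)
            d2, _ = grid_shortest_path(grid2, s, g)
            if d1 is None:
                assert d2 is None
            elif d2 is not None:
                assert d2 >= d1 - 1e-9

    def test_grid_refinement_changes_free_space_distance_little(self):
        # voxel path length between fixed points at spacing 1.0 vs 0.5
        p, q = np.array([2.3, 2.3, 2.3]), np.array([11.2, 7.9, 5.4])
        lengths = []
        for spacing in (1.0, 0.5):
            n = int(16 / spacing)
            grid = OccupancyGrid(np.zeros(3), spacing,
                                 np.zeros((n, n, n), dtype=bool))
            d, _ = grid_shortest_path(grid, grid.voxel_of(p), grid.voxel_of(q))
            lengths.append(d)
        assert abs(lengths[0] - lengths[1]) / lengths[1] <= 0.05

    def test_oracle_equivalence_on_random_small_grids(self):
        rng = np.random.default_rng(15)
        checked = 0
        while checked < 15:
            blocked = random_obstacle_grid(rng, shape=(10, 10, 10), fill=0.2)
            s = tuple(rng.integers(0, 10, 3))
            g = tuple(rng.integers(0, 10, 3))
            if blocked[s] or blocked[g]:
                continue
            grid = OccupancyGrid(np.zeros(3), 1.0, blocked)
            ours, _ = grid_shortest_path(grid, s, g)
            oracle = dijkstra_grid_distance(blocked, 1.0, s, g)
            if ours is None:
                assert oracle is None
            else:
                assert ours == pytest.approx(oracle, abs=1e-9)
            checked += 1
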