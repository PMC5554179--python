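"""Structural observables vs closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from hydrosorb.analysis import (Frame, as_frame, sasa, radius_of_gyration,
                                residue_distance_map, distance_map_difference,
                                water_clusters, largest_cluster_curve,
                                shell_count_distribution, rdf, first_minimum,
                                local_hydration_difference, block_average,
                                golden_spiral_points, DistanceMap)
from hydrosorb.fixtures import generate_percolation_fixture
from hydrosorb.model import Box


def water_frame(positions, box_length=20.0, periodic=True):
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    return Frame(positions=positions, is_water=np.ones(n, dtype=bool),
                 residue_ids=np.full(n, -1),
                 box=Box([box_length] * 3, periodic=[periodic] * 3))


def matrix_frame(positions, residue_ids, box_length=20.0, radii=None,
                 masses=None, waters=None):
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    is_water = np.zeros(n, dtype=bool)
    rid = np.asarray(residue_ids)
    if waters is not None:
        waters = np.asarray(waters, dtype=float).reshape(-1, 3)
        positions = np.vstack([positions, waters])
        is_water = np.concatenate([is_water, np.ones(len(waters), dtype=bool)])
        rid = np.concatenate([rid, np.full(len(waters), -1)])
    return Frame(positions=positions, is_water=is_water, residue_ids=rid,
                 box=Box([box_length] * 3), radii=radii, masses=masses)


def brute_min_image_dist(a, b, L):
    d = np.asarray(a) - np.asarray(b)
    d -= L * np.floor(d / L + 0.5)
    return math.sqrt(float(d @ d))


class TestSasa:
    def test_sphere_points_are_unit(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_isolated_sphere(self):
        f = matrix_frame([[10, 10, 10]], [0], radii=np.array([1.2]))
        _, total = sasa(f, probe_radius=0.4, n_sphere_points=960)
        assert total == pytest.approx(4 * math.pi * 1.6 ** 2, rel=0.01)

    def test_coincident_spheres_share_one_surface(self):
        f = matrix_frame([[10, 10, 10], [10, 10, 10]], [0, 1],
                         radii=np.array([1.0, 1.0]))
        _, total = sasa(f, probe_radius=0.4, n_sphere_points=960)
        assert total == pytest.approx(4 * math.pi * 1.4 ** 2, rel=0.02)

    @pytest.mark.parametrize("d", [0.8, 1.5, 2.2])
    def test_two_sphere_spherical_cap_closed_form(self, d):
        R = 1.4  # radius + probe for both spheres
        f = matrix_frame([[10, 10, 10], [10 + d, 10, 10]], [0, 1],
                         radii=np.array([1.0, 1.0]))
        _, total = sasa(f, probe_radius=0.4, n_sphere_points=960)
        cap = 2 * math.pi * R * (R - d / 2)  # buried cap area per sphere
        expected = 2 * (4 * math.pi * R * R - cap)
        assert total == pytest.approx(expected, rel=0.01)

    def test_burial_monotonicity(self):
        f = matrix_frame([[10, 10, 10], [13, 10, 10], [10, 13, 10]],
                         [0, 1, 2])
        _, apart = sasa(f, probe_radius=0.5)
        f.positions[1] = [10.6, 10, 10]
        _, buried = sasa(f, probe_radius=0.5)
        assert buried <= apart

    def test_periodic_neighbor_occlusion(self):
        # neighbors across the boundary occlude just like direct ones
        f = matrix_frame([[0.2, 5, 5], [9.8, 5, 5]], [0, 1], box_length=10.0)
        _, total = sasa(f, probe_radius=0.4, n_sphere_points=960)
        g = matrix_frame([[5.0, 5, 5], [5.4, 5, 5]], [0, 1], box_length=10.0)
        _, expected = sasa(g, probe_radius=0.4, n_sphere_points=960)
        assert total == pytest.approx(expected, rel=1e-9)


class TestRadiusOfGyration:
    def test_two_particles(self):
        f = matrix_frame([[5, 5, 5], [8, 5, 5]], [0, 0])
        assert radius_of_gyration(f, [[0, 1]]) == pytest.approx(1.5)

    def test_cube_corners(self):
        a = 2.0
        corners = [[i, j, k] for i in (0, a) for j in (0, a) for k in (0, a)]
        f = matrix_frame(np.array(corners) + 5.0, list(range(8)))
        assert radius_of_gyration(f, [list(range(8))]) == \
            pytest.approx(a * math.sqrt(3) / 2)

    def test_mass_weighted_brute_force(self, rng):
        pos = rng.random((20, 3)) * 4 + 8
        masses = rng.random(20) + 0.5
        f = matrix_frame(pos, list(range(20)), masses=masses)
        got = radius_of_gyration(f, [np.arange(20)])
        com = (masses[:, None] * pos).sum(0) / masses.sum()
        rg = math.sqrt((masses * ((pos - com) ** 2).sum(1)).sum() / masses.sum())
        assert got == pytest.approx(rg, abs=1e-12)

    def test_unwrap_across_boundary(self):
        # 4-bead chain straddling the periodic boundary, bonds provided
        pos = [[19.0, 5, 5], [19.9, 5, 5], [0.8, 5, 5], [1.7, 5, 5]]
        bonds = np.array([[0, 1], [1, 2], [2, 3]])
        f = matrix_frame(pos, [0, 1, 2, 3])
        got = radius_of_gyration(f, [np.arange(4)], bonds)
        flat = matrix_frame([[0, 5, 5], [0.9, 5, 5], [1.8, 5, 5],
                             [2.7, 5, 5]], [0, 1, 2, 3])
        want = radius_of_gyration(flat, [np.arange(4)])
        assert got == pytest.approx(want, abs=1e-12)

    def test_disconnected_group_raises(self):
        f = matrix_frame([[1, 5, 5], [10, 5, 5], [11, 5, 5]], [0, 1, 2])
        with pytest.raises(ValueError, match="split"):
            radius_of_gyration(f, [np.arange(3)], np.array([[1, 2]]))


class TestDistanceMaps:
    def test_single_particle_residues(self):
        f = matrix_frame([[5, 5, 5], [10, 5, 5]], [0, 1])
        dmap = residue_distance_map([f])
        assert dmap.values[0, 1] == pytest.approx(5.0)
        assert dmap.values[0, 0] == 0.0
        assert np.allclose(dmap.values, dmap.values.T)

    def test_brute_force_oracle(self, rng):
        frames = []
        for _ in range(2):
            pos = rng.random((12, 3)) * 18
            frames.append(matrix_frame(pos, np.repeat([0, 1, 2], 4),
                                       box_length=18.0))
        dmap = residue_distance_map(frames)
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                vals = []
                for f in frames:
                    best = min(
                        brute_min_image_dist(f.positions[i], f.positions[j],
                                             18.0)
                        for i in range(a * 4, a * 4 + 4)
                        for j in range(b * 4, b * 4 + 4))
                    vals.append(best)
                assert dmap.values[a, b] == pytest.approx(np.mean(vals),
                                                          abs=1e-12)

    def test_copy_averaging(self, rng):
        pos = rng.random((8, 3)) * 15
        f = matrix_frame(pos, list(range(8)), box_length=15.0)
        copies = [[[0], [1], [2], [3]], [[4], [5], [6], [7]]]
        dmap = residue_distance_map([f], grouping=copies)
        m1 = residue_distance_map([f], grouping=[[0], [1], [2], [3]]).values
        m2 = residue_distance_map([f], grouping=[[4], [5], [6], [7]]).values
        assert np.allclose(dmap.values, 0.5 * (m1 + m2), atol=1e-12)

    def test_difference(self, rng):
        a = rng.random((4, 4))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0)
        same = distance_map_difference(DistanceMap(a, 1), DistanceMap(a, 1))
        assert np.all(same == 0)
        swollen = distance_map_difference(DistanceMap(1.1 * a, 1),
                                          DistanceMap(a, 1))
        off = ~np.eye(4, dtype=bool) & (a > 0)
        assert np.all(swollen[off] > 0)
        with pytest.raises(ValueError, match="shape"):
            distance_map_difference(a, a[:3, :3])


class TestWaterClusters:
    def test_chain_under_cutoff(self):
        f = water_frame([[5, 5, 5], [8, 5, 5], [11, 5, 5]])
        res = water_clusters(f, cutoff=3.5)
        assert len(res.sizes) == 1 and res.largest_fraction == 1.0

    def test_singletons_above_cutoff(self):
        f = water_frame([[5, 5, 5], [9, 5, 5], [13, 5, 5]])
        res = water_clusters(f, cutoff=3.5)
        assert len(res.sizes) == 3
        assert res.largest_fraction == pytest.approx(1 / 3)

    def test_spanning_row_and_broken_row(self):
        box = Box([12.0, 12.0, 12.0])
        spanning = generate_percolation_fixture(box, 3.0, spanning=True)
        res = water_clusters(spanning, cutoff=3.5)
        assert res.spanning[0]
        broken = generate_percolation_fixture(box, 3.0, spanning=False)
        res = water_clusters(broken, cutoff=3.5)
        assert not res.spanning[0]

    def test_sizes_partition_waters(self, rng):
        f = water_frame(rng.random((40, 3)) * 15, box_length=15.0)
        res = water_clusters(f, cutoff=2.0)
        assert res.sizes.sum() == 40
        assert len(res.labels) == 40

    def test_relabeling_and_translation_invariance(self, rng):
        pos = rng.random((30, 3)) * 15
        f = water_frame(pos, box_length=15.0)
        base = water_clusters(f, cutoff=2.5)
        perm = rng.permutation(30)
        g = water_frame(pos[perm], box_length=15.0)
        permuted = water_clusters(g, cutoff=2.5)
        assert sorted(base.sizes) == sorted(permuted.sizes)
        shifted = water_frame((pos + rng.random(3) * 15) % 15.0,
                              box_length=15.0)
        trans = water_clusters(shifted, cutoff=2.5)
        assert sorted(base.sizes) == sorted(trans.sizes)
        assert base.largest_fraction == trans.largest_fraction

    def test_spanning_matches_replicated_brute_force(self, rng):
        # brute-force oracle: replicate the box 3x in x; a spanning cluster
        # keeps one component connecting x-copies, a broken one does not
        for spanning in (True, False):
            box = Box([9.0, 9.0, 9.0])
            f = generate_percolation_fixture(box, 3.0, spanning=spanning,
                                             seed=5)
            got = water_clusters(f, cutoff=3.5).spanning[0]
            assert got == spanning == self._replication_spans(f, 3.5)

    @staticmethod
    def _replication_spans(frame, cutoff):
        L = frame.box.lengths
        tiles = []
        for sx in (0, 1, 2):
            shift = np.array([sx * L[0], 0, 0])
            tiles.append(frame.positions + shift)
        pos = np.vstack(tiles)
        n = len(frame.positions)
        # connect under open boundaries in x, periodic in y/z
        adj = np.zeros((3 * n, 3 * n), dtype=bool)
        for i in range(3 * n):
            for j in range(i + 1, 3 * n):
                d = pos[i] - pos[j]
                d[1:] -= L[1:] * np.floor(d[1:] / L[1:] + 0.5)
                if d @ d < cutoff * cutoff:
                    adj[i, j] = adj[j, i] = True
        from scipy.sparse.csgraph import connected_components
        _, labels = connected_components(adj)
        # spanning iff some particle's three x-copies share a component
        return any(labels[i] == labels[i + n] for i in range(n))


class TestShellsAndRdf:
    def test_point_masses(self):
        f = matrix_frame([[5, 5, 5]], [0])
        hist = shell_count_distribution([f], "matrix", "water", 4.3)
        assert hist.probabilities[0] == 1.0
        f = matrix_frame([[5, 5, 5]], [0],
                         waters=[[6, 5, 5], [5, 6, 5], [5, 5, 6]])
        hist = shell_count_distribution([f], "matrix", "water", 4.3)
        assert hist.probabilities[3] == 1.0
        assert hist.mean() == pytest.approx(3.0)

    def test_self_pairs_excluded(self):
        f = matrix_frame([[5, 5, 5], [6, 5, 5]], [0, 1])
        hist = shell_count_distribution([f], "matrix", "matrix", 2.0)
        assert hist.probabilities[1] == 1.0  # each sees the other, not itself

    def test_brute_force_histogram(self, rng):
        f = matrix_frame(rng.random((10, 3)) * 12,
                         list(range(10)), box_length=12.0,
                         waters=rng.random((25, 3)) * 12)
        cutoff = 3.0
        hist = shell_count_distribution([f], "matrix", "water", cutoff)
        centers = np.flatnonzero(~f.is_water)
        partners = np.flatnonzero(f.is_water)
        counts = []
        for c in centers:
            k = sum(brute_min_image_dist(f.positions[c], f.positions[p],
                                         12.0) < cutoff for p in partners)
            counts.append(k)
        expected = np.bincount(counts) / len(counts)
        assert np.allclose(hist.probabilities, expected, atol=1e-12)
        assert hist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rdf_ideal_gas_is_flat(self, rng):
        frames = [water_frame(rng.random((400, 3)) * 20) for _ in range(8)]
        r, g = rdf(frames, "water", "water", r_max=8.0, n_bins=40)
        assert np.allclose(g[r > 1.0], 1.0, atol=0.15)

    def test_rdf_two_particle_single_bin(self):
        f = water_frame([[5, 5, 5], [8, 5, 5]])
        r, g = rdf([f], "water", "water", r_max=9.0, n_bins=30)
        occupied = np.flatnonzero(g > 0)
        assert len(occupied) == 1
        assert abs(r[occupied[0]] - 3.0) <= 0.15

    def test_first_minimum_on_constructed_curve(self):
        r = np.linspace(0.05, 10, 200)
        g = np.exp(-((r - 2.0) ** 2)) + 0.6 * np.exp(-((r - 5.0) ** 2) / 4)
        # analytic interior minimum of the double Gaussian near r = 3.4
        got = first_minimum(r, g)
        from scipy.optimize import minimize_scalar
        want = minimize_scalar(
            lambda x: np.exp(-((x - 2) ** 2)) + 0.6 * np.exp(-((x - 5) ** 2) / 4),
            bounds=(2.5, 4.5), method="bounded").x
        assert got == pytest.approx(want, abs=0.06)

    def test_first_minimum_requires_peak(self):
        r = np.linspace(0.1, 5, 50)
        with pytest.raises(ValueError):
            first_minimum(r, np.linspace(1, 2, 50))


class TestLargestClusterCurve:
    def test_planted_partition(self, rng):
        # 70-water blob and 30-water blob, well separated
        blob = lambda n, c: c + 0.45 * rng.random((n, 3))
        frames = [water_frame(np.vstack([blob(70, [3, 3, 3]),
                                         blob(30, [15, 15, 15])]))
                  for _ in range(5)]
        curve = largest_cluster_curve({0.1: frames}, cutoff=3.5)
        assert curve.largest_fraction.iloc[0] == pytest.approx(0.70)
        assert curve.stderr.iloc[0] == 0.0

    def test_all_connected_and_all_singletons(self, rng):
        dense = [water_frame(5 + 0.5 * rng.random((20, 3)))]
        sparse = [water_frame(np.array(
            [[i * 5.0, j * 5.0, 5.0] for i in range(4) for j in range(4)]))]
        curve = largest_cluster_curve({0.1: dense, 0.2: sparse}, cutoff=3.5)
        assert curve.largest_fraction.iloc[0] == 1.0
        assert curve.largest_fraction.iloc[1] == pytest.approx(1 / 16)


class TestLocalHydrationDifference:
    def _frames(self, rng, extra_at=None, n=6):
        frames = []
        beads = np.array([[4.0, 4, 4], [12.0, 12, 12]])
        for _ in range(n):
            waters = [[4.5, 4, 4], [12.5, 12, 12]]
            if extra_at is not None:
                waters += [[extra_at[0] + 0.5, extra_at[1], extra_at[2]],
                           [extra_at[0], extra_at[1] + 0.5, extra_at[2]]]
            frames.append(matrix_frame(beads, [0, 1], waters=waters))
        return frames

    def test_identical_sets_give_zero(self, rng):
        a = self._frames(rng)
        diff, err = local_hydration_difference(a, a, cutoff=2.0,
                                               h_tolerance=10.0)
        assert np.all(diff == 0)

    def test_planted_difference(self, rng):
        ads = self._frames(rng, extra_at=[4.0, 4.0, 4.0])
        des = self._frames(rng)
        diff, err = local_hydration_difference(ads, des, cutoff=2.0,
                                               h_tolerance=10.0)
        assert diff[0] == pytest.approx(2.0)
        assert diff[1] == pytest.approx(0.0)

    def test_antisymmetry(self, rng):
        ads = self._frames(rng, extra_at=[4.0, 4.0, 4.0])
        des = self._frames(rng)
        d1, _ = local_hydration_difference(ads, des, cutoff=2.0,
                                           h_tolerance=10.0)
        d2, _ = local_hydration_difference(des, ads, cutoff=2.0,
                                           h_tolerance=10.0)
        assert np.allclose(d1, -d2, atol=1e-12)

    def test_mismatched_hydration_raises(self, rng):
        ads = self._frames(rng, extra_at=[4.0, 4.0, 4.0])
        des = self._frames(rng)
        with pytest.raises(ValueError, match="hydration"):
            local_hydration_difference(ads, des, cutoff=2.0,
                                       h_tolerance=1e-6)


class TestBlockAverage:
    def test_constant_series(self):
        mean, err = block_average(np.full(20, 1.7))
        assert (mean, err) == (pytest.approx(1.7), 0.0)

    def test_closed_form_five_blocks(self):
        x = np.array([1.0, 2, 3, 4, 5])
        mean, err = block_average(x, 5)
        assert mean == 3.0
        assert err == pytest.approx(np.std(x) / math.sqrt(5))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            block_average(np.ones(3), 5)

    def test_matches_analytic_se(self, rng):
        hits = 0
        for _ in range(100):
            _, err = block_average(rng.normal(size=1000), 5)
            if 0.5 / math.sqrt(1000) < err < 2.0 / math.sqrt(1000):
                hits += 1
        assert hits >= 80
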