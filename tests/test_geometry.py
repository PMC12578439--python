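"""Pair θ angles, orientation classes, chain grouping and decoration stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mtoligo as m
from mtoligo.errors import ConfigurationError, ValidationError
from mtoligo.geometry import (
    OTHER,
    PARALLEL,
    PERPENDICULAR,
    PairRecord,
    histogram_mode,
    minimal_arc,
    pair_theta,
)

from conftest import random_rotations


def particle_on_cylinder(path, s, phi_deg, r=23.0, y_along=None):
    """Helper: position + orientation with z outward, y along given vector."""
    pos = path.point_at(s, phi_deg, r)
    z = (pos - path.point_at(s)) / r
    y = np.array([0.0, 0.0, 1.0]) if y_along is None else np.asarray(y_along, float)
    y = y - (y @ z) * z
    y /= np.linalg.norm(y)
    x = np.cross(y, z)
    return pos, np.column_stack([x, y, z])


def make_table(path, entries):
    pos, rot = zip(*entries)
    return m.ParticleTable(
        np.array(pos), np.array(rot),
        filament_ids=np.full(len(pos), path.filament_id),
    )


class TestPairTheta:
    def test_axial_displacement_same_y_sense_is_parallel(self, straight_path):
        p = straight_path
        a = particle_on_cylinder(p, 50, 0)
        b = particle_on_cylinder(p, 60, 0)
        pairs = m.compute_pairs(make_table(p, [a, b]), {0: p}, max_dist=16)
        assert len(pairs) == 1
        assert abs(pairs[0].theta - 0.0) < 1e-9

    def test_circumferential_displacement_is_perpendicular(self, straight_path):
        p = straight_path
        a = particle_on_cylinder(p, 50, 0)
        b = particle_on_cylinder(p, 50, 20)
        pairs = m.compute_pairs(make_table(p, [a, b]), {0: p}, max_dist=16)
        assert abs(pairs[0].theta - 90.0) < 1e-9

    def test_opposite_y_sense_gives_supplementary_angle(self, straight_path):
        p = straight_path
        a = particle_on_cylinder(p, 50, 0, y_along=[0, 0, -1])
        b = particle_on_cylinder(p, 60, 0, y_along=[0, 0, -1])
        pairs = m.compute_pairs(make_table(p, [a, b]), {0: p}, max_dist=16)
        assert abs(pairs[0].theta - 180.0) < 1e-9

    def test_matches_brute_force_vector_recomputation(self, straight_path, rng):
        p = straight_path
        n = 60
        pos = np.column_stack([
            rng.uniform(-25, 25, n), rng.uniform(-25, 25, n), rng.uniform(0, 500, n)
        ])
        rot = random_rotations(rng, n)
        table = m.ParticleTable(pos, rot, filament_ids=np.zeros(n, int))
        pairs = m.compute_pairs(table, {0: p}, max_dist=16)
        assert pairs, "fixture produced no pairs"
        t = np.array([0.0, 0.0, 1.0])  # growth tangent of the straight plus path
        for pr in pairs:
            d = pos[pr.id_b] - pos[pr.id_a]
            brute = np.degrees(np.arccos(np.clip(d @ t / np.linalg.norm(d), -1, 1)))
            assert abs(pr.theta - brute) < 1e-6

    def test_theta_invariant_under_rigid_transforms(self, rng):
        raw = np.array([[0, 0, 0], [5, 3, 60], [0, 0, 120]], float)
        path = m.resample_path(raw, 7.0, polarity="plus", filament_id=0)
        n = 40
        pos = path.points[rng.integers(0, path.n_points, n)] + rng.normal(0, 8, (n, 3))
        rot = random_rotations(rng, n)
        table = m.ParticleTable(pos, rot, filament_ids=np.zeros(n, int))
        ref = m.compute_pairs(table, {0: path}, max_dist=16)
        for _ in range(5):
            R = random_rotations(rng, 1)[0]
            tvec = rng.uniform(-100, 100, 3)
            path2 = m.resample_path(raw @ R.T + tvec, 7.0, polarity="plus", filament_id=0)
            table2 = m.ParticleTable(
                pos @ R.T + tvec, np.einsum("ij,njk->nik", R, rot),
                filament_ids=np.zeros(n, int),
            )
            got = m.compute_pairs(table2, {0: path2}, max_dist=16)
            assert len(got) == len(ref)
            for a, b in zip(ref, got):
                assert abs(a.theta - b.theta) < 1e-6

    def test_reversed_polarity_maps_theta_to_supplement(self, straight_path, rng):
        p = straight_path
        n = 30
        pos = np.column_stack([
            rng.uniform(-25, 25, n), rng.uniform(-25, 25, n), rng.uniform(0, 500, n)
        ])
        table = m.ParticleTable(pos, random_rotations(rng, n), filament_ids=np.zeros(n, int))
        fwd = m.compute_pairs(table, {0: p}, max_dist=16)
        minus = m.straight_path(500, 7, filament_id=0, polarity="minus")
        bwd = m.compute_pairs(table, {0: minus}, max_dist=16)
        for a, b in zip(fwd, bwd):
            assert abs((180.0 - a.theta) - b.theta) < 1e-6

    def test_unassigned_particles_skipped(self, straight_path):
        table = m.ParticleTable(np.zeros((2, 3)) + [[0, 0, 0], [0, 0, 5]],
                                filament_ids=[-1, -1])
        assert m.compute_pairs(table, {0: straight_path}) == []


class TestClassification:
    @pytest.mark.parametrize(
        "theta,tol_perp,tol_par,expect",
        [
            (90, 30, 20, PERPENDICULAR),
            (0, 30, 20, PARALLEL),
            (180, 30, 20, PARALLEL),
            (55, 30, 20, OTHER),
            (60, 30, 20, PERPENDICULAR),
            (33, 20, 20, OTHER),
        ],
    )
    def test_window_arithmetic(self, theta, tol_perp, tol_par, expect):
        p = PairRecord(0, 1, 8.0, theta)
        assert m.classify_pair(p, tol_perp, tol_par) == expect

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            m.classify_pair(PairRecord(0, 1, 8.0, 45.0), tol_perp=80, tol_par=20)


def union_find_oracle(n_nodes, edges):
    """Independent union-find over node indices 0..n-1."""
    parent = list(range(n_nodes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i in range(n_nodes):
        comps.setdefault(find(i), set()).add(i)
    return sorted(tuple(sorted(c)) for c in comps.values())


class TestChainGrouping:
    def _pair(self, a, b, dist=8.0, theta=90.0, cls=PERPENDICULAR):
        return PairRecord(a, b, dist, theta, cls, 0)

    def test_transitive_linking(self):
        pairs = [self._pair(0, 1), self._pair(1, 2)]
        chains = m.group_chains(pairs, particle_ids=[0, 1, 2])
        assert len(chains) == 1 and chains[0].copy_number == 3

    def test_no_retained_pairs_gives_singletons(self):
        pairs = [self._pair(0, 1, cls=PARALLEL)]
        chains = m.group_chains(pairs, particle_ids=[0, 1, 2, 3])
        assert len(chains) == 4
        assert all(c.copy_number == 1 for c in chains)

    def test_distance_window_excludes_edges(self):
        pairs = [self._pair(0, 1, dist=12.0)]  # outside (5, 10)
        chains = m.group_chains(pairs, dist_window=(5, 10), particle_ids=[0, 1])
        assert len(chains) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        n_edges = int(rng.integers(0, 90))
        edges = [tuple(map(int, rng.integers(0, n, 2))) for _ in range(n_edges)]
        edges = [(a, b) for a, b in edges if a != b]
        pairs = [self._pair(a, b) for a, b in edges]
        chains = m.group_chains(pairs, particle_ids=list(range(n)))
        got = sorted(tuple(sorted(c.member_ids)) for c in chains)
        assert got == union_find_oracle(n, edges)

    def test_members_ordered_by_azimuth_with_extent(self):
        pairs = [self._pair(0, 1), self._pair(1, 2)]
        az = {0: 350.0, 1: 10.0, 2: 30.0}
        chains = m.group_chains(pairs, particle_ids=[0, 1, 2], azimuth_of=az)
        assert chains[0].member_ids == [0, 1, 2]
        assert abs(chains[0].angular_extent - 40.0) < 1e-9


class TestHistogramsAndDensity:
    def test_chain_length_frequency_counts(self):
        chains = [m.ChainRecord([0], 1, 0.0), m.ChainRecord([1], 1, 0.0),
                  m.ChainRecord([2, 3], 2, 20.0), m.ChainRecord([4, 5, 6], 3, 40.0)]
        h, max_len = m.chain_length_frequency(chains)
        assert max_len == 3
        np.testing.assert_array_equal(h.counts, [2, 1, 1])

    def test_empty_chain_list(self):
        h, max_len = m.chain_length_frequency([])
        assert max_len is None and len(h) == 0

    def test_theta_mode_at_90(self):
        h = m.theta_histogram([90.0] * 10)
        assert histogram_mode(h) == 90.0

    def test_mode_tie_breaks_low(self):
        h = m.theta_histogram([80.0, 80.0, 100.0, 100.0])
        assert histogram_mode(h) == 80.0

    def test_uniform_thetas_have_flat_histogram(self, rng):
        # multinomial bound: 18,000 uniform draws over 18 full-width bins
        th = rng.uniform(0, 180, size=18_000)
        h = m.theta_histogram(th)
        inner = h.counts[1:-1]  # edge bins at 0 and 180 are half-width
        assert inner.max() / inner.min() < 1.3

    def test_empty_pairs_error(self):
        with pytest.raises(ValidationError):
            m.theta_histogram([])

    def test_linear_density_example(self, straight_path):
        path = m.straight_path(70, 7, filament_id=0)
        t = m.ParticleTable(np.tile([[23.0, 0, 0]], (14, 1)),
                            filament_ids=np.zeros(14, int))
        assert abs(m.linear_density(t, path) - 0.2) < 1e-12

    def test_empty_decoration_density_zero(self):
        path = m.straight_path(70, 7, filament_id=0)
        t = m.ParticleTable(np.zeros((0, 3)))
        assert m.linear_density(t, path) == 0.0

    def test_pooled_density_identity(self, rng):
        paths = {i: m.straight_path(70 * (i + 1), 7, filament_id=i) for i in range(3)}
        n_per = [5, 11, 2]
        fids = np.repeat(np.arange(3), n_per)
        t = m.ParticleTable(rng.uniform(0, 50, (sum(n_per), 3)), filament_ids=fids)
        per, pooled = m.linear_density_summary(t, paths)
        total_len = sum(p.length for p in paths.values())
        assert abs(pooled - sum(n_per) / total_len) < 1e-12
        weighted = sum(per[i] * paths[i].length for i in per) / total_len
        assert abs(pooled - weighted) < 1e-12


class TestAngularExtent:
    def test_single_particle_zero(self):
        assert minimal_arc([123.0]) == 0.0

    def test_simple_span(self):
        assert abs(minimal_arc([0, 20, 40]) - 40.0) < 1e-9

    def test_wraparound_uses_short_arc(self):
        assert abs(minimal_arc([350, 10]) - 20.0) < 1e-9

    def test_matches_rotation_search_oracle(self, rng):
        for _ in range(50):
            phis = rng.uniform(0, 360, size=int(rng.integers(2, 12)))
            # oracle: minimal over all rotations of the linear span
            best = 360.0
            for base in phis:
                shifted = (phis - base) % 360.0
                best = min(best, shifted.max())
            assert abs(minimal_arc(phis) - best) < 1e-9
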