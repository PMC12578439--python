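"""Ring seeding and the subtomogram cleaning steps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import mtoligo as m
from mtoligo.coords_io import FLAG_FLIPPED, FLAG_SEED
from mtoligo.errors import ValidationError


def brute_force_greedy_dedup(positions, scores, min_dist):
    """O(n^2) oracle for distance-based duplicate removal."""
    n = len(positions)
    scores = np.nan_to_num(np.asarray(scores, float), nan=0.0)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        if all(np.linalg.norm(positions[i] - positions[j]) > min_dist for j in kept):
            kept.append(i)
    return sorted(kept)


class TestRingSeeding:
    def test_straight_70nm_path_yields_198_seeds(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())
        assert len(seeds) == 11 * 18
        assert all(FLAG_SEED in f for f in seeds.flags)

    def test_all_seeds_exactly_23nm_from_ring_centers(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())
        centers = np.repeat(path.points, 18, axis=0)
        d = np.linalg.norm(seeds.positions - centers, axis=1)
        np.testing.assert_allclose(d, 23.0, atol=1e-12)

    def test_rings_exactly_ring_spacing_apart(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())
        z = seeds.positions[:, 2].reshape(11, 18)
        np.testing.assert_allclose(np.diff(z.mean(axis=1)), 7.0, atol=1e-12)

    def test_seed_count_always_points_times_per_ring(self):
        path = m.straight_path(140, 7)
        for per_ring in (1, 5, 18):
            seeds = m.generate_ring_seeds(path, m.SeedSpec(per_ring=per_ring))
            assert len(seeds) == path.n_points * per_ring

    def test_single_seed_per_ring_forms_parallel_offset_line(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec(per_ring=1))
        np.testing.assert_allclose(seeds.positions[:, 0], 23.0, atol=1e-12)
        np.testing.assert_allclose(seeds.positions[:, 1], 0.0, atol=1e-12)

    def test_seed_z_axis_points_outwards(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())
        centers = np.repeat(path.points, 18, axis=0)
        outward = seeds.positions - centers
        outward /= np.linalg.norm(outward, axis=1, keepdims=True)
        zaxes = seeds.rotations[:, :, 2]
        np.testing.assert_allclose(zaxes, outward, atol=1e-9)

    def test_internal_resample_when_spacing_differs(self):
        path = m.straight_path(70, 10)
        seeds = m.generate_ring_seeds(path, m.SeedSpec(ring_spacing=7))
        assert len(seeds) == 11 * 18


class TestAzimuthRandomization:
    def test_positions_unchanged_and_deterministic(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())
        a = m.randomize_azimuth(seeds, rng_seed=5)
        b = m.randomize_azimuth(seeds, rng_seed=5)
        np.testing.assert_array_equal(a.positions, seeds.positions)
        np.testing.assert_array_equal(a.rotations, b.rotations)

    def test_z_axis_preserved_by_spin(self):
        path = m.straight_path(70, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())
        spun = m.randomize_azimuth(seeds, rng_seed=5)
        np.testing.assert_allclose(
            spun.rotations[:, :, 2], seeds.rotations[:, :, 2], atol=1e-12
        )

    def test_applied_angles_uniform_on_circle(self):
        path = m.straight_path(7 * 556, 7)
        seeds = m.generate_ring_seeds(path, m.SeedSpec())  # ~10k seeds
        spun = m.randomize_azimuth(seeds, rng_seed=11)
        # recover the applied in-plane spin from x-axis rotation about z
        rel = np.einsum("nji,njk->nik", seeds.rotations, spun.rotations)
        ang = (np.degrees(np.arctan2(rel[:, 1, 0], rel[:, 0, 0]))) % 360.0
        stat = kstest(ang / 360.0, "uniform")
        assert stat.pvalue > 0.01


class TestDeduplication:
    def test_higher_score_dominates(self):
        t = m.ParticleTable(
            [[0, 0, 0], [0, 0, 1]], scores=[0.9, 0.5]
        )
        kept = m.remove_duplicates(t, min_dist=5)
        assert len(kept) == 1 and kept.scores[0] == 0.9

    def test_grid_spaced_beyond_min_dist_all_kept(self):
        g = np.mgrid[0:40:10, 0:40:10, 0:10:10].reshape(3, -1).T
        t = m.ParticleTable(g.astype(float))
        assert len(m.remove_duplicates(t, min_dist=5)) == len(t)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_matches_brute_force_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 120))
        pos = rng.uniform(0, 30, size=(n, 3))
        scores = rng.uniform(-1, 1, size=n)
        t = m.ParticleTable(pos, scores=scores)
        kept = m.remove_duplicates(t, min_dist=6.0)
        oracle = brute_force_greedy_dedup(pos, scores, 6.0)
        got = sorted(np.flatnonzero([
            any(np.allclose(p, pos[i]) for p in kept.positions) for i in range(n)
        ]))
        assert got == oracle

    def test_kept_set_respects_min_distance(self, rng):
        pos = rng.uniform(0, 50, size=(500, 3))
        t = m.ParticleTable(pos, scores=rng.uniform(0, 1, size=500))
        kept = m.remove_duplicates(t, min_dist=7.0)
        d = np.linalg.norm(kept.positions[:, None] - kept.positions[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 7.0


class TestScoreFilter:
    def test_threshold_is_inclusive(self):
        t = m.ParticleTable(np.zeros((3, 3)) + np.arange(3)[:, None] * 10,
                            scores=[0.20, 0.32, 0.50])
        kept = m.filter_by_score(t, 0.32)
        assert len(kept) == 2
        assert set(np.round(kept.scores, 2)) == {0.32, 0.50}

    def test_zero_threshold_keeps_nonnegative_scores(self, rng):
        t = m.ParticleTable(rng.uniform(0, 9, (20, 3)), scores=rng.uniform(0, 1, 20))
        assert len(m.filter_by_score(t, 0.0)) == 20

    def test_counting_matches_brute_force(self, rng):
        scores = rng.uniform(-1, 1, size=300)
        t = m.ParticleTable(rng.uniform(0, 99, (300, 3)), scores=scores)
        kept = m.filter_by_score(t, 0.32)
        assert len(kept) == int(np.sum(scores >= 0.32))

    def test_idempotent(self, rng):
        t = m.ParticleTable(rng.uniform(0, 9, (50, 3)), scores=rng.uniform(-1, 1, 50))
        once = m.filter_by_score(t, 0.32)
        twice = m.filter_by_score(once, 0.32)
        assert len(once) == len(twice)

    def test_unscored_particle_is_an_error(self):
        t = m.ParticleTable(np.zeros((2, 3)), scores=[0.5, np.nan])
        with pytest.raises(ValidationError, match="score"):
            m.filter_by_score(t, 0.32)


class TestPolarityFlip:
    def _seeds(self):
        path = m.straight_path(70, 7)
        return path, m.generate_ring_seeds(path, m.SeedSpec())

    def test_all_plus_is_identity(self):
        _, seeds = self._seeds()
        out = m.flip_polarity(seeds, {0: "plus"})
        np.testing.assert_array_equal(out.rotations, seeds.rotations)

    def test_flip_is_involution(self):
        _, seeds = self._seeds()
        once = m.flip_polarity(seeds, {0: "minus"})
        twice = m.flip_polarity(once, {0: "minus"})
        assert np.max(np.abs(twice.rotations - seeds.rotations)) < 1e-9
        assert all(FLAG_FLIPPED not in f for f in twice.flags)

    def test_y_axis_tangent_dot_changes_sign(self):
        path, seeds = self._seeds()
        flipped = m.flip_polarity(seeds, {0: "minus"})
        before = seeds.rotations[:, :, 1] @ np.array([0, 0, 1.0])
        after = flipped.rotations[:, :, 1] @ np.array([0, 0, 1.0])
        np.testing.assert_allclose(after, -before, atol=1e-12)
        assert all(FLAG_FLIPPED in f for f in flipped.flags)

    def test_positions_never_move(self):
        _, seeds = self._seeds()
        out = m.flip_polarity(seeds, {0: "minus"})
        np.testing.assert_array_equal(out.positions, seeds.positions)

    def test_unknown_filament_warns_and_noop(self):
        _, seeds = self._seeds()
        with pytest.warns(UserWarning, match="polarity"):
            out = m.flip_polarity(seeds, {})
        np.testing.assert_array_equal(out.rotations, seeds.rotations)
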