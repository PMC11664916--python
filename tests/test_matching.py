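"""Cloud alignment, overlap/score computation, triage and filtering."""

import numpy as np
import pytest

from catalocavity.cavity import PointCloud
from catalocavity.matching import (
    DEFAULT_EPSILON,
    HBOND_COMPAT_TOL,
    MatchResult,
    W_GEO,
    W_PROP,
    align_clouds,
    filter_matches,
    flavin_same_side,
    overlap_fraction,
    total_score,
)
from catalocavity.structure_io import FlavinFrame
from catalocavity.synthetic_data import make_cloud_pair, random_rotation


def brute_force_overlap(a: PointCloud, b: PointCloud, transform,
                        epsilon=DEFAULT_EPSILON) -> float:
    """O(n^2) reference: same pairing rules, no spatial index."""
    R, t = transform
    moved = a.coords @ np.asarray(R, float).T + np.asarray(t, float)
    deadband = 0.10 * np.abs(a.properties[:, 0]).max()
    count = 0
    for i in range(len(a)):
        ea, da, aa = a.properties[i, 0], a.properties[i, 1], a.properties[i, 2]
        for j in range(len(b)):
            if np.linalg.norm(moved[i] - b.coords[j]) > epsilon:
                continue
            eb, db, ab = b.properties[j, 0], b.properties[j, 1], b.properties[j, 2]
            sign_ok = abs(ea) <= deadband or abs(eb) <= deadband or ea * eb > 0
            if sign_ok and abs(da - db) <= HBOND_COMPAT_TOL \
                    and abs(aa - ab) <= HBOND_COMPAT_TOL:
                count += 1
                break
    return 100.0 * count / len(a)


def simple_cloud(coords, electro=1.0, frame=None, **props):
    coords = np.asarray(coords, float).reshape(-1, 3)
    p = np.zeros((len(coords), 5))
    p[:, 0] = electro
    for key, col in (("donor", 1), ("acceptor", 2), ("hydro", 3), ("buried", 4)):
        if key in props:
            p[:, col] = props[key]
    if frame is None:
        frame = FlavinFrame(coords[0] + [0.5, 0, 1.0], coords[0], [0, 0, 1.0])
    return PointCloud(coords, p, frame, 1.0, source_id="simple")


IDENTITY = (np.eye(3), np.zeros(3))


class TestOverlap:
    def test_identical_clouds_100(self):
        c = simple_cloud(np.random.default_rng(0).uniform(0, 10, (30, 3)))
        assert overlap_fraction(c, c, IDENTITY) == 100.0

    def test_directional_counting(self):
        """10 points inside a 40-point cloud: 100% one way, 25% back."""
        rng = np.random.default_rng(1)
        big = rng.uniform(0, 50, (40, 3))  # sparse: points well separated
        small = big[:10]
        a, b = simple_cloud(small), simple_cloud(big)
        assert overlap_fraction(a, b, IDENTITY) == 100.0
        assert overlap_fraction(b, a, IDENTITY) == 25.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        a, b, m = make_cloud_pair(seed=seed, n_points=60, overlap_target=40)
        R = np.array(m.planted["rotation"])
        t = np.array(m.planted["translation"])
        fast = overlap_fraction(a, b, (R, t))
        assert fast == brute_force_overlap(a, b, (R, t))
        assert fast == pytest.approx(m.planted["overlap_a_to_b"], abs=1e-12)

    def test_epsilon_validation(self):
        c = simple_cloud([[0, 0, 0]])
        with pytest.raises(ValueError):
            overlap_fraction(c, c, IDENTITY, epsilon=0.0)


class TestTotalScore:
    def test_identical_clouds_zero(self):
        c = simple_cloud(np.random.default_rng(2).uniform(0, 10, (25, 3)))
        assert total_score(c, c, IDENTITY) == 0.0

    def test_disjoint_clouds_one(self):
        a = simple_cloud(np.random.default_rng(3).uniform(0, 5, (10, 3)))
        b = simple_cloud(np.random.default_rng(4).uniform(100, 105, (10, 3)))
        assert total_score(a, b, IDENTITY) == 1.0

    def test_formula_on_planted_pair(self):
        """Half of a overlaps b perfectly: score from the stated formula."""
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 60, (20, 3))  # widely separated
        a = simple_cloud(base)
        b = simple_cloud(np.vstack([base[:10], base[10:] + 500.0]))
        ov = 50.0  # both directions
        sym = 2 * ov * ov / (ov + ov)
        # matched pairs have identical properties -> property term 0 from
        # 20 matched contributions
        expected = W_GEO * (1 - sym / 100.0) + W_PROP * 0.0
        assert total_score(a, b, IDENTITY) == pytest.approx(expected, abs=1e-12)

    def test_common_transform_invariance(self):
        a, b, m = make_cloud_pair(seed=9, n_points=50, overlap_target=60)
        R0 = np.array(m.planted["rotation"])
        t0 = np.array(m.planted["translation"])
        s0 = total_score(a, b, (R0, t0))
        rng = np.random.default_rng(7)
        Q = random_rotation(rng)
        u = rng.uniform(-5, 5, 3)
        a2, b2 = a.transformed(Q, u), b.transformed(Q, u)
        # transform relating the moved clouds: Q (R0, t0) Q^-1
        R1 = Q @ R0 @ Q.T
        t1 = Q @ t0 + u - R1 @ u
        assert total_score(a2, b2, (R1, t1)) == pytest.approx(s0, abs=1e-9)


class TestAlign:
    def test_self_match(self):
        a, _, _ = make_cloud_pair(seed=11, n_points=80)
        r = align_clouds(a, a)
        assert r.total_score == 0.0
        assert r.overlap_1to2 == r.overlap_2to1 == 100.0
        np.testing.assert_allclose(r.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(r.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_recovers_known_transform(self, seed):
        a, b, m = make_cloud_pair(seed=seed, n_points=150, overlap_target=100)
        r = align_clouds(a, b)
        R = np.array(m.planted["rotation"])
        t = np.array(m.planted["translation"])
        assert np.linalg.norm(r.rotation - R) < 1e-4
        assert np.linalg.norm(r.translation - t) < 1e-4
        assert r.total_score < 1e-6

    def test_disjoint_supports_worst_case(self):
        a, _, _ = make_cloud_pair(seed=13, n_points=30)
        b = a.transformed(np.eye(3), np.zeros(3))
        b.coords = b.coords + np.array([500.0, 0.0, 0.0])
        # keep frames superposable but supports disjoint
        b.frame = a.frame
        r = align_clouds(a, b)
        assert r.overlap_1to2 == 0.0 and r.overlap_2to1 == 0.0
        assert r.total_score == 1.0

    def test_empty_cloud_rejected(self):
        a, _, _ = make_cloud_pair(seed=14, n_points=10)
        empty = PointCloud(np.empty((0, 3)), np.empty((0, 5)), a.frame, 1.0)
        with pytest.raises(ValueError):
            align_clouds(a, empty)

    def test_self_match_is_optimal(self):
        a, b, _ = make_cloud_pair(seed=15, n_points=60, overlap_target=70)
        self_score = align_clouds(a, a).total_score
        other_score = align_clouds(a, b).total_score
        assert self_score <= other_score


class TestFlavinSide:
    def test_self_is_same_side(self):
        a, _, _ = make_cloud_pair(seed=16, n_points=40)
        assert flavin_same_side(a, a, IDENTITY) is True

    def test_reflected_frame_is_opposite(self):
        a, _, _ = make_cloud_pair(seed=17, n_points=40)
        centroid = a.coords.mean(axis=0)
        normal = a.frame.ring_normal

        def reflect(p):
            return p - 2 * np.dot(p - centroid, normal) * normal

        b = a.transformed(np.eye(3), np.zeros(3))
        b.frame = FlavinFrame(reflect(a.frame.n5), reflect(a.frame.ring_centroid),
                              a.frame.ring_normal)
        assert flavin_same_side(a, b, IDENTITY) is False

    def test_antiparallel_normals_fail(self):
        """Flavins facing opposite directions (normal angle 180 degrees)."""
        a, _, _ = make_cloud_pair(seed=18, n_points=40)
        b = a.transformed(np.eye(3), np.zeros(3))
        b.frame = FlavinFrame(a.frame.n5, a.frame.ring_centroid,
                              -a.frame.ring_normal)
        assert flavin_same_side(b, a, IDENTITY) is False


def result(score, ov12, ov21, **kw):
    return MatchResult(np.eye(3), np.zeros(3), score, ov12, ov21,
                       True, True, "tmpl", kw.pop("target", "tgt"))


class TestFilter:
    def test_passing_result_kept(self):
        # the 0.047-style match: below the 0.05 gate with 75/12 overlaps
        kept = filter_matches([result(0.047, 75.0, 12.0)])
        assert len(kept) == 1 and kept[0].kept is True

    def test_boundaries_fail_strict_inequalities(self):
        results = [result(0.05, 90.0, 50.0),   # score at gate
                   result(0.01, 70.0, 50.0),   # ov12 at gate
                   result(0.01, 90.0, 10.0)]   # ov21 at gate
        assert filter_matches(results) == []

    def test_large_pool_strict_reverse_overlap(self):
        r = result(0.01, 80.0, 12.0)
        assert len(filter_matches([r], large_pool=False)) == 1
        assert filter_matches([r], large_pool=True) == []

    def test_order_preserved_and_monotone(self):
        rng = np.random.default_rng(19)
        results = [result(rng.uniform(0, 0.1), rng.uniform(50, 100),
                          rng.uniform(0, 50), target=f"t{i}")
                   for i in range(30)]
        kept_tight = filter_matches(results, score_max=0.03)
        kept_loose = filter_matches(results, score_max=0.08)
        ids_tight = [r.target_id for r in kept_tight]
        ids_loose = [r.target_id for r in kept_loose]
        assert set(ids_tight) <= set(ids_loose)
        order = [r.target_id for r in results]
        assert ids_loose == [i for i in order if i in set(ids_loose)]
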