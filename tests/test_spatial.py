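import numpy as np
import pytest
from scipy import stats

from gluquanta.spatial import (
    ClusterSet,
    cluster_sites,
    cluster_composition,
    convex_hull_areas,
    detect_dual_active_zone,
    hull_area_um2,
    reshuffle_normalized_area,
)


def _naive_average_linkage(points, t):
    """O(n^3) agglomerative average linkage cut at distance t."""
    clusters = [[i] for i in range(len(points))]

    def dist(a, b):
        return np.mean(
            [np.linalg.norm(points[i] - points[j]) for i in a for j in b]
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > t:
            break
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(points), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def _refine_naive(points, labels, radius):
    labels = labels.copy()
    for _ in range(20):
        ids = np.unique(labels)
        cents = {i: points[labels == i].mean(axis=0) for i in ids}
        moved = False
        for j, p in enumerate(points):
            ds = {i: np.linalg.norm(p - c) for i, c in cents.items()}
            best = min(ds, key=ds.get)
            tgt = best if ds[best] <= radius else labels.max() + 1
            if tgt != labels[j]:
                labels[j] = tgt
                moved = True
        if not moved:
            break
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _partition(labels):
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_two_events_within_diameter_merge(self):
        assert cluster_sites(np.array([[0.0, 0.0], [50.0, 0.0]])).n_clusters == 1

    def test_two_events_beyond_diameter_split(self):
        assert cluster_sites(np.array([[0.0, 0.0], [150.0, 0.0]])).n_clusters == 2

    def test_singleton(self):
        cs = cluster_sites(np.array([[10.0, 20.0]]))
        assert cs.n_clusters == 1

    def test_matches_naive_linkage_oracle(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = r.normal(0, 120, (20, 2))
            got = cluster_sites(pts).assignments
            expect = _refine_naive(pts, _naive_average_linkage(pts, 100.0), 100.0)
            assert _partition(got) == _partition(expect)

    def test_events_within_centroid_radius(self, rng):
        pts = rng.normal(0, 200, (40, 2))
        cs = cluster_sites(pts)
        for p, l in zip(pts, cs.assignments):
            assert np.linalg.norm(p - cs.centroids[l]) <= 100.0 + 1e-9

    def test_input_order_invariance(self, rng):
        pts = rng.normal(0, 150, (25, 2))
        perm = rng.permutation(25)
        a = cluster_sites(pts).assignments
        b = cluster_sites(pts[perm]).assignments
        pa = _partition(a)
        pb = {frozenset(int(perm[i]) for i in g) for g in _partition(b)}
        assert pa == pb


class TestDualActiveZone:
    @pytest.mark.parametrize("d,expect", [(650.0, False), (700.0, True), (900.0, True)])
    def test_centroid_distance_rule(self, d, expect):
        pts = np.array([[0.0, 0.0], [d, 0.0]])
        cs = cluster_sites(pts)
        assert detect_dual_active_zone(cs) is expect

    def test_single_cluster_is_single_az(self, rng):
        cs = cluster_sites(rng.normal(0, 20, (10, 2)))
        assert not detect_dual_active_zone(cs)


class TestComposition:
    def _clusterset(self, labels, modes):
        pts = np.array([[100.0 * l, 0.0] for l in labels])
        return ClusterSet(
            assignments=np.array(labels),
            centroids=np.array([[100.0 * i, 0.0] for i in range(max(labels) + 1)]),
            positions=pts,
            modes=np.array(modes),
        )

    def test_mixed_and_pure_clusters(self):
        cs = self._clusterset(
            [0, 0, 1, 1], ["synchronous", "asynchronous", "synchronous", "synchronous"]
        )
        out = cluster_composition(cs)
        assert out["mixed_fraction"] == pytest.approx(0.5)
        per = out["per_size"]
        assert per.loc[2, "n_clusters"] == 2

    def test_mixed_fraction_matches_binomial_closed_form(self, rng):
        # i.i.d. modes with p_sync = 0.75: P(mixed | k) = 1 - p^k - (1-p)^k
        p = 0.75
        counts = {}
        labels, modes = [], []
        cid = 0
        for _ in range(1000):
            k = rng.integers(2, 6)
            labels.extend([cid] * k)
            m = rng.random(k) < p
            modes.extend(["synchronous" if x else "asynchronous" for x in m])
            counts.setdefault(k, []).append(m.any() and not m.all())
            cid += 1
        cs = self._clusterset(labels, modes)
        out = cluster_composition(cs)
        obs = np.array([np.sum(v) for k, v in sorted(counts.items())], dtype=float)
        n = np.array([len(v) for k, v in sorted(counts.items())], dtype=float)
        exp = np.array(
            [n_i * (1 - p**k - (1 - p) ** k) for (k, _), n_i in zip(sorted(counts.items()), n)]
        )
        chi2 = np.sum((obs - exp) ** 2 / np.maximum(exp * (1 - exp / n), 1e-9))
        assert stats.chi2.sf(chi2, df=len(obs)) > 0.001
        assert abs(out["mixed_fraction"] - np.mean(np.concatenate(list(counts.values())))) < 1e-12


class TestConvexHulls:
    def test_unit_right_triangle(self):
        pts = np.array([[0, 0], [1000.0, 0], [0, 1000.0]])
        area, degenerate = hull_area_um2(pts)
        assert area == pytest.approx(0.5)
        assert not degenerate

    def test_collinear_degenerate(self):
        pts = np.array([[0, 0], [500.0, 500.0], [1000.0, 1000.0]])
        area, degenerate = hull_area_um2(pts)
        assert area == 0.0 and degenerate

    def test_matches_bruteforce_hull_oracle(self, rng):
        # O(n^3) oracle: hull vertices are points not strictly inside any
        # triangle of others; shoelace on the angularly sorted vertices
        def brute_area(pts):
            n = len(pts)
            verts = []
            for i in range(n):
                inside = False
                for a in range(n):
                    for b in range(a + 1, n):
                        for c in range(b + 1, n):
                            if i in (a, b, c):
                                continue
                            p, q, r = pts[a], pts[b], pts[c]
                            d = (q[1] - r[1]) * (p[0] - r[0]) + (r[0] - q[0]) * (p[1] - r[1])
                            if abs(d) < 1e-12:
                                continue
                            l1 = ((q[1] - r[1]) * (pts[i][0] - r[0]) + (r[0] - q[0]) * (pts[i][1] - r[1])) / d
                            l2 = ((r[1] - p[1]) * (pts[i][0] - r[0]) + (p[0] - r[0]) * (pts[i][1] - r[1])) / d
                            l3 = 1 - l1 - l2
                            if l1 > 1e-9 and l2 > 1e-9 and l3 > 1e-9:
                                inside = True
                    if inside:
                        break
                if not inside:
                    verts.append(pts[i])
            verts = np.array(verts)
            c = verts.mean(axis=0)
            ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
            v = verts[np.argsort(ang)]
            x, y = v[:, 0], v[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        for seed in range(5):
            r = np.random.default_rng(seed)
            pts = r.uniform(0, 1000, (10, 2))
            area, _ = hull_area_um2(pts)
            assert area == pytest.approx(brute_area(pts) * 1e-6, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 800, (12, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([1234.5, -987.0])
        a1, _ = hull_area_um2(pts)
        a2, _ = hull_area_um2(moved)
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_mode_requirements(self, rng):
        pts = rng.uniform(0, 500, (6, 2))
        modes = np.array(["synchronous"] * 6)
        with pytest.raises(ValueError, match="both"):
            convex_hull_areas(pts, modes)
        with pytest.raises(ValueError, match=">= 5"):
            convex_hull_areas(pts[:3], modes[:3])

    def test_mode_areas_bounded_by_total(self, rng):
        pts = rng.uniform(0, 500, (20, 2))
        modes = np.where(rng.random(20) < 0.5, "synchronous", "asynchronous")
        if len(set(modes)) < 2:
            modes[0] = "synchronous"
            modes[1] = "asynchronous"
        ra = convex_hull_areas(pts, modes)
        assert ra.S_sync <= ra.S_all + 1e-12
        assert ra.S_async <= ra.S_all + 1e-12


class TestReshuffle:
    def test_identity_permutation_normalizes_to_one(self, rng):
        pts = rng.uniform(0, 500, (12, 2))
        modes = np.array(["synchronous"] * 6 + ["asynchronous"] * 6)
        perm = np.arange(12)[None, :]
        ra = reshuffle_normalized_area(pts, modes, permutations=perm)
        assert ra.normalized_sync == pytest.approx(1.0)
        assert ra.normalized_async == pytest.approx(1.0)

    def test_exchangeable_null_is_near_one(self):
        # both modes drawn from one distribution: median normalized area ~ 1
        vals_s, vals_a = [], []
        for seed in range(60):
            r = np.random.default_rng(seed)
            pts = r.normal(0, 150, (14, 2))
            modes = np.array(["synchronous"] * 7 + ["asynchronous"] * 7)
            ra = reshuffle_normalized_area(pts, modes, n_shuffles=150, seed=seed)
            vals_s.append(ra.normalized_sync)
            vals_a.append(ra.normalized_async)
        assert abs(np.median(vals_s) - 1.0) < 0.1
        assert abs(np.median(vals_a) - 1.0) < 0.1

    def test_dispersed_async_detected(self):
        # async positions with 2x spatial SD: normalized async > sync
        wins = 0
        n = 80
        for seed in range(n):
            r = np.random.default_rng(1000 + seed)
            sync = r.normal(0, 100, (8, 2))
            asyn = r.normal(0, 200, (8, 2))
            pts = np.vstack([sync, asyn])
            modes = np.array(["synchronous"] * 8 + ["asynchronous"] * 8)
            ra = reshuffle_normalized_area(pts, modes, n_shuffles=120, seed=seed)
            wins += ra.normalized_async > ra.normalized_sync
        assert stats.binomtest(wins, n, 0.5, alternative="greater").pvalue < 0.01
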