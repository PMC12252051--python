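"""DimWise, overlap, confidence and severity: hand-computable cases,
brute-force oracle equivalence, and structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitlens import explain
from gaitlens.explain import (cluster_feature_stats, confidence, dimwise,
                              explain_clusters, overlap, region_scores,
                              severity, severity_scores)
from gaitlens.schema import DEFAULT_SCHEMA, REGIONS


def _embed(points_per_joint):
    """Build (n, 18, 3) vectors with every joint set to the same 3-vectors."""
    pts = np.asarray(points_per_joint, dtype=float)  # (n, 3)
    return np.repeat(pts[:, None, :], 18, axis=1)


class TestClusterStats:
    def test_hand_computed_mean_and_trace(self):
        vecs = _embed([[0, 0, 0], [2, 0, 0]])
        stats = cluster_feature_stats(vecs, np.zeros(2, dtype=int), 0)
        assert np.allclose(stats.means[0], [1, 0, 0])
        assert np.isclose(stats.variances[0], 2.0)  # sample variance, n-1

    def test_identical_points_floored_with_warning(self):
        vecs = _embed([[1, 1, 1]] * 4)
        with pytest.warns(UserWarning, match="zero variance"):
            stats = cluster_feature_stats(vecs, np.zeros(4, dtype=int), 0)
        assert np.allclose(stats.variances, explain.VARIANCE_FLOOR)

    def test_matches_brute_force_on_random_fixture(self, rng):
        vecs = rng.normal(size=(40, 18, 3))
        assign = rng.integers(0, 2, size=40)
        stats = cluster_feature_stats(vecs, assign, 1)
        sel = vecs[assign == 1]
        for j in (0, 7, 17):
            mu = sel[:, j].mean(axis=0)
            cov = sum(np.outer(p - mu, p - mu) for p in sel[:, j]) / (len(sel) - 1)
            assert np.abs(stats.means[j] - mu).max() < 1e-12
            assert abs(stats.variances[j] - np.trace(cov)) < 1e-10


class TestOverlap:
    def _two_clusters(self, a_pts, r_pts):
        a, r = _embed(a_pts), _embed(r_pts)
        vecs = np.concatenate([a, r])
        assign = np.array([0] * len(a) + [1] * len(r))
        sa = cluster_feature_stats(vecs, assign, 0)
        sr = cluster_feature_stats(vecs, assign, 1)
        return sa, a, sr, r

    def test_fully_separated_is_one(self, rng):
        a = rng.normal(0, 1, size=(50, 3))
        r = rng.normal(10, 1, size=(50, 3)) + 20
        sa, pa, sr, pr = self._two_clusters(a, r)
        assert overlap(0, sa, pa, sr, pr) == 1.0

    def test_hand_check_one_axis(self):
        a = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        r = [[10, 0, 0], [11, 0, 0], [12, 0, 0]]
        sa, pa, sr, pr = self._two_clusters(a, r)
        assert overlap(0, sa, pa, sr, pr) == 1.0

    def test_matches_per_point_oracle_on_overlapping_gaussians(self, rng):
        """Same-sample brute-force count (scipy Mahalanobis per point)
        reproduces the vectorized result exactly."""
        from scipy.spatial.distance import mahalanobis
        a = rng.normal(0.0, 1.0, size=(200, 3))
        r = rng.normal(1.0, 1.0, size=(200, 3))
        sa, pa, sr, pr = self._two_clusters(a, r)
        got = overlap(4, sa, pa, sr, pr)
        via = np.linalg.inv(sa.covs[4])
        vir = np.linalg.inv(sr.covs[4])
        crossed = 0
        for x in pa[:, 4]:
            if mahalanobis(x, sr.means[4], vir) < mahalanobis(x, sa.means[4], via):
                crossed += 1
        for x in pr[:, 4]:
            if mahalanobis(x, sa.means[4], via) < mahalanobis(x, sr.means[4], vir):
                crossed += 1
        oracle = 1 - crossed / 400
        assert abs(got - oracle) < 1e-12
        assert 0.1 < got < 0.9  # genuinely overlapping fixture

    def test_identical_clusters_strict_inequality_gives_one(self):
        pts = [[0, 0, 0], [1, 1, 1], [2, 2, 2]]
        sa, pa, sr, pr = self._two_clusters(pts, pts)
        # exact distance ties never satisfy the strict inequality
        with pytest.warns(UserWarning, match="identical"):
            assert overlap(0, sa, pa, sr, pr) == 1.0


class TestDimWise:
    def _stats(self, var, mean):
        s = cluster_feature_stats(_embed([[0, 0, 0], [2, 0, 0]]),
                                  np.zeros(2, dtype=int), 0)
        s.variances[:] = var
        s.means[:] = np.asarray(mean)
        return s

    def test_arithmetic_cases(self):
        a = self._stats(1.0, [0, 0, 0])
        r = self._stats(1.0, [0, 0, 0])
        assert dimwise(0, a, r, 1.0) == pytest.approx(2.0)
        assert dimwise(0, a, r, 0.0) == pytest.approx(1.0)

    def test_monotone_in_centroid_gap(self):
        a = self._stats(1.0, [0, 0, 0])
        r1 = self._stats(1.0, [1, 0, 0])
        r3 = self._stats(1.0, [3, 0, 0])
        assert dimwise(0, a, r1, 1.0) == pytest.approx(4.0)
        assert dimwise(0, a, r3, 1.0) == pytest.approx(8.0)

    def test_decreasing_in_variance(self):
        r = self._stats(1.0, [1, 0, 0])
        lo = dimwise(0, self._stats(0.5, [0, 0, 0]), r, 0.5)
        hi = dimwise(0, self._stats(2.0, [0, 0, 0]), r, 0.5)
        assert lo > hi


class TestRegionScores:
    def test_symmetric_input_uniform_percentages(self):
        # equal per-region sums under equal weights -> 1/6 each
        imp = np.zeros(18)
        for region in REGIONS:
            joints = DEFAULT_SCHEMA.region_joints(region)
            imp[joints] = 1.0 / len(joints)
        weights = {r: 1.0 for r in REGIONS}
        with pytest.warns(UserWarning, match="tied"):
            pct, ranks = region_scores(imp, weights=weights)
        assert all(np.isclose(v, 1 / 6) for v in pct.values())
        assert sorted(ranks.values()) == [1, 2, 3, 4, 5, 6]

    @given(st.lists(st.floats(0, 50), min_size=18, max_size=18))
    @settings(max_examples=50, deadline=None)
    def test_softmax_properties(self, raw):
        imp = np.asarray(raw)
        pct, ranks = region_scores(imp)
        assert abs(sum(pct.values()) - 1.0) < 1e-9
        assert sorted(ranks.values()) == [1, 2, 3, 4, 5, 6]
        # rank order consistent with percentages
        ordered = sorted(REGIONS, key=lambda r: ranks[r])
        vals = [pct[r] for r in ordered]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invariant_to_constant_shift_of_weighted_sums(self):
        weights = {r: 1.0 for r in REGIONS}
        imp = np.zeros(18)
        for i, region in enumerate(REGIONS):
            imp[DEFAULT_SCHEMA.region_joints(region)[0]] = float(i)
        pct1, _ = region_scores(imp, weights=weights)
        shifted = imp.copy()
        for region in REGIONS:
            shifted[DEFAULT_SCHEMA.region_joints(region)[0]] += 7.5
        pct2, _ = region_scores(shifted, weights=weights)
        for r in REGIONS:
            assert pct1[r] == pytest.approx(pct2[r], abs=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            region_scores(np.ones(18), weights={**{r: 1.0 for r in REGIONS},
                                                "head": 0.0})


class TestConfidence:
    M_R = np.zeros(54)
    M_A = np.concatenate([np.full(1, 4.0), np.zeros(53)])

    def test_at_abnormal_centroid(self):
        assert confidence(self.M_A, self.M_A, self.M_R) == pytest.approx(1.0)

    def test_at_midpoint(self):
        mid = (self.M_A + self.M_R) / 2
        assert confidence(mid, self.M_A, self.M_R) == pytest.approx(0.5)

    def test_collinear_beyond_abnormal(self):
        p = 1.5 * self.M_A  # 1.5 Dist from M_r along the segment
        assert confidence(p, self.M_A, self.M_R) == pytest.approx(1.5)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            confidence(self.M_A, self.M_R, self.M_R)


class TestSeverity:
    def test_equidistant_instances_score_one(self):
        d = np.full(10, 3.3)
        assert np.allclose(severity_scores(d), 1.0)

    def test_twice_the_common_distance_scores_two(self):
        d = np.array([2.0] + [1.0] * 50)
        s = severity_scores(d)
        assert s[0] == pytest.approx(2.0)

    @given(st.lists(st.floats(0.1, 10), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_vectorized_equals_scalar_definition(self, ds):
        d = np.asarray(ds)
        s = severity_scores(d)
        for i in range(len(d)):
            assert s[i] == pytest.approx(
                severity(d[i], np.delete(d, i)), rel=1e-12)

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError):
            severity_scores(np.zeros(5))


class TestExplainClusters:
    def _three_cluster_vectors(self, rng, d_near=1.0, d_far=3.0, n=40):
        reg = rng.normal(0, 0.1, size=(n, 54))
        near = rng.normal(0, 0.1, size=(n, 54))
        near[:, 0] += d_near
        far = rng.normal(0, 0.1, size=(n, 54))
        far[:, 0] += d_far
        vecs = np.concatenate([reg, near, far])
        assign = np.repeat([0, 1, 2], n)
        return vecs, assign

    def test_severity_orders_with_centroid_distance(self, rng):
        vecs, assign = self._three_cluster_vectors(rng)
        rep = explain_clusters(vecs, assign, regular_cluster_id=0,
                               feature_scaling="none")
        assert rep.mean_severity[2] > rep.mean_severity[1]
        assert rep.regular_mean_severity < rep.mean_severity[1]

    def test_perturbed_joint_region_ranked_first(self, rng):
        """A mean shift confined to one joint's dims puts that joint's
        region on top."""
        n = 50
        reg = rng.normal(0, 1.0, size=(n, 18, 3))
        ab = rng.normal(0, 1.0, size=(n, 18, 3))
        j = DEFAULT_SCHEMA.index("l_knee")
        ab[:, j, :] += 4.0
        vecs = np.concatenate([reg, ab])
        assign = np.repeat([0, 1], n)
        rep = explain_clusters(vecs, assign, 0)
        ranks = rep.dimwise[1].region_ranks
        assert ranks["left_leg"] == 1

    def test_oracle_recomputation_of_full_dimwise(self, rng):
        """Scores agree with a from-scratch recomputation of Eqs. on the
        same clusters (independent loop-based code path)."""
        vecs, assign = self._three_cluster_vectors(rng, n=25)
        rep = explain_clusters(vecs, assign, 0, feature_scaling="none")
        feats = vecs.reshape(-1, 18, 3)
        for cid in (1, 2):
            a_pts = feats[assign == cid]
            r_pts = feats[assign == 0]
            for j in (0, 9):
                mu_a = a_pts[:, j].mean(axis=0)
                mu_r = r_pts[:, j].mean(axis=0)
                var_a = np.trace(np.cov(a_pts[:, j], rowvar=False, ddof=1))
                o = rep.dimwise[cid].overlaps[j]
                expected = (1 / var_a) * (1 + o) * (1 + np.linalg.norm(mu_r - mu_a))
                assert rep.dimwise[cid].importances[j] == pytest.approx(
                    expected, rel=1e-10)

    def test_confidence_means_positive_and_bounded_below(self, rng):
        vecs, assign = self._three_cluster_vectors(rng)
        rep = explain_clusters(vecs, assign, 0, feature_scaling="none")
        for v in rep.mean_confidence.values():
            assert v >= 0.5

    def test_scalar_mode_agrees_on_rank1_signal(self, rng):
        n = 50
        reg = rng.normal(0, 1.0, size=(n, 18, 3))
        ab = rng.normal(0, 1.0, size=(n, 18, 3))
        ab[:, 10, :] += 4.0  # r_ankle
        vecs = np.concatenate([reg, ab])
        assign = np.repeat([0, 1], n)
        for mode in ("vector", "scalar"):
            rep = explain_clusters(vecs, assign, 0, feature_mode=mode)
            assert rep.dimwise[1].region_ranks["right_leg"] == 1
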