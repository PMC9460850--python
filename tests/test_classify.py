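"""Centroid fitting, labeling, and nearest-centroid staging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respstage import (Centroid, CentroidSet, FeatureVector, ScalingConfig,
                       SleepStage, apply_scaling, classify, classify_session,
                       euclidean_distance, fit_centroids, label_centroids,
                       stage_mean_centroids)
from respstage.errors import (AmbiguousLabelError, EmptyClusterError,
                              InvalidModelError, InvalidParameterError)

STAGES = list(SleepStage)

coords = st.floats(-50, 50, allow_nan=False)


def fv(x, y, stage=None):
    return FeatureVector(abs(x), abs(y), stage) if x >= 0 and y >= 0 else None


class TestEuclideanDistance:
    def test_point_equal_to_centroid_gives_zero(self):
        assert euclidean_distance((1.6, 0.8), Centroid(1, 1.6, 0.8)) == 0.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            euclidean_distance((float("nan"), 0), Centroid(1, 0, 0))
        with pytest.raises(InvalidParameterError):
            Centroid(1, float("inf"), 0)

    @settings(derandomize=True, max_examples=200)
    @given(ax=coords, ay=coords, bx=coords, by=coords, cx=coords, cy=coords)
    def test_metric_axioms(self, ax, ay, bx, by, cx, cy):
        """Non-negativity, identity, symmetry, triangle inequality."""
        a, b, c = (ax, ay), (bx, by), (cx, cy)
        d_ab = euclidean_distance(a, Centroid(1, *b))
        d_ba = euclidean_distance(b, Centroid(1, *a))
        d_ac = euclidean_distance(a, Centroid(1, *c))
        d_cb = euclidean_distance(c, Centroid(1, *b))
        assert d_ab >= 0
        assert euclidean_distance(a, Centroid(1, *a)) == 0
        assert d_ab == d_ba
        assert d_ab <= d_ac + d_cb + 1e-9


def gaussian_clouds(centers, sd, n_per, seed):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for stage, (cx, cy) in zip(STAGES, centers):
        xy = rng.normal((cx, cy), sd, size=(n_per, 2))
        xy = np.abs(xy)
        pts += [FeatureVector(x, y, stage) for x, y in xy]
        labels += [stage] * n_per
    return pts, labels


WELL_SEPARATED = [(2.0, 2.0), (8.0, 2.0), (2.0, 8.0), (8.0, 8.0), (5.0, 13.0)]


class TestFitCentroids:
    def test_k_equal_n_puts_each_point_at_its_own_centroid(self):
        pts = [fv(1, 1), fv(4, 2), fv(2, 6)]
        cset = fit_centroids(pts, k=3, seed=0, n_init=3)
        assert cset.metadata["objective"] == pytest.approx(0.0, abs=1e-12)
        got = sorted((c.x, c.y) for c in cset.centroids)
        assert got == sorted((p.rate_bpm, p.voltage) for p in pts)

    def test_fewer_points_than_k_raises(self):
        with pytest.raises(InvalidParameterError):
            fit_centroids([fv(1, 1)], k=2)

    def test_fixed_seed_is_bit_reproducible(self):
        pts, _ = gaussian_clouds(WELL_SEPARATED, 0.4, 30, seed=5)
        a = fit_centroids(pts, k=5, seed=11)
        b = fit_centroids(pts, k=5, seed=11)
        assert [(c.x, c.y) for c in a.centroids] == [(c.x, c.y) for c in b.centroids]
        assert a.metadata["objective"] == b.metadata["objective"]

    def test_objective_history_is_non_increasing(self):
        pts, _ = gaussian_clouds(WELL_SEPARATED, 0.8, 40, seed=3)
        cset = fit_centroids(pts, k=5, seed=1)
        hist = cset.metadata["history"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_recovers_separated_cloud_means_within_3_se(self):
        sd, n_per = 0.3, 60
        pts, _ = gaussian_clouds(WELL_SEPARATED, sd, n_per, seed=7)
        cset = fit_centroids(pts, k=5, seed=0)
        tol = 3 * sd / math.sqrt(n_per)
        for cx, cy in WELL_SEPARATED:
            best = min(euclidean_distance((cx, cy), c) for c in cset.centroids)
            assert best <= 3 * tol  # 3 SE per coordinate, diagonal slack

    def test_matches_sklearn_objective(self):
        """Independent oracle: sklearn's k-means reaches the same optimum."""
        from sklearn.cluster import KMeans
        pts, _ = gaussian_clouds(WELL_SEPARATED, 0.5, 40, seed=9)
        X = np.array([(p.rate_bpm, p.voltage) for p in pts])
        ours = fit_centroids(pts, k=5, seed=2).metadata["objective"]
        theirs = KMeans(n_clusters=5, n_init=10, random_state=0).fit(X).inertia_
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestLabelCentroids:
    def _pure_cset(self):
        return CentroidSet([Centroid(i + 1, *WELL_SEPARATED[i])
                            for i in range(5)])

    def test_pure_clusters_get_bijective_labels(self):
        pts, _ = gaussian_clouds(WELL_SEPARATED, 0.3, 10, seed=0)
        cset = label_centroids(self._pure_cset(), pts)
        assert sorted(c.stage for c in cset.centroids) == STAGES

    def test_majority_wins(self):
        cset = CentroidSet([Centroid(1, 0, 0), Centroid(2, 10, 10)])
        pts = [fv(0, 0, SleepStage.N1)] * 3 + [fv(0.5, 0, SleepStage.N2)] \
            + [fv(10, 10, SleepStage.N3)]
        out = label_centroids(cset, pts)
        assert out.centroids[0].stage is SleepStage.N1

    def test_strict_tie_raises(self):
        cset = CentroidSet([Centroid(1, 0, 0), Centroid(2, 10, 10)])
        pts = [fv(0, 0, SleepStage.N1)] * 2 + [fv(0, 0.5, SleepStage.N2)] * 2 \
            + [fv(10, 10, SleepStage.N3)]
        with pytest.raises(AmbiguousLabelError):
            label_centroids(cset, pts, strict=True)

    def test_lenient_tie_resolved_deterministically(self):
        cset = CentroidSet([Centroid(1, 0, 0), Centroid(2, 10, 10)])
        pts = [fv(0, 0, SleepStage.N1)] * 2 + [fv(0, 0.5, SleepStage.N2)] * 2 \
            + [fv(10, 10, SleepStage.N3)]
        out = label_centroids(cset, pts, strict=False)
        assert out.centroids[0].stage is SleepStage.N1  # stage-order tiebreak
        assert out.centroids[1].stage is SleepStage.N3

    def test_strict_duplicate_stage_claim_raises(self):
        cset = CentroidSet([Centroid(1, 0, 0), Centroid(2, 10, 10)])
        pts = [fv(0, 0, SleepStage.REM)] * 2 + [fv(10, 10, SleepStage.REM)] * 3
        with pytest.raises(AmbiguousLabelError):
            label_centroids(cset, pts, strict=True)

    def test_empty_cluster_raises_coverage_error(self):
        cset = CentroidSet([Centroid(1, 0, 0), Centroid(2, 100, 100)])
        pts = [fv(0, 0, SleepStage.N1), fv(1, 1, SleepStage.N2)]
        with pytest.raises(EmptyClusterError):
            label_centroids(cset, pts)


def labeled_cset(centers=WELL_SEPARATED):
    return CentroidSet([Centroid(i + 1, x, y, stage)
                        for i, ((x, y), stage) in enumerate(zip(centers, STAGES))])


class TestClassify:
    def test_point_at_centroid_gets_its_stage(self):
        cset = labeled_cset()
        assert classify((8.0, 8.0), cset) is SleepStage.N3

    def test_matches_brute_force_argmin_on_random_points(self):
        cset = labeled_cset()
        rng = np.random.default_rng(12)
        for x, y in rng.uniform(0, 15, size=(1000, 2)):
            expected = min(
                ((euclidean_distance((x, y), c), i) for i, c in
                 enumerate(cset.centroids)))[1]
            assert classify((x, y), cset) is cset.centroids[expected].stage

    def test_exact_tie_broken_by_lowest_cluster_index(self):
        cset = CentroidSet([Centroid(1, 0, 0, SleepStage.N2),
                            Centroid(2, 2, 0, SleepStage.REM)])
        assert classify((1.0, 0.0), cset) is SleepStage.N2

    def test_unlabeled_set_rejected(self):
        cset = CentroidSet([Centroid(1, 0, 0)])
        with pytest.raises(InvalidModelError):
            classify((0, 0), cset)

    def test_session_classification_composes_pointwise(self):
        cset = labeled_cset()
        rng = np.random.default_rng(3)
        feats = [FeatureVector(x, y) for x, y in rng.uniform(0, 12, (40, 2))]
        assert classify_session(feats, cset) == [classify(f, cset) for f in feats]

    def test_empty_feature_list_gives_empty_hypnogram(self):
        assert classify_session([], labeled_cset()) == []


class TestScalingEquivariance:
    def test_uniform_scaling_preserves_classification(self):
        """Multiplying both axes of points and centroids by the same c > 0
        leaves every nearest-centroid decision unchanged."""
        cset = labeled_cset()
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 12, (200, 2))
        for c in (0.1, 3.0):
            scaled = CentroidSet([Centroid(cc.index_i, c * cc.x, c * cc.y, cc.stage)
                                  for cc in cset.centroids])
            for x, y in pts:
                d = sorted(euclidean_distance((x, y), cc) for cc in cset.centroids)
                if d[1] - d[0] < 1e-9:
                    continue
                assert classify((c * x, c * y), scaled) is classify((x, y), cset)

    def test_centroid_fit_commutes_with_axiswise_scaling(self):
        """Per-stage mean centroids of scaled features equal the scaled
        centroids of raw features — scaling and fitting commute exactly."""
        rng = np.random.default_rng(4)
        pts = [FeatureVector(r, v, STAGES[i % 5]) for i, (r, v) in
               enumerate(rng.uniform(1, 20, (100, 2)))]
        config = ScalingConfig(weight_W=0.1, voltage_reference=7.89)
        direct = stage_mean_centroids(apply_scaling(pts, config))
        raw = stage_mean_centroids(pts)
        for a, b in zip(direct.centroids, raw.centroids):
            assert a.stage is b.stage
            assert a.x == pytest.approx(config.weight_W * b.x, rel=1e-12)
            assert a.y == pytest.approx(b.y / config.voltage_reference, rel=1e-12)


def test_well_separated_stage_clusters_classified_above_95_percent():
    """With per-stage clusters >= 4 sd apart, the fit/label/classify chain
    stays above 95% accuracy."""
    train, _ = gaussian_clouds(WELL_SEPARATED, 0.5, 40, seed=21)
    test, truth = gaussian_clouds(WELL_SEPARATED, 0.5, 40, seed=22)
    cset = label_centroids(fit_centroids(train, k=5, seed=0), train)
    pred = classify_session(test, cset)
    acc = np.mean([p is t for p, t in zip(pred, truth)])
    assert acc >= 0.95
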