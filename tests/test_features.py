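import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import statistics_naive
from tepc.connectivity import (
    KernelSpec,
    PointCloud,
    build_connectivity,
    laplacian_filtration,
    pairwise_distances,
)
from tepc.dynamics import CoupledSystem, OscillatorSpec, integrate
from tepc.features import (
    DEFAULT_STATISTICS,
    balanced_accuracy,
    cross_validate,
    fit_bfactor_regression,
    multiscale_features,
    pearson_cc,
    rs_scores,
    trajectory_statistics,
)
from tepc.synthetic import polygon_cloud


def polygon_family(n=16, p=10):
    d = pairwise_distances(polygon_cloud(n, 1.0))
    conn = build_connectivity(d, KernelSpec("exponential", 3.0))
    return laplacian_filtration(conn, p)


class TestTrajectoryStatistics:
    def test_constant_series(self):
        series = np.full((50, 3), -2.5)
        v = trajectory_statistics(series, stats=DEFAULT_STATISTICS,
                                  transient_fraction=0.0)
        per_var = v.reshape(3, -1)
        for row in per_var:
            mean, sd, mn, mx, med, skew, kurt, rms = row
            assert mean == med == mn == mx == -2.5
            assert sd == 0.0 and skew == 0.0 and kurt == 0.0
            assert rms == 2.5

    def test_three_point_hand_example(self):
        series = np.column_stack([[-1.0, 0.0, 1.0]] * 3)
        v = trajectory_statistics(series, transient_fraction=0.0).reshape(3, -1)
        mean, sd, mn, mx = v[0, 0], v[0, 1], v[0, 2], v[0, 3]
        assert mean == 0.0
        assert sd == pytest.approx(0.816496580927726, abs=1e-12)
        assert mn == -1.0 and mx == 1.0

    def test_matches_naive_two_pass_oracle_on_lorenz(self):
        one = CoupledSystem(OscillatorSpec.lorenz(), np.zeros((1, 1)), epsilon=0.0)
        traj = integrate(one, np.array([[1.0, 1.0, 1.0]]), 1e-3, 2000)
        v = trajectory_statistics(traj, node=0, transient_fraction=0.1).reshape(3, -1)
        start = int(0.1 * traj.states.shape[0])
        for var in range(3):
            ref = statistics_naive(traj.states[start:, 0, var])
            for j, name in enumerate(DEFAULT_STATISTICS):
                assert v[var, j] == pytest.approx(ref[name], abs=1e-10), name

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            trajectory_statistics(np.zeros((2, 3)), transient_fraction=0.9)


class TestMultiscaleFeatures:
    def test_empty_scale_gives_identical_node_rows(self):
        fam = polygon_family(p=10)
        fam.laplacians = [fam.laplacians[-1]]  # the always-empty scale
        fam.p = 1
        feats = multiscale_features(fam, OscillatorSpec.lorenz(),
                                    epsilon=13.6, steps=200)
        assert np.allclose(feats.values, feats.values[:1, :], atol=0)

    def test_node_permutation_equivariance(self):
        fam = polygon_family(n=10, p=4)
        spec = OscillatorSpec.lorenz()
        feats = multiscale_features(fam, spec, epsilon=2.0, steps=200)
        perm = np.random.default_rng(3).permutation(10)
        fam_p = polygon_family(n=10, p=4)
        fam_p.laplacians = [lk[np.ix_(perm, perm)] for lk in fam_p.laplacians]
        feats_p = multiscale_features(fam_p, spec, epsilon=2.0, steps=200)
        assert np.allclose(feats_p.values, feats.values[perm], atol=1e-12)

    def test_synchronized_scale_has_lower_between_node_variance(self):
        fam = polygon_family(n=16, p=10)
        # densest vs empty scale, shared random run: a synchronized ring
        # homogenizes node trajectories, isolated chaos does not
        feats = multiscale_features(
            fam, OscillatorSpec.lorenz(), epsilon=1.1, steps=2000,
            protocol="shared", seed=5,
        )
        per_scale = feats.values.reshape(16, fam.p, -1)
        var_dense = per_scale[:, 0, :].var(axis=0).mean()
        var_empty = per_scale[:, -1, :].var(axis=0).mean()
        assert var_dense < var_empty

    def test_all_scales_diverged_raises(self):
        fam = polygon_family(n=8, p=2)
        with pytest.warns(RuntimeWarning, match="diverged"):
            with pytest.raises(RuntimeError, match="every scale"):
                multiscale_features(fam, OscillatorSpec.lorenz(), epsilon=1.0,
                                    steps=200, divergence_bound=1e-3)

    def test_provenance_records_run_conditions(self):
        fam = polygon_family(n=8, p=2)
        feats = multiscale_features(fam, OscillatorSpec.lorenz(), epsilon=1.0,
                                    steps=100)
        prov = feats.provenance
        assert prov["model"] == "lorenz" and prov["steps"] == 100
        assert prov["dropped_scales"] == []
        assert len(feats.feature_names) == 2 * 3 * len(DEFAULT_STATISTICS)


class TestPearsonCC:
    def test_exact_values(self):
        x = np.arange(1.0, 5.0)
        assert pearson_cc(x, 3 * x + 2) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)
        assert pearson_cc(x, np.array([2.0, 1.0, 4.0, 3.0])) == pytest.approx(0.6)

    @settings(max_examples=100, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_invariant_under_positive_affine_maps(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = pearson_cc(x, y)
        assert pearson_cc(a * x + b, y) == pytest.approx(r0, abs=1e-9)
        assert pearson_cc(x, a * y + b) == pytest.approx(r0, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_cc(np.ones(5), np.arange(5.0))


class TestBfactorRegression:
    def test_perfect_linear_target(self, rng):
        x = rng.normal(size=(60, 4))
        b = 2.0 + 3.0 * x[:, 1]
        res = fit_bfactor_regression(x, b)
        assert res.pcc == pytest.approx(1.0, abs=1e-9)
        assert np.abs(res.predictions - b).max() < 1e-8

    def test_null_features_give_low_in_sample_pcc(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(500, 8))
        b = rng.normal(size=500)
        res = fit_bfactor_regression(x, b)
        assert abs(res.pcc) < 0.2

    def test_rank_deficient_falls_back_to_ridge(self, rng):
        x = rng.normal(size=(40, 3))
        x = np.hstack([x, x[:, :1]])  # exact collinearity
        b = x[:, 0] + rng.normal(scale=0.1, size=40)
        res = fit_bfactor_regression(x, b)
        assert res.ridge is not None and res.ridge > 0
        assert np.isfinite(res.predictions).all()

    def test_variance_reduction_and_ill_posedness(self, rng):
        x = rng.normal(size=(30, 50))
        b = rng.normal(size=30)
        with pytest.raises(ValueError, match="ill-posed"):
            fit_bfactor_regression(x, b)
        res = fit_bfactor_regression(x, b, n_features=10)
        assert res.selected_features.size == 10

    def test_duplicating_all_samples_leaves_fit_unchanged(self, rng):
        x = rng.normal(size=(50, 5))
        b = x @ rng.normal(size=5) + rng.normal(scale=0.3, size=50)
        r1 = fit_bfactor_regression(x, b)
        r2 = fit_bfactor_regression(np.vstack([x, x]), np.concatenate([b, b]))
        assert r2.pcc == pytest.approx(r1.pcc, abs=1e-6)


class TestBalancedAccuracy:
    def test_perfect_and_majority(self):
        y = np.array([0] * 90 + [1] * 10)
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, np.zeros(100, dtype=int)) == 0.5

    def test_three_class_hand_average(self):
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 0, 1, 0, 0, 1])  # recalls 1, 0.5, 0
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.5)

    def test_equals_accuracy_on_balanced_labels(self, rng):
        for _ in range(10):
            y = np.repeat([0, 1, 2], 30)
            pred = rng.integers(0, 3, size=90)
            acc = float((y == pred).mean())
            # balanced classes + uniform predictor: BA ≈ accuracy exactly
            per_class = [float((pred[y == c] == c).mean()) for c in (0, 1, 2)]
            assert balanced_accuracy(y, pred) == pytest.approx(np.mean(per_class))
            assert np.mean(per_class) == pytest.approx(acc)

    def test_stray_predicted_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            balanced_accuracy(np.array([0, 1]), np.array([0, 2]))


class TestCrossValidate:
    def _blobs(self, rng, n=60, sep=8.0):
        x = np.vstack([
            rng.normal(size=(n // 2, 2)),
            rng.normal(size=(n // 2, 2)) + sep,
        ])
        y = np.repeat([0, 1], n // 2)
        return x, y

    def test_separable_blobs_reach_perfect_ba(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = self._blobs(rng)
        rep = cross_validate(x, y, folds=5, seeds=[0, 1],
                             adapter=lambda: KNeighborsClassifier(3))
        assert rep.mean_ba == 1.0
        assert rep.confusion.sum() == 2 * 60

    def test_fold_assignment_reproducible(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = self._blobs(rng)
        rep1 = cross_validate(x, y, 5, [7], lambda: KNeighborsClassifier(3))
        rep2 = cross_validate(x, y, 5, [7], lambda: KNeighborsClassifier(3))
        assert np.array_equal(rep1.fold_assignments[7], rep2.fold_assignments[7])

    def test_permuted_labels_land_at_chance(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(0)
        x = rng.normal(size=(160, 5))
        y = np.repeat([0, 1, 2, 3], 40)
        y = rng.permutation(y)
        rep = cross_validate(x, y, 4, list(range(10)),
                             lambda: KNeighborsClassifier(5))
        assert abs(rep.mean_ba - 0.25) <= 0.05

    def test_small_class_suggests_fewer_folds(self):
        x = np.zeros((7, 2))
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="fewer"):
            cross_validate(x, y, folds=5)


class TestRSScores:
    def test_collapsed_classes_have_unit_similarity(self):
        x = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0]])
        y = np.array([0, 0, 1, 1])
        s = rs_scores(x, y)
        assert np.allclose(s.similarity, 1.0)
        assert np.allclose(s.residue, 1.0)  # all out-of-class means equal r_max

    def test_identical_samples_zero_residue(self):
        x = np.zeros((6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        s = rs_scores(x, y)
        assert np.allclose(s.residue, 0.0)

    def test_two_class_toy_hand_values(self):
        # class 0 at x=0, class 1 at x=1; within-class spread 0.2 on y
        x = np.array([[0, 0], [0, 0.2], [1, 0], [1, 0.2]], dtype=float)
        y = np.array([0, 0, 1, 1])
        s = rs_scores(x, y)
        d_max = np.sqrt(1 + 0.04)
        assert s.similarity[0] == pytest.approx(1 - 0.2 / d_max)
        r0 = (1.0 + d_max) / 2  # mean distance to the two class-1 points
        assert s.residue[0] == pytest.approx(r0 / r0)  # symmetric → r_max = r0

    def test_scores_bounded_random_inputs(self, rng):
        for _ in range(10):
            x = rng.normal(size=(20, 4))
            y = rng.integers(0, 3, size=20)
            if np.min(np.bincount(y, minlength=3)) < 2:
                continue
            s = rs_scores(x, y)
            assert (0 <= s.residue).all() and (s.residue <= 1).all()
            assert (0 <= s.similarity).all() and (s.similarity <= 1).all()

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            rs_scores(np.zeros((3, 2)), np.array([0, 0, 1]))
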