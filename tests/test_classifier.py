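"""Unit and property tests for the PAV-GNB estimator and its building blocks."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import norm
from sklearn.naive_bayes import GaussianNB

from pavgnb.classifier import (BaseLearner, GaussianClassParams, PAVGaussianNB,
                               fit_base_gnb, log_joint_scores,
                               normalize_log_posteriors, sample_feature_subset,
                               stratified_bootstrap)
from pavgnb.io import save_model
from pavgnb.synthdata import ScenarioSpec, generate_dataset


class TestStratifiedBootstrap:
    def test_preserves_class_counts_exactly(self, rng):
        y = np.array(["A"] * 3 + ["B"] * 2)
        idx = stratified_bootstrap(y, np.array(["A", "B"]), rng)
        assert len(idx) == 5
        assert (y[idx] == "A").sum() == 3
        assert (y[idx] == "B").sum() == 2

    def test_singleton_classes_resample_with_certainty(self, rng):
        y = np.array(["a", "b", "c"])
        idx = stratified_bootstrap(y, np.array(["a", "b", "c"]), rng)
        assert sorted(idx.tolist()) == [0, 1, 2]

    def test_within_class_sampling_is_uniform(self, rng):
        # Monte-Carlo check: each A row should fill A slots with prob 1/4.
        y = np.array(["A"] * 4 + ["B"] * 6)
        draws = 10_000
        hits = 0
        for _ in range(draws):
            idx = stratified_bootstrap(y, np.array(["A", "B"]), rng)
            hits += (idx == 0).sum()
        p_hat = hits / (4 * draws)
        se = np.sqrt(0.25 * 0.75 / (4 * draws))
        assert abs(p_hat - 0.25) < 3 * se

    def test_empty_class_raises(self, rng):
        y = np.array(["A", "A"])
        with pytest.raises(ValueError, match="no members"):
            stratified_bootstrap(y, np.array(["A", "B"]), rng)


class TestFeatureSubset:
    @pytest.mark.parametrize("p,frac,expected_m", [
        (100, 0.25, 25),   # the benchmark setting
        (10, 1.0, 10),     # full-feature case
        (7, 0.1, 1),       # floor clamps to >= 1
        (50, 0.25, 12),
    ])
    def test_subset_size(self, rng, p, frac, expected_m):
        subset = sample_feature_subset(p, frac, rng)
        assert len(subset) == expected_m
        assert len(np.unique(subset)) == expected_m
        assert subset.min() >= 0 and subset.max() < p

    def test_invalid_fraction_raises(self, rng):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                sample_feature_subset(10, bad, rng)


class TestFitBaseGNB:
    def test_textbook_moments_and_priors(self):
        X = np.array([[1.0], [2.0], [3.0], [5.0], [5.0], [5.0], [7.0]])
        y = np.array(["A", "A", "A", "B", "B", "B", "B"])
        lrn = fit_base_gnb(X, y, np.array(["A", "B"]), [0], 1e-12)
        assert lrn.params.means[0, 0] == pytest.approx(2.0)
        assert lrn.params.variances[0, 0] == pytest.approx(1.0)  # ddof=1
        np.testing.assert_allclose(lrn.params.priors, [3 / 7, 4 / 7])

    def test_constant_feature_floored(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array(["A"] * 5 + ["B"] * 5)
        floor = 1e-9
        lrn = fit_base_gnb(X, y, np.array(["A", "B"]), [0, 1], floor)
        assert lrn.params.variances[0, 0] == floor
        scores = log_joint_scores(lrn, X)
        assert np.isfinite(scores).all()

    def test_singleton_class_uses_pooled_variance(self):
        X = np.array([[0.0], [2.0], [4.0], [10.0]])
        y = np.array(["A", "A", "A", "B"])
        with pytest.warns(RuntimeWarning, match="single member"):
            lrn = fit_base_gnb(X, y, np.array(["A", "B"]), [0], 1e-12)
        assert lrn.params.variances[1, 0] == pytest.approx(4.0)  # pooled = var(A)

    def test_missing_class_raises(self):
        X = np.zeros((3, 1))
        y = np.array(["A", "A", "A"])
        with pytest.raises(ValueError, match="no members"):
            fit_base_gnb(X, y, np.array(["A", "B"]), [0], 1e-12)


def _manual_learner(priors, means, variances, subset):
    return BaseLearner(
        params=GaussianClassParams(priors=np.asarray(priors, float),
                                   means=np.asarray(means, float),
                                   variances=np.asarray(variances, float)),
        feature_subset=np.asarray(subset, dtype=np.intp))


class TestLogJointScores:
    def test_standard_normal_at_mode(self):
        lrn = _manual_learner([1.0], [[0.0]], [[1.0]], [0])
        score = log_joint_scores(lrn, np.array([[0.0]]))
        assert score[0, 0] == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_identical_classes_give_identical_columns(self, rng):
        lrn = _manual_learner([0.5, 0.5], [[1.0, -1.0]] * 2, [[2.0, 0.5]] * 2,
                              [0, 2])
        X = rng.normal(size=(6, 3))
        s = log_joint_scores(lrn, X)
        np.testing.assert_allclose(s[:, 0], s[:, 1])

    def test_matches_bruteforce_normal_logpdf_sum(self, rng):
        # independent oracle: term-by-term scalar normal log-densities
        K, m, p = 3, 2, 5
        priors = np.array([0.2, 0.5, 0.3])
        means = rng.normal(size=(K, m))
        variances = rng.uniform(0.5, 2.0, size=(K, m))
        subset = np.array([1, 3])
        lrn = _manual_learner(priors, means, variances, subset)
        X = rng.normal(size=(5, p))
        expected = np.empty((5, K))
        for i in range(5):
            for k in range(K):
                expected[i, k] = np.log(priors[k]) + sum(
                    norm.logpdf(X[i, subset[j]], means[k, j],
                                np.sqrt(variances[k, j]))
                    for j in range(m))
        np.testing.assert_allclose(log_joint_scores(lrn, X), expected,
                                   rtol=1e-10, atol=1e-10)

    def test_nonfinite_query_identified(self):
        lrn = _manual_learner([1.0], [[0.0]], [[1.0]], [0])
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError, match="row 1, column 0"):
            log_joint_scores(lrn, X)


class TestNormalizeLogPosteriors:
    def test_symmetric_row(self):
        np.testing.assert_allclose(
            normalize_log_posteriors([[0.0, 0.0, 0.0]]), [[1 / 3] * 3])

    def test_log_odds_row(self):
        np.testing.assert_allclose(
            normalize_log_posteriors([[np.log(1.0), np.log(3.0)]]),
            [[0.25, 0.75]], atol=1e-15)

    def test_extreme_scores_no_underflow(self):
        # logistic of the score difference, computed exactly
        out = normalize_log_posteriors([[-10000.0, -10001.0]])
        sig1 = 1.0 / (1.0 + np.exp(-1.0))
        np.testing.assert_allclose(out, [[sig1, 1 - sig1]], rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scores=arrays(np.float64, (4, 3),
                         elements=st.floats(-700, 700)),
           shift=st.floats(-500, 500))
    def test_simplex_rows_and_shift_invariance(self, scores, shift):
        post = normalize_log_posteriors(scores)
        assert np.all(post >= 0) and np.all(post <= 1)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        shifted = normalize_log_posteriors(scores + shift)
        np.testing.assert_allclose(shifted, post, atol=1e-12)


class TestEnsemble:
    def test_degenerate_ensemble_equals_plain_gnb(self, small_dataset):
        """T=1, alpha=1, identity resample == direct Bayes-rule evaluation."""
        ds = small_dataset
        model = PAVGaussianNB(n_iter=1, feature_fraction=1.0, random_state=0,
                              bootstrap=False).fit(ds.X, ds.y)
        # independent oracle: per-class product of scalar normal pdfs
        classes = model.classes_
        dens = np.ones((ds.n, len(classes)))
        for k, c in enumerate(classes):
            rows = ds.X[ds.y == c]
            mu, var = rows.mean(axis=0), rows.var(axis=0, ddof=1)
            prior = rows.shape[0] / ds.n
            dens[:, k] = prior * norm.pdf(ds.X, mu, np.sqrt(var)).prod(axis=1)
        expected = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(model.predict_proba(ds.X), expected,
                                   atol=1e-10)

    def test_close_to_sklearn_gaussian_nb(self, small_dataset):
        """Cross-check against sklearn's GNB (ddof=0 variances -> approximate)."""
        ds = small_dataset
        ours = PAVGaussianNB(n_iter=1, feature_fraction=1.0, random_state=0,
                             bootstrap=False).fit(ds.X, ds.y)
        ref = GaussianNB().fit(ds.X, ds.y)
        # column order: ours is first-appearance, sklearn sorts labels
        order = np.searchsorted(ref.classes_, ours.classes_)
        np.testing.assert_allclose(ours.predict_proba(ds.X),
                                   ref.predict_proba(ds.X)[:, order],
                                   atol=2e-2)
        assert (ours.predict(ds.X) == ref.predict(ds.X)).mean() > 0.95

    def test_predict_proba_matches_loop_average_oracle(self, small_dataset):
        ds = small_dataset
        model = PAVGaussianNB(n_iter=5, feature_fraction=0.5,
                              random_state=3).fit(ds.X, ds.y)
        Xq = ds.X[:10]
        acc = np.zeros((10, 3))
        for lrn in model.learners_:
            acc += normalize_log_posteriors(log_joint_scores(lrn, Xq))
        np.testing.assert_allclose(model.predict_proba(Xq), acc / 5,
                                   atol=1e-12)

    def test_parallel_determinism(self, small_dataset, tmp_path):
        ds = small_dataset
        paths = []
        for jobs in (1, 2, 4):
            model = PAVGaussianNB(n_iter=8, feature_fraction=0.4, n_jobs=jobs,
                                  random_state=99).fit(ds.X, ds.y)
            path = tmp_path / f"model_{jobs}.json"
            save_model(model, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1] == paths[2]

    def test_subset_sizes_and_inclusion_counts(self):
        ds = generate_dataset(ScenarioSpec(n=300, p=50, K=3, spacing=2.0,
                                           rho=0.5, seed=11))
        model = PAVGaussianNB(n_iter=100, feature_fraction=0.25,
                              random_state=5).fit(ds.X, ds.y)
        sizes = {len(l.feature_subset) for l in model.learners_}
        assert sizes == {12}
        counts = np.bincount(
            np.concatenate([l.feature_subset for l in model.learners_]),
            minlength=50)
        assert counts.sum() == 1200          # mean inclusion = 24 exactly
        sd = np.sqrt(100 * 0.24 * 0.76)      # binomial sd per feature
        assert np.abs(counts - 24).max() < 5 * sd

    def test_priors_equal_training_proportions_under_stratification(
            self, small_dataset):
        ds = small_dataset
        model = PAVGaussianNB(n_iter=6, feature_fraction=0.5,
                              random_state=2).fit(ds.X, ds.y)
        expected = np.array([(ds.y == c).mean() for c in model.classes_])
        for lrn in model.learners_:
            np.testing.assert_allclose(lrn.params.priors, expected)

    def test_permutation_equivariance_of_scoring(self, small_dataset, rng):
        ds = small_dataset
        model = PAVGaussianNB(n_iter=4, feature_fraction=0.5,
                              random_state=8).fit(ds.X, ds.y)
        perm = rng.permutation(ds.p)
        inv = np.argsort(perm)
        base = model.predict_proba(ds.X)
        for lrn in model.learners_:       # remap subsets into permuted space
            lrn.feature_subset = inv[lrn.feature_subset]
        np.testing.assert_allclose(model.predict_proba(ds.X[:, perm]), base,
                                   atol=1e-12)

    def test_tie_breaks_to_first_class_in_vocabulary(self):
        model = PAVGaussianNB(n_iter=1)
        model.classes_ = np.array(["b_first", "a_second"])
        model.n_features_in_ = 1
        model.learners_ = [_manual_learner([0.5, 0.5], [[0.0], [0.0]],
                                           [[1.0], [1.0]], [0])]
        assert model.predict(np.array([[0.3]]))[0] == "b_first"

    def test_class_vocabulary_first_appearance_order(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array(["z", "a", "m"] * 10)
        model = PAVGaussianNB(n_iter=2, random_state=0).fit(X, y)
        assert model.classes_.tolist() == ["z", "a", "m"]

    def test_column_count_mismatch_raises(self, small_dataset):
        ds = small_dataset
        model = PAVGaussianNB(n_iter=2, random_state=0).fit(ds.X, ds.y)
        with pytest.raises(ValueError, match="columns"):
            model.predict(ds.X[:, :3])

    def test_monotone_accuracy_in_overlap(self):
        """Held-out accuracy is non-increasing in the overlap level."""
        from pavgnb.bench import Cell, ExperimentGrid, run_experiment, summarize
        grid = ExperimentGrid("mono", tuple(
            Cell(level=lv, n=300, p=20, K=3, n_iter=25, feature_fraction=0.25,
                 label=lv) for lv in ("none", "low", "moderate", "high")),
            replicates=10, base_seed=4)
        means = summarize(run_experiment(grid))["accuracy_mean"].to_numpy()
        assert np.all(np.diff(means) <= 1e-12)

    def test_sklearn_param_interface(self):
        model = PAVGaussianNB(n_iter=7)
        assert model.get_params()["n_iter"] == 7
        model.set_params(feature_fraction=0.3)
        assert model.feature_fraction == 0.3
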