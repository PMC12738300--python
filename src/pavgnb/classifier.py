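"""Posterior-averaging Gaussian naive Bayes (PAV-GNB) ensemble classifier.

Each of T base learners is a plain Gaussian naive Bayes model fitted on a
class-stratified bootstrap of the training rows and a uniformly random subset
of ``m = floor(feature_fraction * p)`` feature columns.  At prediction time
every learner produces a posterior matrix via log-sum-exp-normalized
log-joint scores, and the ensemble posterior is the arithmetic mean of the
member posteriors; the predicted label is its row-wise argmax.

Averaging posteriors (soft voting) rather than majority-voting hard labels
keeps the aggregate a proper probability simplex point and reduces the
variance of the posterior estimate by roughly 1/T when members are weakly
correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import class_vocabulary_of

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianClassParams:
    """Per-class priors and per-(class, feature) Gaussian moments of one learner.

    ``means`` and ``variances`` have shape (K, m) where m is the size of the
    learner's feature subset; ``variances`` are floored to stay strictly
    positive so log-densities remain finite.
    """

    priors: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("class priors must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be strictly positive after flooring")


@dataclass
class BaseLearner:
    """Gaussian parameters bound to the original-space feature columns they use."""

    params: GaussianClassParams
    feature_subset: np.ndarray
    iteration_index: int = 0


def stratified_bootstrap(labels, class_order, rng) -> np.ndarray:
    """Bootstrap row indices with replacement *within* each class.

    Per-class counts in the output equal the original per-class counts
    exactly, so class proportions are preserved by construction.  The output
    is grouped by ``class_order`` (deterministic given the rng state).
    """
    labels = np.asarray(labels)
    parts = []
    for c in class_order:
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"class {c!r} has no members; cannot stratify")
        parts.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(parts)


def sample_feature_subset(p: int, feature_fraction: float, rng) -> np.ndarray:
    """Draw m = min(max(floor(feature_fraction*p), 1), p) distinct column indices."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 < feature_fraction <= 1.0:
        raise ValueError("feature_fraction must be in (0, 1]")
    m = min(max(int(np.floor(feature_fraction * p)), 1), p)
    return rng.choice(p, size=m, replace=False)


def fit_base_gnb(X, labels, class_order, feature_subset, variance_floor,
                 iteration_index: int = 0) -> BaseLearner:
    """Fit one Gaussian naive Bayes learner on the given rows/columns.

    Means are per-class sample means; variances use the unbiased n_k - 1
    denominator and are floored at ``variance_floor``.  Priors are the class
    proportions of the rows passed in (under exact stratification these equal
    the original training proportions).  A class reduced to a single row gets
    the pooled within-class variance as a fallback.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    feature_subset = np.asarray(feature_subset, dtype=np.intp)
    K, m = len(class_order), feature_subset.size
    n = X.shape[0]

    means = np.empty((K, m))
    variances = np.empty((K, m))
    counts = np.empty(K, dtype=np.intp)
    singleton = []
    for k, c in enumerate(class_order):
        rows = np.flatnonzero(labels == c)
        counts[k] = rows.size
        if rows.size == 0:
            raise ValueError(f"class {c!r} has no members in the sample")
        block = X[np.ix_(rows, feature_subset)]
        means[k] = block.mean(axis=0)
        if rows.size >= 2:
            variances[k] = block.var(axis=0, ddof=1)
        else:
            singleton.append(k)
    if singleton:
        dof = np.maximum(counts - 1, 0)
        ok = dof > 0
        if ok.any():
            pooled = (variances[ok] * dof[ok, None]).sum(axis=0) / dof[ok].sum()
        else:
            pooled = np.zeros(m)
        for k in singleton:
            variances[k] = pooled
        warnings.warn(
            f"classes {[class_order[k] for k in singleton]} have a single member; "
            "using pooled within-class variances", RuntimeWarning)

    np.maximum(variances, variance_floor, out=variances)
    params = GaussianClassParams(priors=counts / n, means=means, variances=variances)
    return BaseLearner(params=params, feature_subset=feature_subset,
                       iteration_index=iteration_index)


def log_joint_scores(learner: BaseLearner, X) -> np.ndarray:
    """Unnormalized log-posterior scores of one learner on original-space queries.

    Entry (i, k) is ``log pi_k + sum_{j in F} [-0.5 log(2 pi s2_kj)
    - (x_ij - mu_kj)^2 / (2 s2_kj)]``, evaluated over the learner's own
    feature subset F.  Implemented as two (n, m) @ (m, K) products by
    expanding the quadratic.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite query value at row {i}, column {j}")
    p = learner.params
    Xs = X[:, learner.feature_subset]
    inv2v = 0.5 / p.variances                       # (K, m)
    const = (np.log(p.priors)
             - 0.5 * (_LOG_2PI + np.log(p.variances)).sum(axis=1)
             - (p.means ** 2 * inv2v).sum(axis=1))  # (K,)
    return const + Xs @ (2.0 * p.means * inv2v).T - (Xs ** 2) @ inv2v.T


def normalize_log_posteriors(log_scores) -> np.ndarray:
    """Row-wise softmax via the log-sum-exp trick.

    Subtracting the per-row maximum before exponentiating avoids underflow,
    so rows sum to 1 even for scores around -1e4; the result is invariant to
    adding any constant to a row.
    """
    log_scores = np.asarray(log_scores, dtype=float)
    return np.exp(log_scores - logsumexp(log_scores, axis=1, keepdims=True))


def _fit_one(X, y, class_order, feature_fraction, variance_floor, base_seed, t,
             bootstrap):
    """Fit learner t; its randomness depends only on (base_seed, t).

    Equivalent to ``fit_base_gnb`` on the materialized bootstrap rows, but
    computes the class moments through bootstrap multiplicity weights so the
    (n, p) matrix is never copied per learner — only the m selected columns.
    """
    rng = np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(t,)))
    n = len(y)
    if bootstrap:
        idx = stratified_bootstrap(y, class_order, rng)
        weights = np.bincount(idx, minlength=n).astype(float)
    else:
        weights = np.ones(n)
    subset = sample_feature_subset(X.shape[1], feature_fraction, rng)
    try:
        return _fit_weighted_gnb(X, y, class_order, subset, weights,
                                 variance_floor, iteration_index=t)
    except ValueError as exc:  # tag with the iteration that failed
        raise ValueError(f"iteration {t}: {exc}") from exc


def _fit_weighted_gnb(X, y, class_order, feature_subset, weights,
                      variance_floor, iteration_index=0) -> BaseLearner:
    """Gaussian moments under per-row multiplicity weights (fast fit path).

    Identical (up to float summation order) to fitting on rows repeated
    ``weights`` times.  Columns are centered before the second-moment pass so
    the E[x^2] - mu^2 form cannot cancel catastrophically.
    """
    feature_subset = np.asarray(feature_subset, dtype=np.intp)
    K, m = len(class_order), feature_subset.size
    Xs = X[:, feature_subset]      # always a fresh copy (fancy index)
    shift = Xs.mean(axis=0)
    Xs -= shift

    means = np.empty((K, m))
    variances = np.empty((K, m))
    counts = np.empty(K)
    singleton = []
    for k, c in enumerate(class_order):
        w = np.where(y == c, weights, 0.0)
        nk = w.sum()
        counts[k] = nk
        if nk == 0:
            raise ValueError(f"class {c!r} has no members in the sample")
        mu = (w @ Xs) / nk
        means[k] = mu
        if nk >= 2:
            m2 = np.einsum("i,ij,ij->j", w, Xs, Xs)
            variances[k] = (m2 - nk * mu ** 2) / (nk - 1.0)
        else:
            singleton.append(k)
    if singleton:
        dof = np.maximum(counts - 1, 0)
        ok = dof > 0
        pooled = ((variances[ok] * dof[ok, None]).sum(axis=0) / dof[ok].sum()
                  if ok.any() else np.zeros(m))
        for k in singleton:
            variances[k] = pooled
        warnings.warn(
            f"classes {[class_order[k] for k in singleton]} have a single member; "
            "using pooled within-class variances", RuntimeWarning)
    means += shift
    np.maximum(variances, variance_floor, out=variances)
    params = GaussianClassParams(priors=counts / counts.sum(), means=means,
                                 variances=variances)
    return BaseLearner(params=params, feature_subset=feature_subset,
                       iteration_index=iteration_index)


class PAVGaussianNB(ClassifierMixin, BaseEstimator):
    """Posterior-averaging Gaussian naive Bayes ensemble.

    Parameters
    ----------
    n_iter : int, default=100
        Number of ensemble members T (bootstrap iterations).
    feature_fraction : float, default=0.5
        Fraction alpha of feature columns each member sees; the subset size is
        ``min(max(floor(alpha * p), 1), p)``.
    n_jobs : int, default=1
        Workers used to fit members in parallel.  An execution hint only:
        results are bit-identical for any value because each member's
        randomness is keyed by ``(base_seed, t)``.
    random_state : int or None, default=None
        Base seed of the per-member random substreams.
    var_smoothing : float, default=1e-9
        Relative variance floor; per-feature class variances are floored at
        ``var_smoothing * (mean global feature variance + 1)`` so constant
        features keep finite log-densities.
    bootstrap : bool, default=True
        If False, members are fitted on the identity resample (all rows);
        useful for reducing the T=1, alpha=1 ensemble to plain GNB.

    Attributes
    ----------
    classes_ : ndarray of shape (K,)
        Class labels in order of first appearance in ``y``.  Posterior
        columns and argmax tie-breaking (lowest index wins) follow this
        order.
    learners_ : list of BaseLearner, length ``n_iter``.
    variance_floor_ : float
        The absolute floor applied to all member variances.
    base_seed_ : int
        The resolved base seed.
    n_features_in_ : int
    """

    def __init__(self, n_iter: int = 100, feature_fraction: float = 0.5,
                 n_jobs: int = 1, random_state=None,
                 var_smoothing: float = 1e-9, bootstrap: bool = True):
        self.n_iter = n_iter
        self.feature_fraction = feature_fraction
        self.n_jobs = n_jobs
        self.random_state = random_state
        self.var_smoothing = var_smoothing
        self.bootstrap = bootstrap

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must be in (0, 1]")
        self.classes_ = class_vocabulary_of(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least two classes")
        self.n_features_in_ = X.shape[1]
        self.variance_floor_ = self.var_smoothing * (X.var(axis=0).mean() + 1.0)
        if self.random_state is None:
            self.base_seed_ = int(np.random.SeedSequence().generate_state(1)[0])
        else:
            self.base_seed_ = int(self.random_state)
        # Column-major layout makes each member's column-subset gather a
        # contiguous copy; worthwhile from ~1e6 elements up.
        if X.size > 1_000_000:
            X = np.asfortranarray(X)
        # Members are independent given (base_seed, t): any execution order
        # and any n_jobs yield the identical ensemble.
        self.learners_ = Parallel(n_jobs=self.n_jobs)(
            delayed(_fit_one)(X, y, self.classes_, self.feature_fraction,
                              self.variance_floor_, self.base_seed_, t,
                              self.bootstrap)
            for t in range(self.n_iter))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Ensemble posterior: the mean of the member posterior matrices."""
        check_is_fitted(self, "learners_")
        X = check_array(X, dtype=float, ensure_all_finite=False)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.n_features_in_}")
        if X.size > 1_000_000:
            X = np.asfortranarray(X)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for learner in self.learners_:
            proba += normalize_log_posteriors(log_joint_scores(learner, X))
        proba /= len(self.learners_)
        return proba

    def predict(self, X) -> np.ndarray:
        """Argmax of the averaged posterior; ties break to the lowest class index."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
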