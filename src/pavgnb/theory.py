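"""Variance and margin-bound calculators for posterior-averaging ensembles.

For T ensemble members whose class posteriors at a fixed query x share a
marginal variance sigma^2(x) and an average pairwise correlation rho(x),
the averaged posterior has

    Var[P_bar_T] = sigma^2 (1 + rho (T - 1)) / T,

which interpolates between sigma^2 / T (rho = 0) and sigma^2 (rho = 1) and
tends to rho sigma^2 as T grows — the irreducible correlated component.

If additionally the member posterior of the true class is unbiased up to
b(x) (E[P_t(Y|x)] = p*(Y|x) + b(x)) and the Bayes margin
gamma(x) = p*(Y|x) - max_{k != Y} p*(C_k|x) is positive, a Cantelli-type
argument bounds the misclassification probability of the averaged argmax:

    Pr[pred != Y | x] <= Var[P_bar_T] / [gamma/2 - |b|]_+^2,

reported as +inf when the denominator collapses.  The Monte-Carlo harnesses
below verify both results by simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import PAVGaussianNB, log_joint_scores, normalize_log_posteriors
from .synthdata import ScenarioSpec, generate_dataset


def _check_variance_inputs(sigma2: float, rho: float, n_members: int) -> None:
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    lower = -1.0 / (n_members - 1) if n_members > 1 else -1.0
    if not lower <= rho <= 1.0:
        raise ValueError(
            f"rho must lie in [{lower:.4g}, 1] for a {n_members}-member ensemble")


def ensemble_posterior_variance(sigma2: float, rho: float, n_members: int) -> float:
    """Variance of the mean of equicorrelated members: sigma2 (1 + rho(T-1)) / T."""
    _check_variance_inputs(sigma2, rho, n_members)
    return sigma2 * (1.0 + rho * (n_members - 1)) / n_members


def margin_error_bound(sigma2: float, rho: float, n_members: int,
                       gamma: float, bias: float = 0.0) -> float:
    """Misclassification bound Var[P_bar_T] / [gamma/2 - |bias|]_+^2.

    Returns ``numpy.inf`` (the unbounded sentinel) when ``gamma/2 <= |bias|``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0 (positive Bayes margin assumed)")
    denom = max(gamma / 2.0 - abs(bias), 0.0)
    if denom == 0.0:
        return float(np.inf)
    return ensemble_posterior_variance(sigma2, rho, n_members) / denom ** 2


def simulate_equicorrelated_members(sigma2: float, rho: float, n_members: int,
                                    n_draws: int, rng) -> float:
    """Empirical Var[mean] of T equicorrelated variables (single-common-factor).

    Each draw is ``sqrt(sigma2) * (sqrt(rho) Z0 + sqrt(1 - rho) Z_t)`` with
    independent standard normals, which has marginal variance ``sigma2`` and
    pairwise correlation ``rho`` — the only moments the variance identity
    depends on.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1] for the common-factor construction")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a usable estimate")
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, n_members))
    members = np.sqrt(sigma2) * (np.sqrt(rho) * z0[:, None] + np.sqrt(1.0 - rho) * z)
    return float(members.mean(axis=1).var(ddof=1))


def true_posterior(X, means, cov) -> np.ndarray:
    """Exact class posteriors under the generating Gaussian model.

    ``p*(C_k | x) ∝ pi_k exp(-0.5 (x - mu_k)^T Sigma^{-1} (x - mu_k))`` with
    uniform priors; evaluated with the closed-form equicorrelation inverse.
    """
    X = np.asarray(X, dtype=float)
    means = np.asarray(means, dtype=float)
    shrink = cov.rho / (1.0 + cov.rho * (cov.p - 1))
    log_post = np.empty((X.shape[0], means.shape[0]))
    for k, mu in enumerate(means):
        delta = X - mu
        quad = ((delta ** 2).sum(axis=1) - shrink * delta.sum(axis=1) ** 2)
        log_post[:, k] = -0.5 * quad / (1.0 - cov.rho)
    return normalize_log_posteriors(log_post)


def empirical_bound_check(spec: ScenarioSpec, n_iter: int = 50,
                          feature_fraction: float = 0.25, n_fits: int = 20,
                          n_eval: int = 200, base_seed: int = 0) -> dict:
    """Verify the margin bound pointwise on a scenario.

    Fits ``n_fits`` ensembles on independent training draws, estimates per
    evaluation point the member-posterior variance sigma^2(x), the average
    pairwise member correlation rho(x) (Pearson, true-class posteriors,
    estimated across fits) and the bias b(x) against the exact posterior,
    evaluates the bound, and compares it with the empirical misclassification
    frequency of the averaged prediction.

    Returns a dict with the per-point table (``points``) and summary
    fractions; ``fraction_within_bound`` is the share of evaluable points
    (positive margin, finite bound) where the empirical error does not exceed
    the bound.
    """
    ss = np.random.SeedSequence(base_seed, spawn_key=(0,))
    eval_seed, *fit_seeds = [int(s) for s in ss.generate_state(n_fits + 1)]

    eval_ds = generate_dataset(spec.with_seed(eval_seed % 2 ** 31))
    Xe, ye = eval_ds.X[:n_eval], eval_ds.y[:n_eval]
    cov = spec.covariance()
    post_star = true_posterior(Xe, spec.class_means(), cov)
    p_true = post_star[np.arange(len(ye)), ye]
    rival = post_star.copy()
    rival[np.arange(len(ye)), ye] = -np.inf
    gamma = p_true - rival.max(axis=1)

    member_post = np.empty((n_fits, n_iter, len(ye)))  # true-class posteriors
    errors = np.empty((n_fits, len(ye)), dtype=bool)
    for r, seed in enumerate(fit_seeds):
        train = generate_dataset(spec.with_seed(seed % 2 ** 31))
        model = PAVGaussianNB(n_iter=n_iter, feature_fraction=feature_fraction,
                              random_state=seed % 2 ** 31).fit(train.X, train.y)
        avg = np.zeros((len(ye), len(model.classes_)))
        class_col = {c: j for j, c in enumerate(model.classes_)}
        cols = np.array([class_col[c] for c in ye])
        for t, learner in enumerate(model.learners_):
            post = normalize_log_posteriors(log_joint_scores(learner, Xe))
            member_post[r, t] = post[np.arange(len(ye)), cols]
            avg += post
        errors[r] = model.classes_[np.argmax(avg, axis=1)] != ye

    sigma2 = member_post.reshape(-1, len(ye)).var(axis=0, ddof=1)
    bias = member_post.reshape(-1, len(ye)).mean(axis=0) - p_true
    rho_hat = np.empty(len(ye))
    for i in range(len(ye)):
        M = member_post[:, :, i]                      # (n_fits, n_iter)
        sd = M.std(axis=0)
        keep = sd > 1e-12
        if keep.sum() < 2:
            rho_hat[i] = 0.0                          # degenerate: sigma2 ~ 0 anyway
            continue
        C = np.corrcoef(M[:, keep].T)
        rho_hat[i] = (C.sum() - np.trace(C)) / (C.shape[0] * (C.shape[0] - 1))
    rho_hat = np.clip(rho_hat, -1.0 / max(n_iter - 1, 1), 1.0)

    bound = np.full(len(ye), np.inf)
    valid = gamma > 0
    for i in np.flatnonzero(valid):
        bound[i] = margin_error_bound(sigma2[i], rho_hat[i], n_iter,
                                      gamma[i], bias[i])
    err_rate = errors.mean(axis=0)

    points = pd.DataFrame({
        "gamma": gamma, "sigma2": sigma2, "rho": rho_hat, "bias": bias,
        "bound": bound, "empirical_error": err_rate, "margin_positive": valid,
    })
    evaluable = valid & np.isfinite(bound)
    within = err_rate[evaluable] <= bound[evaluable] + 1e-12
    return {
        "points": points,
        "n_evaluable": int(evaluable.sum()),
        "fraction_within_bound": float(within.mean()) if evaluable.any() else np.nan,
        "mean_bound": float(np.minimum(bound[evaluable], 1.0).mean())
        if evaluable.any() else np.nan,
        "mean_empirical_error": float(err_rate.mean()),
    }
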