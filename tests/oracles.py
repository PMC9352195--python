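"""Independent reference computations used to validate the package.

These deliberately avoid the code paths they check: the change-point
oracle integrates the model exhaustively instead of sampling; the
Fisher discriminant oracle derives the two-class boundary in closed
form; the censored-duration oracle is plain Monte Carlo on the stated
distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def changepoint_split_posterior(z: np.ndarray, n_sigma: int = 400) -> np.ndarray:
    """Exhaustive posterior over the discrete split index k (first k bins
    in state 1) for the single-change-point model.

    mu1, mu2 are integrated analytically (normal-normal); sigma is
    integrated on a grid against the HalfCauchy(1) prior.  The continuous
    tau prior contributes interval lengths (half cells at the ends).
    Returns probabilities over k = 0..n.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    sig = np.linspace(1e-3, 10.0, n_sigma)
    log_prior_sig = -np.log1p(sig**2)  # half-Cauchy(1) up to a constant
    S1 = np.concatenate([[0.0], np.cumsum(z)])
    S2 = np.concatenate([[0.0], np.cumsum(z**2)])

    def seg_logml(s1: float, s2: float, m: int, s: np.ndarray) -> np.ndarray:
        # marginal of m iid N(mu, s^2) observations with mu ~ N(0, 1)
        if m == 0:
            return np.zeros_like(s)
        v = s**2
        return (
            -0.5 * m * np.log(2 * np.pi * v)
            - 0.5 * np.log1p(m / v)
            - 0.5 * (s2 / v - (s1 / v) ** 2 / (1 + m / v))
        )

    logp = np.empty(n + 1)
    dsig = np.gradient(sig)
    for k in range(n + 1):
        lml = (
            seg_logml(S1[k], S2[k], k, sig)
            + seg_logml(S1[n] - S1[k], S2[n] - S2[k], n - k, sig)
            + log_prior_sig
        )
        length = 0.5 if k in (0, n) else 1.0
        logp[k] = logsumexp(lml, b=dsig) + np.log(length)
    return np.exp(logp - logsumexp(logp))


def mcmc_split_probs(tau_samples: np.ndarray, n: int) -> np.ndarray:
    """Bin tau draws into the split intervals (k - 0.5, k + 0.5]."""
    edges = np.concatenate([[0.0], np.arange(0.5, n, 1.0), [float(n)]])
    h, _ = np.histogram(np.ravel(tau_samples), bins=edges)
    return h / h.sum()


def fisher_two_class_predictions(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Closed-form Fisher discriminant for two classes, equal priors.

    w = S_pooled^-1 (mu_1 - mu_0); classify by the sign of
    w.(x - (mu_0 + mu_1)/2).  Returns predicted labels.
    """
    labels = np.unique(y_train)
    assert labels.size == 2
    mu = {l: X_train[y_train == l].mean(axis=0) for l in labels}
    pooled = sum(
        np.cov(X_train[y_train == l].T, bias=False) * ((y_train == l).sum() - 1)
        for l in labels
    ) / (len(y_train) - 2)
    w = np.linalg.solve(pooled, mu[labels[1]] - mu[labels[0]])
    mid = 0.5 * (mu[labels[0]] + mu[labels[1]])
    score = (X_test - mid) @ w
    return np.where(score > 0, labels[1], labels[0])


def censored_scaled_duration_ratio(
    mean_duration: float,
    drop: float,
    sigma: float = 0.4,
    n_mc: int = 200_000,
    seed: int = 123,
) -> float:
    """Expected (post-onset mean) / (pre-onset mean) rearing duration when
    durations are lognormal, scaled by (1 - drop) after onset, and events
    under the 0.5 s scoring threshold are censored."""
    rng = np.random.default_rng(seed)
    mu = np.log(mean_duration) - sigma**2 / 2.0
    d = rng.lognormal(mu, sigma, n_mc)
    pre = d[d >= 0.5]
    post = d * (1.0 - drop)
    post = post[post >= 0.5]
    return float(post.mean() / pre.mean())


def permutation_mean_abs_spearman(
    trial_ranks: np.ndarray, n_perm: int = 4000, seed: int = 0
) -> float:
    """Null expectation of |Spearman rho| between an arbitrary continuous
    rate vector and the (tied) palatability ranks, by permutation."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    x = rng.normal(size=trial_ranks.size)
    vals = np.empty(n_perm)
    for i in range(n_perm):
        vals[i] = abs(stats.spearmanr(rng.permutation(x), trial_ranks).statistic)
    return float(vals.mean())
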