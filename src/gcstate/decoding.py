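"""Ensemble taste decoding with linear discriminant analysis.

Taste discriminability is the leave-one-out accuracy of an LDA
classifier decoding the delivered taste from the ensemble firing-rate
vector in each 250 ms bin; chance is 25% for the 4-taste set.  Epoch
summaries collapse bins into the early / middle (identity, 400-700 ms) /
late (palatability, 800-1100 ms) response epochs.  A within-session
protocol trains on the first 5 trials per taste and tracks accuracy over
later 5-trial blocks, which localizes when discriminability degrades as
sickness sets in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .datatypes import TASTES, EnsembleRecording, EpochDefinition
from .taste_response import classify_responsiveness

logger = logging.getLogger(__name__)

CHANCE = 1.0 / len(TASTES)


def _make_lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    """Plain LDA, switching to shrinkage when the pooled covariance is
    ill-conditioned (few trials relative to ensemble size)."""
    n_per_class = min(np.bincount(pd.factorize(y)[0]))
    pooled = sum(
        np.cov(X[y == t].T) * max((y == t).sum() - 1, 1) for t in np.unique(y)
    ) / max(len(y) - len(np.unique(y)), 1)
    cond = np.linalg.cond(np.atleast_2d(pooled))
    if X.shape[1] >= n_per_class * (len(np.unique(y)) - 1) or cond > 1e8:
        logger.info("ill-conditioned within-class covariance; using shrinkage LDA")
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    return LinearDiscriminantAnalysis(solver="svd")


def _loo_lda_predict(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact leave-one-out LDA predictions via downdating.

    Removing sample i of class k changes only that class mean and the
    pooled within-class scatter (rank-one downdate), so each held-out
    prediction needs one small solve instead of a full refit.  Matches
    sklearn's plain (svd) LDA decision rule with empirical priors.
    """
    classes, yi = np.unique(y, return_inverse=True)
    n, d = X.shape
    k_n = np.bincount(yi).astype(float)
    sums = np.zeros((len(classes), d))
    np.add.at(sums, yi, X)
    means = sums / k_n[:, None]
    centered = X - means[yi]
    S_w = centered.T @ centered
    pred = np.empty(n, dtype=yi.dtype)
    for i in range(n):
        k = yi[i]
        dev = X[i] - means[k]
        S_i = S_w - (k_n[k] / (k_n[k] - 1.0)) * np.outer(dev, dev)
        mu = means.copy()
        mu[k] = (sums[k] - X[i]) / (k_n[k] - 1.0)
        nk = k_n.copy()
        nk[k] -= 1.0
        cov = S_i / (n - 1 - len(classes))
        try:
            W = np.linalg.solve(cov, mu.T)  # (d, K)
        except np.linalg.LinAlgError:
            W = np.linalg.lstsq(cov, mu.T, rcond=None)[0]
        scores = X[i] @ W - 0.5 * np.einsum("kd,dk->k", mu, W) + np.log(nk / (n - 1))
        pred[i] = np.argmax(scores)
    return classes[pred]


def _rebin(rec: EnsembleRecording, bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Counts re-binned to ``bin_ms``; returns (counts, bin start times)."""
    factor = bin_ms / rec.bin_ms
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("bin_ms must be a multiple of the recording bin width")
    factor = int(round(factor))
    n_bins = rec.n_bins // factor
    counts = rec.counts[:, :, : n_bins * factor].reshape(
        rec.n_neurons, rec.n_trials, n_bins, factor
    ).sum(axis=3)
    starts = rec.bin_starts_ms()[: n_bins * factor : factor]
    return counts, starts


def _epoch_of_bins(
    starts: np.ndarray, bin_ms: float, epochs: EpochDefinition
) -> dict[str, np.ndarray]:
    """Assign each bin to the epoch it overlaps most (ties to the earlier
    epoch); bins with no overlap belong to no epoch."""
    out: dict[str, list[int]] = {name: [] for name, _ in epochs.items()}
    for j, s in enumerate(starts):
        e = s + bin_ms
        best, best_ov = None, 0.0
        for name, (lo, hi) in epochs.items():
            ov = max(0.0, min(e, hi) - max(s, lo))
            if ov > best_ov:
                best, best_ov = name, ov
        if best is not None:
            out[best].append(j)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


@dataclass
class DecodingResult:
    bin_starts_ms: np.ndarray
    accuracy: np.ndarray  # per bin
    correct: np.ndarray  # (trials, bins) 0/1
    epoch_correct: dict[str, np.ndarray]  # per-trial fraction correct per epoch
    n_trials: int
    n_neurons: int
    bin_ms: float = 250.0

    @property
    def epoch_means(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.epoch_correct.items()}


def lda_loo_accuracy(
    rec: EnsembleRecording,
    bin_ms: float = 250.0,
    epochs: EpochDefinition = EpochDefinition(),
    t_range_ms: tuple[float, float] | None = None,
) -> DecodingResult:
    """Leave-one-out LDA accuracy per ``bin_ms`` time bin.

    ``t_range_ms`` restricts decoding to bins starting inside the given
    window (default: the whole recording).
    """
    for taste in np.unique(rec.tastes):
        if (rec.tastes == taste).sum() < 2:
            raise ValueError("need at least 2 trials per taste for leave-one-out")
    counts, starts = _rebin(rec, bin_ms)
    if t_range_ms is not None:
        keep = (starts >= t_range_ms[0]) & (starts < t_range_ms[1])
        counts, starts = counts[:, :, keep], starts[keep]
    y = rec.tastes
    n_bins = counts.shape[2]
    correct = np.zeros((rec.n_trials, n_bins))
    for j in range(n_bins):
        X = counts[:, :, j].T.astype(float)  # trials x neurons
        clf = _make_lda(X, y)
        if clf.solver == "svd":
            pred = _loo_lda_predict(X, y)  # closed-form LOO, same rule
        else:
            pred = cross_val_predict(clf, X, y, cv=LeaveOneOut())
        correct[:, j] = pred == y
    bin_epochs = _epoch_of_bins(starts, bin_ms, epochs)
    epoch_correct = {
        name: correct[:, idx].mean(axis=1)
        for name, idx in bin_epochs.items()
        if idx.size
    }
    return DecodingResult(
        bin_starts_ms=starts,
        accuracy=correct.mean(axis=0),
        correct=correct,
        epoch_correct=epoch_correct,
        n_trials=rec.n_trials,
        n_neurons=rec.n_neurons,
        bin_ms=bin_ms,
    )


def epoch_condition_test(
    saline: list[DecodingResult],
    licl: list[DecodingResult],
    method: str = "mannwhitney",
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-epoch condition comparison of decoding accuracy, Bonferroni
    corrected over epochs.

    ``method='mannwhitney'`` is unpaired; ``method='paired_t'`` pairs
    sessions.  With multiple sessions per condition the exchangeable
    unit is the session (per-session mean correctness): per-trial
    correctness within an ensemble shares the ensemble's random tuning,
    so trial-level ranking across several sessions would overstate the
    effective sample size.  With a single session per condition the
    trial is the only unit available and is used as such.
    """
    epochs = saline[0].epoch_correct.keys()
    n_epochs = len(epochs)
    session_level = len(saline) > 1 or len(licl) > 1
    out = {}
    for name in epochs:
        if session_level:
            a = np.array([r.epoch_correct[name].mean() for r in saline])
            b = np.array([r.epoch_correct[name].mean() for r in licl])
        else:
            a = np.concatenate([r.epoch_correct[name] for r in saline])
            b = np.concatenate([r.epoch_correct[name] for r in licl])
        if method == "mannwhitney":
            if np.ptp(np.concatenate([a, b])) == 0:
                stat, p = np.nan, 1.0
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
        elif method == "paired_t":
            a_s = np.array([r.epoch_correct[name].mean() for r in saline])
            b_s = np.array([r.epoch_correct[name].mean() for r in licl])
            res = stats.ttest_rel(a_s, b_s)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        p_corr = min(1.0, p * n_epochs)
        out[name] = {
            "saline_mean": float(a.mean()),
            "licl_mean": float(b.mean()),
            "stat": stat,
            "p_corrected": p_corr,
            "significant": p_corr < alpha,
        }
    return out


@dataclass
class BlockAccuracy:
    block_accuracy: np.ndarray  # mean accuracy per 5-trial block
    per_trial_correct: pd.DataFrame = field(repr=False)  # taste, block, correct
    n_neurons: int = 0


def within_session_block_accuracy(
    rec: EnsembleRecording,
    train_trials: int = 5,
    block_trials: int = 5,
    window_ms: tuple[float, float] = (200.0, 1200.0),
    responsive_only: bool = True,
    n_iterations: int = 10,
    seed: int = 0,
) -> BlockAccuracy:
    """Accuracy of an LDA trained on the first ``train_trials`` trials per
    taste, evaluated on later trials grouped into ``block_trials`` blocks.

    Training and test trials are disjoint by construction.  Predictions
    are averaged over ``n_iterations`` refits that break decision-score
    ties at random (discrete spike counts make exact ties possible).
    """
    if responsive_only:
        classes = classify_responsiveness(rec)
        keep = [i for i, c in enumerate(classes) if c.responsive]
        if not keep:
            raise ValueError("no taste-responsive neurons in the ensemble")
    else:
        keep = list(range(rec.n_neurons))
    rates = rec.window_rates(*window_ms)[keep]  # (neurons, trials)

    train_idx, test_rows = [], []
    for taste in TASTES:
        t_idx = np.flatnonzero(rec.tastes == taste)
        if t_idx.size < train_trials + block_trials:
            raise ValueError(
                f"taste {taste} has {t_idx.size} trials; need >= "
                f"{train_trials + block_trials}"
            )
        train_idx.extend(t_idx[:train_trials])
        for pos, trial in enumerate(t_idx[train_trials:]):
            test_rows.append((trial, taste, pos // block_trials))
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray([r[0] for r in test_rows])

    X_train, y_train = rates[:, train_idx].T, rec.tastes[train_idx]
    X_test, y_test = rates[:, test_idx].T, rec.tastes[test_idx]
    rng = np.random.default_rng(seed)
    correct = np.zeros(len(test_idx))
    clf = _make_lda(X_train, y_train)
    for _ in range(n_iterations):
        clf.fit(X_train, y_train)
        scores = clf.decision_function(X_test)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        scores = scores + rng.uniform(0, 1e-9, scores.shape)  # random tie-breaks
        pred = clf.classes_[np.argmax(scores, axis=1)]
        correct += pred == y_test
    correct /= n_iterations

    df = pd.DataFrame(
        {
            "taste": [r[1] for r in test_rows],
            "block": [r[2] for r in test_rows],
            "correct": correct,
        }
    )
    block_acc = df.groupby("block")["correct"].mean().to_numpy()
    return BlockAccuracy(
        block_accuracy=block_acc, per_trial_correct=df, n_neurons=len(keep)
    )


def block_rm_anova(block_traces: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Repeated-measures ANOVA across blocks over sessions, on per-session
    min-max-normalized block accuracies, with Bonferroni paired t
    follow-ups of each block against block 1."""
    rows = []
    for s, trace in enumerate(block_traces):
        rng = trace.max() - trace.min()
        norm = (trace - trace.min()) / rng if rng > 0 else np.zeros_like(trace)
        for b, v in enumerate(norm):
            rows.append((s, b, v))
    df = pd.DataFrame(rows, columns=["session", "block", "acc"])
    aov = pg.rm_anova(data=df, dv="acc", within="block", subject="session")
    row = aov.iloc[0]
    n_blocks = df["block"].nunique()
    followups = {}
    first = df.loc[df["block"] == 0].sort_values("session")["acc"].to_numpy()
    for b in range(1, n_blocks):
        other = df.loc[df["block"] == b].sort_values("session")["acc"].to_numpy()
        t, p = stats.ttest_rel(other, first)
        followups[b] = {"t": float(t), "p_corrected": min(1.0, float(p) * (n_blocks - 1))}
    return {
        "F": float(row["F"]),
        "df1": float(row["ddof1"]),
        "df2": float(row["ddof2"]),
        "p": float(row["p_unc"]),
        "significant": bool(row["p_unc"] < alpha),
        "followups_vs_block1": followups,
    }
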