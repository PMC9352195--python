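"""Sickness-onset quantification from rearing-event streams.

Rearing (both forepaws off the floor for >0.5 s) is a healthy
exploratory behavior whose durations collapse as malaise sets in.  The
stages here are: total rearing seconds per time bin (events split
proportionally across bin boundaries), the normalized licl-saline
difference trace across cohorts, per-quartile rank tests, and a
4-parameter logistic fit whose transition localizes the onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import BehaviorSession

logger = logging.getLogger(__name__)


def durations_per_bin(session: BehaviorSession, bin_min: float = 1.0) -> np.ndarray:
    """Total rearing seconds per ``bin_min``-minute bin.

    Events spanning a bin boundary contribute proportionally to each bin
    they overlap, so the trace sums exactly to the total event duration.
    """
    n_bins_f = session.session_minutes / bin_min
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError("bin_min must divide session_minutes")
    n_bins = int(round(n_bins_f))
    bin_s = bin_min * 60.0
    trace = np.zeros(n_bins)
    for onset, dur in session.events:
        start, end = onset, onset + dur
        first = int(start // bin_s)
        last = min(int(np.ceil(end / bin_s)), n_bins)
        for b in range(first, last):
            lo, hi = b * bin_s, (b + 1) * bin_s
            trace[b] += max(0.0, min(end, hi) - max(start, lo))
    return trace


def _minmax(trace: np.ndarray) -> np.ndarray | None:
    rng = trace.max() - trace.min()
    if rng == 0:
        return None
    return (trace - trace.min()) / rng


def normalized_condition_difference(
    licl_sessions: Sequence[BehaviorSession],
    saline_sessions: Sequence[BehaviorSession],
    bin_min: float = 1.0,
) -> dict:
    """Per-bin mean normalized licl - saline rearing-duration difference.

    Each animal's duration trace is min-max normalized to [0, 1];
    all-zero traces are excluded with a warning.  Returns the per-bin
    difference of condition means and its SEM (cohorts are independent,
    so SEMs add in quadrature).
    """
    traces: dict[str, list[np.ndarray]] = {"licl": [], "saline": []}
    for cond, sessions in (("licl", licl_sessions), ("saline", saline_sessions)):
        if not sessions:
            raise ValueError(f"need at least one {cond} session")
        for s in sessions:
            norm = _minmax(durations_per_bin(s, bin_min))
            if norm is None:
                logger.warning("session %s has a constant trace; excluded", s.session_id)
                continue
            traces[cond].append(norm)
    licl = np.asarray(traces["licl"])
    sal = np.asarray(traces["saline"])
    diff = licl.mean(axis=0) - sal.mean(axis=0)
    sem = np.sqrt(
        licl.std(axis=0, ddof=1) ** 2 / len(licl)
        + sal.std(axis=0, ddof=1) ** 2 / len(sal)
    ) if min(len(licl), len(sal)) > 1 else np.full(diff.shape, np.nan)
    return {"difference": diff, "sem": sem, "n_licl": len(licl), "n_saline": len(sal)}


@dataclass
class SigmoidFit:
    """4-parameter logistic fit of a per-bin trace.

    ``f(t) = lower + (upper - lower) / (1 + exp(-slope * (t - midpoint)))``
    """

    lower: float
    upper: float
    midpoint: float  # minutes
    slope: float  # per minute
    r_squared: float
    degenerate: bool = False

    @property
    def onset_min(self) -> float:
        """Time at which the fit has completed 95% of its transition
        (the approach to the asymptote it tends to late in the session)."""
        return self.midpoint + np.log(19.0) / abs(self.slope)


def _logistic(t, lower, upper, midpoint, slope):
    z = np.clip(-slope * (np.asarray(t) - midpoint), -500, 500)
    return lower + (upper - lower) / (1.0 + np.exp(z))


def fit_sigmoid(
    trace: np.ndarray,
    bin_min: float = 1.0,
    midpoint_starts: Sequence[float] = (4.0, 8.0, 12.0, 16.0),
) -> SigmoidFit:
    """Nonlinear least-squares 4-parameter logistic fit.

    Multi-start over a grid of midpoint initializations guards against
    local minima; the best fit by residual sum of squares wins.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 bins to fit a sigmoid")
    t = (np.arange(y.size) + 0.5) * bin_min
    if np.ptp(y) == 0:  # flat trace: nothing to fit
        return SigmoidFit(
            lower=float(y[0]), upper=float(y[0]), midpoint=float(t[y.size // 2]),
            slope=0.0, r_squared=0.0, degenerate=True,
        )
    span = y.max() - y.min()
    best = None
    errors = []
    for m0 in midpoint_starts:
        for k0 in (1.0, -1.0):
            p0 = [y[: max(2, y.size // 4)].mean(), y[-max(2, y.size // 4):].mean(), m0, k0]
            try:
                popt, _ = optimize.curve_fit(
                    _logistic, t, y, p0=p0, maxfev=5_000,
                    # slope capped at 6/min: transitions faster than ~1 bin
                    # are indistinguishable from noise spikes at 1-min bins
                    bounds=(
                        [y.min() - 2 * span, y.min() - 2 * span, t[0], -6.0],
                        [y.max() + 2 * span, y.max() + 2 * span, t[-1], 6.0],
                    ),
                )
            except RuntimeError as exc:  # no convergence from this start
                errors.append(str(exc))
                continue
            ssr = float(((y - _logistic(t, *popt)) ** 2).sum())
            if best is None or ssr < best[0]:
                best = (ssr, popt)
    if best is None:
        raise RuntimeError(
            "sigmoid fit failed to converge from every start: " + "; ".join(errors[:2])
        )
    ssr, (lower, upper, midpoint, slope) = best
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = (1.0 - ssr / sst) if sst > 0 else 0.0
    degenerate = abs(upper - lower) < 1e-3 * span or abs(slope) < 1e-3
    # canonical orientation: positive slope, `upper` is the late asymptote
    # (swapping asymptotes while negating the slope leaves the curve unchanged)
    if slope < 0:
        lower, upper, slope = upper, lower, -slope
    return SigmoidFit(
        lower=float(lower),
        upper=float(upper),
        midpoint=float(midpoint),
        slope=float(slope),
        r_squared=float(r2),
        degenerate=bool(degenerate),
    )


def quartile_wilcoxon(
    licl_sessions: Sequence[BehaviorSession],
    saline_sessions: Sequence[BehaviorSession],
    bin_min: float = 1.0,
    quartile_min: float = 5.0,
    paired: bool = False,
) -> dict[int, dict]:
    """Per-quartile rank test of rearing durations between conditions.

    Default is the two-sample Mann-Whitney/rank-sum form (the cohorts
    are separate animals); ``paired=True`` switches to the signed-rank
    test for within-animal designs.  Small samples use exact p-values.
    Effect size is r = Z / sqrt(N).
    """
    per_q = int(round(quartile_min / bin_min))
    def quartiles(sessions):
        arr = np.array([durations_per_bin(s, bin_min) for s in sessions])
        n_q = arr.shape[1] // per_q
        return arr[:, : n_q * per_q].reshape(len(sessions), n_q, per_q).mean(axis=2)

    licl_q = quartiles(licl_sessions)
    sal_q = quartiles(saline_sessions)
    out: dict[int, dict] = {}
    for q in range(licl_q.shape[1]):
        a, b = licl_q[:, q], sal_q[:, q]
        n = len(a) + len(b)
        if np.ptp(np.concatenate([a, b])) == 0:
            logger.warning("quartile %d is all ties; p set to 1", q + 1)
            out[q + 1] = {"stat": np.nan, "p": 1.0, "r": 0.0}
            continue
        if paired:
            res = stats.wilcoxon(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            n_pairs = len(a)
            mu = n_pairs * (n_pairs + 1) / 4
            sd = np.sqrt(n_pairs * (n_pairs + 1) * (2 * n_pairs + 1) / 24)
            z = (stat - mu) / sd if sd > 0 else 0.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            mu = len(a) * len(b) / 2
            sd = np.sqrt(len(a) * len(b) * (n + 1) / 12)
            z = (stat - mu) / sd if sd > 0 else 0.0
        out[q + 1] = {"stat": stat, "p": p, "r": float(abs(z) / np.sqrt(n))}
    return out
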