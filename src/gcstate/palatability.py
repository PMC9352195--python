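"""Palatability-related content of taste responses.

Two complementary statistics:

* Moving-window Spearman correlation between single-trial firing rates
  and the canonical palatability ranks (sucrose > NaCl > citric acid >
  quinine), windows of 250 ms stepped by 25 ms.  Its magnitude rises
  into the late epoch where hedonic coding lives.

* The pure palatability index (PPI): within an epoch, the mean Euclidean
  distance between a neuron's trial-averaged responses to tastes of
  opposite hedonic valence minus the mean distance between tastes of the
  same valence.  Exchangeable responses give PPI = 0; a polarized
  good-vs-bad code gives a large positive PPI.  Distances are scaled by
  sqrt(#bins) so the index is per-bin and comparable across window
  sizes; a normalized (ratio) variant is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DISSIMILAR_PAIRS,
    PALATABILITY_RANKS,
    SIMILAR_PAIRS,
    TASTES,
    EnsembleRecording,
    EpochDefinition,
)

logger = logging.getLogger(__name__)


@dataclass
class PalatabilityTrace:
    window_starts_ms: np.ndarray
    rho: np.ndarray = field(repr=False)  # (neurons, windows), NaN when undefined
    condition: str = ""
    window_ms: float = 250.0
    step_ms: float = 25.0
    n_excluded_windows: int = 0

    @property
    def mean_abs_rho(self) -> np.ndarray:
        return np.nanmean(np.abs(self.rho), axis=0)

    @property
    def mean_rho2(self) -> np.ndarray:
        return np.nanmean(self.rho**2, axis=0)

    def epoch_values(
        self, epochs: EpochDefinition, stat: str = "abs_rho"
    ) -> pd.DataFrame:
        """Per-neuron mean |rho| (or rho^2) over windows centered in each
        epoch; long-form (neuron index, epoch, value)."""
        centers = self.window_starts_ms + self.window_ms / 2.0
        rows = []
        for name, (lo, hi) in epochs.items():
            sel = (centers >= lo) & (centers < hi)
            vals = np.abs(self.rho[:, sel]) if stat == "abs_rho" else self.rho[:, sel] ** 2
            per_neuron = np.nanmean(vals, axis=1)
            for i, v in enumerate(per_neuron):
                rows.append((i, name, float(v)))
        return pd.DataFrame(rows, columns=["neuron", "epoch", "value"])


def moving_spearman(
    rec: EnsembleRecording,
    ranks: dict[str, int] | None = None,
    window_ms: float = 250.0,
    step_ms: float = 25.0,
    t_range_ms: tuple[float, float] = (-250.0, 1250.0),
) -> PalatabilityTrace:
    """Per-neuron, per-window Spearman rho between trial firing rates and
    the delivered taste's palatability rank."""
    if ranks is None:
        ranks = PALATABILITY_RANKS
    missing = set(TASTES) - set(np.unique(rec.tastes))
    if missing:
        raise ValueError(f"all 4 tastes required; missing {sorted(missing)}")
    trial_ranks = np.array([ranks[t] for t in rec.tastes], dtype=float)
    r_pal = stats.rankdata(trial_ranks)
    r_pal_c = r_pal - r_pal.mean()
    denom_pal = np.sqrt((r_pal_c**2).sum())

    starts = np.arange(t_range_ms[0], t_range_ms[1] - window_ms + step_ms / 2, step_ms)
    rho = np.full((rec.n_neurons, starts.size), np.nan)
    excluded = 0
    for w, s in enumerate(starts):
        counts = rec.window_counts(s, s + window_ms)  # (neurons, trials)
        rk = stats.rankdata(counts, axis=1)
        rk_c = rk - rk.mean(axis=1, keepdims=True)
        denom = np.sqrt((rk_c**2).sum(axis=1)) * denom_pal
        num = rk_c @ r_pal_c
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / denom
        bad = denom == 0
        excluded += int(bad.sum())
        rho[:, w] = np.where(bad, np.nan, r)
    if excluded:
        logger.info("%d zero-variance neuron-windows excluded", excluded)
    return PalatabilityTrace(
        window_starts_ms=starts,
        rho=rho,
        condition=rec.condition,
        window_ms=window_ms,
        step_ms=step_ms,
        n_excluded_windows=excluded,
    )


def spearman_condition_test(
    saline: PalatabilityTrace,
    licl: PalatabilityTrace,
    epochs: EpochDefinition = EpochDefinition(),
    stat: str = "abs_rho",
) -> dict[str, dict]:
    """Kruskal-Wallis comparison of per-neuron epoch palatability
    correlations between conditions."""
    out = {}
    sal = saline.epoch_values(epochs, stat)
    lic = licl.epoch_values(epochs, stat)
    for name, _ in epochs.items():
        a = sal.loc[sal["epoch"] == name, "value"].dropna().to_numpy()
        b = lic.loc[lic["epoch"] == name, "value"].dropna().to_numpy()
        h, p = stats.kruskal(a, b)
        out[name] = {
            "H": float(h),
            "df": 1,
            "p": float(p),
            "saline_mean": float(a.mean()),
            "licl_mean": float(b.mean()),
        }
    return out


# ---------------------------------------------------------------------------
# Pure palatability index
# ---------------------------------------------------------------------------

def compute_ppi(
    rec: EnsembleRecording,
    epochs: EpochDefinition = EpochDefinition(),
    mode: str = "difference",
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
    central_ms: float = 150.0,
) -> pd.DataFrame:
    """Per-neuron, per-epoch pure palatability index.

    Responses are baseline-normalized (the neuron's mean rate over the
    500 ms before delivery is subtracted), trial-averaged per taste over
    the central ``central_ms`` of each epoch, and compared as Euclidean
    distances divided by sqrt(#bins).  ``mode='difference'`` returns
    D_dissimilar - D_similar; ``mode='normalized'`` the ratio
    (D_dis - D_sim) / (D_dis + D_sim).

    Returns a frame with columns neuron_id, condition, epoch, d_similar,
    d_dissimilar, ppi.
    """
    if mode not in ("difference", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    present = set(np.unique(rec.tastes))
    missing = set(TASTES) - present
    if missing:
        raise ValueError(f"missing tastes {sorted(missing)}")
    baseline = rec.window_rates(*baseline_ms).mean(axis=1)  # (neurons,)
    rows = []
    for name, _ in epochs.items():
        lo, hi = epochs.central_window(name, central_ms)
        binned = rec.window_binned_rates(lo, hi)  # (neurons, trials, bins)
        n_bins = binned.shape[2]
        resp = binned - baseline[:, None, None]
        taste_mean = {
            t: resp[:, rec.tastes == t, :].mean(axis=1) for t in TASTES
        }  # each (neurons, bins)

        def pair_dist(pairs):
            d = [
                np.linalg.norm(taste_mean[a] - taste_mean[b], axis=1) / np.sqrt(n_bins)
                for a, b in pairs
            ]
            return np.mean(d, axis=0)

        d_sim = pair_dist(SIMILAR_PAIRS)
        d_dis = pair_dist(DISSIMILAR_PAIRS)
        if mode == "difference":
            ppi = d_dis - d_sim
        else:
            denom = d_dis + d_sim
            with np.errstate(invalid="ignore", divide="ignore"):
                ppi = np.where(denom > 0, (d_dis - d_sim) / denom, 0.0)
        for i, nid in enumerate(rec.neuron_ids):
            rows.append(
                (nid, rec.condition, name, float(d_sim[i]), float(d_dis[i]), float(ppi[i]))
            )
    return pd.DataFrame(
        rows, columns=["neuron_id", "condition", "epoch", "d_similar", "d_dissimilar", "ppi"]
    )


def ppi_tests(
    saline_ppi: pd.DataFrame,
    licl_ppi: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-epoch PPI statistics: one-sample t vs 0 within each condition,
    and an unpaired rank (Mann-Whitney) comparison between conditions
    with effect size r = Z / sqrt(N)."""
    out = {}
    for name in saline_ppi["epoch"].unique():
        a = saline_ppi.loc[saline_ppi["epoch"] == name, "ppi"].to_numpy()
        b = licl_ppi.loc[licl_ppi["epoch"] == name, "ppi"].to_numpy()
        if min(a.size, b.size) < 10:
            raise ValueError("need >= 10 neurons per condition")
        one_sample = {
            "saline": stats.ttest_1samp(a, 0.0),
            "licl": stats.ttest_1samp(b, 0.0),
        }
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = np.nan, 1.0
            z = 0.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
            mu = a.size * b.size / 2
            sd = np.sqrt(a.size * b.size * (a.size + b.size + 1) / 12)
            z = (u - mu) / sd
        out[name] = {
            "saline_mean": float(a.mean()),
            "licl_mean": float(b.mean()),
            "one_sample": {
                k: {"t": float(v.statistic), "p": float(v.pvalue)}
                for k, v in one_sample.items()
            },
            "between": {
                "U": u,
                "p": p,
                "r": float(abs(z) / np.sqrt(a.size + b.size)),
                "significant": p < alpha,
            },
        }
    return out
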