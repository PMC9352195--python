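"""Held-unit identification, response-difference vectors, and clustering.

A unit recorded in two sessions is "held" when its between-session
waveform dissimilarity is smaller than the 95th percentile of a
within-session null built by comparing each session's first-third
waveforms to its last-third waveforms (bootstrapped).  The dissimilarity
statistic is the Euclidean distance between mean waveforms normalized by
the pooled per-sample SD; it is pluggable.

For held units, the condition response change per taste is summarized as
a response-difference (RD) point: (saline response, licl response),
each the post-minus-pre change of the unit's min-max-normalized firing,
in % of maximum responsiveness.  RDs are clustered with a Gaussian
mixture model (k chosen by BIC); points outside a cluster's 95%
Mahalanobis confidence ellipse stay unassigned.  A final aligned-rank
ANOVA asks whether palatability content (Spearman rho^2) depends on
cluster x epoch x condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.formula.api import ols

from .datatypes import EnsembleRecording, EpochDefinition, TASTES

logger = logging.getLogger(__name__)

PRE_WINDOW_MS = (-750.0, -250.0)
POST_WINDOW_MS = (250.0, 750.0)


# ---------------------------------------------------------------------------
# Waveform stability
# ---------------------------------------------------------------------------

def waveform_dissimilarity(wf_a: np.ndarray, wf_b: np.ndarray) -> float:
    """Distance between mean waveforms in pooled per-sample-SD units.

    sqrt(mean_j ((mean_a_j - mean_b_j) / s_j)^2) with s_j the pooled SD
    of sample j across both sets.
    """
    ma, mb = wf_a.mean(axis=0), wf_b.mean(axis=0)
    va = wf_a.var(axis=0, ddof=1)
    vb = wf_b.var(axis=0, ddof=1)
    na, nb = len(wf_a), len(wf_b)
    pooled_sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    pooled_sd = np.where(pooled_sd > 0, pooled_sd, 1.0)
    return float(np.sqrt(np.mean(((ma - mb) / pooled_sd) ** 2)))


@dataclass
class HeldUnitDecision:
    neuron_id: str
    between_stat: float
    within_null: np.ndarray = field(repr=False)
    threshold: float = 0.0  # 95th percentile of the within null
    held: bool = False


def held_unit_test(
    wf_a: np.ndarray,
    wf_b: np.ndarray,
    neuron_id: str = "unit",
    n_boot: int = 200,
    percentile: float = 95.0,
    statistic: Callable[[np.ndarray, np.ndarray], float] = waveform_dissimilarity,
    seed: int = 0,
) -> HeldUnitDecision:
    """Decide whether the unit recorded in sessions A and B is the same.

    The within-session null bootstraps the first-third vs last-third
    comparison inside each session; the unit is held when the A-vs-B
    statistic falls below the null's 95th percentile.
    """
    wf_a, wf_b = np.asarray(wf_a, float), np.asarray(wf_b, float)
    if wf_a.shape[1] != wf_b.shape[1]:
        raise ValueError(
            f"waveform lengths differ: {wf_a.shape[1]} vs {wf_b.shape[1]}"
        )
    if min(len(wf_a), len(wf_b)) < 50:
        raise ValueError("need at least 50 waveforms per session")
    rng = np.random.default_rng(seed)
    null = []
    for wf in (wf_a, wf_b):
        third = len(wf) // 3
        first, last = wf[:third], wf[-third:]
        for _ in range(n_boot):
            f = first[rng.integers(0, third, third)]
            l = last[rng.integers(0, third, third)]
            null.append(statistic(f, l))
    null = np.asarray(null)
    between = statistic(wf_a, wf_b)
    thr = float(np.percentile(null, percentile))
    return HeldUnitDecision(
        neuron_id=neuron_id,
        between_stat=between,
        within_null=null,
        threshold=thr,
        held=between < thr,
    )


# ---------------------------------------------------------------------------
# Response-difference vectors
# ---------------------------------------------------------------------------

def response_difference_vectors(
    saline: EnsembleRecording,
    licl: EnsembleRecording,
    held_ids: Sequence[str] | None = None,
    pre_ms: tuple[float, float] = PRE_WINDOW_MS,
    post_ms: tuple[float, float] = POST_WINDOW_MS,
) -> pd.DataFrame:
    """One RD point per held unit x taste.

    Per unit: pre- and post-delivery mean rates (trial-averaged, per
    taste, per condition) are min-max normalized across both sessions
    jointly (so condition differences stay meaningful) and expressed as
    % of maximum responsiveness; the condition response is post - pre.
    Columns: neuron_id, taste, saline_resp, licl_resp, distance, angle.
    """
    if held_ids is None:
        held_ids = list(saline.neuron_ids)
    rows = []
    recs = {"saline": saline, "licl": licl}
    for nid in held_ids:
        vals: dict[tuple[str, str, str], float] = {}
        for cond, rec in recs.items():
            i = list(rec.neuron_ids).index(nid)
            pre = rec.window_rates(*pre_ms)[i]
            post = rec.window_rates(*post_ms)[i]
            for taste in TASTES:
                sel = rec.tastes == taste
                vals[(cond, taste, "pre")] = float(pre[sel].mean())
                vals[(cond, taste, "post")] = float(post[sel].mean())
        arr = np.array(list(vals.values()))
        vmin, vmax = arr.min(), arr.max()
        if vmax == vmin:
            logger.warning("unit %s silent in both sessions; excluded", nid)
            continue
        norm = {k: 100.0 * (v - vmin) / (vmax - vmin) for k, v in vals.items()}
        for taste in TASTES:
            s_resp = norm[("saline", taste, "post")] - norm[("saline", taste, "pre")]
            l_resp = norm[("licl", taste, "post")] - norm[("licl", taste, "pre")]
            dist = float(np.hypot(s_resp, l_resp))
            angle = float(np.degrees(np.arctan2(l_resp, s_resp)) % 360.0)
            rows.append((nid, taste, s_resp, l_resp, dist, angle))
    return pd.DataFrame(
        rows,
        columns=["neuron_id", "taste", "saline_resp", "licl_resp", "distance", "angle"],
    )


# ---------------------------------------------------------------------------
# GMM clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    best_k: int
    bic: dict[int, float]
    labels: np.ndarray  # cluster index per RD, -1 = unassigned
    means: np.ndarray
    covariances: np.ndarray = field(repr=False)
    n_angle_peaks: int = 0


def _count_angle_peaks(angles: np.ndarray, n_bins: int = 18) -> int:
    """Peaks of the circular angle histogram (20-degree bins)."""
    hist, _ = np.histogram(angles, bins=n_bins, range=(0.0, 360.0))
    n = len(hist)
    peaks = 0
    for i in range(n):
        left, right = hist[(i - 1) % n], hist[(i + 1) % n]
        if hist[i] > left and hist[i] >= right and hist[i] > 0:
            peaks += 1
    return peaks


def gmm_cluster(
    rds: pd.DataFrame,
    k_max: int = 6,
    confidence: float = 0.95,
    seed: int = 0,
    n_init: int = 5,
) -> ClusterResult:
    """Cluster RD points with a Gaussian mixture; pick k by BIC.

    Points outside their cluster's ``confidence`` Mahalanobis ellipse are
    left unassigned (label -1).
    """
    X = rds[["saline_resp", "licl_resp"]].to_numpy()
    if len(X) < 10:
        raise ValueError("need at least 10 RD points to cluster")
    bic: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1e-6,
            n_init=n_init,
            random_state=seed,
        ).fit(X)
        bic[k] = float(gm.bic(X))
        models[k] = gm
    best_k = min(bic, key=bic.get)
    gm = models[best_k]
    labels = gm.predict(X)
    # 95% confidence membership: squared Mahalanobis distance to the
    # assigned centroid under a 2-D Gaussian is chi^2(2)
    cutoff = stats.chi2.ppf(confidence, df=X.shape[1])
    for i, lab in enumerate(labels):
        diff = X[i] - gm.means_[lab]
        m2 = diff @ np.linalg.solve(gm.covariances_[lab], diff)
        if m2 > cutoff:
            labels[i] = -1
    return ClusterResult(
        best_k=best_k,
        bic=bic,
        labels=labels,
        means=gm.means_,
        covariances=gm.covariances_,
        n_angle_peaks=_count_angle_peaks(rds["angle"].to_numpy()),
    )


# ---------------------------------------------------------------------------
# Cluster-specific palatability (aligned-rank ANOVA)
# ---------------------------------------------------------------------------

def aligned_rank_anova(
    df: pd.DataFrame,
    dv: str,
    factors: list[str],
    cluster_col: str | None = None,
) -> pd.DataFrame:
    """Aligned-rank-transform factorial ANOVA (fixed effects).

    For every main effect and interaction of ``factors``: the response is
    aligned for that term (full-model residuals plus the term's fitted
    component), rank-transformed, and refitted with the full factorial
    model; the term's F and p from that fit are reported.

    ``cluster_col`` names a grouping whose rows are correlated (e.g. the
    neuron contributing one row per epoch x condition cell); when given,
    term tests use cluster-robust covariance, without which the F tests
    overstate the effective sample size.
    """
    formula_rhs = " * ".join(f"C({f})" for f in factors)
    full = ols(f"{dv} ~ {formula_rhs}", data=df).fit()
    # design-matrix column blocks per term
    design = dmatrix(formula_rhs, df, return_type="dataframe")
    term_slices = design.design_info.term_name_slices
    rows = []
    for term_name, sl in term_slices.items():
        if term_name == "Intercept":
            continue
        component = design.iloc[:, sl].to_numpy() @ full.params.iloc[sl].to_numpy()
        aligned = full.resid.to_numpy() + component
        tmp = df.copy()
        tmp["_aligned_rank"] = stats.rankdata(aligned)
        if cluster_col is not None:
            fit = ols(f"_aligned_rank ~ {formula_rhs}", data=tmp).fit(
                cov_type="cluster", cov_kwds={"groups": tmp[cluster_col]}
            )
            wald = fit.wald_test_terms(scalar=True).table.loc[term_name]
            rows.append(
                {
                    "term": term_name,
                    "F": float(wald["statistic"]),
                    "df_num": int(wald["df_constraint"]),
                    "df_den": int(tmp[cluster_col].nunique() - 1),
                    "p": float(wald["pvalue"]),
                }
            )
        else:
            fit = ols(f"_aligned_rank ~ {formula_rhs}", data=tmp).fit()
            aov = sm.stats.anova_lm(fit, typ=2)
            row = aov.loc[term_name]
            rows.append(
                {
                    "term": term_name,
                    "F": float(row["F"]),
                    "df_num": int(row["df"]),
                    "df_den": int(aov.loc["Residual", "df"]),
                    "p": float(row["PR(>F)"]),
                }
            )
    return pd.DataFrame(rows).set_index("term")


def _factorial_design(codes: list[np.ndarray], levels: list[int]):
    """Drop-first dummy design for a full factorial; returns the list of
    column blocks per term, ordered mains then interactions by order."""
    import itertools

    dummies = []
    for code, k in zip(codes, levels):
        d = np.zeros((code.size, k - 1))
        for j in range(1, k):
            d[:, j - 1] = code == j
        dummies.append(d)
    n = codes[0].size
    blocks: dict[tuple[int, ...], np.ndarray] = {(): np.ones((n, 1))}
    n_fac = len(codes)
    for order in range(1, n_fac + 1):
        for combo in itertools.combinations(range(n_fac), order):
            cols = [dummies[i] for i in combo]
            block = cols[0]
            for c in cols[1:]:
                block = np.einsum("ni,nj->nij", block, c).reshape(n, -1)
            blocks[combo] = block
    return blocks


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _art_threeway_f(
    y: np.ndarray, codes: list[np.ndarray], levels: list[int]
) -> float:
    """Aligned-rank-transform F for the highest-order interaction."""
    blocks = _factorial_design(codes, levels)
    top = tuple(range(len(codes)))
    X_full = np.hstack(list(blocks.values()))
    X_reduced = np.hstack([b for key, b in blocks.items() if key != top])
    # align for the top term: full-model residuals + its fitted component
    rss_f, beta = _rss(X_full, y)
    offset = X_full.shape[1] - blocks[top].shape[1]  # top block is last
    comp = blocks[top] @ beta[offset:]
    resid = y - X_full @ beta
    ranked = stats.rankdata(resid + comp)
    rss_full, _ = _rss(X_full, ranked)
    rss_red, _ = _rss(X_reduced, ranked)
    q = blocks[top].shape[1]
    dof = y.size - X_full.shape[1]
    if rss_full <= 0 or dof <= 0:
        return np.inf
    return ((rss_red - rss_full) / q) / (rss_full / dof)


def cluster_palatability_anova(
    rho2_table: pd.DataFrame,
    min_cluster_size: int = 3,
    alpha: float = 0.05,
    n_permutations: int = 300,
    seed: int = 0,
) -> dict:
    """Cluster x epoch x condition aligned-rank ANOVA on per-neuron
    palatability content (Spearman rho^2).

    ``rho2_table`` columns: neuron_id, cluster, epoch, condition, rho2.
    Clusters with fewer than ``min_cluster_size`` units are dropped.
    The three-way interaction p-value comes from a neuron-level
    cluster-label permutation null of the aligned-rank F (each neuron's
    six epoch x condition rows move together, so within-neuron
    correlation cannot inflate the test).  Follow-ups: per-cluster
    condition comparison of late-epoch rho^2.
    """
    df = rho2_table.loc[rho2_table["cluster"] >= 0].copy()
    sizes = df.groupby("cluster")["neuron_id"].nunique()
    small = sizes[sizes < min_cluster_size].index.tolist()
    if small:
        logger.info("dropping clusters with <%d units: %s", min_cluster_size, small)
        df = df.loc[~df["cluster"].isin(small)]
    if df["cluster"].nunique() < 2:
        raise ValueError("need at least 2 clusters for the interaction test")
    aov = aligned_rank_anova(df, "rho2", ["cluster", "epoch", "condition"])
    three_way = aov.loc["C(cluster):C(epoch):C(condition)"]

    # permutation inference on the three-way ART F
    y = df["rho2"].to_numpy()
    c_code, _ = pd.factorize(df["cluster"])
    e_code, _ = pd.factorize(df["epoch"])
    o_code, _ = pd.factorize(df["condition"])
    levels = [c_code.max() + 1, e_code.max() + 1, o_code.max() + 1]
    f_obs = _art_threeway_f(y, [c_code, e_code, o_code], levels)
    rng = np.random.default_rng(seed)
    neuron_codes, neuron_idx = pd.factorize(df["neuron_id"])
    unit_cluster = np.empty(len(neuron_idx), dtype=int)
    unit_cluster[neuron_codes] = c_code  # cluster per neuron
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(unit_cluster)
        f_p = _art_threeway_f(y, [perm[neuron_codes], e_code, o_code], levels)
        exceed += f_p >= f_obs
    p_perm = (1 + exceed) / (n_permutations + 1)

    followups = {}
    late = df.loc[df["epoch"] == "late"]
    for c, sub in late.groupby("cluster"):
        a = sub.loc[sub["condition"] == "saline", "rho2"].to_numpy()
        b = sub.loc[sub["condition"] == "licl", "rho2"].to_numpy()
        if min(a.size, b.size) < 2 or np.ptp(np.concatenate([a, b])) == 0:
            followups[int(c)] = {"p": 1.0, "licl_minus_saline": 0.0}
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        followups[int(c)] = {
            "p": float(res.pvalue),
            "licl_minus_saline": float(b.mean() - a.mean()),
        }
    return {
        "anova": aov,
        "interaction": {
            "F": float(f_obs),
            "df_num": int(three_way["df_num"]),
            "df_den": int(three_way["df_den"]),
            "p": float(p_perm),
            "p_parametric": float(three_way["p"]),
            "significant": bool(p_perm < alpha),
        },
        "late_epoch_followups": followups,
    }


# ---------------------------------------------------------------------------
# Baseline equivalence
# ---------------------------------------------------------------------------

def baseline_equivalence(
    saline: EnsembleRecording,
    licl: EnsembleRecording,
    held_ids: Sequence[str] | None = None,
    window_ms: tuple[float, float] = (-500.0, 0.0),
) -> dict:
    """Check that pre-stimulus firing is condition independent.

    Paired t test on per-unit mean baseline rates plus a KS test of the
    saline - licl differences against a zero-centered Gaussian with the
    sample SD.
    """
    if held_ids is None:
        held_ids = list(saline.neuron_ids)
    idx_s = [list(saline.neuron_ids).index(n) for n in held_ids]
    idx_l = [list(licl.neuron_ids).index(n) for n in held_ids]
    a = saline.window_rates(*window_ms)[idx_s].mean(axis=1)
    b = licl.window_rates(*window_ms)[idx_l].mean(axis=1)
    diff = a - b
    if np.allclose(diff, 0):
        t, t_p = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b)
        t, t_p = float(res.statistic), float(res.pvalue)
    sd = diff.std(ddof=1)
    if sd == 0:
        ks, ks_p = 0.0, 1.0
    else:
        res = stats.kstest(diff, "norm", args=(0.0, sd))
        ks, ks_p = float(res.statistic), float(res.pvalue)
    return {
        "t": t,
        "t_df": len(held_ids) - 1,
        "t_p": t_p,
        "ks": ks,
        "ks_p": ks_p,
        "saline_mean": float(a.mean()),
        "licl_mean": float(b.mean()),
    }
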