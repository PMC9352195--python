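"""Single-neuron taste responsiveness and condition effects on magnitude.

A neuron is taste responsive when its trialwise evoked firing rate
(200-1200 ms post delivery; the first 200 ms is somatosensory, not
chemosensory, and is always excluded) differs from its trialwise
baseline rate (the 1 s before delivery) by a Mann-Whitney U test.  The
direction labels "excitatory"/"inhibitory" refer only to the sign of the
firing-rate change from baseline, not to cell type or synaptic
mechanism.  The condition analysis asks whether illness shrinks response
magnitudes, separately for the two directions, via a condition x
direction ANOVA on per-neuron-per-taste |magnitudes| with Tukey
follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols

from .datatypes import TASTES, EnsembleRecording

BASELINE_MS = (-1000.0, 0.0)
EVOKED_MS = (200.0, 1200.0)


@dataclass
class ResponseClassification:
    neuron_id: str
    responsive: bool
    p: float
    direction: str | None  # 'excitatory' | 'inhibitory' | None (undefined)
    magnitude_hz: float  # mean evoked - baseline rate, signed


def classify_responsiveness(
    rec: EnsembleRecording,
    alpha: float = 0.05,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    evoked_ms: tuple[float, float] = EVOKED_MS,
) -> list[ResponseClassification]:
    """Mann-Whitney classification of taste responsiveness per neuron.

    Trials are pooled across tastes: the flag captures responsiveness to
    oral stimulation as such, not taste specificity.
    """
    if rec.n_trials < 10:
        raise ValueError("need at least 10 trials to classify responsiveness")
    base = rec.window_rates(*baseline_ms)  # (neurons, trials)
    evoked = rec.window_rates(*evoked_ms)
    out = []
    for i, nid in enumerate(rec.neuron_ids):
        if rec.counts[i].sum() == 0:
            out.append(ResponseClassification(nid, False, 1.0, None, 0.0))
            continue
        if np.ptp(np.concatenate([base[i], evoked[i]])) == 0:
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(evoked[i], base[i], alternative="two-sided").pvalue
            )
        mag = float(evoked[i].mean() - base[i].mean())
        direction = None
        if mag > 0:
            direction = "excitatory"
        elif mag < 0:
            direction = "inhibitory"
        out.append(ResponseClassification(nid, p < alpha, p, direction, mag))
    return out


def magnitude_table(
    rec: EnsembleRecording,
    classes: list[ResponseClassification] | None = None,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    evoked_ms: tuple[float, float] = EVOKED_MS,
) -> pd.DataFrame:
    """Per neuron x taste response magnitudes with direction labels.

    One row per neuron per taste (4 rows/neuron), the granularity used by
    the condition x direction ANOVA.
    """
    if classes is None:
        classes = classify_responsiveness(rec)
    by_id = {c.neuron_id: c for c in classes}
    base = rec.window_rates(*baseline_ms)
    evoked = rec.window_rates(*evoked_ms)
    rows = []
    for i, nid in enumerate(rec.neuron_ids):
        c = by_id[nid]
        if c.direction is None:
            continue
        for taste in TASTES:
            sel = rec.tastes == taste
            if not sel.any():
                continue
            mag = float(evoked[i, sel].mean() - base[i, sel].mean())
            rows.append((nid, rec.condition, taste, c.direction, mag, abs(mag)))
    return pd.DataFrame(
        rows,
        columns=["neuron_id", "condition", "taste", "direction", "magnitude", "abs_magnitude"],
    )


def magnitude_condition_anova(
    saline_table: pd.DataFrame, licl_table: pd.DataFrame
) -> dict:
    """Condition x direction ANOVA on |response magnitude| with Tukey
    follow-ups per direction.

    The analysis unit is the neuron x taste magnitude (4 rows per
    neuron), but a neuron's four rows share its baseline and response
    strength, so the reported F tests use neuron-cluster-robust
    covariance (a plain residual-based ANOVA on these rows would be
    miscalibrated).  The naive ANOVA table is also returned for
    comparison with analyses that treat rows as independent.
    """
    df = pd.concat([saline_table, licl_table], ignore_index=True)
    cells = df.groupby(["condition", "direction"]).size()
    for cond in ("saline", "licl"):
        for direc in ("excitatory", "inhibitory"):
            if cells.get((cond, direc), 0) < 2:
                raise ValueError(f"ANOVA cell ({cond}, {direc}) has fewer than 2 entries")
    # cluster id: a neuron recorded in both conditions is still one cluster
    clusters = df["condition"] + ":" + df["neuron_id"]
    model = ols("abs_magnitude ~ C(condition) * C(direction)", data=df).fit(
        cov_type="cluster", cov_kwds={"groups": clusters}
    )
    wald = model.wald_test_terms(scalar=True).table
    inter = wald.loc["C(condition):C(direction)"]
    cond_main = wald.loc["C(condition)"]
    naive = sm.stats.anova_lm(
        ols("abs_magnitude ~ C(condition) * C(direction)", data=df).fit(), typ=2
    )

    df = df.assign(cell=df["condition"] + ":" + df["direction"])
    tukey = pg.pairwise_tukey(data=df, dv="abs_magnitude", between="cell")
    per_direction = {}
    for direc in ("excitatory", "inhibitory"):
        row = tukey[
            (tukey["A"].str.endswith(direc)) & (tukey["B"].str.endswith(direc))
        ].iloc[0]
        per_direction[direc] = {"p": float(row["p_tukey"]), "diff": float(row["diff"])}

    # signed condition main effect (licl - saline mean |magnitude|)
    cond_effect = float(
        df.loc[df["condition"] == "licl", "abs_magnitude"].mean()
        - df.loc[df["condition"] == "saline", "abs_magnitude"].mean()
    )
    return {
        "interaction": {
            "F": float(inter["statistic"]),
            "df_num": int(inter["df_constraint"]),
            "n_clusters": int(clusters.nunique()),
            "p": float(inter["pvalue"]),
        },
        "condition_main": {
            "F": float(cond_main["statistic"]),
            "p": float(cond_main["pvalue"]),
            "effect_licl_minus_saline": cond_effect,
        },
        "naive_anova": {
            "interaction_F": float(naive.loc["C(condition):C(direction)", "F"]),
            "interaction_p": float(naive.loc["C(condition):C(direction)", "PR(>F)"]),
            "df_den": int(naive.loc["Residual", "df"]),
        },
        "tukey_per_direction": per_direction,
    }
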