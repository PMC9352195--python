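"""Band-power extraction from LFP traces and the group quartile comparison.

Raw traces are reduced to per-minute power in a frequency band (default
mu, 7-12 Hz) with a Welch averaged periodogram (1 s Hann windows, 50%
overlap) computed within each 1-minute bin; multi-channel input is
averaged in the power domain.  Per-session series are min-max normalized
across the whole session, and the group analysis compares |session A -
session B| per animal, averaged within 5-minute quartiles, with a mixed
(group x quartile) ANOVA plus per-quartile one-way follow-ups.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import signal, stats

from .datatypes import PowerSeries

Pair = tuple[PowerSeries, PowerSeries]


def compute_band_power(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = (7.0, 12.0),
    bin_s: float = 60.0,
    animal_id: str = "unknown",
    condition: str = "unknown",
    window_s: float = 1.0,
) -> PowerSeries:
    """Per-bin mean spectral power in ``band`` from a raw voltage trace.

    ``trace`` may be (n_samples,) or (n_channels, n_samples); channels
    are averaged after per-channel power estimation.
    """
    x = np.atleast_2d(np.asarray(trace, dtype=float))
    if np.isnan(x).any():
        idx = int(np.flatnonzero(np.isnan(x).any(axis=0))[0])
        raise ValueError(f"NaN sample in trace at index {idx}")
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist ({fs / 2} Hz)")
    if lo >= hi:
        raise ValueError("band must be an increasing interval")
    samples_per_bin = int(round(bin_s * fs))
    n_bins = x.shape[1] // samples_per_bin
    if n_bins < 1:
        raise ValueError("trace shorter than one bin")
    nperseg = min(int(round(window_s * fs)), samples_per_bin)
    values = np.empty(n_bins)
    for b in range(n_bins):
        seg = x[:, b * samples_per_bin : (b + 1) * samples_per_bin]
        freqs, psd = signal.welch(
            seg, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
        )
        sel = (freqs >= lo) & (freqs <= hi)
        values[b] = psd[:, sel].mean()
    return PowerSeries(animal_id=animal_id, condition=condition, values=values, band=band)


def normalize_power(series: PowerSeries) -> PowerSeries:
    """Min-max normalize a power series to [0, 1] across the session."""
    v = series.values
    rng = v.max() - v.min()
    if rng == 0:
        raise ValueError("normalization undefined for a constant series")
    return series.copy_with(values=(v - v.min()) / rng, normalized=True)


def _quartile_means(values: np.ndarray, quartile_min: int = 5) -> np.ndarray:
    n_q = values.size // quartile_min
    return values[: n_q * quartile_min].reshape(n_q, quartile_min).mean(axis=1)


def quartile_difference_table(
    exp_pairs: Sequence[Pair],
    ctrl_pairs: Sequence[Pair],
    quartile_min: int = 5,
) -> pd.DataFrame:
    """Per animal x quartile |session difference| of normalized power."""
    rows = []
    for group, pairs in (("experimental", exp_pairs), ("control", ctrl_pairs)):
        for a, b in pairs:
            if a.n_minutes != b.n_minutes:
                raise ValueError(
                    f"unequal bin counts for animal {a.animal_id}:"
                    f" {a.n_minutes} vs {b.n_minutes}"
                )
            na = a.values if a.normalized else normalize_power(a).values
            nb = b.values if b.normalized else normalize_power(b).values
            qdiff = _quartile_means(np.abs(na - nb), quartile_min)
            for q, val in enumerate(qdiff, start=1):
                rows.append((a.animal_id, group, q, val))
    return pd.DataFrame(rows, columns=["animal", "group", "quartile", "abs_diff"])


def quartile_difference_anova(
    exp_pairs: Sequence[Pair],
    ctrl_pairs: Sequence[Pair],
    quartile_min: int = 5,
) -> dict:
    """Mixed (group x quartile) ANOVA on |saline - licl| quartile means.

    Returns the interaction term (F, dfs, p) and per-quartile one-way
    follow-ups comparing the two groups.
    """
    df = quartile_difference_table(exp_pairs, ctrl_pairs, quartile_min)
    aov = pg.mixed_anova(
        data=df, dv="abs_diff", within="quartile", subject="animal", between="group"
    )
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    followups = {}
    for q, sub in df.groupby("quartile"):
        g1 = sub.loc[sub["group"] == "experimental", "abs_diff"]
        g2 = sub.loc[sub["group"] == "control", "abs_diff"]
        f, p = stats.f_oneway(g1, g2)
        followups[int(q)] = {
            "F": float(f),
            "df1": 1,
            "df2": int(len(g1) + len(g2) - 2),
            "p": float(p),
        }
    return {
        "interaction": {
            "F": float(inter["F"]),
            "df1": float(inter["DF1"]),
            "df2": float(inter["DF2"]),
            "p": float(inter["p_unc"]),
        },
        "per_quartile": followups,
        "table": df,
    }
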