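"""Core in-memory containers shared across the analysis stages.

Conventions
-----------
* Time within a trial is measured in milliseconds relative to taste
  delivery (negative = pre-stimulus).
* Session time is measured in minutes post-injection; LFP power series
  are one value per 1-minute bin over a 20-minute window by default.
* The four tastants and their canonical hedonic order are fixed:
  sucrose > NaCl > citric acid > quinine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

TASTES: tuple[str, ...] = ("sucrose", "nacl", "citric_acid", "quinine")

#: Canonical palatability ranks (higher = more palatable).
PALATABILITY_RANKS: dict[str, int] = {
    "sucrose": 4,
    "nacl": 3,
    "citric_acid": 2,
    "quinine": 1,
}

#: Taste pairs sharing hedonic valence (palatable pair, aversive pair).
SIMILAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("sucrose", "nacl"),
    ("citric_acid", "quinine"),
)

#: Taste pairs of opposite hedonic valence.
DISSIMILAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("sucrose", "citric_acid"),
    ("sucrose", "quinine"),
    ("nacl", "citric_acid"),
    ("nacl", "quinine"),
)

CONDITIONS: tuple[str, str] = ("saline", "licl")


@dataclass(frozen=True)
class EpochDefinition:
    """Post-delivery response epochs in ms.

    The middle (identity) and late (palatability) epochs follow the
    standard cortical taste-response chronometry; the early epoch fills
    the gap between the 200 ms non-chemosensory period and the middle
    epoch.
    """

    early: tuple[float, float] = (200.0, 400.0)
    middle: tuple[float, float] = (400.0, 700.0)
    late: tuple[float, float] = (800.0, 1100.0)

    def items(self):
        return (("early", self.early), ("middle", self.middle), ("late", self.late))

    def central_window(self, name: str, width_ms: float = 150.0) -> tuple[float, float]:
        """Central ``width_ms`` of the named epoch."""
        lo, hi = dict(self.items())[name]
        mid = 0.5 * (lo + hi)
        return (mid - width_ms / 2.0, mid + width_ms / 2.0)


@dataclass
class PowerSeries:
    """One session's band power in 1-minute bins."""

    animal_id: str
    condition: str
    values: np.ndarray
    normalized: bool = False
    band: tuple[float, float] = (7.0, 12.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("PowerSeries values must be 1-D")

    @property
    def n_minutes(self) -> int:
        return self.values.size

    def copy_with(self, **kw) -> "PowerSeries":
        return replace(self, **kw)


@dataclass
class EnsembleRecording:
    """Simultaneously recorded spike counts: neurons x trials x time bins.

    ``t0_bin`` is the index of the first bin at/after taste delivery, so
    bin ``j`` covers ``[(j - t0_bin) * bin_ms, (j - t0_bin + 1) * bin_ms)``
    ms relative to delivery.
    """

    counts: np.ndarray  # (n_neurons, n_trials, n_bins) non-negative ints
    bin_ms: float
    t0_bin: int
    tastes: np.ndarray  # (n_trials,) labels from TASTES
    condition: str
    neuron_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.tastes = np.asarray(self.tastes)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (neurons, trials, bins)")
        if self.tastes.shape[0] != self.counts.shape[1]:
            raise ValueError("one taste label per trial required")
        if (self.counts < 0).any():
            raise ValueError("spike counts must be non-negative")
        unknown = set(np.unique(self.tastes)) - set(TASTES)
        if unknown:
            raise ValueError(f"unknown taste labels: {sorted(unknown)}")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:03d}" for i in range(self.counts.shape[0])]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def bin_starts_ms(self) -> np.ndarray:
        """Start time of each bin in ms relative to delivery."""
        return (np.arange(self.n_bins) - self.t0_bin) * self.bin_ms

    def _bin_slice(self, t_start_ms: float, t_end_ms: float) -> slice:
        if t_end_ms <= t_start_ms:
            raise ValueError("window end must exceed start")
        starts = self.bin_starts_ms()
        lo = int(np.searchsorted(starts, t_start_ms - 1e-9))
        hi = int(np.searchsorted(starts, t_end_ms - 1e-9))
        if lo == hi:
            raise ValueError(f"window [{t_start_ms}, {t_end_ms}) covers no bins")
        return slice(lo, hi)

    def window_counts(self, t_start_ms: float, t_end_ms: float) -> np.ndarray:
        """Summed spike counts per neuron x trial in [t_start, t_end) ms."""
        return self.counts[:, :, self._bin_slice(t_start_ms, t_end_ms)].sum(axis=2)

    def window_rates(self, t_start_ms: float, t_end_ms: float) -> np.ndarray:
        """Mean firing rate (Hz) per neuron x trial in [t_start, t_end) ms."""
        sl = self._bin_slice(t_start_ms, t_end_ms)
        dur_s = (sl.stop - sl.start) * self.bin_ms / 1000.0
        return self.counts[:, :, sl].sum(axis=2) / dur_s

    def window_binned_rates(self, t_start_ms: float, t_end_ms: float) -> np.ndarray:
        """Per-bin firing rates (Hz), shape (neurons, trials, bins in window)."""
        sl = self._bin_slice(t_start_ms, t_end_ms)
        return self.counts[:, :, sl] / (self.bin_ms / 1000.0)


@dataclass
class BehaviorSession:
    """Scored rearing events for one session."""

    session_id: str
    condition: str
    events: list[tuple[float, float]]  # (onset_s, duration_s)
    session_minutes: float = 20.0

    def __post_init__(self) -> None:
        for onset, dur in self.events:
            if dur < 0.5:
                raise ValueError("rearing events must last >= 0.5 s (scoring rule)")
            if not 0 <= onset < self.session_minutes * 60:
                raise ValueError("event onset outside the session")


@dataclass
class GroundTruth:
    """Planted parameters emitted by the synthetic generator."""

    true_tau_min: dict[str, float] = field(default_factory=dict)  # animal -> tau
    shift_sign: dict[str, int] = field(default_factory=dict)  # animal -> +1/-1
    response_direction: dict[str, str] = field(default_factory=dict)  # neuron -> dir
    cluster_id: dict[str, int] = field(default_factory=dict)  # held neuron -> cluster
    palatability_ranks: dict[str, int] = field(default_factory=dict)
    sickness_onset_min: float | None = None

    def __post_init__(self) -> None:
        if not self.palatability_ranks:
            self.palatability_ranks = dict(PALATABILITY_RANKS)
        ranks = sorted(self.palatability_ranks.values())
        if len(self.palatability_ranks) != 4 or ranks != sorted(set(ranks)):
            raise ValueError("palatability ranks must strictly order exactly 4 tastes")
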