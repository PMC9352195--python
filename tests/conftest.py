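import numpy as np
import pytest

from gcstate.datatypes import TASTES, EnsembleRecording
from gcstate.synth import GeneratorConfig, gen_ensemble_pair

#: configuration turning every illness effect off (for null fixtures)
NULL_EFFECTS = dict(
    illness_magnitude_shrink=0.0,
    illness_identity_loss=0.0,
    illness_palatability_boost=0.0,
)


@pytest.fixture
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=7, n_neurons=12, n_trials_per_taste=12)


@pytest.fixture
def default_pair():
    """One (saline, licl) ensemble pair at study-condition defaults."""
    return gen_ensemble_pair(GeneratorConfig(seed=11))


def make_recording(
    rates_hz: dict[str, np.ndarray] | None = None,
    n_neurons: int = 5,
    n_trials_per_taste: int = 15,
    baseline_hz: float = 6.0,
    bin_ms: float = 25.0,
    seed: int = 0,
    condition: str = "saline",
    evoked_window_ms: tuple[float, float] = (200.0, 1200.0),
) -> EnsembleRecording:
    """Poisson recording with per-taste evoked rates (Hz) in a window.

    ``rates_hz`` maps taste -> (n_neurons,) evoked rate; everything else
    fires at ``baseline_hz``.  Used to build hand-specified fixtures.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.array(TASTES), n_trials_per_taste)
    rng.shuffle(labels)
    n_bins = int(2500 / bin_ms)
    t0_bin = int(1000 / bin_ms)
    starts = (np.arange(n_bins) - t0_bin) * bin_ms
    in_win = (starts >= evoked_window_ms[0]) & (starts < evoked_window_ms[1])
    rate = np.full((n_neurons, labels.size, n_bins), baseline_hz, dtype=float)
    if rates_hz:
        for taste, r in rates_hz.items():
            r = np.broadcast_to(np.asarray(r, float), (n_neurons,))
            sel = labels == taste
            rate[:, sel, :] = np.where(in_win[None, None, :], r[:, None, None], baseline_hz)
    counts = rng.poisson(rate * bin_ms / 1000.0)
    return EnsembleRecording(
        counts=counts, bin_ms=bin_ms, t0_bin=t0_bin, tastes=labels, condition=condition
    )
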