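"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline can be exercised on the output of
this module: per-animal band-power series with an optional planted mean
shift, trial-structured ensemble spike counts with epochal taste coding
and condition (illness) effects, rearing-event streams whose durations
drop after a planted sickness onset, and paired spike-waveform sets for
the held-unit stability test.

Each generator draws from its own RNG stream, seeded from
``GeneratorConfig.seed`` through a fixed offset table, so the different
fixture families can be regenerated independently and deterministically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    PALATABILITY_RANKS,
    TASTES,
    BehaviorSession,
    EnsembleRecording,
    GroundTruth,
    PowerSeries,
)

_STREAM_OFFSETS = {"lfp": 101, "ensemble": 202, "behavior": 303, "waveforms": 404}

#: Trial time axis: 1 s pre-delivery, 1.5 s post-delivery.
PRE_MS = 1000.0
POST_MS = 1500.0

# Within-trial modulation epochs (ms post delivery). The first 200 ms is
# deliberately left at baseline: early post-delivery activity is
# somatosensory, not chemosensory, and carries no taste information.
_EARLY = (200.0, 400.0)
_MIDDLE = (400.0, 700.0)
_LATE = (800.0, 1100.0)


@dataclass
class GeneratorConfig:
    """Study conditions for all synthetic fixtures.

    Defaults mirror the experimental design being emulated: a 20-minute
    post-injection observation window in 1-minute bins, 4 tastants x 30
    trials delivered to ~20-neuron ensembles in 25 ms bins, a band-power
    mean shift of 3x the noise SD around minute 15, and rearing durations
    that collapse after a sickness onset near minute 12.
    """

    n_animals: int = 7
    session_minutes: int = 20
    power_noise_sd: float = 1.0
    power_shift: float = 3.0
    true_tau: float = 15.0
    n_neurons: int = 20
    n_trials_per_taste: int = 30
    bin_ms: float = 25.0
    baseline_rate: float = 7.0
    identity_effect: float = 0.2
    palatability_gain: float = 0.25
    illness_magnitude_shrink: float = 0.3
    illness_identity_loss: float = 0.4
    illness_palatability_boost: float = 0.5
    frac_inhibitory: float = 0.3
    rearing_rate: float = 3.0  # events / minute
    rearing_mean_duration: float = 4.0  # seconds
    sickness_onset: float = 12.0  # minutes
    duration_drop: float = 0.6
    #: amplitude (in noise-SD units) of a post-handling power transient
    #: shared by an animal's two sessions; 0 = stationary noise
    session_profile_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "illness_magnitude_shrink": self.illness_magnitude_shrink,
            "illness_identity_loss": self.illness_identity_loss,
            "illness_palatability_boost": self.illness_palatability_boost,
            "frac_inhibitory": self.frac_inhibitory,
            "duration_drop": self.duration_drop,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not 0 < self.true_tau < self.session_minutes:
            raise ValueError(
                f"true_tau must lie in (0, {self.session_minutes}), got {self.true_tau}"
            )
        if not 0 < self.sickness_onset < self.session_minutes:
            raise ValueError(
                f"sickness_onset must lie in (0, {self.session_minutes}),"
                f" got {self.sickness_onset}"
            )
        if self.n_trials_per_taste < 6:
            raise ValueError("n_trials_per_taste must be >= 6 (5 training + 1 test)")
        for name in ("n_animals", "n_neurons", "session_minutes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic RNG for one generator family."""
        return np.random.default_rng([int(self.seed), _STREAM_OFFSETS[stream]])


# ---------------------------------------------------------------------------
# LFP band power
# ---------------------------------------------------------------------------

def gen_lfp_power(
    cfg: GeneratorConfig,
    signs: list[int] | None = None,
    condition: str = "licl",
) -> tuple[list[PowerSeries], GroundTruth]:
    """Per-animal 1-min-binned band power with a planted mean shift.

    Each animal's series is Gaussian noise (SD ``power_noise_sd``) whose
    mean jumps by ``power_shift`` at ``true_tau`` minutes.  The sign of
    the jump alternates across animals by default (illness changes band
    power in either direction depending on the individual); pass
    ``signs`` to override.  ``power_shift=0`` yields stationary noise.
    """
    rng = cfg.rng("lfp")
    if signs is None:
        signs = [1 if i % 2 == 0 else -1 for i in range(cfg.n_animals)]
    if len(signs) != cfg.n_animals:
        raise ValueError("one shift sign per animal required")
    n = cfg.session_minutes
    # bin centers: minute bin i covers (i, i+1], center i + 0.5
    centers = np.arange(n) + 0.5
    series: list[PowerSeries] = []
    truth = GroundTruth()
    for i in range(cfg.n_animals):
        animal = f"a{i:02d}"
        vals = rng.normal(0.0, cfg.power_noise_sd, size=n)
        vals[centers >= cfg.true_tau] += signs[i] * cfg.power_shift
        series.append(PowerSeries(animal_id=animal, condition=condition, values=vals))
        truth.true_tau_min[animal] = cfg.true_tau if cfg.power_shift != 0 else np.nan
        truth.shift_sign[animal] = int(signs[i])
    return series, truth


def gen_lfp_experiment(
    cfg: GeneratorConfig, n_control: int = 5
) -> tuple[list[tuple[PowerSeries, PowerSeries]], list[tuple[PowerSeries, PowerSeries]], GroundTruth]:
    """Paired (saline, licl) series for the experimental group and paired
    (saline, saline) series for the control group.

    Only the experimental group's second session carries the planted
    shift; all other sessions are stationary noise.
    """
    rng = cfg.rng("lfp")
    n = cfg.session_minutes
    centers = np.arange(n) + 0.5
    signs = [1 if i % 2 == 0 else -1 for i in range(cfg.n_animals)]
    truth = GroundTruth()

    def profile() -> np.ndarray:
        # post-handling transient, common to an animal's two sessions
        if cfg.session_profile_amp == 0:
            return np.zeros(n)
        amp = cfg.session_profile_amp * cfg.power_noise_sd * rng.uniform(0.7, 1.3)
        return amp * np.exp(-centers / 4.0)

    exp_pairs = []
    for i in range(cfg.n_animals):
        animal = f"exp{i:02d}"
        base = profile()
        sal = PowerSeries(animal, "saline", base + rng.normal(0, cfg.power_noise_sd, n))
        vals = base + rng.normal(0, cfg.power_noise_sd, n)
        vals[centers >= cfg.true_tau] += signs[i] * cfg.power_shift
        lic = PowerSeries(animal, "licl", vals)
        exp_pairs.append((sal, lic))
        truth.true_tau_min[animal] = cfg.true_tau if cfg.power_shift != 0 else np.nan
        truth.shift_sign[animal] = signs[i]
    ctrl_pairs = []
    for i in range(n_control):
        animal = f"ctl{i:02d}"
        base = profile()
        a = PowerSeries(animal, "saline", base + rng.normal(0, cfg.power_noise_sd, n))
        b = PowerSeries(animal, "saline", base + rng.normal(0, cfg.power_noise_sd, n))
        ctrl_pairs.append((a, b))
    return exp_pairs, ctrl_pairs, truth


# ---------------------------------------------------------------------------
# Ensemble spike data
# ---------------------------------------------------------------------------

# Held-unit condition motifs: (saline direction, licl multiplier applied
# to the saline modulation).  Cluster 1 flips excitatory -> inhibitory,
# cluster 2 the reverse, cluster 3 keeps excitation but weakens it.
_HELD_MOTIFS = {
    1: (+1.0, -0.8),
    2: (-0.8, +1.0),
    3: (+1.0, +0.4),
}


def _centered_ranks() -> np.ndarray:
    """Palatability ranks mapped to a zero-mean, unit-max code."""
    r = np.array([PALATABILITY_RANKS[t] for t in TASTES], dtype=float)
    r -= r.mean()
    return r / np.abs(r).max()  # sucrose=+1 ... quinine=-1


def gen_ensemble_pair(
    cfg: GeneratorConfig,
    n_held: int = 0,
    tastes: tuple[str, ...] = TASTES,
    shrink_excitatory_only: bool = False,
) -> tuple[EnsembleRecording, EnsembleRecording, GroundTruth]:
    """A matched (saline, licl) pair of ensemble recordings.

    Trial spike counts are Poisson with a piecewise-constant rate: the
    baseline holds through the first 200 ms post-delivery (no taste
    information there), a taste-independent response occupies the early
    epoch, taste-identity separation (scaled by ``identity_effect``)
    appears in the middle epoch, and late-epoch firing is monotone in
    palatability rank (scaled by ``palatability_gain``).  The licl
    session shrinks response magnitudes, degrades identity separation,
    and boosts the palatability component, leaving the baseline intact.
    The first ``n_held`` neurons are flagged as held across sessions and
    realize the three condition-change motifs in planted clusters.
    """
    if len(tastes) < 4:
        raise ValueError("at least the 4 canonical tastes are required")
    rng = cfg.rng("ensemble")
    n_neur, n_tr = cfg.n_neurons, cfg.n_trials_per_taste
    if n_held > n_neur:
        raise ValueError("n_held cannot exceed n_neurons")

    # Per-neuron parameters, shared across conditions.
    baseline = rng.gamma(4.0, cfg.baseline_rate / 4.0, size=n_neur)
    inhibitory = rng.random(n_neur) < cfg.frac_inhibitory
    direction = np.where(inhibitory, -1.0, 1.0)
    resp_strength = rng.uniform(0.4, 1.0, size=n_neur)
    tuning = rng.normal(0.0, 1.0, size=(n_neur, len(tastes)))
    tuning -= tuning.mean(axis=1, keepdims=True)  # identity code, mean-free
    pal_sign = np.where(rng.random(n_neur) < 0.5, 1.0, -1.0)
    pal_strength = rng.uniform(0.5, 1.0, size=n_neur) * pal_sign

    truth = GroundTruth(sickness_onset_min=cfg.sickness_onset)
    neuron_ids = [f"n{i:03d}" for i in range(n_neur)]
    for nid, inh in zip(neuron_ids, inhibitory):
        truth.response_direction[nid] = "inhibitory" if inh else "excitatory"

    held_motif = np.zeros(n_neur, dtype=int)
    held_amp = rng.uniform(0.6, 1.0, size=n_neur)
    for j in range(n_held):
        cluster = (j % 3) + 1
        held_motif[j] = cluster
        truth.cluster_id[neuron_ids[j]] = cluster
        truth.response_direction[neuron_ids[j]] = (
            "inhibitory" if _HELD_MOTIFS[cluster][0] < 0 else "excitatory"
        )

    # Trial structure: pseudo-random taste order, same labels per session.
    labels = np.repeat(np.array(tastes[:4]), n_tr)
    rng.shuffle(labels)
    taste_idx = np.array([tastes.index(t) for t in labels])

    n_bins = int(round((PRE_MS + POST_MS) / cfg.bin_ms))
    t0_bin = int(round(PRE_MS / cfg.bin_ms))
    starts = (np.arange(n_bins) - t0_bin) * cfg.bin_ms
    in_early = (starts >= _EARLY[0]) & (starts < _EARLY[1])
    in_middle = (starts >= _MIDDLE[0]) & (starts < _MIDDLE[1])
    in_late = (starts >= _LATE[0]) & (starts < _LATE[1])
    in_evoked = (starts >= _EARLY[0]) & (starts < _LATE[1])
    pal_code = _centered_ranks()

    recs: dict[str, EnsembleRecording] = {}
    for cond in CONDITIONS:
        ill = cond == "licl"
        amp = direction * resp_strength
        if ill:
            shrink = np.where(
                inhibitory if shrink_excitatory_only else False,
                0.0,
                cfg.illness_magnitude_shrink,
            )
            amp = amp * (1.0 - shrink)
        # Held units follow their planted motif instead.
        for j in range(n_held):
            sal_m, lic_m = _HELD_MOTIFS[held_motif[j]]
            amp[j] = held_amp[j] * (lic_m if ill else sal_m)
        idt = cfg.identity_effect * (1.0 - cfg.illness_identity_loss if ill else 1.0)
        pal = cfg.palatability_gain * (
            1.0 + cfg.illness_palatability_boost if ill else 1.0
        )

        # modulation (neurons, trials, bins), relative to baseline = 1
        mod = np.ones((n_neur, len(labels), n_bins))
        mod += in_evoked[None, None, :] * amp[:, None, None]
        mod += in_middle[None, None, :] * (idt * tuning[:, taste_idx])[:, :, None]
        mod += in_late[None, None, :] * (
            pal * pal_strength[:, None] * pal_code[taste_idx][None, :]
        )[:, :, None]
        rate = baseline[:, None, None] * np.clip(mod, 0.05, None)
        counts = rng.poisson(rate * (cfg.bin_ms / 1000.0))
        recs[cond] = EnsembleRecording(
            counts=counts,
            bin_ms=cfg.bin_ms,
            t0_bin=t0_bin,
            tastes=labels.copy(),
            condition=cond,
            neuron_ids=list(neuron_ids),
        )
    return recs["saline"], recs["licl"], truth


def gen_drifting_ensemble(
    cfg: GeneratorConfig,
    onset_trial: int | None = None,
    trials_per_min: float = 3.0,
) -> tuple[EnsembleRecording, GroundTruth]:
    """A single session whose taste coding degrades mid-session.

    Emulates the protocol where tastes are delivered immediately after
    the emetic injection: trials are in chronological order, and from
    ``onset_trial`` onward (default: the trial nearest
    ``cfg.sickness_onset`` at ``trials_per_min``) the identity separation
    is scaled down by ``illness_identity_loss`` and response magnitudes
    by ``illness_magnitude_shrink``.  ``onset_trial=None`` with
    effect fractions of zero yields a stationary session.
    """
    rng = cfg.rng("ensemble")
    n_neur, n_tr = cfg.n_neurons, cfg.n_trials_per_taste
    if onset_trial is None:
        onset_trial = int(round(cfg.sickness_onset * trials_per_min))
    baseline = rng.gamma(4.0, cfg.baseline_rate / 4.0, size=n_neur)
    inhibitory = rng.random(n_neur) < cfg.frac_inhibitory
    direction = np.where(inhibitory, -1.0, 1.0)
    resp_strength = rng.uniform(0.4, 1.0, size=n_neur)
    tuning = rng.normal(0.0, 1.0, size=(n_neur, 4))
    tuning -= tuning.mean(axis=1, keepdims=True)
    pal_strength = rng.uniform(0.5, 1.0, size=n_neur) * np.where(
        rng.random(n_neur) < 0.5, 1.0, -1.0
    )
    labels = np.repeat(np.array(TASTES), n_tr)
    rng.shuffle(labels)
    taste_idx = np.array([TASTES.index(t) for t in labels])

    n_bins = int(round((PRE_MS + POST_MS) / cfg.bin_ms))
    t0_bin = int(round(PRE_MS / cfg.bin_ms))
    starts = (np.arange(n_bins) - t0_bin) * cfg.bin_ms
    in_middle = (starts >= _MIDDLE[0]) & (starts < _MIDDLE[1])
    in_late = (starts >= _LATE[0]) & (starts < _LATE[1])
    in_evoked = (starts >= _EARLY[0]) & (starts < _LATE[1])
    pal_code = _centered_ranks()

    sick = np.arange(len(labels)) >= onset_trial  # chronological order
    idt = cfg.identity_effect * np.where(sick, 1.0 - cfg.illness_identity_loss, 1.0)
    amp_scale = np.where(sick, 1.0 - cfg.illness_magnitude_shrink, 1.0)
    amp = direction * resp_strength
    mod = np.ones((n_neur, len(labels), n_bins))
    mod += in_evoked[None, None, :] * (amp[:, None] * amp_scale[None, :])[:, :, None]
    mod += in_middle[None, None, :] * (idt[None, :] * tuning[:, taste_idx])[:, :, None]
    mod += in_late[None, None, :] * (
        cfg.palatability_gain * pal_strength[:, None] * pal_code[taste_idx][None, :]
    )[:, :, None]
    rate = baseline[:, None, None] * np.clip(mod, 0.05, None)
    counts = rng.poisson(rate * (cfg.bin_ms / 1000.0))
    truth = GroundTruth(sickness_onset_min=onset_trial / trials_per_min)
    for i, inh in enumerate(inhibitory):
        truth.response_direction[f"n{i:03d}"] = "inhibitory" if inh else "excitatory"
    rec = EnsembleRecording(
        counts=counts,
        bin_ms=cfg.bin_ms,
        t0_bin=t0_bin,
        tastes=labels,
        condition="licl",
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Rearing behavior
# ---------------------------------------------------------------------------

def gen_behavior(
    cfg: GeneratorConfig,
    n_saline: int = 4,
    n_licl: int = 5,
) -> tuple[list[BehaviorSession], GroundTruth]:
    """Rearing event streams for a saline and a licl cohort.

    Events arrive as a Poisson process at ``rearing_rate`` per minute;
    durations are lognormal with mean ``rearing_mean_duration``.  In licl
    sessions, events starting after ``sickness_onset`` have their
    durations scaled by ``1 - duration_drop``; scaled events shorter than
    the 0.5 s scoring threshold are censored (a scorer would not count
    them), mirroring how brief rears vanish from real scored data.
    """
    rng = cfg.rng("behavior")
    sigma = 0.4
    mu = np.log(cfg.rearing_mean_duration) - sigma**2 / 2.0
    truth = GroundTruth(sickness_onset_min=cfg.sickness_onset)
    sessions: list[BehaviorSession] = []
    for cond, n_sess in (("saline", n_saline), ("licl", n_licl)):
        for i in range(n_sess):
            n_events = rng.poisson(cfg.rearing_rate * cfg.session_minutes)
            onsets = np.sort(rng.uniform(0, cfg.session_minutes * 60.0, n_events))
            durations = rng.lognormal(mu, sigma, n_events)
            if cond == "licl":
                post = onsets >= cfg.sickness_onset * 60.0
                durations = np.where(
                    post, durations * (1.0 - cfg.duration_drop), durations
                )
            keep = durations >= 0.5
            events = list(zip(onsets[keep].tolist(), durations[keep].tolist()))
            sessions.append(
                BehaviorSession(
                    session_id=f"{cond[:3]}{i:02d}",
                    condition=cond,
                    events=events,
                    session_minutes=cfg.session_minutes,
                )
            )
    return sessions, truth


# ---------------------------------------------------------------------------
# Spike waveforms for held-unit stability
# ---------------------------------------------------------------------------

def _spike_template(n_samples: int, amplitude: float, width: float) -> np.ndarray:
    """Biphasic extracellular spike shape: sharp trough, slow rebound."""
    t = np.linspace(-1.0, 2.0, n_samples)
    trough = -amplitude * np.exp(-0.5 * (t / width) ** 2)
    rebound = 0.45 * amplitude * np.exp(-0.5 * ((t - 0.9) / (2.2 * width)) ** 2)
    return trough + rebound


def gen_waveform_pair(
    cfg: GeneratorConfig,
    n_spikes: int = 150,
    n_samples: int = 40,
    amp_scale_b: float = 1.0,
    noise_sd: float = 8.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two sessions' waveform sets for one unit.

    Session B uses the same mean shape as session A when
    ``amp_scale_b == 1`` (a genuinely held unit); other values plant a
    different neuron in session B.  Returns arrays (n_spikes, n_samples).
    """
    if rng is None:
        rng = cfg.rng("waveforms")
    amp = rng.uniform(60.0, 120.0)
    width = rng.uniform(0.15, 0.3)
    shape_a = _spike_template(n_samples, amp, width)
    shape_b = _spike_template(n_samples, amp * amp_scale_b, width)
    wf_a = shape_a[None, :] + rng.normal(0, noise_sd, (n_spikes, n_samples))
    wf_b = shape_b[None, :] + rng.normal(0, noise_sd, (n_spikes, n_samples))
    return wf_a, wf_b


# ---------------------------------------------------------------------------
# Fixture tables on disk
# ---------------------------------------------------------------------------

def trials_table(rec: EnsembleRecording) -> pd.DataFrame:
    """Long-form trials table (one row per neuron x trial x bin)."""
    n_neur, n_tr, n_bins = rec.counts.shape
    neuron, trial, b = np.meshgrid(
        np.arange(n_neur), np.arange(n_tr), np.arange(n_bins), indexing="ij"
    )
    starts = rec.bin_starts_ms()
    return pd.DataFrame(
        {
            "neuron_id": np.asarray(rec.neuron_ids)[neuron.ravel()],
            "trial_id": trial.ravel(),
            "taste": rec.tastes[trial.ravel()],
            "condition": rec.condition,
            "bin_start_ms": starts[b.ravel()],
            "count": rec.counts.ravel(),
        }
    )


def events_table(sessions: list[BehaviorSession]) -> pd.DataFrame:
    rows = [
        (s.session_id, s.condition, onset, dur)
        for s in sessions
        for onset, dur in s.events
    ]
    return pd.DataFrame(rows, columns=["session_id", "condition", "onset_s", "duration_s"])


def power_table(series: list[PowerSeries]) -> pd.DataFrame:
    rows = [
        (s.animal_id, s.condition, m, v)
        for s in series
        for m, v in enumerate(s.values)
    ]
    return pd.DataFrame(rows, columns=["animal_id", "condition", "minute_bin", "power"])


def write_fixture_bundle(
    out_dir: str | Path,
    cfg: GeneratorConfig,
    n_held: int = 0,
) -> dict[str, Path]:
    """Generate and write the full fixture set (CSV + ground-truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    series, lfp_truth = gen_lfp_power(cfg)
    paths["power"] = out / "power.csv"
    power_table(series).to_csv(paths["power"], index=False)

    sal, lic, ens_truth = gen_ensemble_pair(cfg, n_held=n_held)
    paths["trials"] = out / "trials.csv"
    pd.concat([trials_table(sal), trials_table(lic)]).to_csv(
        paths["trials"], index=False
    )

    sessions, beh_truth = gen_behavior(cfg)
    paths["events"] = out / "events.csv"
    events_table(sessions).to_csv(paths["events"], index=False)

    truth = {
        "true_tau_min": lfp_truth.true_tau_min,
        "shift_sign": lfp_truth.shift_sign,
        "response_direction": ens_truth.response_direction,
        "cluster_id": ens_truth.cluster_id,
        "palatability_ranks": ens_truth.palatability_ranks,
        "sickness_onset_min": beh_truth.sickness_onset_min,
        "config": asdict(cfg),
    }
    paths["truth"] = out / "ground_truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2, default=float))
    return paths


def read_trials_csv(path: str | Path) -> dict[str, EnsembleRecording]:
    """Rebuild EnsembleRecordings (one per condition) from a trials table."""
    df = pd.read_csv(path)
    out: dict[str, EnsembleRecording] = {}
    for cond, sub in df.groupby("condition"):
        neurons = sorted(sub["neuron_id"].unique())
        trials = np.sort(sub["trial_id"].unique())
        starts = np.sort(sub["bin_start_ms"].unique())
        bin_ms = float(np.diff(starts).min())
        pivot = sub.set_index(["neuron_id", "trial_id", "bin_start_ms"])["count"]
        counts = (
            pivot.unstack(["trial_id", "bin_start_ms"])  # type: ignore[arg-type]
            .loc[neurons]
            .to_numpy()
            .reshape(len(neurons), len(trials), len(starts))
        )
        tastes = (
            sub.drop_duplicates("trial_id").set_index("trial_id")["taste"].loc[trials]
        )
        out[str(cond)] = EnsembleRecording(
            counts=counts.astype(int),
            bin_ms=bin_ms,
            t0_bin=int(np.searchsorted(starts, 0)),
            tastes=tastes.to_numpy(),
            condition=str(cond),
            neuron_ids=[str(n) for n in neurons],
        )
    return out
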