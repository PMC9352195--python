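"""Generator contracts: determinism, planted effects, degenerate inputs."""

import numpy as np
import pytest

from gcstate.synth import (
    GeneratorConfig,
    gen_behavior,
    gen_drifting_ensemble,
    gen_ensemble_pair,
    gen_lfp_experiment,
    gen_lfp_power,
    gen_waveform_pair,
    power_table,
    read_trials_csv,
    trials_table,
    write_fixture_bundle,
)

from .conftest import NULL_EFFECTS
from .oracles import censored_scaled_duration_ratio


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"true_tau": 25.0},
            {"true_tau": 0.0},
            {"sickness_onset": -1.0},
            {"frac_inhibitory": 1.5},
            {"duration_drop": -0.1},
            {"n_trials_per_taste": 5},
            {"n_neurons": 0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_too_few_tastes_rejected(self):
        with pytest.raises(ValueError, match="4"):
            gen_ensemble_pair(GeneratorConfig(seed=0), tastes=("sucrose", "nacl"))


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        for gen in (
            lambda c: gen_lfp_power(c)[0][0].values,
            lambda c: gen_ensemble_pair(c)[1].counts,
            lambda c: np.array(
                [d for s in gen_behavior(c)[0] for _, d in s.events]
            ),
            lambda c: gen_waveform_pair(c)[0],
        ):
            a = gen(GeneratorConfig(seed=42))
            b = gen(GeneratorConfig(seed=42))
            np.testing.assert_array_equal(a, b)

    def test_streams_independent_of_call_order(self):
        # drawing the ensemble first must not perturb the LFP stream
        cfg = GeneratorConfig(seed=5)
        lfp_only = gen_lfp_power(GeneratorConfig(seed=5))[0][0].values
        gen_ensemble_pair(cfg)
        np.testing.assert_array_equal(gen_lfp_power(cfg)[0][0].values, lfp_only)


class TestLfpPower:
    def test_no_shift_is_stationary(self):
        series, truth = gen_lfp_power(GeneratorConfig(seed=1, power_shift=0.0))
        v = series[0].values
        # split-half means indistinguishable at 3 SE
        se = v.std(ddof=1) * np.sqrt(1 / 10 + 1 / 10)
        assert abs(v[10:].mean() - v[:10].mean()) < 3 * se
        assert np.isnan(truth.true_tau_min["a00"])

    def test_planted_shift_magnitude(self):
        # shift = 3x noise SD at tau=15: difference of segment means
        # estimates the shift with SE = sd * sqrt(1/5 + 1/15)
        cfg = GeneratorConfig(seed=2, power_shift=3.0, power_noise_sd=1.0, true_tau=15.0)
        series, truth = gen_lfp_power(cfg, signs=[1] * cfg.n_animals)
        se = 1.0 * np.sqrt(1 / 5 + 1 / 15)
        diffs = [s.values[15:].mean() - s.values[:15].mean() for s in series]
        # average over animals tightens the check; each animal within 3 SE
        for d in diffs:
            assert abs(d - 3.0) < 3 * se
        assert all(t == 15.0 for t in truth.true_tau_min.values())

    def test_shift_signs_alternate(self):
        series, truth = gen_lfp_power(GeneratorConfig(seed=3, n_animals=7))
        signs = [truth.shift_sign[s.animal_id] for s in series]
        assert signs == [1, -1, 1, -1, 1, -1, 1]

    def test_experiment_control_pairs_stationary(self):
        _, ctrl, _ = gen_lfp_experiment(GeneratorConfig(seed=4))
        assert all(a.condition == b.condition == "saline" for a, b in ctrl)


class TestEnsemble:
    def test_baseline_poisson_mean(self):
        # 250 ms pre-stimulus window: mean count ~ per-neuron rate * 0.25
        cfg = GeneratorConfig(seed=6, n_neurons=30)
        sal, _, _ = gen_ensemble_pair(cfg)
        counts = sal.window_counts(-500.0, -250.0)  # (neurons, trials)
        mean_all = counts.mean()
        expected = counts.mean(axis=1)  # per-neuron empirical
        # pooled across 30x120 draws: SE of the grand mean under Poisson
        se = np.sqrt(mean_all / counts.size)
        # grand mean must sit near the per-neuron rate average (3 SE +
        # allowance for gamma spread already realized in expected)
        assert abs(mean_all - expected.mean()) < 3 * se + 1e-9

    def test_first_200ms_carries_no_taste_information(self):
        cfg = GeneratorConfig(seed=8, n_neurons=40)
        sal, lic, _ = gen_ensemble_pair(cfg)
        from scipy import stats

        for rec in (sal, lic):
            early = rec.window_rates(0.0, 200.0).mean(axis=0)  # per trial
            groups = [early[rec.tastes == t] for t in np.unique(rec.tastes)]
            assert stats.f_oneway(*groups).pvalue > 0.01

    def test_null_construction_is_exchangeable(self):
        cfg = GeneratorConfig(
            seed=9, n_neurons=40, identity_effect=0.0, palatability_gain=0.0,
            **NULL_EFFECTS,
        )
        sal, _, _ = gen_ensemble_pair(cfg)
        late = sal.window_rates(800.0, 1100.0)
        per_taste = np.array(
            [late[:, sal.tastes == t].mean() for t in np.unique(sal.tastes)]
        )
        assert per_taste.max() - per_taste.min() < 0.5  # Hz

    def test_baseline_unchanged_by_illness(self):
        sal, lic, _ = gen_ensemble_pair(GeneratorConfig(seed=10, n_neurons=40))
        b_s = sal.window_rates(-1000.0, 0.0).mean()
        b_l = lic.window_rates(-1000.0, 0.0).mean()
        assert abs(b_s - b_l) < 0.3  # Hz; same planted baselines

    def test_held_units_get_cluster_ids(self):
        _, _, truth = gen_ensemble_pair(GeneratorConfig(seed=11), n_held=9)
        assert len(truth.cluster_id) == 9
        assert sorted(set(truth.cluster_id.values())) == [1, 2, 3]

    def test_drifting_ensemble_onset(self):
        cfg = GeneratorConfig(seed=12, illness_identity_loss=1.0)
        rec, truth = gen_drifting_ensemble(cfg, onset_trial=40)
        assert truth.sickness_onset_min == pytest.approx(40 / 3.0)
        assert rec.n_trials == 4 * cfg.n_trials_per_taste


class TestBehavior:
    def test_no_drop_same_law(self):
        cfg = GeneratorConfig(seed=13, duration_drop=0.0)
        sessions, _ = gen_behavior(cfg, n_saline=30, n_licl=30)
        durs = {
            c: np.array([d for s in sessions if s.condition == c for _, d in s.events])
            for c in ("saline", "licl")
        }
        for q in (25, 50, 75):
            a, b = np.percentile(durs["saline"], q), np.percentile(durs["licl"], q)
            assert abs(a - b) / a < 0.1

    def test_post_onset_drop_matches_censored_oracle(self):
        cfg = GeneratorConfig(seed=14, duration_drop=0.8, sickness_onset=12.0)
        sessions, _ = gen_behavior(cfg, n_saline=0, n_licl=60)
        pre, post = [], []
        for s in sessions:
            for onset, dur in s.events:
                (pre if onset < 12 * 60 else post).append(dur)
        observed = np.mean(post) / np.mean(pre)
        expected = censored_scaled_duration_ratio(
            cfg.rearing_mean_duration, cfg.duration_drop
        )
        assert observed == pytest.approx(expected, rel=0.1)

    def test_moderate_drop_matches_naive_factor(self):
        # at drop=0.4 essentially nothing is censored, so the mean ratio
        # is just (1 - drop)
        cfg = GeneratorConfig(seed=15, duration_drop=0.4, sickness_onset=10.0)
        sessions, _ = gen_behavior(cfg, n_saline=0, n_licl=60)
        pre = [d for s in sessions for o, d in s.events if o < 600]
        post = [d for s in sessions for o, d in s.events if o >= 600]
        assert np.mean(post) / np.mean(pre) == pytest.approx(0.6, rel=0.08)

    def test_zero_rate_empty_sessions(self):
        cfg = GeneratorConfig(seed=16, rearing_rate=0.0)
        sessions, _ = gen_behavior(cfg)
        assert all(not s.events for s in sessions)


class TestFixtureTables:
    def test_trials_roundtrip(self, tmp_path, small_cfg):
        sal, lic, _ = gen_ensemble_pair(small_cfg)
        path = tmp_path / "trials.csv"
        import pandas as pd

        pd.concat([trials_table(sal), trials_table(lic)]).to_csv(path, index=False)
        recs = read_trials_csv(path)
        np.testing.assert_array_equal(recs["saline"].counts, sal.counts)
        np.testing.assert_array_equal(recs["licl"].tastes, lic.tastes)
        assert recs["licl"].t0_bin == lic.t0_bin

    def test_bundle_files_exist(self, tmp_path):
        cfg = GeneratorConfig(seed=17, n_neurons=6, n_trials_per_taste=6, n_animals=2)
        paths = write_fixture_bundle(tmp_path, cfg, n_held=3)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        pw = power_table(gen_lfp_power(cfg)[0])
        assert set(pw.columns) == {"animal_id", "condition", "minute_bin", "power"}
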