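"""Moving-window rank correlation and the pure palatability index."""

import numpy as np
import pytest

from gcstate.datatypes import (
    PALATABILITY_RANKS,
    TASTES,
    EnsembleRecording,
    EpochDefinition,
)
from gcstate.palatability import (
    compute_ppi,
    moving_spearman,
    ppi_tests,
    spearman_condition_test,
)
from gcstate.synth import GeneratorConfig, gen_ensemble_pair

from .conftest import NULL_EFFECTS, make_recording
from .oracles import permutation_mean_abs_spearman


def deterministic_recording(rate_by_taste, n_trials_per_taste=8, value_window=None):
    """Noise-free recording: every bin's count equals a taste-specific value
    (inside value_window if given, else everywhere post-delivery)."""
    labels = np.repeat(np.array(TASTES), n_trials_per_taste)
    n_bins, t0 = 100, 40
    counts = np.zeros((1, labels.size, n_bins), dtype=int)
    starts = (np.arange(n_bins) - t0) * 25.0
    if value_window is None:
        sel = starts >= 0
    else:
        sel = (starts >= value_window[0]) & (starts < value_window[1])
    for taste, val in rate_by_taste.items():
        counts[0, labels == taste][:, :] = 0
        block = counts[0, labels == taste, :]
        block[:, sel] = val
        counts[0, labels == taste, :] = block
    return EnsembleRecording(
        counts=counts, bin_ms=25.0, t0_bin=t0, tastes=labels, condition="saline"
    )


class TestMovingSpearman:
    def test_rates_equal_ranks_give_rho_one(self):
        rec = deterministic_recording(
            {t: PALATABILITY_RANKS[t] for t in TASTES}
        )
        trace = moving_spearman(rec, t_range_ms=(0.0, 1200.0))
        assert np.nanmin(trace.rho) == pytest.approx(1.0)

    def test_anti_ordered_rates_give_rho_minus_one(self):
        rec = deterministic_recording(
            {t: 5 - PALATABILITY_RANKS[t] for t in TASTES}
        )
        trace = moving_spearman(rec, t_range_ms=(0.0, 1200.0))
        assert np.nanmax(trace.rho) == pytest.approx(-1.0)

    def test_null_matches_permutation_expectation(self):
        cfg = GeneratorConfig(
            seed=0, n_neurons=60, identity_effect=0.0, palatability_gain=0.0,
            **NULL_EFFECTS,
        )
        sal, _, _ = gen_ensemble_pair(cfg)
        trace = moving_spearman(sal)
        late = trace.epoch_values(EpochDefinition(), "abs_rho")
        obs = late.loc[late["epoch"] == "late", "value"].mean()
        ranks = np.array([PALATABILITY_RANKS[t] for t in sal.tastes], float)
        expected = permutation_mean_abs_spearman(ranks, seed=1)
        assert obs == pytest.approx(expected, rel=0.2)
        assert abs(np.nanmean(trace.rho)) < 0.03  # signed mean ~ 0

    def test_missing_taste_rejected(self):
        rec = make_recording(None, seed=1)
        sub = EnsembleRecording(
            counts=rec.counts[:, rec.tastes != "quinine"],
            bin_ms=rec.bin_ms, t0_bin=rec.t0_bin,
            tastes=rec.tastes[rec.tastes != "quinine"], condition="saline",
        )
        with pytest.raises(ValueError, match="quinine"):
            moving_spearman(sub)

    def test_illness_boost_raises_late_correlation(self):
        cfg = GeneratorConfig(seed=2, n_neurons=40, illness_palatability_boost=1.0)
        sal, lic, _ = gen_ensemble_pair(cfg)
        rep = spearman_condition_test(moving_spearman(sal), moving_spearman(lic))
        assert rep["late"]["licl_mean"] > rep["late"]["saline_mean"]
        assert rep["late"]["p"] < 0.05


class TestPPI:
    def test_hand_computed_toy(self):
        """2-bin toy with hand-computable distances.

        Late-epoch central 50 ms = 2 bins at 25 ms.  Counts per bin:
        sucrose 4, NaCl 3, CA 1, quinine 0 -> rates 160, 120, 40, 0 Hz.
        All pair distances are |r_a - r_b| (flat vectors, /sqrt(2) bins
        scaling cancels): D_sim = (40 + 40)/2 = 40,
        D_dis = (120 + 160 + 80 + 120)/4 = 120, PPI = 80.
        """
        rec = deterministic_recording(
            {"sucrose": 4, "nacl": 3, "citric_acid": 1, "quinine": 0},
            value_window=(800.0, 1100.0),
        )
        ppi = compute_ppi(rec, central_ms=50.0)
        late = ppi[ppi["epoch"] == "late"].iloc[0]
        assert late["d_similar"] == pytest.approx(40.0)
        assert late["d_dissimilar"] == pytest.approx(120.0)
        assert late["ppi"] == pytest.approx(80.0)

    def test_pure_good_bad_code(self):
        rec = deterministic_recording(
            {"sucrose": 3, "nacl": 3, "citric_acid": 0, "quinine": 0},
            value_window=(800.0, 1100.0),
        )
        late = compute_ppi(rec).query("epoch == 'late'").iloc[0]
        assert late["d_similar"] == 0.0
        assert late["ppi"] > 0
        norm = compute_ppi(rec, mode="normalized").query("epoch == 'late'").iloc[0]
        assert norm["ppi"] == pytest.approx(1.0)

    def test_translation_invariance(self):
        rec = deterministic_recording(
            {"sucrose": 5, "nacl": 4, "citric_acid": 2, "quinine": 1},
            value_window=(800.0, 1100.0),
        )
        shifted_counts = rec.counts.copy()
        starts = rec.bin_starts_ms()
        sel = (starts >= 800) & (starts < 1100)
        shifted_counts[:, :, sel] += 7  # same constant for every taste
        rec2 = EnsembleRecording(
            counts=shifted_counts, bin_ms=25.0, t0_bin=rec.t0_bin,
            tastes=rec.tastes, condition="saline",
        )
        a = compute_ppi(rec).query("epoch == 'late'")["ppi"].iloc[0]
        b = compute_ppi(rec2).query("epoch == 'late'")["ppi"].iloc[0]
        assert a == pytest.approx(b)

    def test_difference_mode_linear_normalized_mode_scale_free(self):
        base = {"sucrose": 4, "nacl": 3, "citric_acid": 1, "quinine": 0}
        rec1 = deterministic_recording(base, value_window=(800.0, 1100.0))
        rec3 = deterministic_recording(
            {t: 3 * v for t, v in base.items()}, value_window=(800.0, 1100.0)
        )
        d1 = compute_ppi(rec1).query("epoch == 'late'")["ppi"].iloc[0]
        d3 = compute_ppi(rec3).query("epoch == 'late'")["ppi"].iloc[0]
        assert d3 == pytest.approx(3 * d1)
        n1 = compute_ppi(rec1, mode="normalized").query("epoch == 'late'")["ppi"].iloc[0]
        n3 = compute_ppi(rec3, mode="normalized").query("epoch == 'late'")["ppi"].iloc[0]
        assert n1 == pytest.approx(n3)

    def test_exchangeable_tastes_mean_ppi_near_zero(self):
        cfg = GeneratorConfig(
            seed=3, n_neurons=120, identity_effect=0.0, palatability_gain=0.0,
            **NULL_EFFECTS,
        )
        sal, _, _ = gen_ensemble_pair(cfg)
        vals = compute_ppi(sal).query("epoch == 'late'")["ppi"]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se + 1e-12

    def test_unknown_mode_rejected(self, default_pair):
        with pytest.raises(ValueError, match="mode"):
            compute_ppi(default_pair[0], mode="ratio")


class TestPPITests:
    def test_boost_raises_late_ppi(self):
        hits = 0
        for s in range(5):
            cfg = GeneratorConfig(seed=s, n_neurons=40, illness_palatability_boost=1.0)
            sal, lic, _ = gen_ensemble_pair(cfg)
            rep = ppi_tests(compute_ppi(sal), compute_ppi(lic))
            hits += (
                rep["late"]["between"]["p"] < 0.05
                and rep["late"]["licl_mean"] > rep["late"]["saline_mean"]
            )
        assert hits >= 4

    def test_identical_inputs_p_one(self, default_pair):
        ppi = compute_ppi(default_pair[0])
        rep = ppi_tests(ppi, ppi.copy())
        assert all(v["between"]["p"] == 1.0 for v in rep.values())

    def test_min_neuron_requirement(self):
        cfg = GeneratorConfig(seed=4, n_neurons=5)
        sal, lic, _ = gen_ensemble_pair(cfg)
        with pytest.raises(ValueError, match="10 neurons"):
            ppi_tests(compute_ppi(sal), compute_ppi(lic))
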