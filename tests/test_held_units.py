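"""Held-unit stability, response-difference vectors, GMM clustering, and
the cluster-specific palatability ANOVA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gcstate.held_units import (
    aligned_rank_anova,
    baseline_equivalence,
    cluster_palatability_anova,
    gmm_cluster,
    held_unit_test,
    response_difference_vectors,
    waveform_dissimilarity,
)
from gcstate.synth import GeneratorConfig, gen_ensemble_pair, gen_waveform_pair


def planted_rd_frame(rng, n_per_cluster=59, sep=5.0, within_sd=6.0):
    """RD points in 3 planted Gaussian clusters whose pairwise center
    distances are ``sep`` x the within-cluster SD (Fig-8-like geometry:
    ~176 points when n_per_cluster=59)."""
    # vertices of an equilateral triangle with side = sep * within_sd
    side = sep * within_sd
    r = side / np.sqrt(3.0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    centers = np.array([[r * np.cos(a), r * np.sin(a)] for a in angles])
    centers += np.array([20.0, 5.0])  # arbitrary offset of the RD cloud
    pts, labels = [], []
    for c, ctr in enumerate(centers):
        pts.append(ctr + rng.normal(0, within_sd, (n_per_cluster, 2)))
        labels += [c] * n_per_cluster
    X = np.vstack(pts)
    return (
        pd.DataFrame(
            {
                "neuron_id": [f"u{i}" for i in range(len(X))],
                "taste": "sucrose",
                "saline_resp": X[:, 0],
                "licl_resp": X[:, 1],
                "distance": np.hypot(*X.T),
                "angle": np.degrees(np.arctan2(X[:, 1], X[:, 0])) % 360,
            }
        ),
        np.array(labels),
    )


class TestHeldUnitTest:
    def test_same_shape_held(self):
        cfg = GeneratorConfig(seed=0)
        rng = cfg.rng("waveforms")
        held = 0
        for i in range(20):
            wa, wb = gen_waveform_pair(cfg, rng=rng)
            held += held_unit_test(wa, wb, seed=i).held
        assert held >= 19

    def test_doubled_amplitude_rejected(self):
        cfg = GeneratorConfig(seed=1)
        rng = cfg.rng("waveforms")
        rejected = 0
        for i in range(20):
            wa, wb = gen_waveform_pair(cfg, amp_scale_b=2.0, rng=rng)
            rejected += not held_unit_test(wa, wb, seed=i).held
        assert rejected >= 19

    def test_identical_sets_trivially_held(self):
        cfg = GeneratorConfig(seed=2)
        wa, _ = gen_waveform_pair(cfg)
        dec = held_unit_test(wa, wa, seed=0)
        assert dec.between_stat == 0.0 and dec.held

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            held_unit_test(np.zeros((60, 40)), np.zeros((60, 35)))

    def test_too_few_waveforms_rejected(self):
        with pytest.raises(ValueError, match="50 waveforms"):
            held_unit_test(np.zeros((10, 40)), np.zeros((60, 40)))

    def test_dissimilarity_is_symmetric_and_zero_on_self(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(80, 40))
        b = rng.normal(size=(80, 40)) + 1.0
        assert waveform_dissimilarity(a, a.copy()) == 0.0
        assert waveform_dissimilarity(a, b) == pytest.approx(
            waveform_dissimilarity(b, a)
        )


class TestRDVectors:
    def test_count_contract_44_units(self):
        cfg = GeneratorConfig(seed=4, n_neurons=44)
        sal, lic, truth = gen_ensemble_pair(cfg, n_held=44)
        rds = response_difference_vectors(sal, lic, list(truth.cluster_id))
        assert len(rds) == 176  # 44 held units x 4 tastes

    def test_quadrants_encode_motifs(self):
        cfg = GeneratorConfig(seed=5, n_neurons=30, baseline_rate=12.0)
        sal, lic, truth = gen_ensemble_pair(cfg, n_held=30)
        rds = response_difference_vectors(sal, lic, list(truth.cluster_id))
        rds["cluster"] = rds["neuron_id"].map(truth.cluster_id)
        # excitatory -> inhibitory units: saline response +, licl response -
        c1 = rds[rds["cluster"] == 1]
        assert ((c1["angle"] > 270) & (c1["angle"] < 360)).mean() > 0.8
        c2 = rds[rds["cluster"] == 2]  # inhibitory -> excitatory
        assert ((c2["angle"] > 90) & (c2["angle"] < 180)).mean() > 0.8

    def test_no_condition_change_small_distance(self):
        cfg = GeneratorConfig(seed=6, n_neurons=20, **{
            "illness_magnitude_shrink": 0.0,
            "illness_identity_loss": 0.0,
            "illness_palatability_boost": 0.0,
        })
        sal, lic, _ = gen_ensemble_pair(cfg)
        rds = response_difference_vectors(sal, lic)
        # no condition change: points hug the identity diagonal (equal
        # responses in both sessions), i.e. angles near 45 or 225 degrees
        corr = np.corrcoef(rds["saline_resp"], rds["licl_resp"])[0, 1]
        assert corr > 0.8
        off_diag = np.minimum(
            np.abs(rds["angle"] - 45.0), np.abs(rds["angle"] - 225.0)
        )
        assert (off_diag < 30.0).mean() > 0.8


class TestGMM:
    def test_planted_three_clusters_recovered(self):
        rng = np.random.default_rng(7)
        hits, aris = 0, []
        for s in range(10):
            rds, truth = planted_rd_frame(rng)
            res = gmm_cluster(rds, seed=s)
            hits += res.best_k == 3
            keep = res.labels >= 0
            aris.append(adjusted_rand_score(truth[keep], res.labels[keep]))
        assert hits >= 9
        assert np.mean(aris) > 0.9

    def test_single_gaussian_selects_k1(self):
        rng = np.random.default_rng(8)
        hits = 0
        for s in range(10):
            X = rng.normal(0, 10, (60, 2))
            rds = pd.DataFrame(
                {
                    "neuron_id": [f"u{i}" for i in range(60)],
                    "taste": "sucrose",
                    "saline_resp": X[:, 0],
                    "licl_resp": X[:, 1],
                    "distance": np.hypot(*X.T),
                    "angle": np.degrees(np.arctan2(X[:, 1], X[:, 0])) % 360,
                }
            )
            hits += gmm_cluster(rds, seed=s).best_k == 1
        assert hits >= 9

    def test_rotation_preserves_partition(self):
        rng = np.random.default_rng(9)
        rds, _ = planted_rd_frame(rng)
        res1 = gmm_cluster(rds, seed=0)
        th = np.deg2rad(35.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        XY = rds[["saline_resp", "licl_resp"]].to_numpy() @ R.T
        rds2 = rds.assign(saline_resp=XY[:, 0], licl_resp=XY[:, 1])
        res2 = gmm_cluster(rds2, seed=0)
        keep = (res1.labels >= 0) & (res2.labels >= 0)
        assert adjusted_rand_score(res1.labels[keep], res2.labels[keep]) == 1.0

    def test_angle_peaks_on_motif_fixture(self):
        cfg = GeneratorConfig(seed=10, n_neurons=45, baseline_rate=12.0)
        sal, lic, truth = gen_ensemble_pair(cfg, n_held=45)
        rds = response_difference_vectors(sal, lic, list(truth.cluster_id))
        res = gmm_cluster(rds, seed=0)
        assert res.n_angle_peaks >= 2  # three motifs, finite sampling

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(11)
        rds, _ = planted_rd_frame(rng, n_per_cluster=2)
        with pytest.raises(ValueError, match="10 RD"):
            gmm_cluster(rds.iloc[:6], seed=0)


def rho2_fixture(rng, boost_cluster=None, n_per_cluster=16, boost=0.15):
    rows = []
    for c in range(1, 4):
        for i in range(n_per_cluster):
            nid = f"c{c}u{i}"
            for epoch in ("early", "middle", "late"):
                for cond in ("saline", "licl"):
                    base = 0.05 + (0.1 if epoch == "late" else 0.0)
                    if (
                        boost_cluster == c
                        and epoch == "late"
                        and cond == "licl"
                    ):
                        base += boost
                    rows.append((nid, c, epoch, cond, base + rng.gamma(2, 0.02)))
    return pd.DataFrame(
        rows, columns=["neuron_id", "cluster", "epoch", "condition", "rho2"]
    )


class TestClusterAnova:
    def test_boosted_cluster_detected(self):
        rng = np.random.default_rng(12)
        rep = cluster_palatability_anova(rho2_fixture(rng, boost_cluster=3))
        assert rep["interaction"]["p"] < 0.05
        assert rep["late_epoch_followups"][3]["p"] < 0.05
        assert rep["late_epoch_followups"][3]["licl_minus_saline"] > 0

    def test_no_effect_usually_not_detected(self):
        rej = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            rep = cluster_palatability_anova(rho2_fixture(rng))
            rej += rep["interaction"]["p"] < 0.05
        assert rej <= 2

    def test_permuted_clusters_destroy_interaction(self):
        rng = np.random.default_rng(13)
        df = rho2_fixture(rng, boost_cluster=3)
        # permute cluster labels at the neuron level
        units = df["neuron_id"].unique()
        perm = dict(zip(units, rng.permutation(
            df.drop_duplicates("neuron_id").set_index("neuron_id")["cluster"]
        )))
        rej = 0
        for s in range(8):
            rng_s = np.random.default_rng(200 + s)
            df_s = rho2_fixture(rng_s, boost_cluster=3)
            perm_s = dict(zip(units, rng_s.permutation(
                df_s.drop_duplicates("neuron_id").set_index("neuron_id")["cluster"]
            )))
            df_s["cluster"] = df_s["neuron_id"].map(perm_s)
            rej += cluster_palatability_anova(df_s)["interaction"]["p"] < 0.05
        assert rej <= 2

    def test_small_cluster_dropped(self):
        rng = np.random.default_rng(14)
        df = rho2_fixture(rng)
        df = pd.concat(
            [df, df.iloc[:6].assign(neuron_id="lonely", cluster=9)],
            ignore_index=True,
        )
        rep = cluster_palatability_anova(df)
        assert 9 not in rep["late_epoch_followups"]

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(15)
        df = rho2_fixture(rng)
        with pytest.raises(ValueError, match="2 clusters"):
            cluster_palatability_anova(df[df["cluster"] == 1])

    def test_aligned_rank_anova_terms_complete(self):
        rng = np.random.default_rng(16)
        aov = aligned_rank_anova(
            rho2_fixture(rng), "rho2", ["cluster", "epoch", "condition"]
        )
        assert len(aov) == 7  # 3 mains + 3 two-way + 1 three-way


class TestBaselineEquivalence:
    def test_unchanged_baseline_non_significant(self):
        ok = 0
        for s in range(10):
            cfg = GeneratorConfig(seed=s, n_neurons=44)
            sal, lic, truth = gen_ensemble_pair(cfg, n_held=12)
            rep = baseline_equivalence(sal, lic)
            ok += rep["t_p"] > 0.05 and rep["ks_p"] > 0.05
        assert ok >= 9

    def test_planted_shift_detected(self):
        cfg = GeneratorConfig(seed=17, n_neurons=44)
        sal, lic, _ = gen_ensemble_pair(cfg)
        shifted = lic.counts.copy()
        sl = lic._bin_slice(-500.0, 0.0)
        shifted[:, :, sl] += 1  # ~2 Hz baseline elevation
        from gcstate.datatypes import EnsembleRecording

        lic2 = EnsembleRecording(
            counts=shifted, bin_ms=lic.bin_ms, t0_bin=lic.t0_bin,
            tastes=lic.tastes, condition="licl", neuron_ids=lic.neuron_ids,
        )
        assert baseline_equivalence(sal, lic2)["t_p"] < 0.01

    def test_zero_difference_t_zero(self):
        cfg = GeneratorConfig(seed=18)
        sal, _, _ = gen_ensemble_pair(cfg)
        rep = baseline_equivalence(sal, sal)
        assert rep["t"] == 0.0 and rep["t_p"] == 1.0
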