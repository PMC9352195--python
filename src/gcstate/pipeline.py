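"""End-to-end orchestration: synthesize fixtures, run every analysis
stage in dependency order, write machine-readable per-stage outputs and a
top-level summary.

Every stochastic stage receives a sub-seed derived deterministically from
the run seed, so a re-run with the same config is byte-identical.  The
summary is assembled purely from the per-stage JSON files (the reporter
recomputes nothing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import changepoint as cpt
from . import coupling as cpl
from . import decoding as dec
from . import held_units as held
from . import lfp
from . import palatability as pal
from . import synth
from . import taste_response as tr
from .datatypes import EpochDefinition

logger = logging.getLogger(__name__)

STAGES = (
    "synth",
    "lfp",
    "changepoint",
    "behavior",
    "coupling",
    "taste_response",
    "decoding",
    "palatability",
    "held_units",
)

_STAGE_SEED_OFFSET = {name: 17 + 13 * i for i, name in enumerate(STAGES)}

#: stage -> stages whose outputs it needs
_DEPENDS = {"coupling": ("changepoint", "behavior")}


@dataclass
class RunConfig:
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    alpha: float = 0.05
    n_shuffles: int = 50
    shuffle_percentile: float = 99.0
    n_held: int = 12
    out_dir: str = "gcstate_out"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        if self.n_held > self.generator.n_neurons:
            raise ValueError(
                f"n_held ({self.n_held}) exceeds generator n_neurons"
                f" ({self.generator.n_neurons})"
            )
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {"generator", "stages", "alpha", "n_shuffles",
                   "shuffle_percentile", "n_held", "out_dir", "seed"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        gen = synth.GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 9973 + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "to_dict"):  # DataFrames are dropped from JSON output
        return None
    return obj


def _write(out: Path, name: str, payload: dict) -> None:
    (out / f"{name}.json").write_text(
        json.dumps(_jsonable(payload), indent=2, sort_keys=True)
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator
    enabled = cfg.stages
    epochs = EpochDefinition()

    for stage, deps in _DEPENDS.items():
        if enabled.get(stage):
            missing = [d for d in deps if not enabled.get(d)]
            if missing:
                raise ValueError(
                    f"stage '{stage}' requires disabled stage(s): {missing}"
                )

    if enabled["synth"]:
        logger.info("stage=synth seed=%d", gen.seed)
        synth.write_fixture_bundle(out / "fixtures", gen, n_held=cfg.n_held)

    exp_pairs, ctrl_pairs, lfp_truth = synth.gen_lfp_experiment(gen)

    if enabled["lfp"]:
        logger.info("stage=lfp")
        rep = lfp.quartile_difference_anova(exp_pairs, ctrl_pairs)
        _write(out, "lfp", {"interaction": rep["interaction"],
                            "per_quartile": rep["per_quartile"]})

    if enabled["changepoint"]:
        seed = cfg.stage_seed("changepoint")
        logger.info("stage=changepoint seed=%d", seed)
        licl_series = [p[1].values for p in exp_pairs]
        results = cpt.batch_shuffle_detect(
            licl_series,
            n_shuffles=cfg.n_shuffles,
            percentile=cfg.shuffle_percentile,
            seed=seed,
        )
        payload = {
            "per_animal": {
                p[1].animal_id: {
                    "estimate_min": r.estimate,
                    "true_tau_min": lfp_truth.true_tau_min[p[1].animal_id],
                    "rhat": r.rhat,
                }
                for p, r in zip(exp_pairs, results)
            }
        }
        ests = [r.estimate for r in results if r.estimate is not None]
        payload["mean_estimate_min"] = float(np.mean(ests)) if ests else None
        _write(out, "changepoint", payload)

    if enabled["behavior"]:
        logger.info("stage=behavior")
        sessions, _ = synth.gen_behavior(gen)
        licl_s = [s for s in sessions if s.condition == "licl"]
        sal_s = [s for s in sessions if s.condition == "saline"]
        diff = beh.normalized_condition_difference(licl_s, sal_s)
        fit = beh.fit_sigmoid(diff["difference"])
        wil = beh.quartile_wilcoxon(licl_s, sal_s)
        _write(out, "behavior", {
            "sigmoid": {
                "midpoint_min": fit.midpoint,
                "onset_min": fit.onset_min,
                "r_squared": fit.r_squared,
                "degenerate": fit.degenerate,
            },
            "quartile_wilcoxon": wil,
        })

    if enabled["coupling"]:
        seed = cfg.stage_seed("coupling")
        logger.info("stage=coupling seed=%d", seed)
        cp_payload = json.loads((out / "changepoint.json").read_text())
        beh_payload = json.loads((out / "behavior.json").read_text())
        lfp_cps = [
            v["estimate_min"]
            for v in cp_payload["per_animal"].values()
            if v["estimate_min"] is not None
        ]
        b_onset = beh_payload["sigmoid"]["midpoint_min"]
        if lfp_cps:
            res = cpl.coupling_test(
                [b_onset], lfp_cps, window=(0.0, float(gen.session_minutes)), seed=seed
            )
            _write(out, "coupling", {
                "observed_stat": res.observed_stat,
                "p": res.p,
                "p_alternative": res.p_alternative,
                "mode": res.mode,
            })
        else:
            _write(out, "coupling", {"p": None, "note": "no LFP change points detected"})

    sal_rec, licl_rec, ens_truth = synth.gen_ensemble_pair(gen, n_held=cfg.n_held)

    if enabled["taste_response"]:
        logger.info("stage=taste_response")
        cls_s = tr.classify_responsiveness(sal_rec, alpha=cfg.alpha)
        cls_l = tr.classify_responsiveness(licl_rec, alpha=cfg.alpha)
        rep = tr.magnitude_condition_anova(
            tr.magnitude_table(sal_rec, cls_s), tr.magnitude_table(licl_rec, cls_l)
        )
        _write(out, "taste_response", {
            "n_responsive_saline": sum(c.responsive for c in cls_s),
            "n_responsive_licl": sum(c.responsive for c in cls_l),
            "anova": rep,
        })

    if enabled["decoding"]:
        logger.info("stage=decoding")
        res_s = dec.lda_loo_accuracy(sal_rec, epochs=epochs)
        res_l = dec.lda_loo_accuracy(licl_rec, epochs=epochs)
        rep = dec.epoch_condition_test([res_s], [res_l], alpha=cfg.alpha)
        _write(out, "decoding", {
            "saline_epoch_means": res_s.epoch_means,
            "licl_epoch_means": res_l.epoch_means,
            "epoch_test": rep,
        })

    if enabled["palatability"]:
        logger.info("stage=palatability")
        tr_s = pal.moving_spearman(sal_rec)
        tr_l = pal.moving_spearman(licl_rec)
        kw = pal.spearman_condition_test(tr_s, tr_l, epochs)
        ppi_s = pal.compute_ppi(sal_rec, epochs)
        ppi_l = pal.compute_ppi(licl_rec, epochs)
        tests = pal.ppi_tests(ppi_s, ppi_l, alpha=cfg.alpha)
        _write(out, "palatability", {"spearman_kruskal": kw, "ppi": tests})

    if enabled["held_units"]:
        seed = cfg.stage_seed("held_units")
        logger.info("stage=held_units seed=%d", seed)
        held_ids = [n for n in ens_truth.cluster_id]
        rds = held.response_difference_vectors(sal_rec, licl_rec, held_ids)
        payload: dict = {"n_rd": len(rds)}
        if len(rds) >= 10:
            clu = held.gmm_cluster(rds, seed=seed)
            rho2_s = pal.moving_spearman(sal_rec).epoch_values(epochs, "rho2")
            rho2_l = pal.moving_spearman(licl_rec).epoch_values(epochs, "rho2")
            id_by_idx = {i: n for i, n in enumerate(sal_rec.neuron_ids)}
            cluster_by_unit = dict(
                rds.assign(cluster=clu.labels).groupby("neuron_id")["cluster"]
                .agg(lambda s: s.mode().iloc[0])
            )
            rows = []
            for cond, tab in (("saline", rho2_s), ("licl", rho2_l)):
                for _, r in tab.iterrows():
                    nid = id_by_idx[int(r["neuron"])]
                    if nid in cluster_by_unit:
                        rows.append((nid, int(cluster_by_unit[nid]), r["epoch"], cond, r["value"]))
            rho2_table = pd.DataFrame(
                rows, columns=["neuron_id", "cluster", "epoch", "condition", "rho2"]
            )
            try:
                anova = held.cluster_palatability_anova(rho2_table, alpha=cfg.alpha)
                payload["cluster_anova"] = {
                    "interaction": anova["interaction"],
                    "late_epoch_followups": anova["late_epoch_followups"],
                }
            except ValueError as exc:
                payload["cluster_anova"] = {"note": str(exc)}
            payload["gmm"] = {"best_k": clu.best_k, "bic": clu.bic,
                              "n_angle_peaks": clu.n_angle_peaks,
                              "n_unassigned": int((clu.labels == -1).sum())}
        payload["baseline"] = held.baseline_equivalence(sal_rec, licl_rec, held_ids or None)
        _write(out, "held_units", payload)

    # summary: assembled from stage files only
    summary = {"config": {"seed": cfg.seed, "alpha": cfg.alpha,
                          "generator": asdict(gen)}}
    for s in STAGES:
        f = out / f"{s}.json"
        if s != "synth" and enabled[s] and f.exists():
            summary[s] = json.loads(f.read_text())
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return summary
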