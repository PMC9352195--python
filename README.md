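# gcstate

Analysis pipeline for **illness-modulated gustatory cortical coding**:
how a malaise state (LiCl-induced sickness in rat) registers in
gustatory cortex — as a change point in LFP μ-band (7–12 Hz) power, as
a drop in rearing behavior, and as a reorganization of single-neuron
and ensemble taste responses toward a simple "good vs. bad" code.

It is written for systems neuroscientists running passive taste-delivery
experiments with chronic extracellular recordings: you bring per-minute
band-power series (or raw LFP traces), trial-structured spike counts
with taste labels, scored rearing events, and spike waveforms; the
package provides the statistics. A built-in synthetic generator with
planted ground truth makes every stage testable without any recordings.

## The analyses

* **Change point in μ power.** For a z-scored per-minute series the
  model is a single switch between two Gaussian states:

      μ₁, μ₂ ~ N(0, 1),  σ ~ HalfCauchy(1),  τ ~ Uniform(0, 20)
      y_t ~ N(μ₁, σ) for t < τ;  y_t ~ N(μ₂, σ) for t ≥ τ

  sampled with a fully conjugate Gibbs sampler (exact conditional draw
  of τ). The decision rule compares the τ posterior against 50
  temporally shuffled refits: cells of the posterior exceeding the 99th
  percentile of the shuffled peak densities are marked, and the change
  point is their mean.
* **Behavior onset.** Rearing seconds per minute, normalized
  LiCl–saline difference traces, per-quartile rank tests, and a
  4-parameter logistic fit whose transition localizes sickness onset;
  plus a Monte-Carlo test of whether behavioral and LFP latencies from
  separate cohorts are more coupled than independent uniform draws.
* **Taste responsiveness.** Mann–Whitney baseline-vs-evoked
  classification per neuron (the first 200 ms post-delivery is
  non-chemosensory and always excluded), and a condition × direction
  ANOVA on response magnitudes with neuron-cluster-robust inference.
* **Ensemble decoding.** Leave-one-out LDA taste classification per
  250 ms bin (closed-form LOO; chance 25%), epoch-wise condition
  comparisons, and a within-session protocol (train on the first 5
  trials per taste, track later 5-trial blocks) that localizes when
  discriminability collapses as sickness sets in.
* **Palatability.** Moving-window (250 ms / 25 ms) Spearman correlation
  of firing with the canonical hedonic ranks sucrose > NaCl > citric
  acid > quinine, and the **pure palatability index**
  PPI = D_dissimilar − D_similar — the mean response distance between
  opposite-valence taste pairs minus that between same-valence pairs
  (0 under exchangeable tastes, positive under good/bad polarization).
* **Held units.** Waveform-stability test against a bootstrapped
  within-session null (95th-percentile rule), response-difference
  vectors per unit × taste across conditions, BIC-selected Gaussian
  mixture clustering with 95% Mahalanobis membership, and a
  permutation-calibrated aligned-rank ANOVA of cluster-specific
  palatability content.

See `docs/methods.md` for model details, defaults, calibration
measurements, and known limitations.

## Worked example

```python
from gcstate.synth import GeneratorConfig, gen_lfp_power, gen_ensemble_pair
from gcstate.changepoint import shuffle_detect
from gcstate.decoding import lda_loo_accuracy
from gcstate.palatability import compute_ppi, ppi_tests

cfg = GeneratorConfig(seed=42)          # study-condition defaults

series, truth = gen_lfp_power(cfg)      # 7 animals, shift planted at 15 min
res = shuffle_detect(series[0], seed=1)
print(f"planted tau = {truth.true_tau_min['a00']:.1f} min, "
      f"estimate = {res.estimate:.2f} min (R-hat {res.rhat:.3f})")

sal, lic, _ = gen_ensemble_pair(cfg)    # paired healthy/ill ensembles
acc_s, acc_l = lda_loo_accuracy(sal), lda_loo_accuracy(lic)
print("middle-epoch decoding: saline %.1f%%, licl %.1f%% (chance 25%%)"
      % (100 * acc_s.epoch_means["middle"], 100 * acc_l.epoch_means["middle"]))

late = ppi_tests(compute_ppi(sal), compute_ppi(lic))["late"]
print("late-epoch PPI: saline %.2f, licl %.2f, p = %.3f"
      % (late["saline_mean"], late["licl_mean"], late["between"]["p"]))
```

prints

```
planted tau = 15.0 min, estimate = 15.00 min (R-hat 1.000)
middle-epoch decoding: saline 45.8%, licl 28.3% (chance 25%)
late-epoch PPI: saline -0.05, licl 0.79, p = 0.022
```

The detector recovers the planted 15-minute power shift exactly; the
"ill" session decodes taste identity barely above chance in the
identity (middle) epoch while the healthy session reaches ~46%; and the
late-epoch PPI rises significantly under illness — the polarization of
responses into a good/bad code that reconciles losing identity
information while gaining palatability-related content.

## Command line

```bash
gcstate run --config run.yaml --seed 7 --out results/   # full pipeline
gcstate synth --out fixtures/                           # CSV fixtures + truth
gcstate changepoint --input fixtures/power.csv --animal a00 --seed 7
gcstate coupling --behavior cps_b.json --lfp cps_l.json --sims 10000
gcstate decode --input fixtures/trials.csv --mode loo
```

`gcstate run` executes synthesize → analyze → report with one seed,
writing per-stage JSON plus a `summary.json` assembled purely from the
stage files; a rerun with the same config is byte-identical.

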