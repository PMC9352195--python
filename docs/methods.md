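# Methods

`gcstate` implements the analysis battery used to ask how systemic
illness (LiCl-induced malaise in rat) is reflected in gustatory cortex:
when network state shifts (LFP μ-band power), when sickness behavior
emerges (rearing), and how single-neuron and ensemble taste coding
change. Every stage can be exercised end-to-end on the built-in
synthetic generator, which plants known ground truth.

## 1. Band power and the group quartile comparison (`lfp`)

Raw LFP traces (1–300 Hz) are reduced to per-minute power in a band
(default μ, 7–12 Hz) by a Welch averaged periodogram inside each
1-minute bin — 1 s Hann windows at 50% overlap, chosen for variance
reduction at this bin length; multi-channel input is averaged in the
power domain (whether channel averaging happens on voltage or power is
ambiguous in practice; power-domain averaging is robust to phase
differences across wires). Each session's series is min-max normalized
to [0, 1] across the whole 20-minute window.

The group analysis takes, per animal, the per-bin |difference| between
its two sessions (saline–LiCl in the experimental group, saline–saline
in the control group), averages within 5-minute quartiles, and runs a
mixed group × quartile ANOVA with per-quartile one-way follow-ups.
A caution established during development: with min-max normalization,
the |difference| between two *stationary-noise* sessions is ~0.3–0.5 in
every quartile whatever the target, and a large late shift inflates the
shifted session's range, misaligning the early quartiles after
normalization. The interaction statistic therefore has modest power
unless the two sessions share slow within-session dynamics (as real
spectrograms do). The generator exposes `session_profile_amp` — a
post-handling power transient common to an animal's two sessions — to
emulate that regime; its default is 0 so that `power_shift=0` yields
exactly stationary noise.

## 2. Single change point in μ power (`changepoint`)

Model, on the z-scored per-minute series (bin centers at j + 0.5 min):

    μ1, μ2 ~ Normal(0, 1)        state means
    σ      ~ HalfCauchy(1)       shared observation SD
    τ      ~ Uniform(0, 20)      change position (minutes)
    y_t    ~ Normal(μ1, σ) if t < τ else Normal(μ2, σ)

Inference is a fully conjugate Gibbs sampler: normal–normal updates for
the means; the HalfCauchy prior written as an inverse-gamma scale
mixture (σ² | a ~ IG(½, 1/a), a ~ IG(½, 1)) giving closed-form σ²
updates; and an *exact* conditional draw of τ — its conditional
posterior is piecewise constant between consecutive bin centers, so the
sampler draws the interval from the exact categorical and then τ
uniformly within it. Defaults: 4 chains × 2000 post-warmup draws
(1000 warmup); convergence is monitored with split-chain R̂ on τ
(flagged unreliable at R̂ ≥ 1.1). All updates are vectorized over
chains and over a batch of series, which is what makes the
50-refit-per-series shuffle protocol cheap (a full 51-series detection
runs in ~0.2 s; hundreds of series batch together).

The test suite holds the sampler to an exhaustive oracle: the discrete
split posterior computed by integrating μ1, μ2 analytically and σ on a
grid. Total-variation distance between the MCMC and the oracle
posterior is required to be ≤ 0.1 (measured ~0.02).

**Detection.** The τ posterior of the observed series is histogrammed
on a 0.5-minute grid and compared with the posteriors of 50 temporally
shuffled copies (random permutation of the minute bins), which contain
no change point by construction. The threshold is the 99th percentile
of the per-shuffle *peak* density heights; grid cells where the
observed density exceeds it are marked, and the estimate is the mean of
marked cells (absent when none). Comparing every cell against pooled
per-cell shuffle heights instead would face a 40-cell multiplicity
problem (~20–30% false detection on stationary series); the peak-height
null holds the family-wise rate near 1/(n_shuffles + 1) ≈ 2%, at the
cost of occasionally missing a genuine 3-SD shift whose posterior is
diffuse (measured ~85% detection, essentially never mislocalized).

## 3. Behavior onset (`behavior`) and coupling (`coupling`)

Rearing events (≥ 0.5 s by the scoring rule) are binned into total
seconds per minute, events split proportionally across bin boundaries
(total duration is conserved exactly). Each animal's trace is min-max
normalized; the licl-cohort mean minus the saline-cohort mean per bin
is the difference trace. A 4-parameter logistic is fitted by nonlinear
least squares with multi-start midpoints {4, 8, 12, 16} min and the
slope bounded at 6/min (transitions faster than one bin are
indistinguishable from noise spikes and otherwise capture them). The
onset readout is the time the fit completes 95% of its transition
toward the late asymptote. With 4–5 animal cohorts the per-simulation
midpoint SD is ~2.5 min; the estimator is tested for *bias* (< 1 min
over simulations), not per-run accuracy, which these cohort sizes
cannot support. Per 5-minute quartile, conditions are compared with the
two-sample rank-sum test (exact p at small n; a paired signed-rank mode
exists for within-animal designs), with effect size r = Z/√N.

The coupling test asks whether behavioral-onset and LFP change-point
latencies — from separate cohorts — are more tightly clustered than
independent uniform draws over (0, 20) min. The statistic is the summed
absolute distance over all cross-cohort pairs (the mean-vs-mean reading
is always computed alongside); p is the fraction of 10,000 simulated
independent-uniform statistics at or below the observed one.

## 4. Taste responsiveness (`taste_response`)

Per neuron, trialwise firing in the 1 s before delivery is compared
with the evoked window by a Mann–Whitney U test, pooling trials across
tastes. The first 200 ms post-delivery is always excluded (it is
somatosensory, not chemosensory, in this passive-delivery paradigm);
the evoked window defaults to [200, 1200) ms. "Excitatory" and
"inhibitory" label only the sign of the rate change from baseline.

The condition analysis uses per-neuron-per-taste |magnitudes| (4 rows
per neuron) in a condition × direction ANOVA. Because a neuron's four
rows share its baseline and response strength, the primary F tests use
neuron-cluster-robust covariance — a plain residual-based F on these
rows is badly miscalibrated (measured 0% null rejection for paired
populations, 31% for unpaired, at α = 0.05). The naive ANOVA table is
returned alongside (`naive_anova`) for comparison with analyses that
treat rows as independent. Tukey follow-ups compare conditions within
each direction.

## 5. Ensemble decoding (`decoding`)

Taste discriminability is the leave-one-out accuracy of an LDA decoding
the delivered taste from the ensemble rate vector in each 250 ms bin
(chance 25%). Plain LDA is used while the pooled covariance is
well-conditioned; with more features than per-class trials (or
condition number > 1e8) it switches to Ledoit–Wolf-shrinkage LDA and
logs the switch. The plain path uses an exact closed-form leave-one-out
computation (rank-one downdate of the pooled scatter per held-out
trial), verified prediction-for-prediction against refitting; this is
~40× faster and makes the calibration studies affordable. Epochs —
early 200–400 ms (the gap before the identity epoch), middle 400–700 ms
(identity), late 800–1100 ms (palatability) — collect the bins that
overlap them most.

Condition comparisons per epoch are Bonferroni-corrected. With several
sessions per condition the exchangeable unit is the session (per-session
mean correctness; trial-level ranking across sessions overstates the
effective sample size because trials within an ensemble share its
random tuning — measured 14% null rejection at α = 0.05); with exactly
one session per condition the trial is the only unit available and is
used as such. Both an unpaired rank test and a paired-session t test
are provided.

The within-session protocol trains once on the first 5 trials per taste
and evaluates later trials in 5-trial blocks (train and test disjoint
by construction), restricted to taste-responsive units. Predictions are
averaged over refits with randomized tie-breaking of decision scores
(integer spike counts make exact ties possible). Block means are
min-max normalized per session before the repeated-measures ANOVA and
paired follow-ups against block 1.

## 6. Palatability content (`palatability`)

A moving window (250 ms, step 25 ms) correlates each neuron's
single-trial firing with the canonical palatability ranks
(sucrose > NaCl > citric acid > quinine) by Spearman's ρ, vectorized
over neurons per window; zero-variance windows are excluded and
counted. Group traces report mean |ρ| (default) and mean ρ² (used by
the cluster analysis); per-epoch condition comparisons use
Kruskal–Wallis.

The pure palatability index (PPI) measures good-vs-bad polarization:
per neuron and epoch, responses (baseline-normalized against the 500 ms
pre-delivery mean, trial-averaged per taste over the central 150 ms of
the epoch — "central" keeps epoch-specific dynamics out of the
average) are compared as Euclidean distances divided by √(#bins).
PPI = D_dissimilar − D_similar, the mean over the 4 opposite-valence
pairs minus the mean over the 2 same-valence pairs (unweighted means,
so the pair-count imbalance does not bias the index). Exchangeable
tastes give E[PPI] = 0; a noiseless pure good/bad code gives
D_similar = 0. A normalized mode, (D_dis − D_sim)/(D_dis + D_sim),
bounded at 1 for a pure code, is provided because both readings of the
index are defensible; the difference mode is the default and the two
are reported side by side by the pipeline. Tests: one-sample t of PPI
against 0 within condition; unpaired rank test between conditions.

## 7. Held units and response-difference clustering (`held_units`)

A unit recorded in two sessions counts as held when its between-session
waveform dissimilarity is below the 95th percentile of a within-session
null built by bootstrapping the comparison of each session's
first-third against last-third waveforms. The dissimilarity statistic —
Euclidean distance between mean waveforms in pooled per-sample-SD units
— is deliberately pluggable (`statistic=` argument), since the
field uses several interchangeable spike-shape scores.

Per held unit × taste, the condition response is the post-delivery
(250→750 ms) minus pre-delivery (−750→−250 ms) mean of the unit's
min-max-normalized firing (normalized jointly across both sessions so
condition differences stay meaningful), in % of maximum responsiveness.
The pre-delivery window is read as −750→−250 ms, symmetric with the
post window. The RD point (saline response, licl response) is
summarized by its distance from the origin and its Cartesian angle;
the four quadrants encode the response-change motifs (e.g.
saline-excitatory/licl-inhibitory points sit at 270–360°). Note the
distance measures overall responsiveness — a unit whose response is
unchanged by illness sits far from the origin *on the diagonal*, not at
the origin.

RDs are clustered with full-covariance Gaussian mixtures (ridge 1e−6),
k = 1..6 chosen by BIC; points outside their cluster's 95% Mahalanobis
ellipse (χ²₂ cutoff) stay unassigned, and the number of peaks in the
circular angle histogram (20° bins) is reported as a cross-check.

Cluster-specific palatability: per-neuron epoch ρ² enters a
cluster × epoch × condition aligned-rank-transform ANOVA. The full ART
table is reported, but its fixed-effects F is anti-conservative here
(each neuron contributes six correlated epoch × condition rows;
measured 19% null rejection), and cluster-robust Wald over-rejects with
few clusters (50%). The three-way interaction p therefore comes from a
neuron-level cluster-label permutation null of the ART F — each
neuron's six rows move together, so within-neuron correlation cannot
inflate the test; measured null rejection is 5.0% at α = 0.05.
Follow-ups compare late-epoch ρ² between conditions within each
cluster. Baseline equivalence across sessions is checked with a paired
t test on per-unit pre-stimulus means plus a Kolmogorov–Smirnov test of
the difference distribution against a zero-centered Gaussian.

## 8. Synthetic data (`synth`)

One RNG stream per generator family, seeded from `GeneratorConfig.seed`
through a fixed offset table, so fixture families regenerate
independently and bit-identically.

*LFP*: per animal, Gaussian noise (SD 1 a.u.) whose mean jumps by
`power_shift` (default 3× the noise SD) at `true_tau` (default 15 min),
jump sign alternating across animals — illness moves μ power in either
direction depending on the individual. The experiment-level generator
produces paired sessions for 7 experimental and 5 control animals.

*Ensembles*: 20 neurons × 30 trials × 4 tastes in 25 ms bins, −1 s to
+1.5 s around delivery. Rates are piecewise-constant: baseline
(Gamma-distributed around 7 Hz, CV 0.5) through the first 200 ms; a
taste-independent response (≈30% inhibitory) across the evoked window;
mean-free per-taste tuning scaled by `identity_effect` in the middle
epoch; late-epoch firing monotone in palatability rank scaled by
`palatability_gain`. Counts are Poisson per bin — the analyses consume
binned rates only, so refractoriness would add nothing testable.
Illness multiplies the response by (1 − 0.3), the identity separation
by (1 − 0.4), and the palatability slope by (1 + 0.5), leaving baseline
untouched. `identity_effect = 0.2` and `palatability_gain = 0.25` were
set so the saline/licl middle-epoch decoding accuracy lands at the
scale reported for real ensembles (~48%/33% here vs 43.8%/34.1%
observed in vivo). Held units override the response term with three
planted motifs (excitatory→inhibitory, the reverse, and
excitatory→weaker-excitatory). A separate drifting-session generator
orders trials chronologically and degrades coding after a planted
onset, for the within-session protocol.

*Behavior*: Poisson rearing events (3/min) with lognormal durations
(mean 4 s, σ_log 0.4). In licl sessions, events after `sickness_onset`
(12 min) are scaled by (1 − `duration_drop`); scaled events shorter
than the 0.5 s scoring threshold are censored, exactly as a scorer
would drop them — so the observed post/pre mean ratio is the *censored*
expectation, slightly above (1 − drop) at large drops.

*Waveforms*: biphasic templates (sharp trough, slow rebound) with
per-unit amplitude/width, plus white noise per spike; session B can
reuse the template (held) or scale it (distinct unit).

**What the generator does not emulate** — and hence what green tests do
not establish about real recordings: spike-train autocorrelation and
bursting, trial-to-trial rate drift within healthy sessions, correlated
noise across simultaneously recorded neurons, electrode drift in
waveforms, 1/f LFP background and oscillatory structure beyond a mean
shift, and any coupling between an animal's behavioral and neural
streams (the coupling test's inputs are planted independently).

## 9. Problem sizes and numerical choices

Simulation studies in the test suite use: 100 series (plus 100 null
series) for change-point recovery; 500 neurons for the PPI null; 50
seeds for cluster recovery; 200 replicates per stage for type-I-error
calibration, with cohorts of 10 sessions (behavior) or 6 session pairs
of 8-neuron/40-trial ensembles (decoding) so the rank tests' exact
small-sample levels are near-continuous at α = 0.05. Degenerate inputs
are defined errors, not silent results: constant series cannot be
z-scored or normalized, all-tied quartiles return p = 1 with a warning,
all-zero neurons are flagged non-responsive with undefined direction,
and units silent in both sessions are excluded from RDs with a log
line.
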