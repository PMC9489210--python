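# ratereplay

Analysis pipeline for two-track hippocampal replay experiments: naive Bayes
position decoding, shuffle-based replay-sequence detection, a regression test
for experience-driven **rate reinstatement** during replay, and a
*sequenceless* log-odds method that identifies which context a replay event
represents from rate and place information alone. A synthetic session
generator with ground truth makes every stage verifiable without recorded
data.

## The scientific problem

During rest, hippocampal place-cell ensembles re-express ("replay")
time-compressed spatial trajectories from earlier behavior. Replay has
traditionally been defined by *sequence* — the order in which place fields
activate. But place cells also carry a *rate* code: when an animal runs on
two different linear tracks, cells globally remap and additionally modulate
their peak in-field firing rate between the tracks. This package implements
the analyses needed to ask whether that between-track rate modulation is
reinstated inside replay events, and whether rate alone can identify the
replayed context.

The pipeline, for a session with epochs PRE / RUN (track 1) / RUN (track 2)
/ POST:

1. **Ratemaps & cell selection.** Speed-filtered (4–50 cm/s) occupancy
   ratemaps at 10 cm bins; place cells need an unsmoothed peak > 1 Hz, and
   "stable" cells need > 1 Hz in both halves of the run. The regression
   cohort is stable on **both** tracks.
2. **Decoding.** Naive Bayes with both tracks' ratemaps concatenated, so the
   posterior `P(x | n) ∝ ∏ᵢ fᵢ(x)^{nᵢ} · exp(−τ Σᵢ fᵢ(x))` is normalized
   *across tracks* per time bin (τ = 250 ms for behavior, 20 ms for replay).
3. **Replay detection.** Candidate events are multi-unit activity bursts
   (1 ms bins, Gaussian σ = 5 ms, z > 3, burst ≤ 300 ms, merged within
   50 ms) filtered by speed < 5 cm/s, ≥ 5 active units, 100–750 ms duration
   and ripple power z > 3. Each event is scored per track with the weighted
   correlation `corr(x, t; prob)` of its decoded posterior and tested
   against three 1000-fold shuffle nulls (spike-train circular shift,
   place-field shift, per-time-bin posterior shift); MUA-split halves are
   additionally tested at p < 0.025. Events significant for both tracks are
   assigned by a 60 % Bayesian-bias rule (regression cohort) or excluded
   (log-odds cohort).
4. **Rate reinstatement.** Per cell, the Track 1 − Track 2 difference in
   field peak rate is regressed (OLS) against the difference in mean peak
   instantaneous replay rate (1 ms trains filtered with a 100 ms Gaussian,
   σ = 20 ms), with median event rate and mean spikes per event as
   alternative metrics, plus rate-insensitive re-detection controls (track
   rate shuffle, replay rate shuffle) and a rank-order (Spearman)
   detection alternative.
5. **Sequenceless log odds.** Per event,
   `ln(ΣProb(T1) / ΣProb(T2))`, z-scored against a per-cell ratemap
   track-label swap (1000 permutations). Information-restriction
   manipulations (rate fixed, place removed, and their randomized negative
   controls) plus ROC/AUC with paired bootstrap and DeLong comparisons
   quantify how much context information rate and place each carry.

## Worked example

```python
from ratereplay import PipelineConfig, SimConfig, make_session, run_full_pipeline

session = make_session(SimConfig(seed=7, n_cells=40, n_laps=10,
                                 n_events_pre=30, n_events_post_per_track=30))
config = PipelineConfig(seed=7)
report = run_full_pipeline(session, config, out_dir="demo_out")

print(report.decoding_summary.round(3).to_string(index=False))
reg = report.regressions
reg = reg[reg.metric == "peak_instantaneous_rate"]
print(reg[["epoch", "B", "F", "p", "R2", "n"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
roc = report.roc_summary
print(roc[roc.epoch == "POST"][["manipulation", "auc", "auc_ci_lo", "auc_ci_hi"]]
      .round(3).to_string(index=False))
```

prints

```
 track  median_error_cm  classification_accuracy
     1             3.00                    0.996
     2             3.75                    0.993
epoch    B    F        p    R2   n
  PRE  NaN  NaN      NaN   NaN NaN
  RUN 3.16 42.8 1.16e-07 0.536  39
 POST 3.56 65.9 7.98e-10 0.634  40
                 manipulation   auc  auc_ci_lo  auc_ci_hi
                     original 1.000      1.000      1.000
                   rate_fixed 1.000      1.000      1.000
                place_removed 0.851      0.714      0.959
  rate_fixed_place_randomized 0.542      0.347      0.711
place_removed_rate_randomized 0.607      0.425      0.768
```

Reading this: position decoding recovers the simulated trajectory to a few
cm with > 99 % track classification. The reinstatement regression is
strongly positive for awake (RUN) and POST replay — cells that fired faster
on one track during behavior also fired faster during that track's replay
events — while PRE yields no fit at all because, with no prior experience
structure, almost no PRE candidate passes the sequence-significance test.
The replayed context is perfectly discriminable from the full posterior
(AUC = 1.0), still well above chance from rate alone (place removed,
AUC ≈ 0.85), and at chance for both randomized negative controls (CIs cover
0.5).

The same stages are available from a thin CLI
(`ratereplay simulate | ratemaps | decode | detect-replay | regress-rates |
logodds | roc | report`), all driven by a YAML config whose defaults are the
published analysis values.

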