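# Methods

This note documents the models, conventions and design decisions behind
`ratereplay`, in the order the pipeline runs them.

## Session model and conventions

Time is seconds (float64) throughout; positions are cm; spatial bins are
0-based and half-open `[left, right)`. A session has four epochs ordered in
time (PRE, RUN1, RUN2, POST), per-cell spike trains (strictly sorted), a
uniformly sampled linearized position trace with a track id (0 off-track)
and speed, and an optional ripple-band power trace. Bundles are plain TSV,
written at 17 significant digits and parsed with round-trip float precision
so write → read is the identity.

One global seed drives everything. Each stochastic stage derives an
independent generator keyed by `(seed, stage-name, event-key)` (CRC32 of
the stage name feeds `numpy.random.default_rng`), so results do not depend
on the order in which stages run, and re-running any stage in isolation
reproduces its pipeline output.

## Ratemaps and cell selection

Ratemaps are speed-filtered (4–50 cm/s) spike histograms divided by
speed-filtered dwell time; 10 cm bins feed the decoder, 2 cm bins exist
for display only, and only *unsmoothed* maps are ever decoded (smoothing,
Gaussian σ = 1 bin, is display-only). Zero-dwell bins get rate 0 with a
flag rather than NaN so decoding needs no special-casing.

Putative pyramidal cells require waveform half-width-half-max > 500 µs
(when available) and session mean rate < 5 Hz. A place cell on a track has
an unsmoothed peak > 1 Hz; stability additionally requires > 1 Hz in both
the first and the second half of that track's run. The reinstatement
cohort is stable on both tracks; pyramidal cells under 1 Hz on both tracks
are retained as non-spatial controls.

Field detection (10 cm maps): local maxima > 1 Hz are candidate peaks;
peaks closer than 4 bins (40 cm) merge into the larger; a field's extent is
the contiguous run of bins above 1 Hz around its peak, and fields narrower
than 2 bins (20 cm) are dropped. For multi-field cells the per-cell scalar
used in regressions is the global map maximum; the field AUC (trapezoidal,
on the 10 cm decoding grid — configurable) is that of the field containing
the global peak. Laps are segmented from position extrema with 10 cm
hysteresis.

The lap-bootstrap remapping classifier resamples N-of-N laps with
replacement (default 1000 iterations) per track, rebuilds the ratemap, and
flags a parameter (peak rate, peak location) as modulated iff one track's
median lies strictly outside the other's [5th, 95th] percentile interval.

## Decoding

Naive Bayes with a uniform prior over the concatenated two-track grid:

    P(x | n) ∝ ∏ᵢ fᵢ(x)^{nᵢ} · exp(−τ Σᵢ fᵢ(x))

evaluated in log space with per-column max subtraction and normalized so
every time bin sums to 1 across both tracks. A rate floor of 0.01 Hz is
added to the decoding ratemaps when the model is built (configurable), so
likelihoods are strictly positive and the floor participates in any
rate-scaling manipulations exactly. τ is 250 ms for behavior and 20 ms for
replay; event bins are anchored at event start and a trailing remainder
< 20 ms is discarded. Argmax ties break toward the lowest concatenated bin
index — a stated convention, not an inference about how such ties "should"
count. Decoding error uses bins whose argmax lies on the true track;
classification accuracy is the fraction of speed-filtered RUN bins decoded
to the current track.

## Candidate events and replay significance

Multi-unit activity (all cells pooled) is binned at 1 ms, smoothed with a
Gaussian (σ = 5 ms) and z-scored per epoch. Contiguous stretches above
z = 3 lasting at most 300 ms seed candidates; stretches closer than 50 ms
merge; surviving events must last 100–750 ms, have ≥ 5 active units
(≥ 1 spike), occur below 5 cm/s, and contain ripple power above z = 3
(0.1 s moving average) when a power trace is present — the ripple criterion
is skipped with a warning otherwise.

Events are scored per track with the weighted correlation of the decoded
posterior (weighted mean/covariance/correlation over position and time bin
indices; per-column normalization retained from the two-track decode).
Significance is assessed against three 1000-fold shuffle nulls — per-cell
circular shift of the event spike-count vectors in time, per-cell per-track
circular shift of the ratemaps in space (both re-decoded per shuffle), and
per-time-bin circular shift of the posterior within the scored track's
block. All conserve mass: per-cell event spike counts, per-map value
multisets, and per-column (and per-track-block) sums respectively.

Two conventions deserve emphasis:

* **Two-sided scoring.** Replay runs forward and backward, so the test is
  on |weighted correlation| against the |shuffle| distribution
  (equivalently |score| > the null's 95th percentile). A one-sided rule
  would be blind to reverse sweeps, which are half of all events in the
  generator and common in real data.
* **Empirical p-values** are `(1 + #{|shuffle| ≥ |observed|}) / (1 + n)`,
  never zero; NaN scores (degenerate posteriors, e.g. zero weighted
  variance) are never significant. A uniform posterior scores 0 — defined,
  and never extreme — while the genuinely undefined case is zero marginal
  variance.

Every candidate is also split at the MUA minimum within its middle third;
each half that independently re-passes the candidate filters is tested at
p < 0.025, and an event is significant for a track if the whole event or
either half passes all three nulls (an OR rule — splitting is a rescue
path for events with noisy decoding at one end). Events significant for
both tracks are assigned to the higher-bias track if the Bayesian bias
(that track's share of the summed posterior) exceeds 60 % for the
regression cohort, and are excluded outright from the log-odds cohort.

The rank-order alternative correlates per-cell median spike times with
field-peak positions (Spearman), with a 1000-fold within-event
cell-identity permutation null, two-sided on |ρ| for the same
forward/reverse reason.

## Rate reinstatement

Per cell and track, over the significant events assigned to that track in
which the cell fired ≥ 1 spike: mean peak instantaneous rate (1 ms binary
train convolved with a unit-sum 100 ms Gaussian window, σ = 20 ms, 101
taps, ×1000 → Hz; zero-phase convolution — peak values are lag-invariant
for symmetric kernels), median event rate (spikes / duration, median over
events), and mean spikes per event. Cells need ≥ 1 event per track and a
field peak ≥ 1 Hz on both tracks. Track 1 − Track 2 differences enter an
OLS regression with an F-test of the slope; differencing removes per-cell
excitability offsets exactly (adding a constant to both tracks changes
nothing).

The two rate-insensitive re-detection controls multiply, per cell, either
the track ratemaps (peak rescaled to a draw from the cohort's empirical
peak distribution on that track) or the event count matrices (mean event
rate rescaled to a draw from the cohort's empirical mean-event-rate
distribution; real-valued counts are valid in the Poisson log-likelihood).
Re-detection re-scores the same MUA candidates — the controls target the
sequence-significance stage, not burst finding — and the regression is then
re-fit on the *original* spikes and fields restricted to the re-identified
significant events. Temporal analyses re-qualify cells within each window:
cumulative regressions per lap (awake local replay) and independent
regressions per 70 consecutive events.

## Sequenceless log odds

Raw log odds = natural log of the ratio of summed posterior probability,
Track 1 over Track 2, across all time bins of an event. Each raw value is
z-scored against the ratemap track-label shuffle: 1000 permutations in
which every cell independently keeps or swaps its two track maps with
probability ½ (the swap-count is not constrained), re-decoding each time;
zero shuffle spread (identical maps on both tracks) defines z = 0 with a
flag. Only stable-both-tracks cells and single-track-significant events
enter; RUN events are restricted to local replay (content matches the
current track).

Manipulations: *rate fixed* rescales each cell's per-track map so both
peaks equal their mean and rescales the cell's counts in each event to its
mean rate across the events it participated in (zero-count cells are
untouched; the rescaling removes across-event and hence between-track rate
variation — note it deliberately preserves a cell's overall excitability,
so decoding is not invariant to a global per-cell gain). *Place removed*
decodes with one position bin per track (each cell's mean rate on that
track at speed > 5 cm/s) and one time bin per event (τ = event duration),
making the result exactly invariant to within-event spike timing. The
negative controls randomize the surviving representation: a per-event cell
ID permutation after rate fixing, and a per-cell per-track rate redraw from
the cohort's empirical distribution after place removal. Negative controls
are run 10 times and the run whose session-mean track difference is the
median is reported (all runs retained), because a single random projection
of ensemble structure can produce spuriously high discrimination.

Session significance: per session, Δz = mean z over Track 1 events − mean z
over Track 2 events; the null resamples each session's events with
replacement (1000×) with random track labels, and the observed session
means are compared against the pooled per-session shuffled differences by a
one-tailed rank-sum test. Pooling per-session shuffle values (rather than
averaging across sessions per iteration) keeps the null's variance matched
to the observations; the averaged variant is anticonservative (measured
~12 % false positives at α = 0.05 with four sessions, vs ~4 % for the
pooled form over 200 simulations).

ROC curves sweep the unique z values; AUC is trapezoidal, equivalently the
rank statistic with half-credit for ties so identical score multisets give
exactly 0.5. Bootstrap (1000 resamples of (score, label) pairs) uses one
shared index matrix per epoch so conditions are paired; the DeLong
comparison uses z = (AUC_A − AUC_B)/√(var_A + var_B − 2 cov_AB) with
variance and covariance taken from the paired bootstrap AUC samples (the
structural-components estimator would be the alternative; the bootstrap
form is used because the variances are defined by the same 1000-fold
bootstrap as the confidence intervals). Self-comparison yields z = 0,
p = 1 by convention.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, not
hippocampal biophysics (no theta sequences, phase precession, bursting, or
interneuron dynamics; ripple power is generated directly as a power trace).

* **Fields.** One Gaussian field per cell per track, σ = 15 cm on a 200 cm
  track (2–3 fields fit a track); peak rates log-normal (median 8 Hz,
  log-sd 0.4). Global remapping draws Track 2 centers independently;
  Track 2 peaks are Track 1 peaks × exp(N(0, 0.5)). This reproduces the
  target regime of low between-track and high within-track population-vector
  correlation.
* **Behavior.** Back-and-forth laps at 30 cm/s with 2 s reward pauses,
  position sampled at 40 Hz; spiking is inhomogeneous Poisson with
  intensity equal to the field rate at the current position.
* **Replay.** Rest events sweep a virtual position in 20 ms steps at
  10 cm/bin (the compression is a free simulation parameter; no published
  value exists), sweep lengths 80–140 cm, intensity = 5× the field rate
  along the sweep (the gain stands in for the population burst during
  ripples). Sweeps may overhang the track ends by up to 40 cm: strictly
  on-track sweeps over-sample the track center, which couples a field's
  eccentricity into its replay participation and adds structured noise to
  the reinstatement regression. Events are spaced ~4 s apart (a realistic
  rest-period event rate, and enough quiet background for the per-epoch
  z-scoring of MUA and ripple power to leave bursts clearly above
  threshold); each event coincides with a ripple-power burst. Background
  activity is homogeneous Poisson (25 Hz summed over the population).
* **Reinstatement.** On track k a cell's replay amplitude is
  `own_peakᵏ^s · base^(1−s)` where `s` is the reinstatement slope and
  `base` is a per-cell log-normal amplitude drawn *independently* of the
  field peaks. So the log replay-rate ratio between tracks is `s` times
  the log field-rate ratio; `s = 1` is full reinstatement and `s = 0` is a
  true null in which replay rates carry no field-rate information. (An
  earlier design used the geometric mean of the two field peaks as the
  `s = 0` amplitude; that leaves replay rates correlated with field-rate
  magnitude, which makes the OLS slope test anticonservative — variance
  grows with |x| — and violates the requirement that null configurations
  yield calibrated p-values.) The induced regression slope is monotone in
  `s` and is measured, never assumed.
* **PRE.** Identical sweep construction with per-cell intensity profiles
  permuted across cells per event: population activity looks the same, but
  neither sequence nor rate aligns with any cell's own fields.
* **Structureless calibration events** are fully homogeneous: every cell
  fires at the population-average mean field rate × gain, constant in
  time. Keeping per-cell rate heterogeneity would *not* be a valid null
  for the spatial shuffles — posterior columns then concentrate where the
  high-rate cells' fields sit, deflating the observed score's position
  variance relative to shuffled nulls (measured false-positive rates up to
  0.13 at α = 0.05). This is a caveat of spatial-shuffle nulls worth
  remembering with real data too.

What passing tests show — and don't. Recovery and calibration results on
these sessions validate the estimators and the significance machinery
under the generative assumptions (stationary Gaussian fields, Poisson
spiking, clean sweeps). They do not certify behavior under real-data
features the generator omits: drift and instability of fields, theta
sequences during behavior, bursting, overdispersed spiking, or
reward-biased replay content.

## Problem sizes

The test suite and the acceptance script run the analyses at desk scale,
chosen as the smallest sizes at which the statistical assertions are
stable: 30–50 cells, 8–10 laps per track, 20–120 events per track, and the
full 1000-fold shuffles wherever a significance test is asserted (smaller
shuffle counts appear only in unit tests of mechanics). Monte-Carlo
criteria use 20–50 seeds with fixed seed bases; all statistical assertions
are derandomized.

## Known limitations

* Ratemaps are direction-agnostic; directional fields are out of scope.
* The pipeline analyzes one session at a time; the multi-session rank-sum
  utilities expect records pooled by the caller (the acceptance machinery
  does this for synthetic cohorts).
* The OLS reinstatement regression pools cells that share events, so
  residuals are not strictly independent; with the generator's event
  counts the slope test is calibrated (measured 5 % at α = 0.05), but
  very small event counts would make it anticonservative.
* NWB or other binary neurophysiology containers are not read; sessions
  enter as TSV bundles.
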