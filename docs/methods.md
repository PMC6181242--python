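# Methods

This note documents the models, defaults, and numerical choices behind
`nirsreject`, and what the synthetic validation does and does not show.

## Signal model

A session is a block design: `n_trials` (default 6) cycles of 10-s rest,
3-s instruction, 24-s stimulus, on a 0.1-s sampling grid. The epoch of
trial *k* is the half-open window `[onset_k − 13 s, onset_k + 37 s)`;
half-open windows make adjacent epochs tile the record exactly, and onsets
snap to the nearest grid sample. Synthetic recordings space stimuli 26 s
apart so consecutive epoch windows abut without overlap.

The clean synthetic signal is `f(t) = (h*b)(t) + p(t) + m(t)`:

* **Hemodynamic response** `h(t) = (t/τ)^{n−1} e^{−t/τ} / ((n−1)!·τ)` with
  τ = 1.08 s, n = 3 (peak at τ(n−1) = 2.16 s). For convolution the discrete
  kernel is normalized to unit *sum*, so a long boxcar of amplitude `a`
  produces a response plateau of exactly `a` — the drawn amplitude is then
  identically the activation scale that enters SNR and power calculations.
* **Boxcar amplitude**: one Gaussian draw `N(μ, σ)` *per signal*, shared by
  all six trials (per-trial independent draws are available via
  `BoxcarParams(per_trial=True)`). The shared draw is the model under which
  the published power anchors are coherent: with per-trial draws the
  one-sample t-test power at activation mean/SD ratio 0.85 with five epochs
  caps near 40%, whereas the asymptotic power of the shared-draw model is
  `Φ(μ/σ)` — 80.2% at ratio 0.85 and 97.7% at ratio 2, which is exactly the
  "five epochs / three epochs for 80% power" structure the simulation is
  meant to show. Defaults: μ = 0.22 mM·mm (midpoint of the plausible
  0.14–0.30 range for real activations), σ set via the ratio.
* **Physiological noise** `p(t)`: white Gaussian, SD 1/6, shaped by a
  Butterworth band-pass 0.08–0.15 Hz (order 4 as given to the design call),
  applied causally — a stochastic realization needs no phase correction.
* **Machine noise** `m(t)`: white Gaussian with SD `μ_act / 10^(SNR/20)`,
  i.e. calibrated so the SNR statistic evaluated with the activation scale
  as μ equals the requested value in dB. For null (zero-activation)
  simulations the calibration scale falls back to
  `NoiseModelParams.snr_reference_amp` (0.22).

### Artifact models and ground truth

With noise models enabled, 0–6 events (at most one per trial; count uniform
unless forced) are injected, each annotated in `GroundTruth`:

* **Recovered spike**: a 1-s rebound step convolved with the analytic first
  derivative `h'(t)`, rescaled to a signed peak drawn uniformly from
  0.14–0.48 mM·mm. The kernel integrates to ~0, so the signal recovers.
* **Non-recovery spike**: the same construction with `h'` modified beyond
  its maximum to `2h'(t) − max h'`; the kernel is continuous at the splice
  and settles at `−max h'`, leaving a lasting base-level offset. The offset
  is held to the end of the trial's epoch window and released there: events
  perturb their own epoch, consistent with the ground-truth annotation
  being per-trial. (An earlier rendering held offsets to the end of the
  recording; the global detrend then absorbed most of the offset, events
  hardly damaged the activation statistics, and no rejection scheme — not
  even ground-truth-guided — could improve the false-negative rate. Long
  held pulses also smear through the zero-phase filter into neighbouring
  epochs, contaminating the "clean" epochs that rejection retains.)
* **Baseline shift**: a slope of signed magnitude `N(0.025, 0.0125)` mM·mm/s
  (truncated below at 0.001) added over the 13-s prestimulus interval only
  — the literal reading of "a slope in the baseline interval". After
  baseline zeroing, the epoch's activation shifts by roughly
  −(sign)·(baseline mean of the ramp); the return at stimulus onset is
  itself a sudden non-recovering amplitude change, so shifts are detectable
  by both criteria 1 and 2.

Spike placement is uniform within the epoch window at least 2 s from its
edges (events flush to a boundary would leave no measurable base level);
event types are drawn with p(shift) = 1/2 and p(recovered) =
p(non-recovered) = 1/4.

All generator randomness flows through one `numpy.random.Generator`;
identical parameters and seed give bit-identical recordings.

## Preprocessing

Fixed order: linear detrend over the full record → Butterworth band-pass
0.01–0.8 Hz (order 4 to the design call), forward–backward for zero phase →
epoch extraction → rejection → per-epoch baseline zeroing (mean of the
*first 10 s* of the window — the rest period, not the full 13-s
prestimulus) → activation statistics.

Numerical choice worth knowing: at a 0.01 Hz cutoff the filter's impulse
response (~100 s) exceeds the record's 26-s lead-in, and `sosfiltfilt`'s
default short odd-reflection padding leaves a start/end transient that
triples the activation-noise SD of the first and last epochs and distorts
the t-test's calibration (empirical type-I error 0.015 at α = 0.05). The
band-pass therefore uses even-reflection padding of 100 s, after which
epoch noise is homogeneous and the null test is calibrated (0.059 at
α = 0.05, 1000 simulations).

`compute_snr` uses μ over `[onset+4 s, stimulus end)` and σ (sample SD,
ddof = 1) over the 10 s before onset; a non-positive μ yields a NaN
"undefined" sentinel rather than a complex logarithm.

## Noise criteria

* **Criterion 1** (amplitude jump): consecutive-sample differences above
  the threshold form events; runs separated by fewer than 2 sub-threshold
  samples merge (a multi-sample artifact is one event). Base levels are
  1-s means before the event onset and after its end; windows truncated
  below 0.3 s by an epoch edge use the available samples and log a
  warning. Severity = largest absolute base shift among failing events.
  Flag-set nesting along a threshold sweep is guaranteed for isolated step
  events; overlapping artifacts can in principle merge differently as the
  threshold moves.
* **Criterion 2** (baseline slope): absolute least-squares slope over the
  full 13-s prestimulus ("extremely high/low" reads as two-sided);
  severity = |slope|.
* **Criterion 3** (correlation outlier): per retained epoch, the sum of
  Pearson correlations with every other retained epoch; quartiles by
  linear interpolation between order statistics (numpy's default, position
  `p·(n−1)`); fence `Q1 − k·IQR`, one-sided low, strict comparison — so six
  identical epochs (IQR 0) flag nothing. Zero-variance epochs correlate 0
  with every partner: a flat-lined segment is maximally non-similar, hence
  flaggable, rather than undefined. Needs ≥ 3 retained epochs, otherwise
  skipped with a logged notice.

Severities have different units across criteria; the engine only ever
compares them through within-criterion ranks.

## Rejection engine

Per channel and signal type (decisions on the oxy-hemoglobin signal can be
propagated to HHb/total-Hb epoch sets):

1. Run each criterion in the configured order on the currently retained
   epochs (criterion 3's fence adapts to the survivors).
2. A stage rejects *all* of its newly flagged epochs if at least
   `acceptance_rate` epochs would survive; otherwise it rejects none and
   records the flags. Every flag lands in the ledger with its stage and
   fate.
3. After the last stage, retained epochs are ranked by noise level (count
   of recorded flags); while the retained count exceeds the floor and a
   flagged epoch remains, the noisiest is rejected. Ties break by the
   larger sum of within-criterion severity ranks (average ranks for equal
   severities), then by the lower epoch index. Ranking is a single pass:
   recorded criterion-3 severities are not re-derived after each trim.

`acceptance_rate=None` (unlimited) is conventional mode: every stage
rejects unconditionally and the ranking never fires. The floor invariant —
`len(retained) ≥ acceptance_rate` — is asserted inside `RejectionResult`
itself, so every construction anywhere in the package re-checks it. The
engine is deterministic end to end; its behaviour is verified exhaustively
against a literal five-step simulator over all 64³ flag patterns × three
acceptance modes.

`AdaptiveEpochRejector` exposes the engine as a scikit-learn-style outlier
detector (`fit`, `fit_predict`, labels +1/−1, `get_params`/`set_params`)
over an `(n_epochs, n_samples)` matrix.

## Power and false-negative-rate studies

Activation values are t-tested one-tailed against zero at α = 0.05 for the
simulation studies (the test is unspecified there; the real-data
reproducibility protocol uses one-tailed α = 0.025 and that is the default
in `StatTarget`). Each power cell generates recordings, preprocesses,
epochs, zeroes baselines, randomly drops the stated number of epochs, and
tests. Per-simulation seeds derive from `(seed, sim_index)` only, so cells
differing in SNR, ratio, or rejection count share draws — differences
between cells are paired estimates (common random numbers). "Plateau SNR"
is taken as 10 dB, mid-plateau (the power curve flattens above about
−5 dB). At −40 dB power sits slightly *above* α by construction: the
0.22 mM·mm activation mean against ~2.7 mM·mm activation-noise SD leaves a
residual noncentrality of ≈ 0.2·√n SE, worth 2–3 points.

The false-negative-rate experiment generates noisy signals (every signal
carries at least one event; SNR drawn per signal), applies candidate
policies, and reports β and the epoch-average RMSE against the true task
response with and without rejection; with several policies it selects the
β-minimizing one (grid-search protocol). The SNR distribution of real
datasets is not publicly tabulated; the stand-in is negatively skewed,
`−40 + 60·Beta(5, 1.5)` dB (mass near the high end, tail to −40). Under
that full-range distribution the RMSE comparison is dominated by very low
SNR draws, where dropping epochs only raises averaging noise; the
directional benefit of rejection (lower β *and* lower RMSE) is therefore
asserted at moderate SNR (10 dB), where artifact damage — not machine
noise — limits detection. Headline real-data quantities (rejection
accuracies near 72%, β 18% vs 34%) depend on non-public recordings and are
deliberately not reproduced; only directions and calibrations are.

## Optimization harness

`ParameterGrid` spans acceptance ∈ {3, 4, unlimited}, all criteria subsets
(including none), thresholds 0.01–0.05 step 0.001 (criteria 1 and 2) and
0–3×IQR step 0.1 (criterion 3); a `coarse` factor thins the ranges for
desk-scale runs (the full grid is ~16.7 million cells; the cell count is
computed and checked, not guessed). Reproducibility of a policy on a
cohort is the fraction of expected group inferences it reproduces
(one-tailed one-sample t-tests at α = 0.025 on per-subject ROI-pooled
activation means). The "intermedication" contrast is a per-subject
difference of differences — (post − pre medication) − (post − pre placebo)
— formed before testing. A subject-condition whose epochs are all rejected
(possible in unlimited mode) contributes no datum; a group left with fewer
than two data cannot be tested and its target counts as unmet. Sequential
optimization keeps only training-optimal policies and re-scores them on
validation cohorts; rejection accuracy, (TP+TN)/total against reference
labels with "rejected" as positive, breaks ties.

Synthetic cohorts for testing the harness emulate a four-condition
medication study with known effects (null pre-administration and
post-placebo, positive post-medication), so full reproducibility is the
planted truth, and ground-truth noisy-trial labels stand in for visual
inspection (they are labelled as synthetic reference labels, not expert
annotations).

## Known limitations

* The generator emulates one channel and one signal type; real multichannel
  spatial structure, HHb-specific dynamics, heart-rate (> 0.8 Hz) and
  Mayer-wave components outside 0.08–0.15 Hz, and serially correlated
  artifacts are not modelled. Passing tests therefore certify the
  algorithmic machinery and its statistical calibration on this model, not
  performance on any particular real dataset.
* Criterion 3 assumes a constant-interval block design; with imbalanced
  paradigms or resting-state data the correlation-sum statistic is not
  meaningful.
* The per-channel convention (rejection and the acceptance floor apply per
  channel) is a choice; session-level pooling across channels is not
  implemented beyond propagating one channel's decision to other signal
  types.
* Visual-rejection reference labels are accepted via CSV but no real
  labelled data ships with the package.
* SNIRF container import is not implemented; IO is plain CSV/JSON/YAML.
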