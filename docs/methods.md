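# Methods

This document records the modelling assumptions, parameter choices, and
numerical decisions behind `swnemg`. The README covers installation and
usage; this file explains *why* the pieces are the way they are and what the
synthetic benchmark does and does not emulate.

## Problem setting

Surface-EMG gesture classifiers are trained with electrodes at one position
and then used after the armband or electrode grid has been re-donned a
little to the left or right. To first order, a small static displacement of
a rigid electrode array changes each channel's pickup gain (muscle fibres
move closer to or further from each electrode) and mixes a little of each
channel into its neighbours. A classifier trained on absolute signal
amplitudes is sensitive to exactly these changes, so accuracy drops when
electrodes shift.

Sliding-window normalization (SWN) replaces each incoming sample with its
z-score over a short trailing window, per channel and causally. A z-score
is invariant under any per-channel affine map `x -> g*x + b` with `g > 0`,
so the static-gain component of an electrode shift is removed *exactly*
before the classifier ever sees the data. Crosstalk mixing is not a
per-channel map and is not removed; for realistic mixing fractions it is
the smaller part of the perturbation.

The package's headline experiment measures this mechanism end to end: train
a classifier at one electrode position, test it at another, and compare the
*differential accuracy* (cross-position accuracy minus the same-position
baseline) with and without SWN in the preprocessing chain.

## Synthetic signal model

`swnemg.synth` generates labelled multi-channel recordings:

- **Classes.** Three motion classes (`rest`, `flexion`, `extension`) are
  scheduled by holding each class for a dwell drawn uniformly from 0.5–3 s
  and cycling through the classes in freshly shuffled order. Labels are
  emitted at 20 Hz, the prediction frame rate. The `labels` module can also
  derive the same classes from an elbow-angle trace by thresholding the
  angular velocity (±30 deg/s with hysteresis), which is how such labels
  would be produced from motion capture.
- **Per-channel signal.** `signal = envelope * carrier + noise`. The
  envelope is `baseline + activation[channel, class(t)] * burst(t)`,
  smoothed with a 0.1 s moving average. `activation` gives flexor-like
  channels (first half of the array) high gain during flexion and
  extensor-like channels high gain during extension; at rest only the
  measurement-noise floor remains, as in real surface EMG.
- **Burstiness and correlation.** `burst(t)` is a slow stochastic
  modulation shared within each synergist group, emulating force-tracking
  variability. Carriers of channels within a group share a common component
  (`carrier_correlation`), emulating the correlation a spatially coherent
  motor-unit population induces in neighbouring electrodes. Carriers are
  band-limited to 40–200 Hz so synthetic energy survives the analysis
  band-pass.
- **Determinism.** Every trial is a pure function of
  `(config, trial_id, subject_id)`; seeds fan out through
  `numpy.random.SeedSequence`.

### Electrode-shift model

`ShiftModel` applies a static linear perturbation `M @ (g * x)`:

- **Gains.** Per-channel gains are log-normal with log-SD `gain_log_sd`
  (median 1), drawn once per `(seed, position)` so every trial of a session
  sees the same placement. Because displacing a rigid array moves all
  electrodes together, the log-gain is decomposed into a rigid component
  shared across channels (opposite sign for the two synergist halves:
  sliding toward the flexor side raises flexor pickup and lowers extensor
  pickup) plus an independent per-channel residual. Half of the log-gain
  variance is carried by the rigid component; the per-channel marginal
  remains LogNormal(0, `gain_log_sd`²).
- **Crosstalk.** Each output channel borrows a fraction `crosstalk_alpha`
  of its amplitude from its index neighbours (split equally, edge channels
  from their single neighbour); mixing rows sum to 1.
- **Benchmark construction.** The left/center/right datasets of a subject
  re-express the *same underlying trials* through different shift models,
  mirroring a re-donning experiment where the same motions are recorded at
  displaced positions. Labels are therefore identical across positions for
  a given trial id.

### What the synthetic data does not emulate

No motor-unit action-potential physiology (the carrier is filtered noise,
not MUAP trains), no fatigue or electrode-impedance drift within a trial,
no time-varying or nonlinear shift (lift-off, skin deformation), no
inter-subject anatomical variability beyond seeding, and no sensor
artefacts (motion artefact, power-line interference). The benchmark
isolates the static-gain-plus-crosstalk component of electrode shift, which
is precisely the component SWN targets; conclusions about other
perturbations cannot be drawn from it.

## Preprocessing chain

Per trial (`swnemg.pipeline.process_trial`):

1. Causal 6th-order Butterworth band-pass 40–200 Hz (`scipy.signal.sosfilt`,
   no zero-phase filtering — the pipeline must be usable online).
2. Causal 8th-order anti-alias low-pass at 0.8× the target Nyquist, then
   decimation 2000 Hz → 500 Hz.
3. Optional SWN (window 200–1000 ms). The first `L−1` samples are dropped
   (`skip` warm-up policy) because the full-window statistic is undefined
   there; a `grow` policy using partial windows (minimum two samples) is
   available.
4. Rectification (absolute value).
5. Framing at 20 Hz: each frame takes the trailing feature window
   (100–1000 ms), cuts it into 100 ms segments with 50 ms overlap
   (`S = (W−100)/50 + 1` segments, e.g. 19 for 1000 ms), and stacks
   segments channel-wise: frame shape `(C·S, 50)` with segment-major
   ordering. Frame `k` (time `k/20` s) is paired with label `k−1`
   (0-indexed); the first valid frame is the first whose window lies
   entirely inside the recorded (post-warm-up) signal.

Because every stage before SWN is linear and time-invariant, a per-channel
affine map of the raw signal is still a per-channel affine map at the SWN
input, so the whole chain inherits SWN's gain/offset invariance. One
caveat: a constant offset becomes a decaying transient through the causal
band-pass, so exact invariance holds once that transient has decayed
(below 1e−9 after ~1 s at these filter orders); tests compare frames past
that point.

## SWN numerics

- Population (not sample) standard deviation; output is
  `(x − m)/max(s, eps)` and exactly zero where `s ≤ eps` (flat window).
- The batch path uses cumulative sums of `x` and `x²`. Each channel is
  first centred on its own first sample: a z-score is offset invariant, and
  working near zero keeps `sumsq/n − m²` well conditioned when the signal
  rides on a large DC offset (without centring, an offset of 1e6 produces
  errors of order 1; with it, streaming/batch agreement stays below 1e−9
  over 10⁴ samples).
- The streaming state keeps a ring buffer plus running sums, refreshed from
  the buffer once per `L` pushes and whenever cancellation drives the
  computed variance negative, so an arbitrarily long stream matches the
  batch computation to ≤1e−9.

## Classifier

An all-NumPy CNN-LSTM with handwritten forward/backward passes
(`swnemg.nn`, `swnemg.model`):

- Four convolutional blocks: LayerNorm (jointly over channels and time, so
  normalization statistics do not depend on a per-channel relabelling of
  the input) → ReLU → Conv1d (kernel 3, stride 1, padding 2) → dropout
  0.1/0.2/0.3/0.4. An anti-aliased BlurPool ([1,2,1]/4, stride 2) opens
  block 2, halving the 52-sample segment axis to 26.
- Global average pooling over time, LayerNorm, two LSTM layers across the
  frame sequence (forget-gate bias initialized to +1) with dropout 0.1, and
  a zero-initialized linear class head (so an untrained model outputs
  uniform probabilities and the training signal flows before the head
  differentiates).
- Optional domain head for adversarial training: gradient-reversal layer →
  LayerNorm → Linear → ReLU → LayerNorm → zero-initialized Linear.
- Focal loss (γ = 2) summed over frames, with class weights
  `alpha_c = count_c / N`. Note this convention *upweights the majority
  class*; an `inverse` mode with the usual minority-upweighting behaviour
  is provided. True-class probabilities are floored at 1e−12 (with a
  warning) before the log.
- Adam, global gradient-norm clipping at 5.0, float32 by default. A
  `default_dtype` context switches everything to float64, which the test
  suite uses for finite-difference gradient checks of every layer and of
  the full model (all pass at 1e−6-level tolerances).

## Training regimes and evaluation protocol

- **Splits.** Per position, 70 % of trials form the train pool and 30 % the
  test set (20 trials → 14/6). Positions share trial ids, and identical id
  sets split identically, so a trial is never simultaneously in one
  position's pool and another position's test set. Transfer-learning
  tuning uses `int(0.3 · pool)` trials of the target position (20 → 4);
  pooled training uses that many trials from each of the three positions
  (20 → 12).
- **Regimes.** `baseline` (train and test at the same position), `vanilla`
  (train at one position, test across), `tl` (pretrain at the source, then
  fine-tune on target tuning trials at a 10× smaller learning rate with
  every CNN parameter frozen — bit-identical before/after, verified),
  `mix` (train on pooled trials of all positions), and `ada` (pooled
  training plus the adversarial domain head; with the domain loss weight
  at 0 it reproduces `mix` bit for bit).
- **Metric.** Differential accuracy `y[n,i,j] = x[n,i,j] − x_base[n,j,j]`.
  The stored `diff_accuracy` column is recomputed as the literal difference
  of the stored operands, so the bookkeeping identity holds bit for bit.
  (When reading the CSV back, use `float_precision="round_trip"`; pandas'
  default float parser can be 1 ulp off the written shortest-repr value.)
- **Statistics.** Subject-mean differential accuracies are compared with
  the two-sided Wilcoxon rank-sum test (exact enumeration for untied
  samples with `n_a + n_b ≤ 12`, tie-corrected normal approximation with
  continuity correction otherwise) under Bonferroni correction, and with
  the two-way Scheirer–Ray–Hare rank test. SRH forms
  `H = SS_effect / MS_total` on mid-ranks; because `MS_total` is computed
  from the observed mid-ranks, the classical tie-correction divisor is
  already implicit (`SS_total/(N−1) = D·N(N+1)/12` identically), and the
  statistic collapses exactly to the tie-corrected Kruskal–Wallis H when
  one factor has a single level. Monte-Carlo calibration over 1,000 null
  replicates puts the factor-A type-I error at α = 0.05 within 5 % ± 2 %.
- **Window sweep.** The full protocol sweeps normalization windows
  {200,…,1000} ms × feature windows {200,…,1000} ms (25 cells with SWN,
  5 feature-window cells without), selecting the cell with maximal mean
  accuracy (ties toward smaller windows).

## Desk-scale experiment and known training limitations

The shipped benchmark (`ExperimentConfig` defaults) is scaled to run on one
CPU core in minutes: 3 subjects, 8 trials of 25 s per position, 12
channels, gain log-SD 0.3, crosstalk 0.1, a single grid cell (400 ms
normalization, 200 ms feature window), vanilla training for 5 epochs at
batch size 1, learning rate 1e−2.

Two honest caveats, both reproducible from the test suite:

- **SWN-condition training at desk scale.** Under the 5-epoch desk
  protocol the no-normalization model trains well while the SWN model often
  stays near chance: per-sequence gradients at batch size 1 are mutually
  incoherent on SWN features at this scale (pairwise cosine similarities
  between per-sequence gradients range from −0.74 to +0.94, while a linear
  probe reaches 0.97 on the same features, i.e. the features are
  informative but the 15-step optimization is not). The directional result
  is unaffected: SWN's position invariance is exact on this benchmark
  (positions share underlying trials), so its differential accuracy is 0
  while the no-normalization condition degrades under shift.
- **Learning-rate sensitivity of wide feature windows.** At reduced test
  scale, learning rate 1e−2 diverges for the 1000 ms-window model (training
  loss grows, training-pool accuracy stays at chance) while 1e−3 converges
  for both windows (training-pool accuracy 0.99). The window-sweep trend
  test therefore trains both windows at 1e−3; with both models converged,
  the 1000 ms window outperforms 200 ms by a wide margin (mean test
  accuracy 0.94 vs 0.66 over three seeds).

## Limitations

- All empirical results in this repository are on synthetic data; the
  benchmark demonstrates the *mechanism* (affine-invariance of SWN versus
  gain sensitivity of absolute amplitudes), not clinical performance.
- The shift model is static and linear; SWN's exact invariance on this
  benchmark is by construction, and real shifts include components
  (crosstalk, geometry changes, nonstationarity) that SWN does not cancel.
- The classifier is a faithful but small NumPy implementation; it is
  single-threaded and not performance-competitive with GPU frameworks, and
  desk-scale training budgets are deliberately tiny.
- The focal-loss `as_printed` class weighting upweights the majority class;
  it is kept as the default deliberately to preserve the documented
  behaviour of the formula as stated, with `inverse` available for the
  conventional minority-upweighting variant.
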