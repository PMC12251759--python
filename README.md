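# swnemg

Sliding-window normalization (SWN) for electrode-shift-robust surface-EMG
classification: a synthetic benchmark, a causal preprocessing chain, an
all-NumPy CNN-LSTM classifier with four training regimes, and the
nonparametric statistics to compare them.

## The problem

Surface-EMG gesture classifiers are trained with electrodes at one position
and then used after the armband has been re-donned slightly displaced. To
first order a small static shift of a rigid electrode array rescales each
channel's pickup gain and mixes a little of each channel into its
neighbours; a classifier trained on absolute amplitudes loses accuracy
under exactly this perturbation.

SWN replaces each sample with its z-score over a short trailing window, per
channel and causally, so it is usable online. A z-score is invariant under
any per-channel affine map `x -> g*x + b`, so the static-gain component of
an electrode shift is removed exactly before the classifier sees the data.
This package implements that mechanism end to end and measures it: train at
one electrode position, test at another, and compare the *differential
accuracy* (cross-position accuracy minus same-position baseline) with and
without SWN.

See [docs/methods.md](docs/methods.md) for the signal model, the shift
model, what the synthetic data does and does not emulate, and all numerical
choices.

## Worked example: SWN cancels an electrode shift

```python
import numpy as np
from swnemg.pipeline import process_trial
from swnemg.preprocess import PreprocConfig
from swnemg.swn import SwnConfig
from swnemg.synth import (
    ShiftModel, SynthConfig, apply_electrode_shift, generate_trial,
)

cfg = SynthConfig(n_channels=4, trial_duration=4.0, seed=3)
rec, labels = generate_trial(cfg)          # center-position recording
shift = ShiftModel(position_tag="left", gain_log_sd=0.3,
                   crosstalk_alpha=0.0, seed=3)
shifted = apply_electrode_shift(rec, shift)  # same trial, displaced array

pcfg = PreprocConfig(feature_window_ms=200.0)
swn = SwnConfig(window_ms=400.0, fs=500.0)
for name, norm in (("none", None), ("swn", swn)):
    a = process_trial(rec, labels, pcfg, norm)
    b = process_trial(shifted, labels, pcfg, norm)
    keep = a.frame_times >= 1.4   # past the causal filter's transient
    rel = (np.abs(a.frames[keep] - b.frames[keep]).max()
           / np.abs(a.frames[keep]).max())
    print(f"{name:>4}: max relative frame change under electrode shift = {rel:.3g}")
```

Output:

```
none: max relative frame change under electrode shift = 0.329
 swn: max relative frame change under electrode shift = 6.5e-15
```

Without normalization the classifier's input changes by up to 33 % under a
static gain shift; with SWN it changes at the level of floating-point
round-off.

## The end-to-end experiment

`vanilla_shift_robustness` runs the desk-scale benchmark (3 synthetic
subjects, 8 trials of 25 s per position at left/center/right, log-normal
shift gains of log-SD 0.3 with 10 % crosstalk, vanilla training for 5
epochs) and reports the mean differential accuracy per normalization
condition and seed:

```python
from swnemg.experiment import vanilla_shift_robustness
table = vanilla_shift_robustness(seeds=[1, 2, 3, 4, 5])
print(table.pivot(index="seed", columns="normalization",
                  values="mean_diff_accuracy"))
```

```
normalization      none  swn
seed
1             -0.071466  0.0
2             -0.057903  0.0
3             -0.050153  0.0
4             -0.027573  0.0
5             -0.032268  0.0
```

The no-normalization condition loses several accuracy points when tested at
a shifted position, while SWN's differential accuracy is exactly zero on
this benchmark: the left/right datasets re-express the same underlying
trials through static gains, which SWN cancels, so its frames — and hence
its predictions — are identical across positions. The run takes about nine
minutes on one CPU core.

A command-line interface covers the same ground
(`swnemg simulate | preprocess | swn | labels | train | run | evaluate |
sweep | stats`); `swnemg run --config cfg.json --out rundir` writes
`diff_accuracy.csv`, `subject_means.csv`, and `stats.json` with resumable,
per-seed-deterministic training.

## Reproduction

`scripts/acceptance.py` recomputes the headline quantities (chance level,
normalization identities and invariances, streaming-vs-batch agreement, the
shift experiment, statistics calibration, focal-loss closed forms, protocol
arithmetic) and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out acceptance.json
```

Representative values at seed 1 (full file in JSON, `{"value": ..., "n": ...}`):

| quantity | value | n |
| --- | --- | --- |
| chance_level_simulated_pct | 33.093 | 10002 |
| swn_gain_offset_invariance_max_abs_diff | 3.84e-13 | 11204 |
| swn_streaming_vs_batch_max_abs_diff | 5.52e-13 | 10000 |
| shift_experiment_swn_wins | 5 | 5 |
| shift_experiment_none_mean_diff_accuracy | -0.04787 | 5 |
| shift_experiment_swn_mean_diff_accuracy | 0.0 | 5 |
| srh_type_one_error_rate | 0.054 | 1000 |
| focal_loss_half_prob_gamma2 | 0.173287 (= 0.25 ln 2) | 1 |

The whole script runs in under 20 minutes on one CPU core (the shift
experiment dominates). Every number above is also pinned by a test in
`tests/test_acceptance.py`.
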