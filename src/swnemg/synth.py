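"""Synthetic surface-EMG generator with a parametric electrode-shift model.

Real surface EMG is, to first order, a band-limited stochastic carrier whose
amplitude envelope tracks muscle activation.  The generator produces
multi-channel trials of that form: a piecewise-constant motion-class schedule
(rest / elbow flexion / elbow extension) drives per-channel amplitude
envelopes through an activation matrix, the envelopes (modulated by slow
stochastic bursts) scale band-limited unit-variance carriers, and white
measurement noise is added on top.  Three features of real EMG that matter
for normalization studies are emulated explicitly: muscles are silent at
rest (the noise floor dominates), channels over the same synergist group
share a correlated carrier component, and the two groups occupy distinct
spectral sub-bands of the 40-200 Hz analysis band (muscle-specific median
frequency).

Electrode shift is modeled as a static per-channel gain perturbation
(log-normal, median 1) plus optional leakage into index-neighbour channels.
Displacing an electrode a couple of centimetres mainly rescales the amplitude
each channel picks up, so a static linear map is the appropriate first-order
model -- and it makes the gain-invariance property of sliding-window
normalization exactly testable downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SynthConfig",
    "ShiftModel",
    "EmgRecording",
    "MotionLabels",
    "Benchmark",
    "CLASS_NAMES",
    "POSITIONS",
    "generate_trial",
    "apply_electrode_shift",
    "generate_benchmark",
]

CLASS_NAMES = ("rest", "flexion", "extension")
POSITIONS = ("left", "center", "right")

#: Carrier pass band in Hz; matches the analysis band so that synthetic energy
#: survives the band-pass stage of preprocessing.
CARRIER_BAND = (40.0, 200.0)

#: Label sampling rate in Hz (prediction frame rate).
FS_LABELS = 20


def _default_activation(n_channels: int) -> np.ndarray:
    """Channel x class gain matrix: flexor-like channels in the first half,
    extensor-like channels in the second, with mild per-channel variation.
    At rest the muscles are silent and the recording shows only the
    measurement noise floor, as in real surface EMG."""
    act = np.zeros((n_channels, 3))
    half = n_channels // 2
    for c in range(n_channels):
        taper = 1.0 + 0.1 * (c % 3)  # distinct but deterministic channels
        act[c, 0] = 0.0
        if c < half:
            act[c, 1] = 1.6 * taper
            act[c, 2] = 0.02
        else:
            act[c, 1] = 0.02
            act[c, 2] = 1.6 * taper
    return act


def _crc(s: str) -> int:
    return zlib.crc32(s.encode("utf-8")) & 0x7FFFFFFF


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording session.

    ``activation_matrix`` maps motion class to the mean rectified amplitude of
    each channel (arbitrary voltage-like units); ``baseline_activation`` is a
    tonic floor present in every class.  The class schedule holds each class
    for a dwell drawn uniformly from ``class_dwell_range`` seconds and cycles
    through ``allowed_classes`` in freshly shuffled order each cycle.
    """

    n_channels: int = 12
    fs_raw: float = 2000.0
    trial_duration: float = 60.0
    n_trials_per_position: int = 20
    class_dwell_range: tuple[float, float] = (0.5, 3.0)
    activation_matrix: np.ndarray | None = None
    baseline_activation: float = 0.02
    envelope_smoothing: float = 0.1
    measurement_noise_sd: float = 0.05
    carrier_correlation: float = 0.6
    envelope_mod_depth: float = 0.5
    envelope_mod_band: tuple[float, float] = (2.0, 8.0)
    group_carrier_bands: tuple[tuple[float, float], tuple[float, float]] = (
        (40.0, 80.0),
        (140.0, 200.0),
    )
    seed: int = 0
    allowed_classes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        lo, hi = self.class_dwell_range
        if not (0 < lo <= hi):
            raise ValueError("class_dwell_range bounds must be positive and ordered")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs_raw <= 2 * CARRIER_BAND[1]:
            raise ValueError("fs_raw must exceed twice the 200 Hz band edge")
        if self.activation_matrix is not None:
            am = np.asarray(self.activation_matrix, dtype=float)
            if am.shape != (self.n_channels, 3) or (am < 0).any():
                raise ValueError("activation_matrix must be n_channels x 3, nonnegative")
            object.__setattr__(self, "activation_matrix", am)
        if not self.allowed_classes or any(c not in (0, 1, 2) for c in self.allowed_classes):
            raise ValueError("allowed_classes must be a nonempty subset of {0,1,2}")
        if not (0.0 <= self.carrier_correlation <= 1.0):
            raise ValueError("carrier_correlation must lie in [0, 1]")
        if self.envelope_mod_depth < 0:
            raise ValueError("envelope_mod_depth must be nonnegative")
        mlo, mhi = self.envelope_mod_band
        if not (0 < mlo < mhi < self.fs_raw / 2):
            raise ValueError("envelope_mod_band must be ordered and below Nyquist")
        for blo, bhi in self.group_carrier_bands:
            if not (0 < blo < bhi < self.fs_raw / 2):
                raise ValueError("group_carrier_bands must be ordered and below Nyquist")

    @property
    def activation(self) -> np.ndarray:
        if self.activation_matrix is not None:
            return self.activation_matrix
        return _default_activation(self.n_channels)


@dataclass(frozen=True)
class ShiftModel:
    """Static linear electrode-shift perturbation.

    Per-channel gains are log-normal with log-SD ``gain_log_sd`` (median 1),
    drawn deterministically from ``(seed, position_tag)`` so that every trial
    of a session sees the same placement.  Displacing a rigid electrode array
    moves every electrode together, so the log-gain is decomposed into a
    rigid-displacement component shared across channels (opposite sign for
    the two synergist halves of the array: sliding toward the flexor side
    raises flexor pickup and lowers extensor pickup) and an independent
    per-channel residual; ``gain_shift_fraction`` is the fraction of the
    log-gain variance carried by the rigid component, and the per-channel
    marginal stays LogNormal(0, gain_log_sd**2).  ``crosstalk_alpha`` is the
    total amplitude fraction each output channel borrows from its index
    neighbours (split equally; edge channels borrow everything from their
    single neighbour); mixing weights per output channel sum to 1.
    ``gain_scale`` multiplies all gains and exists for controlled
    experiments.
    """

    gain_log_sd: float = 0.3
    crosstalk_alpha: float = 0.0
    position_tag: str = "center"
    seed: int = 0
    gain_scale: float = 1.0
    gain_shift_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.crosstalk_alpha <= 0.5):
            raise ValueError("crosstalk_alpha must lie in [0, 0.5]")
        if self.gain_log_sd < 0:
            raise ValueError("gain_log_sd must be nonnegative")
        if self.position_tag not in POSITIONS:
            raise ValueError(f"position_tag must be one of {POSITIONS}")
        if self.gain_scale <= 0:
            raise ValueError("gain_scale must be strictly positive")
        if not (0.0 <= self.gain_shift_fraction <= 1.0):
            raise ValueError("gain_shift_fraction must lie in [0, 1]")

    def gains(self, n_channels: int) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, _crc(self.position_tag)])
        )
        sd_rigid = self.gain_log_sd * np.sqrt(self.gain_shift_fraction)
        sd_resid = self.gain_log_sd * np.sqrt(1.0 - self.gain_shift_fraction)
        delta = rng.normal(0.0, sd_rigid)
        half = n_channels // 2
        sign = np.where(np.arange(n_channels) < half, 1.0, -1.0)
        logg = sign * delta + rng.normal(0.0, sd_resid, size=n_channels)
        return np.exp(logg) * self.gain_scale

    def mixing_matrix(self, n_channels: int) -> np.ndarray:
        a = self.crosstalk_alpha
        if a == 0.0 or n_channels == 1:
            return np.eye(n_channels)
        m = np.eye(n_channels) * (1.0 - a)
        for c in range(n_channels):
            nb = [i for i in (c - 1, c + 1) if 0 <= i < n_channels]
            for i in nb:
                m[c, i] = a / len(nb)
        return m


@dataclass
class EmgRecording:
    """One trial of multi-channel raw EMG."""

    signal: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: tuple[str, ...]
    position_tag: str
    trial_id: str
    subject_id: str

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MotionLabels:
    """Per-frame motion-class labels (0 rest, 1 flexion, 2 extension)."""

    labels: np.ndarray
    fs_labels: float = float(FS_LABELS)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.labels.size and not np.isin(self.labels, [0, 1, 2]).all():
            raise ValueError("labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return self.labels.size


def _class_schedule(
    config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Labels at FS_LABELS Hz from a dwell schedule that cycles the allowed
    classes in shuffled order.  For trials longer than 10 s the schedule is
    resampled until every allowed class occupies at least 10 % of frames."""
    n_frames = int(round(config.trial_duration * FS_LABELS))
    classes = np.array(config.allowed_classes)
    min_share = 0.10 if config.trial_duration > 10 and classes.size > 1 else 0.0
    for _ in range(1000):
        labels = np.empty(n_frames, dtype=np.int64)
        pos = 0
        while pos < n_frames:
            order = rng.permutation(classes)
            for cls in order:
                dwell = rng.uniform(*config.class_dwell_range)
                n = max(1, int(round(dwell * FS_LABELS)))
                labels[pos : pos + n] = cls
                pos += n
                if pos >= n_frames:
                    break
        counts = np.array([(labels == c).mean() for c in classes])
        if (counts >= min_share).all():
            return labels
    raise RuntimeError("could not draw a class-balanced dwell schedule")


def _bandlimited_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance noise band-limited to ``band`` Hz."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_trial(
    config: SynthConfig, trial_id: str = "T01", subject_id: str = "S01"
) -> tuple[EmgRecording, MotionLabels]:
    """Generate one labelled trial at the center electrode position.

    Per channel ``signal = envelope * carrier + noise``.  The envelope is
    ``baseline + activation[channel, class(t)] * burst(t)`` smoothed by a
    moving average of ``envelope_smoothing`` seconds, where ``burst`` is a
    slow stochastic modulation (``envelope_mod_band`` Hz, depth
    ``envelope_mod_depth``) shared within each synergist group, emulating the
    force-tracking burstiness of voluntary contractions.  Carriers of
    channels in the same synergist group (flexor-like first half,
    extensor-like second half) share a common component with weight
    ``carrier_correlation``, emulating the cross-channel correlation that a
    spatially coherent motor-unit population induces in neighbouring
    electrodes.  Output is a pure function of ``(config, trial_id,
    subject_id)``.
    """
    ss = np.random.SeedSequence([config.seed, _crc(subject_id), _crc(trial_id)])
    rng = np.random.default_rng(ss)
    n_samples = int(round(config.trial_duration * config.fs_raw))

    frame_labels = _class_schedule(config, rng)
    # upsample the 20 Hz schedule to the raw rate (each frame spans fs/20 samples)
    rep = int(round(config.fs_raw / FS_LABELS))
    raw_labels = np.repeat(frame_labels, rep)[:n_samples]
    if raw_labels.size < n_samples:
        raw_labels = np.pad(raw_labels, (0, n_samples - raw_labels.size), mode="edge")

    half = config.n_channels // 2
    group = np.array([0] * half + [1] * (config.n_channels - half))

    act = config.activation
    activation_t = act[:, raw_labels]  # (C, N)
    if config.envelope_mod_depth > 0:
        lfo = _bandlimited_noise(
            2, n_samples, config.fs_raw, config.envelope_mod_band, rng
        )
        burst = np.clip(1.0 + config.envelope_mod_depth * lfo[group], 0.1, None)
        activation_t = activation_t * burst
    env = config.baseline_activation + activation_t
    win = max(1, int(round(config.envelope_smoothing * config.fs_raw)))
    env = uniform_filter1d(env, size=win, axis=1, mode="nearest")

    # group-specific carrier sub-bands: real flexor and extensor EMG differ
    # in median frequency, and that spectral signature survives amplitude
    # normalization downstream
    carrier = np.empty((config.n_channels, n_samples))
    shared = np.empty((2, n_samples))
    for gi, band in enumerate(config.group_carrier_bands):
        members = np.flatnonzero(group == gi)
        if members.size:
            carrier[members] = _bandlimited_noise(
                members.size, n_samples, config.fs_raw, band, rng
            )
        shared[gi] = _bandlimited_noise(1, n_samples, config.fs_raw, band, rng)[0]
    rho = config.carrier_correlation
    if rho > 0 and config.n_channels > 1:
        carrier = np.sqrt(1.0 - rho) * carrier + np.sqrt(rho) * shared[group]
    noise = config.measurement_noise_sd * rng.standard_normal((config.n_channels, n_samples))
    sig = env * carrier + noise

    rec = EmgRecording(
        signal=sig,
        fs=config.fs_raw,
        channel_names=tuple(f"ch{c:02d}" for c in range(config.n_channels)),
        position_tag="center",
        trial_id=trial_id,
        subject_id=subject_id,
    )
    return rec, MotionLabels(frame_labels)


def apply_electrode_shift(rec: EmgRecording, shift: ShiftModel) -> EmgRecording:
    """Apply the static linear shift map ``M @ diag(g) @ signal``.

    ``g`` are the per-(position, channel) log-normal gains and ``M`` the
    neighbour-crosstalk mixing matrix; both are deterministic in
    ``(shift.seed, shift.position_tag)``.  The returned recording carries the
    shift's position tag.
    """
    g = shift.gains(rec.n_channels)
    m = shift.mixing_matrix(rec.n_channels)
    out = m @ (g[:, None] * rec.signal)
    return EmgRecording(
        signal=out,
        fs=rec.fs,
        channel_names=rec.channel_names,
        position_tag=shift.position_tag,
        trial_id=rec.trial_id,
        subject_id=rec.subject_id,
    )


@dataclass
class Benchmark:
    """Multi-subject, three-position dataset with a trial manifest."""

    trials: dict  # (subject_id, position_tag, trial_id) -> EmgRecording
    labels: dict  # (subject_id, trial_id) -> MotionLabels
    manifest: list  # dicts: subject_id, trial_id, position_tag, seed, fs

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.trials})

    def trial_ids(self, subject_id: str) -> list[str]:
        return sorted({k[2] for k in self.trials if k[0] == subject_id})


def generate_benchmark(
    config: SynthConfig,
    shifts: Sequence[ShiftModel],
    n_subjects: int = 1,
) -> Benchmark:
    """Three-session benchmark: per subject, the same underlying center trials
    are re-expressed at left/right positions through ``apply_electrode_shift``
    (center is the identity path), isolating the shift effect from trial-to-
    trial variability.  Shift seeds are re-keyed per subject so placements
    differ across subjects."""
    tags = [s.position_tag for s in shifts]
    if len(shifts) != 3 or len(set(tags)) != 3:
        raise ValueError("three ShiftModels with distinct position tags required")
    if set(tags) != set(POSITIONS):
        raise ValueError(f"position tags must be exactly {POSITIONS}")

    trials: dict = {}
    labels: dict = {}
    manifest: list = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for t in range(config.n_trials_per_position):
            trial = f"T{t + 1:02d}"
            center_rec, lab = generate_trial(config, trial_id=trial, subject_id=subject)
            labels[(subject, trial)] = lab
            for shift in shifts:
                if shift.position_tag == "center":
                    rec = center_rec
                else:
                    subj_shift = replace(
                        shift,
                        seed=(shift.seed * 1000003 + _crc(subject)) % (2**31),
                    )
                    rec = apply_electrode_shift(center_rec, subj_shift)
                trials[(subject, shift.position_tag, trial)] = rec
                manifest.append(
                    {
                        "subject_id": subject,
                        "trial_id": trial,
                        "position_tag": shift.position_tag,
                        "seed": config.seed,
                        "fs": config.fs_raw,
                    }
                )
    return Benchmark(trials=trials, labels=labels, manifest=manifest)
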