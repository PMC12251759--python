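"""Causal EMG processing chain: band-pass, decimation, normalization hook,
rectification, and frame assembly for the sequence classifier.

The chain is strictly causal (single-pass forward filtering) so that every
classifier input at time ``t`` depends only on samples up to ``t`` -- the
pipeline is meant to run in real time.  Per trial:

1. 6th-order Butterworth band-pass 40-200 Hz at the raw rate (2000 Hz),
   applied per channel in second-order sections.
2. Decimation to 500 Hz: causal anti-alias low-pass, then keep every 4th
   sample.
3. (Optional) sliding-window normalization -- see :mod:`swnemg.swn`.
4. Rectification (absolute value).
5. Frame assembly: at each 20 Hz prediction time the trailing
   ``feature_window`` ms are cut into 100 ms segments with 50 ms overlap and
   the segments stacked along the channel axis, so the intra-frame temporal
   length stays constant (50 samples) while the stacked channel count grows
   with the feature window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import EmgRecording, MotionLabels

__all__ = [
    "PreprocConfig",
    "DnnInputSequence",
    "bandpass_decimate",
    "rectify",
    "assemble_frames",
]


@dataclass(frozen=True)
class PreprocConfig:
    band: tuple[float, float] = (40.0, 200.0)
    filter_order: int = 6
    fs_raw: float = 2000.0
    fs_proc: float = 500.0
    segment_len_ms: float = 100.0
    segment_overlap_ms: float = 50.0
    frame_rate: float = 20.0
    feature_window_ms: float = 1000.0

    def __post_init__(self):
        if self.segment_overlap_ms >= self.segment_len_ms:
            raise ValueError("segment_overlap must be smaller than segment_len")
        if self.feature_window_ms < self.segment_len_ms:
            raise ValueError("feature_window must be at least one segment long")
        if (self.fs_proc / self.frame_rate) % 1:
            raise ValueError("fs_proc must be divisible by frame_rate")
        hop = self.segment_len_ms - self.segment_overlap_ms
        if (self.feature_window_ms - self.segment_len_ms) % hop:
            raise ValueError(
                "(feature_window - segment_len) must be a multiple of the segment hop"
            )
        if self.filter_order % 2:
            raise ValueError("band-pass order must be even (second-order sections)")

    @property
    def decim(self) -> int:
        q = self.fs_raw / self.fs_proc
        if q % 1:
            raise ValueError("fs_raw must be an integer multiple of fs_proc")
        return int(q)

    @property
    def seg_samples(self) -> int:
        return int(round(self.segment_len_ms * self.fs_proc / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round((self.segment_len_ms - self.segment_overlap_ms) * self.fs_proc / 1000.0))

    @property
    def window_samples(self) -> int:
        return int(round(self.feature_window_ms * self.fs_proc / 1000.0))

    @property
    def n_segments(self) -> int:
        """Segments per frame: S = (W - seg) / hop + 1."""
        return (self.window_samples - self.seg_samples) // self.hop_samples + 1

    @property
    def frame_hop(self) -> int:
        """Samples at fs_proc between successive 20 Hz frames (50 ms)."""
        return int(self.fs_proc / self.frame_rate)


@dataclass
class DnnInputSequence:
    """Classifier input frames for one trial.

    ``frames`` has shape (F, C_cat, T_seg) with ``C_cat = n_channels * S``
    (segment-major stacking, oldest segment first) and ``T_seg`` the segment
    length in samples (50).  ``frame_times`` are the causal window end times
    on the 20 Hz grid; ``labels`` are aligned by frame end time (each frame
    is labelled with the 50 ms label interval it just completed).
    """

    frames: np.ndarray
    frame_times: np.ndarray
    labels: np.ndarray
    n_channels: int
    config: PreprocConfig

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def bandpass_decimate(rec: EmgRecording, config: PreprocConfig) -> EmgRecording:
    """Causal band-pass then decimate to ``fs_proc``.

    The band-pass is a 6th-order (3 biquad sections) Butterworth applied
    forward-only; decimation applies an explicit causal anti-alias low-pass
    at 80 % of the target Nyquist before keeping every ``q``-th sample.
    Output length is ``ceil(n_samples / q)``.
    """
    if rec.fs != config.fs_raw:
        raise ValueError(f"recording at {rec.fs} Hz but config expects {config.fs_raw}")
    q = config.decim
    sos_bp = sps.butter(
        config.filter_order // 2, config.band, btype="bandpass", fs=config.fs_raw, output="sos"
    )
    y = sps.sosfilt(sos_bp, rec.signal, axis=1)
    sos_aa = sps.butter(8, 0.8 * (config.fs_proc / 2.0), btype="low", fs=config.fs_raw, output="sos")
    y = sps.sosfilt(sos_aa, y, axis=1)
    y = y[:, ::q]
    return EmgRecording(
        signal=y,
        fs=config.fs_proc,
        channel_names=rec.channel_names,
        position_tag=rec.position_tag,
        trial_id=rec.trial_id,
        subject_id=rec.subject_id,
    )


def rectify(signal: np.ndarray) -> np.ndarray:
    """Elementwise absolute value (full-wave rectification)."""
    signal = np.asarray(signal)
    if not np.isfinite(signal).all():
        raise ValueError("non-finite input")
    return np.abs(signal)


def assemble_frames(
    signal: np.ndarray,
    labels: MotionLabels,
    config: PreprocConfig,
    start_offset: int = 0,
) -> DnnInputSequence:
    """Cut a rectified ``(channels, samples)`` signal into classifier frames.

    ``start_offset`` is the index, in the trial's full fs_proc timeline, of
    the first sample of ``signal`` (nonzero when normalization warm-up
    dropped leading samples).  A frame is emitted at each 20 Hz grid time
    whose trailing ``feature_window`` is fully covered by available samples;
    frames therefore never span trial boundaries, and the first frame appears
    once a full window has been seen.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("signal must be (channels, samples)")
    n_ch, n = x.shape
    w = config.window_samples
    hop_f = config.frame_hop
    seg = config.seg_samples
    hop_s = config.hop_samples
    s_count = config.n_segments

    # frame at grid index k ends at trial sample e = k * frame_hop (exclusive
    # end: samples e-w .. e-1); need e - w >= start_offset and e <= offset + n
    k_min = -(-(start_offset + w) // hop_f)  # ceil
    k_max = (start_offset + n) // hop_f
    n_labels = len(labels)
    k_max = min(k_max, n_labels)  # label index k-1 must exist
    if k_max < k_min:
        warnings.warn("signal shorter than the feature window; empty frame sequence")
        return DnnInputSequence(
            frames=np.zeros((0, n_ch * s_count, seg)),
            frame_times=np.zeros(0),
            labels=np.zeros(0, dtype=np.int64),
            n_channels=n_ch,
            config=config,
        )

    ks = np.arange(k_min, k_max + 1)
    # sliding segment view over the local signal
    win_view = np.lib.stride_tricks.sliding_window_view(x, seg, axis=1)  # (C, n-seg+1, seg)
    frames = np.empty((ks.size, n_ch * s_count, seg))
    for fi, k in enumerate(ks):
        e_local = k * hop_f - start_offset  # exclusive end in local samples
        starts = e_local - w + hop_s * np.arange(s_count)  # oldest segment first
        segs = win_view[:, starts, :]  # (C, S, seg)
        frames[fi] = segs.transpose(1, 0, 2).reshape(n_ch * s_count, seg)

    frame_labels = labels.labels[ks - 1]
    return DnnInputSequence(
        frames=frames,
        frame_times=ks / config.frame_rate,
        labels=frame_labels,
        n_channels=n_ch,
        config=config,
    )
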