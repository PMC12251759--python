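"""Preprocessing chain: shape arithmetic, frame-grid enumeration, causal
filtering, rectification, and the full per-trial pipeline."""

import numpy as np
import pytest

from swnemg.pipeline import process_trial
from swnemg.preprocess import (
    PreprocConfig,
    assemble_frames,
    bandpass_decimate,
    rectify,
)
from swnemg.swn import SwnConfig
from swnemg.synth import EmgRecording, MotionLabels


def make_rec(signal, fs=2000.0):
    return EmgRecording(
        signal=signal,
        fs=fs,
        channel_names=tuple(f"ch{i}" for i in range(signal.shape[0])),
        position_tag="center",
        trial_id="T01",
        subject_id="S01",
    )


class TestShapeArithmetic:
    def test_segment_counts(self):
        # S = (W - 100) / 50 + 1 at fs_proc 500, seg 50 samples, hop 25
        assert PreprocConfig(feature_window_ms=1000.0).n_segments == 19
        assert PreprocConfig(feature_window_ms=200.0).n_segments == 3
        assert PreprocConfig(feature_window_ms=100.0).n_segments == 1

    def test_channel_concatenation(self):
        cfg = PreprocConfig(feature_window_ms=1000.0)
        labels = MotionLabels(np.zeros(1200, dtype=np.int64))
        x = np.random.default_rng(0).standard_normal((12, 30000))
        seq = assemble_frames(np.abs(x), labels, cfg)
        assert seq.frames.shape[1] == 228  # 12 channels x 19 segments
        assert seq.frames.shape[2] == 50

    def test_frame_grid_enumeration(self):
        # 60 s trial at 500 Hz, feature window 1000 ms -> (60-1)*20 + 1 frames
        cfg = PreprocConfig(feature_window_ms=1000.0)
        labels = MotionLabels(np.zeros(1200, dtype=np.int64))
        x = np.abs(np.random.default_rng(0).standard_normal((2, 30000)))
        seq = assemble_frames(x, labels, cfg)
        assert seq.n_frames == (60 - 1) * 20 + 1 == 1181

    def test_frame_grid_oracle_any_offset(self):
        """Frame count matches direct enumeration of valid 20 Hz grid times."""
        cfg = PreprocConfig(feature_window_ms=400.0)
        n, offset = 2750, 137
        labels = MotionLabels(np.zeros(130, dtype=np.int64))
        x = np.abs(np.random.default_rng(1).standard_normal((1, n)))
        seq = assemble_frames(x, labels, cfg, start_offset=offset)
        w, hop = cfg.window_samples, cfg.frame_hop
        valid = [
            k
            for k in range(1, len(labels) + 1)
            if k * hop - w >= offset and k * hop <= offset + n
        ]
        assert seq.n_frames == len(valid)
        assert np.allclose(seq.frame_times, np.array(valid) / 20.0)

    def test_degenerate_window_equals_raw_tail(self):
        """feature_window = 100 ms -> one segment = the last 50 samples."""
        cfg = PreprocConfig(feature_window_ms=100.0)
        x = np.abs(np.random.default_rng(2).standard_normal((3, 500)))
        labels = MotionLabels(np.zeros(20, dtype=np.int64))
        seq = assemble_frames(x, labels, cfg)
        for fi, k in enumerate(range(2, seq.n_frames + 2)):
            e = k * cfg.frame_hop
            np.testing.assert_array_equal(seq.frames[fi], x[:, e - 50 : e])

    def test_label_alignment(self):
        """Frame ending at grid index k carries label k-1 (the 50 ms label
        interval the frame just completed)."""
        cfg = PreprocConfig(feature_window_ms=200.0)
        lab = np.arange(40) % 3
        labels = MotionLabels(lab)
        x = np.abs(np.random.default_rng(3).standard_normal((1, 1000)))
        seq = assemble_frames(x, labels, cfg)
        ks = np.round(seq.frame_times * 20).astype(int)
        np.testing.assert_array_equal(seq.labels, lab[ks - 1])

    def test_short_signal_empty_with_warning(self):
        cfg = PreprocConfig(feature_window_ms=1000.0)
        labels = MotionLabels(np.zeros(10, dtype=np.int64))
        with pytest.warns(UserWarning):
            seq = assemble_frames(np.abs(np.ones((2, 100))), labels, cfg)
        assert seq.n_frames == 0

    def test_segment_major_stacking(self):
        """Stacked channel axis is segment-major, oldest segment first."""
        cfg = PreprocConfig(feature_window_ms=200.0)
        x = np.abs(np.random.default_rng(4).standard_normal((2, 600)))
        labels = MotionLabels(np.zeros(24, dtype=np.int64))
        seq = assemble_frames(x, labels, cfg)
        k = int(round(seq.frame_times[0] * 20))
        e = k * cfg.frame_hop
        # segment s of channel c lives at stacked row s * C + c
        for s in range(3):
            start = e - 100 + 25 * s
            for c in range(2):
                np.testing.assert_array_equal(
                    seq.frames[0, s * 2 + c], x[c, start : start + 50]
                )


class TestConfigValidation:
    def test_overlap_must_be_smaller(self):
        with pytest.raises(ValueError):
            PreprocConfig(segment_overlap_ms=100.0)

    def test_window_hop_divisibility(self):
        with pytest.raises(ValueError):
            PreprocConfig(feature_window_ms=230.0)

    def test_odd_filter_order_rejected(self):
        with pytest.raises(ValueError):
            PreprocConfig(filter_order=5)


class TestFiltering:
    def test_decimation_length_and_rate(self, rng):
        rec = make_rec(rng.standard_normal((3, 8000)))
        out = bandpass_decimate(rec, PreprocConfig())
        assert out.fs == 500.0
        assert out.n_samples == 2000

    def test_causality(self, rng):
        """Changing future samples never changes past filter output."""
        cfg = PreprocConfig()
        x = rng.standard_normal((1, 4000))
        x2 = x.copy()
        x2[:, 2000:] += rng.standard_normal((1, 2000))
        y1 = bandpass_decimate(make_rec(x), cfg).signal
        y2 = bandpass_decimate(make_rec(x2), cfg).signal
        np.testing.assert_array_equal(y1[:, :500], y2[:, :500])

    def test_band_selectivity(self):
        """A 100 Hz tone passes; 5 Hz and 600 Hz tones are attenuated."""
        cfg = PreprocConfig()
        t = np.arange(8000) / 2000.0
        gains = {}
        for f in (5.0, 100.0, 600.0):
            rec = make_rec(np.sin(2 * np.pi * f * t)[None, :])
            y = bandpass_decimate(rec, cfg).signal[0, 500:]
            gains[f] = np.sqrt(2) * y.std()
        assert gains[100.0] > 0.9
        assert gains[5.0] < 0.05 and gains[600.0] < 0.05

    def test_sample_rate_mismatch_raises(self, rng):
        rec = make_rec(rng.standard_normal((1, 100)), fs=1000.0)
        with pytest.raises(ValueError):
            bandpass_decimate(rec, PreprocConfig())


class TestRectify:
    def test_abs(self, rng):
        x = rng.standard_normal((2, 30))
        np.testing.assert_array_equal(rectify(x), np.abs(x))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rectify(np.array([1.0, np.inf]))


class TestProcessTrial:
    def test_offsets_account_for_swn_warmup(self, rng):
        rec = make_rec(rng.standard_normal((2, 2000 * 4)))
        labels = MotionLabels(np.zeros(80, dtype=np.int64))
        pcfg = PreprocConfig(feature_window_ms=200.0)
        swn = SwnConfig(window_ms=400.0, fs=500.0)
        seq_n = process_trial(rec, labels, pcfg, None)
        seq_s = process_trial(rec, labels, pcfg, swn)
        # SWN drops L-1 = 199 leading samples, so the first frame moves from
        # grid index ceil(100/25)=4 to ceil((199+100)/25)=12
        assert int(round(seq_n.frame_times[0] * 20)) == 4
        assert int(round(seq_s.frame_times[0] * 20)) == 12

    def test_full_chain_gain_offset_invariance(self, rng):
        """The preprocess chain with SWN inherits per-channel affine
        invariance: gains in [0.5, 2] plus offsets leave frames unchanged."""
        sig = rng.standard_normal((3, 2000 * 3))
        labels = MotionLabels(np.zeros(60, dtype=np.int64))
        pcfg = PreprocConfig(feature_window_ms=200.0)
        swn = SwnConfig(window_ms=400.0, fs=500.0)
        g = rng.uniform(0.5, 2.0, size=(3, 1))
        b = rng.uniform(-2.0, 2.0, size=(3, 1))
        s0 = process_trial(make_rec(sig), labels, pcfg, swn)
        s1 = process_trial(make_rec(g * sig + b), labels, pcfg, swn)
        assert s0.frames.shape == s1.frames.shape and s0.n_frames > 0
        # the causal band-pass turns the constant offset into a transient that
        # decays below 1e-9 within ~1 s; compare frames whose windows start
        # after it (the invariance is exact in steady state)
        keep = s0.frame_times >= 1.4
        assert keep.sum() > 20
        assert np.abs(s0.frames[keep] - s1.frames[keep]).max() <= 1e-9

    def test_no_norm_chain_is_gain_equivariant_not_invariant(self, rng):
        """Without SWN the chain is linear: scaling a channel scales its
        frames, so the no-normalization condition is shift-sensitive."""
        sig = rng.standard_normal((2, 2000 * 3))
        labels = MotionLabels(np.zeros(60, dtype=np.int64))
        pcfg = PreprocConfig(feature_window_ms=200.0)
        s0 = process_trial(make_rec(sig), labels, pcfg, None)
        s1 = process_trial(make_rec(2.0 * sig), labels, pcfg, None)
        assert np.abs(s1.frames - 2.0 * s0.frames).max() <= 1e-9
        assert np.abs(s1.frames - s0.frames).max() > 0.01
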