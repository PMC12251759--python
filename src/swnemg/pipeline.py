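"""End-to-end per-trial processing: raw recording to classifier frames.

Chains the causal stages in the pipeline's fixed order -- band-pass,
decimation, optional sliding-window normalization, rectification, frame
assembly -- tracking the warm-up offset so frames stay aligned to the trial's
20 Hz label grid.
"""

from __future__ import annotations

from dataclasses import replace

from .preprocess import DnnInputSequence, PreprocConfig, assemble_frames, bandpass_decimate, rectify
from .swn import SwnConfig, normalize_stream
from .synth import EmgRecording, MotionLabels

__all__ = ["process_trial"]


def process_trial(
    rec: EmgRecording,
    labels: MotionLabels,
    preproc: PreprocConfig,
    swn: SwnConfig | None = None,
) -> DnnInputSequence:
    """Process one trial into classifier input frames.

    ``swn=None`` selects the no-normalization condition.  When normalization
    is active its sampling rate is forced to ``preproc.fs_proc`` and the
    samples its warm-up withholds are accounted for in the frame grid, so
    the first frame appears once both the normalization window and the
    feature window are filled.
    """
    dec = bandpass_decimate(rec, preproc)
    if swn is not None:
        if swn.fs != preproc.fs_proc:
            swn = replace(swn, fs=preproc.fs_proc)
        y, _, offset = normalize_stream(dec.signal, swn)
    else:
        y, offset = dec.signal, 0
    r = rectify(y)
    return assemble_frames(r, labels, preproc, start_offset=offset)
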