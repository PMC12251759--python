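"""Dataset readers and writers.

On-disk layout of a dataset directory:

* ``<subject>_<position>_<trial>.csv`` -- one trial, comma-separated, header
  row of channel names, '.' decimal, UTF-8; one column per channel.
* ``<subject>_<position>_<trial>.json`` -- sidecar with fs, channel names,
  position tag and ids.
* ``<subject>_<trial>_labels.csv`` -- 20 Hz motion labels.
* ``manifest.json`` -- one record per trial (subject_id, trial_id,
  position_tag, seed, fs).

Frame tensors are stored as NPZ containers with a JSON metadata entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DnnInputSequence, PreprocConfig
from .synth import Benchmark, EmgRecording, MotionLabels

__all__ = [
    "write_recording",
    "read_recording",
    "write_labels",
    "read_labels",
    "write_benchmark",
    "read_benchmark",
    "write_frames",
    "read_frames",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: EmgRecording, path: str | Path) -> Path:
    """Write one trial as CSV plus JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.signal.T, columns=list(rec.channel_names))
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "position_tag": rec.position_tag,
        "trial_id": rec.trial_id,
        "subject_id": rec.subject_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: str | Path, fmt: str = "csv") -> EmgRecording:
    """Read one trial; validates finiteness and sidecar consistency.

    Sampling-rate checks against a processing config are the caller's duty
    (the pipeline raises on mismatch rather than silently resampling).
    """
    path = Path(path)
    if fmt not in ("csv", "container"):
        raise ValueError(f"unsupported format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df[df[col].isna()].index[0])
            raise ValueError(f"NaN sample at row {row}, column {col!r} in {path}")
        names = list(df.columns)
        signal = df.to_numpy().T
    else:
        with np.load(path, allow_pickle=False) as z:
            signal = z["signal"]
        names = meta["channel_names"]
    if names != meta["channel_names"]:
        # re-map by name to the manifest/sidecar channel order
        order = [names.index(c) for c in meta["channel_names"]]
        signal = signal[order]
    if signal.shape[1] < 1:
        raise ValueError(f"empty trial {path}")
    return EmgRecording(
        signal=signal,
        fs=float(meta["fs"]),
        channel_names=tuple(meta["channel_names"]),
        position_tag=meta["position_tag"],
        trial_id=meta["trial_id"],
        subject_id=meta["subject_id"],
    )


def write_labels(labels: MotionLabels, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"label": labels.labels}).to_csv(path, index=False)
    return path


def read_labels(path: str | Path, fs_labels: float = 20.0) -> MotionLabels:
    df = pd.read_csv(path)
    return MotionLabels(df["label"].to_numpy(), fs_labels=fs_labels)


def write_benchmark(bench: Benchmark, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (subject, pos, trial), rec in bench.trials.items():
        write_recording(rec, out / f"{subject}_{pos}_{trial}.csv")
    for (subject, trial), lab in bench.labels.items():
        write_labels(lab, out / f"{subject}_{trial}_labels.csv")
    (out / "manifest.json").write_text(json.dumps(bench.manifest, indent=2))
    return out


def read_benchmark(in_dir: str | Path) -> Benchmark:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    trials, labels = {}, {}
    for row in manifest:
        subj, pos, trial = row["subject_id"], row["position_tag"], row["trial_id"]
        rec = read_recording(src / f"{subj}_{pos}_{trial}.csv")
        if rec.fs != row["fs"]:
            raise ValueError(
                f"sampling rate mismatch for {subj}/{pos}/{trial}: "
                f"sidecar {rec.fs} Hz vs manifest {row['fs']} Hz"
            )
        trials[(subj, pos, trial)] = rec
        if (subj, trial) not in labels:
            labels[(subj, trial)] = read_labels(src / f"{subj}_{trial}_labels.csv")
    return Benchmark(trials=trials, labels=labels, manifest=manifest)


def write_frames(seq: DnnInputSequence, path: str | Path) -> Path:
    path = Path(path)
    from dataclasses import asdict

    meta = {
        "n_channels": seq.n_channels,
        "config": asdict(seq.config),
        "shape": list(seq.frames.shape),
    }
    np.savez(
        path,
        frames=seq.frames,
        frame_times=seq.frame_times,
        labels=seq.labels,
        __meta__=json.dumps(meta),
    )
    return path


def read_frames(path: str | Path) -> DnnInputSequence:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["band"] = tuple(cfg_d["band"])
        return DnnInputSequence(
            frames=z["frames"],
            frame_times=z["frame_times"],
            labels=z["labels"],
            n_channels=int(meta["n_channels"]),
            config=PreprocConfig(**cfg_d),
        )
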