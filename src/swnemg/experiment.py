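"""Experiment orchestration: simulate, process, train, evaluate, test.

Reproduces the full protocol on synthetic data at desk scale: generate a
three-position benchmark, process every trial under each normalization
condition and window-grid cell, train the requested strategies per subject,
assemble the differential-accuracy table, aggregate subject means, and run
the rank statistics.  Every run directory is self-describing (resolved
config, seeds, config hash) and every model artifact is cached under the
config hash so an interrupted run can resume to identical outputs.

A single global seed fans out deterministically to all module seeds via a
CRC-keyed mixing scheme, so one integer reproduces everything.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    accuracy,
    aggregate_subject_means,
    bonferroni,
    make_diff_table,
    scheirer_ray_hare,
    wilcoxon_rank_sum,
)
from .model import CnnLstmClassifier, ModelConfig
from .pipeline import process_trial
from .preprocess import PreprocConfig
from .strategies import TrainConfig, make_splits, predict_trials, train_strategy
from .swn import SwnConfig
from .synth import Benchmark, ShiftModel, SynthConfig, generate_benchmark

__all__ = ["ExperimentConfig", "run_experiment", "vanilla_shift_robustness"]


def _mix(seed: int, *keys: str | int) -> int:
    h = seed & 0x7FFFFFFF
    for k in keys:
        h = (h * 1000003 + (zlib.crc32(str(k).encode()) & 0x7FFFFFFF)) % (2**31)
    return h


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration of one end-to-end experiment.

    Defaults define the desk-scale electrode-shift benchmark: three synthetic
    subjects, eight 25 s trials per position, log-normal shift gains of
    log-SD 0.3 with 10 % neighbour crosstalk, a single window-grid cell
    (400 ms normalization, 200 ms feature window) and short (5-epoch)
    training.
    """

    n_subjects: int = 3
    n_trials_per_position: int = 8
    trial_duration: float = 25.0
    n_channels: int = 12
    fs_raw: float = 2000.0
    gain_log_sd: float = 0.3
    crosstalk_alpha: float = 0.1
    norm_windows: tuple = (400.0,)
    feature_windows: tuple = (200.0,)
    strategies: tuple = ("vanilla",)
    normalizations: tuple = ("swn", "none")
    epochs: int = 5
    batch_size: int = 1
    sequence_length_s: float = 20.0
    lr: float = 1e-2
    lr_retrain: float = 1e-3
    tl_retrain_epochs: int = 10
    focal_gamma: float = 2.0
    grl_lambda: float = 1.0
    domain_loss_weight: float = 1.0
    seed: int = 1

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for k in ("norm_windows", "feature_windows", "strategies", "normalizations"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    # -- derived module configs -------------------------------------------
    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            n_channels=self.n_channels,
            fs_raw=self.fs_raw,
            trial_duration=self.trial_duration,
            n_trials_per_position=self.n_trials_per_position,
            seed=_mix(self.seed, "synth"),
        )

    def shift_models(self) -> list[ShiftModel]:
        return [
            ShiftModel(
                gain_log_sd=self.gain_log_sd,
                crosstalk_alpha=self.crosstalk_alpha,
                position_tag=tag,
                seed=_mix(self.seed, "shift", tag),
            )
            for tag in ("left", "center", "right")
        ]

    def preproc_config(self, feature_ms: float) -> PreprocConfig:
        return PreprocConfig(fs_raw=self.fs_raw, feature_window_ms=feature_ms)

    def swn_config(self, norm_ms: float) -> SwnConfig:
        return SwnConfig(window_ms=norm_ms, fs=500.0)

    def model_config(self, c_cat: int, key: str) -> ModelConfig:
        return ModelConfig(
            n_input_channels=c_cat,
            focal_gamma=self.focal_gamma,
            grl_lambda=self.grl_lambda,
            domain_loss_weight=self.domain_loss_weight,
            seed=_mix(self.seed, "model", key),
        )

    def train_config(self, key: str) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            sequence_length_s=self.sequence_length_s,
            lr=self.lr,
            lr_retrain=self.lr_retrain,
            tl_retrain_epochs=self.tl_retrain_epochs,
            seed=_mix(self.seed, "train", key),
        )


def _process_subject(
    bench: Benchmark, subject: str, pcfg: PreprocConfig, swn_cfg: SwnConfig | None
) -> dict:
    frames = {}
    for (subj, pos, trial), rec in bench.trials.items():
        if subj != subject:
            continue
        frames[(pos, trial)] = process_trial(rec, bench.labels[(subj, trial)], pcfg, swn_cfg)
    return frames


def _train_or_load(cache: Path | None, name: str, fn):
    if cache is not None:
        path = cache / f"{name}.npz"
        if path.exists():
            return CnnLstmClassifier.load(path)
    trained = fn()
    if cache is not None:
        trained.model.save(cache / f"{name}.npz")
    return trained.model


def _evaluate_subject(
    cfg: ExperimentConfig,
    frames: dict,
    subject: str,
    norm_name: str,
    cell: tuple[float, float],
    cache: Path | None,
) -> list[dict]:
    """Differential-accuracy rows for one subject / normalization / grid cell."""
    positions = sorted({p for p, _ in frames})
    splits = make_splits(
        {p: [t for q, t in frames if q == p] for p in positions},
        seed=_mix(cfg.seed, "split", subject),
    )
    c_cat = next(iter(frames.values())).frames.shape[1]
    cell_key = f"{norm_name}_n{cell[0]:g}_f{cell[1]:g}"

    def key(*parts) -> str:
        return "_".join([subject, cell_key, *map(str, parts), cfg.config_hash()])

    # per-position single-position models: baseline at j and vanilla source at i
    pos_models = {}
    for pos in positions:
        mkey = key("vanilla", pos)
        mcfg = cfg.model_config(c_cat, mkey)
        tcfg = cfg.train_config(mkey)
        pos_models[pos] = _train_or_load(
            cache, mkey,
            lambda: train_strategy("vanilla", frames, splits, mcfg, tcfg,
                                   train_position=pos, normalization=norm_name),
        )
    baseline_acc = {}
    for pos in positions:
        preds, labs = predict_trials(pos_models[pos], frames, pos, splits.test(pos))
        baseline_acc[pos] = accuracy(preds, labs)

    rows = []
    for j in positions:
        rows.append(
            {
                "normalization": norm_name, "strategy": "baseline",
                "train_position": j, "test_position": j, "subject": subject,
                "accuracy": baseline_acc[j], "baseline_accuracy": baseline_acc[j],
            }
        )
    for strat in cfg.strategies:
        if strat == "vanilla":
            for i in positions:
                for j in positions:
                    if i == j:
                        continue
                    preds, labs = predict_trials(pos_models[i], frames, j, splits.test(j))
                    rows.append(
                        {
                            "normalization": norm_name, "strategy": "vanilla",
                            "train_position": i, "test_position": j, "subject": subject,
                            "accuracy": accuracy(preds, labs),
                            "baseline_accuracy": baseline_acc[j],
                        }
                    )
        elif strat == "tl":
            for i in positions:
                for j in positions:
                    if i == j:
                        continue
                    mkey = key("tl", i, j)
                    mcfg = cfg.model_config(c_cat, mkey)
                    tcfg = cfg.train_config(mkey)
                    model = _train_or_load(
                        cache, mkey,
                        lambda: train_strategy("tl", frames, splits, mcfg, tcfg,
                                               train_position=(i, j),
                                               normalization=norm_name),
                    )
                    preds, labs = predict_trials(model, frames, j, splits.test(j))
                    rows.append(
                        {
                            "normalization": norm_name, "strategy": "tl",
                            "train_position": i, "test_position": j, "subject": subject,
                            "accuracy": accuracy(preds, labs),
                            "baseline_accuracy": baseline_acc[j],
                        }
                    )
        elif strat in ("mix", "ada"):
            mkey = key(strat)
            mcfg = cfg.model_config(c_cat, mkey)
            tcfg = cfg.train_config(mkey)
            model = _train_or_load(
                cache, mkey,
                lambda: train_strategy(strat, frames, splits, mcfg, tcfg,
                                       normalization=norm_name),
            )
            for j in positions:
                preds, labs = predict_trials(model, frames, j, splits.test(j))
                rows.append(
                    {
                        "normalization": norm_name, "strategy": strat,
                        "train_position": "all", "test_position": j, "subject": subject,
                        "accuracy": accuracy(preds, labs),
                        "baseline_accuracy": baseline_acc[j],
                    }
                )
        else:
            raise ValueError(f"unknown strategy {strat!r}")
    return rows


def run_experiment(
    cfg: ExperimentConfig, out_dir: str | Path, resume: bool = False
) -> dict:
    """Execute simulate -> process -> train -> evaluate -> stats.

    Writes, under ``out_dir``: the resolved config (with hash), the trial
    manifest, the differential-accuracy table, per-subject means, and the
    statistics report.  Model artifacts are cached under ``models/``; with
    ``resume=True`` existing artifacts of the same config hash are reused,
    otherwise a partial run directory of a different hash fails loudly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = out / "models"
    cache.mkdir(exist_ok=True)
    resolved = out / "config.json"
    if resolved.exists():
        prev = json.loads(resolved.read_text())
        if prev.get("config_hash") != cfg.config_hash():
            raise RuntimeError(
                "run directory holds a different configuration; refusing to mix"
            )
        if not resume:
            raise RuntimeError("partial run exists; pass resume=True to continue it")
    resolved.write_text(
        json.dumps({**cfg.to_dict(), "config_hash": cfg.config_hash()}, indent=2)
    )

    bench = generate_benchmark(cfg.synth_config(), cfg.shift_models(), cfg.n_subjects)
    (out / "manifest.json").write_text(json.dumps(bench.manifest, indent=2))

    all_rows = []
    for norm_name in cfg.normalizations:
        norm_windows = cfg.norm_windows if norm_name == "swn" else (0.0,)
        for nw in norm_windows:
            for fw in cfg.feature_windows:
                pcfg = cfg.preproc_config(fw)
                swn_cfg = cfg.swn_config(nw) if norm_name == "swn" else None
                for subject in bench.subjects():
                    frames = _process_subject(bench, subject, pcfg, swn_cfg)
                    all_rows += _evaluate_subject(
                        cfg, frames, subject, norm_name, (nw, fw), cache
                    )

    table = make_diff_table(all_rows)
    table.to_csv(out / "diff_accuracy.csv", index=False)
    means = aggregate_subject_means(table[table["strategy"] != "baseline"])
    means.to_csv(out / "subject_means.csv", index=False)

    stats: dict = {}
    strategies = [s for s in means["strategy"].unique()]
    norms = list(cfg.normalizations)
    if len(norms) == 2:
        pvals = []
        for strat in strategies:
            sel = means["strategy"] == strat
            a = means.loc[sel & (means["normalization"] == norms[0]),
                          "mean_diff_accuracy"].values
            b = means.loc[sel & (means["normalization"] == norms[1]),
                          "mean_diff_accuracy"].values
            if a.size and b.size:
                w, p = wilcoxon_rank_sum(a, b)
                stats[strat] = {"rank_sum": w, "p_raw": p}
                pvals.append((strat, p))
        adj = bonferroni([p for _, p in pvals], m=max(1, len(pvals)))
        for (strat, _), pa in zip(pvals, adj):
            stats[strat]["p_bonferroni"] = float(pa)
        if len(strategies) >= 2:
            sub = means[means["strategy"].isin(strategies)]
            ok = sub.groupby(["normalization", "strategy"]).size().min() >= 2
            if ok:
                srh = scheirer_ray_hare(
                    sub["mean_diff_accuracy"].values,
                    sub["normalization"].values,
                    sub["strategy"].values,
                )
                stats["scheirer_ray_hare"] = {
                    e: {"H": float(r["H"]), "df": int(r["df"]), "p": float(r["p"])}
                    for e, r in srh.iterrows()
                }
    (out / "stats.json").write_text(json.dumps(stats, indent=2))
    return {
        "out_dir": str(out),
        "diff_table": str(out / "diff_accuracy.csv"),
        "subject_means": str(out / "subject_means.csv"),
        "stats": str(out / "stats.json"),
    }


def vanilla_shift_robustness(
    seeds, base: ExperimentConfig | None = None, cache_dir: str | Path | None = None
) -> pd.DataFrame:
    """Scaled-down directional experiment: per seed and normalization
    condition, the mean differential accuracy of the vanilla strategy over
    all subjects and cross-position combinations.

    Returns a DataFrame with columns seed, normalization,
    mean_diff_accuracy.  The headline comparison is whether the sliding-
    window-normalized condition beats the no-normalization condition in most
    seeds.
    """
    base = base or ExperimentConfig()
    out = []
    for seed in seeds:
        cfg = ExperimentConfig.from_dict({**base.to_dict(), "seed": int(seed)})
        bench = generate_benchmark(cfg.synth_config(), cfg.shift_models(), cfg.n_subjects)
        rows = []
        for norm_name in cfg.normalizations:
            nw = cfg.norm_windows[0] if norm_name == "swn" else 0.0
            fw = cfg.feature_windows[0]
            pcfg = cfg.preproc_config(fw)
            swn_cfg = cfg.swn_config(nw) if norm_name == "swn" else None
            for subject in bench.subjects():
                frames = _process_subject(bench, subject, pcfg, swn_cfg)
                rows += _evaluate_subject(cfg, frames, subject, norm_name, (nw, fw), None)
        table = make_diff_table(rows)
        vanilla = table[table["strategy"] == "vanilla"]
        for norm_name, group in vanilla.groupby("normalization"):
            out.append(
                {
                    "seed": int(seed),
                    "normalization": norm_name,
                    "mean_diff_accuracy": float(group["diff_accuracy"].mean()),
                }
            )
    return pd.DataFrame(out)
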