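"""Training regimes and the trial-level split protocol.

Five regimes are supported, all sharing the same classifier, loss and
optimizer settings:

* ``baseline`` -- train and test at the same electrode position (the
  reference accuracy the differential metric subtracts);
* ``vanilla`` -- train on one position's full training pool, test on another
  position (the unadorned cross-position case);
* ``tl`` -- transfer learning: pretrain on the source position, then freeze
  the CNN blocks and fine-tune the LSTM and heads on a small tuning subset
  drawn from the target position's pool, at a reduced learning rate;
* ``mix`` -- pool 30 % of every position's training pool and train once;
* ``ada`` -- the same pooled data as ``mix`` plus an adversarial domain head
  predicting the electrode position through a gradient reversal layer; the
  total loss is the class focal loss plus the domain focal loss.

Splits are drawn at trial granularity: per position, 70 % of trials (floor)
form the training pool and the remainder the common test pool shared by all
regimes.  Because shifted-position trials are derived from the same
underlying center trials in the synthetic benchmark, the split permutation is
seeded identically across positions, so identical trial-id sets split
identically and no underlying trial content leaks from any training pool
into a test pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import CnnLstmClassifier, ModelConfig, build_model, focal_loss_grad, softmax
from .nn import Adam
from .preprocess import DnnInputSequence

__all__ = [
    "STRATEGIES",
    "SplitPlan",
    "TrainConfig",
    "TrainedModel",
    "make_splits",
    "train_strategy",
    "predict_trials",
]

STRATEGIES = ("vanilla", "tl", "ada", "mix", "baseline")
TRAIN_FRACTION = 0.7
TUNE_FRACTION = 0.3  # of the training pool


@dataclass(frozen=True)
class SplitPlan:
    """Per-position train/test pools and the derived per-strategy subsets."""

    pools: dict  # position -> tuple of trial ids (70 %)
    tests: dict  # position -> tuple of trial ids (30 %, common across regimes)
    seed: int

    def pool(self, position: str) -> tuple[str, ...]:
        return self.pools[position]

    def test(self, position: str) -> tuple[str, ...]:
        return self.tests[position]

    def tl_tune(self, position: str) -> tuple[str, ...]:
        n = int(TUNE_FRACTION * len(self.pools[position]))
        return self.pools[position][:n]

    def pooled_train(self) -> dict:
        """ADA/MIX training subset: 30 % (floor) of every position's pool."""
        return {p: self.tl_tune(p) for p in self.pools}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 128
    sequence_length_s: float = 20.0
    lr: float = 1e-3
    lr_retrain: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    tl_retrain_epochs: int = 10
    #: global gradient-norm clip; stabilizes the focal loss, whose gradient
    #: carries a 1/p factor that spikes on confidently wrong frames
    grad_clip_norm: float | None = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.tl_retrain_epochs) < 1:
            raise ValueError("epochs, batch_size and tl_retrain_epochs must be positive")
        if not self.lr_retrain < self.lr:
            raise ValueError("re-training learning rate must be below the training rate")
        if self.grad_clip_norm is not None and self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive or None")


def make_splits(trials_by_position: dict, seed: int) -> SplitPlan:
    """70/30 trial split per position (floor on the training side).

    ``trials_by_position`` maps position tag to an iterable of trial ids.
    Deterministic per seed; positions with identical id sets receive
    identical splits (see module docstring).
    """
    pools, tests = {}, {}
    for pos, ids in trials_by_position.items():
        ids = sorted(ids)
        if len(ids) < 4:
            raise ValueError(f"need at least 4 trials per position, got {len(ids)} at {pos}")
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        perm = rng.permutation(len(ids))
        n_pool = int(TRAIN_FRACTION * len(ids))
        pools[pos] = tuple(ids[i] for i in perm[:n_pool])
        tests[pos] = tuple(ids[i] for i in perm[n_pool:])
    return SplitPlan(pools=pools, tests=tests, seed=seed)


@dataclass
class TrainedModel:
    model: CnnLstmClassifier
    strategy: str
    train_position: str | None
    normalization: str
    log: pd.DataFrame


def _cut_sequences(
    seqs: list[tuple[DnnInputSequence, int]], seq_len: int
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Non-overlapping contiguous runs of ``seq_len`` frames per trial;
    trailing remainder frames are dropped."""
    out = []
    for ds, domain in seqs:
        f = ds.n_frames
        for start in range(0, f - seq_len + 1, seq_len):
            out.append(
                (
                    ds.frames[start : start + seq_len],
                    ds.labels[start : start + seq_len],
                    domain,
                )
            )
    if not out:
        raise ValueError(
            "no training sequence fits: trials are shorter than the sequence length"
        )
    return out


def _run_epochs(
    model: CnnLstmClassifier,
    sequences: list[tuple[np.ndarray, np.ndarray, int]],
    params,
    epochs: int,
    lr: float,
    tcfg: TrainConfig,
    mcfg: ModelConfig,
    use_domain: bool,
    rng: np.random.Generator,
    log_rows: list,
    phase: str,
):
    opt = Adam(params, lr=lr, betas=tcfg.betas)
    n = len(sequences)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for lo in range(0, n, tcfg.batch_size):
            batch = [sequences[i] for i in order[lo : lo + tcfg.batch_size]]
            x = np.stack([b[0] for b in batch])
            y = np.stack([b[1] for b in batch])
            b, f = y.shape
            logits, dom = model.forward(x, train=True, with_domain=use_domain)
            loss, dz = focal_loss_grad(
                logits.reshape(b * f, -1), y.reshape(-1), mcfg.focal_gamma, mcfg.alpha_mode
            )
            d_dom = None
            if use_domain:
                yd = np.repeat([s[2] for s in batch], f)
                dloss, dzd = focal_loss_grad(
                    dom.reshape(b * f, -1), yd, mcfg.focal_gamma, mcfg.alpha_mode
                )
                loss += mcfg.domain_loss_weight * dloss
                d_dom = mcfg.domain_loss_weight * dzd.reshape(b, f, -1)
            opt.zero_grad()
            model.backward(dz.reshape(b, f, -1), d_dom)
            if tcfg.grad_clip_norm is not None:
                gnorm = np.sqrt(sum(float(np.sum(p.g.astype(np.float64) ** 2))
                                    for p in params))
                if gnorm > tcfg.grad_clip_norm:
                    scale = tcfg.grad_clip_norm / gnorm
                    for p in params:
                        p.g *= p.g.dtype.type(scale)
            opt.step()
            total_loss += loss
        log_rows.append({"phase": phase, "epoch": epoch, "loss": total_loss})


def train_strategy(
    strategy: str,
    frames: dict,
    splits: SplitPlan,
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_position: str | None = None,
    normalization: str = "none",
) -> TrainedModel:
    """Train one model under the given regime.

    ``frames`` maps ``(position, trial_id)`` to a :class:`DnnInputSequence`
    for one subject.  ``train_position`` selects the source position for
    ``vanilla``/``baseline`` and the *target* (tuning) position for ``tl``
    is passed via the same argument as a ``(source, target)`` tuple.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    positions = sorted({p for p, _ in frames})
    domain_index = {p: i for i, p in enumerate(positions)}
    use_domain = strategy == "ada"
    mcfg = replace(model_config, with_domain_head=use_domain) if (
        model_config.with_domain_head != use_domain
    ) else model_config
    model = build_model(mcfg)
    frame_rate = next(iter(frames.values())).config.frame_rate
    seq_len = int(round(train_config.sequence_length_s * frame_rate))
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 77]))
    log_rows: list = []

    def gather(position: str, trial_ids) -> list:
        missing = [t for t in trial_ids if (position, t) not in frames]
        if missing:
            raise ValueError(f"missing frames for {position}: {missing}")
        return [(frames[(position, t)], domain_index[position]) for t in trial_ids]

    if strategy in ("vanilla", "baseline"):
        if train_position is None:
            raise ValueError("vanilla/baseline need a train_position")
        seqs = _cut_sequences(gather(train_position, splits.pool(train_position)), seq_len)
        _run_epochs(model, seqs, model.params(), train_config.epochs, train_config.lr,
                    train_config, mcfg, False, rng, log_rows, "train")
    elif strategy == "tl":
        if not isinstance(train_position, tuple) or len(train_position) != 2:
            raise ValueError("tl needs train_position=(source, target)")
        src, tgt = train_position
        if src == tgt:
            raise ValueError("tl source and target positions must differ")
        seqs = _cut_sequences(gather(src, splits.pool(src)), seq_len)
        _run_epochs(model, seqs, model.params(), train_config.epochs, train_config.lr,
                    train_config, mcfg, False, rng, log_rows, "train")
        tune = _cut_sequences(gather(tgt, splits.tl_tune(tgt)), seq_len)
        _run_epochs(model, tune, model.non_cnn_params(), train_config.tl_retrain_epochs,
                    train_config.lr_retrain, train_config, mcfg, False, rng, log_rows,
                    "retrain")
    else:  # ada / mix
        if len(positions) < mcfg.n_domains:
            raise ValueError(f"{strategy} needs data from all positions, got {positions}")
        seqs = []
        for pos, ids in splits.pooled_train().items():
            seqs += gather(pos, ids)
        seqs = _cut_sequences(seqs, seq_len)
        _run_epochs(model, seqs, model.params(), train_config.epochs, train_config.lr,
                    train_config, mcfg, use_domain, rng, log_rows, "train")

    return TrainedModel(
        model=model,
        strategy=strategy,
        train_position=None if isinstance(train_position, tuple) else train_position,
        normalization=normalization,
        log=pd.DataFrame(log_rows),
    )


def predict_trials(
    model: CnnLstmClassifier, frames: dict, position: str, trial_ids
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame predictions over the given trials, each fed as one sequence
    (the recurrent state never crosses a trial boundary)."""
    preds, labels = [], []
    for t in trial_ids:
        ds = frames[(position, t)]
        if ds.n_frames == 0:
            continue
        probs = model.predict_proba(ds.frames[None])
        preds.append(probs[0].argmax(axis=-1))
        labels.append(ds.labels)
    if not preds:
        raise ValueError("no frames to predict")
    return np.concatenate(preds), np.concatenate(labels)
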