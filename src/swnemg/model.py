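"""CNN-LSTM motion classifier with an optional adversarial domain head.

Architecture (per classifier input frame of shape ``C_cat x T_seg``):

* four convolutional blocks, each ``layer norm (joint over channels and
  intra-frame time) -> ReLU -> 1-D conv
  (channel-preserving, kernel 3, stride 1, padding 2) -> dropout`` with
  dropout rates 0.1 / 0.2 / 0.3 / 0.4; anti-aliased blur pooling (kernel 3,
  stride 2, padding 1) is applied once, at the start of the second block, so
  that a 50-sample frame is downsampled to 26 samples before that block's
  convolution;
* global average pooling over the intra-frame time axis, yielding one
  ``C_cat`` feature vector per frame;
* layer norm, two stacked LSTM modules (input and hidden size ``C_cat``)
  each followed by dropout 0.1;
* class head: layer norm -> affine -> softmax over the three motion classes;
* domain head (adversarial domain adaptation only): gradient reversal ->
  layer norm -> affine -> ReLU -> layer norm -> affine -> softmax over the
  three electrode positions.  The head branches from the shared LSTM
  features, so reversed gradients push the extractor toward
  position-invariant features.

The loss is focal loss with label-rate weights:

    L_F = sum_n alpha_{y_n} (1 - p_n)^gamma * CE(y_n, yhat_n),
    alpha_l = count(y = l) / count(y),   p_n = exp(-CE) (true-class prob.)

computed per batch from the batch's true labels.  Note the printed weight
``count_l / count`` up-weights *majority* classes; ``alpha_mode="inverse"``
switches to normalized inverse frequencies for users who want the
conventional balancing behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "PredictionBatch",
    "CnnLstmClassifier",
    "build_model",
    "softmax",
    "focal_loss",
    "focal_loss_grad",
    "gradient_reversal",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    n_input_channels: int = 228
    n_classes: int = 3
    n_domains: int = 3
    t_seg: int = 50
    conv_kernel: int = 3
    conv_padding: int = 2
    dropout_rates: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    lstm_layers: int = 2
    lstm_dropout: float = 0.1
    grl_lambda: float = 1.0
    focal_gamma: float = 2.0
    alpha_mode: str = "as_printed"
    with_domain_head: bool = False
    domain_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_input_channels < 1:
            raise ValueError("n_input_channels must be positive")
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if not np.isfinite(self.grl_lambda):
            raise ValueError("grl_lambda must be finite")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.alpha_mode not in ("as_printed", "inverse"):
            raise ValueError("alpha_mode must be 'as_printed' or 'inverse'")


@dataclass
class PredictionBatch:
    """Per-frame class (and optionally domain) probabilities with labels."""

    class_probs: np.ndarray
    true_labels: np.ndarray
    domain_probs: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.class_probs, dtype=float)
        if p.ndim != 2 or (p < -1e-9).any() or (p > 1 + 1e-9).any():
            raise ValueError("class_probs must be (N, K) probabilities")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        self.class_probs = p
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
        if self.true_labels.shape != (p.shape[0],):
            raise ValueError("true_labels must match the batch size")


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _alpha_weights(labels: np.ndarray, n_classes: int, mode: str) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    total = labels.size
    if mode == "as_printed":
        return counts / total
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    return inv / inv.sum()


def focal_loss(
    batch: PredictionBatch,
    gamma: float = 2.0,
    alpha_mode: str = "as_printed",
) -> float:
    """Focal loss of a prediction batch (summed over samples)."""
    probs = batch.class_probs
    labels = batch.true_labels
    p = probs[np.arange(labels.size), labels]
    if (p < PROB_FLOOR).any():
        warnings.warn("true-class probability below floor; clamping at 1e-12")
        p = np.maximum(p, PROB_FLOOR)
    ce = -np.log(p)
    alpha = _alpha_weights(labels, probs.shape[1], alpha_mode)[labels]
    return float(np.sum(alpha * (1.0 - p) ** gamma * ce))


def focal_loss_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    gamma: float = 2.0,
    alpha_mode: str = "as_printed",
) -> tuple[float, np.ndarray]:
    """Focal loss and its gradient with respect to the logits.

    For one sample with true-class probability ``p`` and softmax row ``q``:
    ``dL/dz_k = dL/dp * p * (1[k = y] - q_k)`` with
    ``dL/dp = alpha * (gamma * (1-p)^(gamma-1) * ln p - (1-p)^gamma / p)``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    q = softmax(logits)
    n = labels.size
    idx = np.arange(n)
    p = np.maximum(q[idx, labels], PROB_FLOOR)
    ce = -np.log(p)
    alpha = _alpha_weights(labels, logits.shape[-1], alpha_mode)[labels]
    one_m = 1.0 - p
    loss = float(np.sum(alpha * one_m**gamma * ce))
    if gamma == 0:
        dldp = -alpha / p
    else:
        dldp = alpha * (gamma * one_m ** (gamma - 1) * np.log(p) - one_m**gamma / p)
    onehot = np.zeros_like(q)
    onehot[idx, labels] = 1.0
    dz = (dldp * p)[:, None] * (onehot - q)
    return loss, dz


def gradient_reversal(features: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """Forward pass of the gradient reversal operation (identity).

    The gradient contract (backward sensitivities multiplied by ``-lam``) is
    carried by :class:`swnemg.nn.GradReversal` inside the model graph.
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    return np.asarray(features)


class CnnLstmClassifier:
    """The full sequence classifier; see the module docstring.

    ``forward`` consumes ``(batch, frames, C_cat, T_seg)`` and returns
    per-frame class logits ``(batch, frames, n_classes)`` plus, when the
    domain head is enabled, domain logits of the same leading shape.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.dtype = nn.DTYPE
        c = config.n_input_channels

        def rng(key: int) -> np.random.Generator:
            return np.random.default_rng(np.random.SeedSequence([config.seed, key]))

        # intra-frame lengths through the blocks (conv pad 2 lengthens by 2;
        # blur pooling at the start of block 2 downsamples once)
        blocks = []
        t_in = config.t_seg
        for bi, rate in enumerate(config.dropout_rates):
            layers = []
            if bi == 1:
                layers.append(nn.BlurPool1d())
                t_in = nn.BlurPool1d.out_len(t_in)
            # joint (channels, time) normalization: per-frame scale is removed
            # but cross-channel amplitude ratios -- the discriminative cue for
            # the unnormalized condition -- are preserved
            layers.append(nn.LayerNorm((c, t_in)))
            layers.append(nn.ReLU())
            layers.append(nn.Conv1d(c, c, config.conv_kernel, config.conv_padding, rng(10 + bi)))
            t_in = t_in + 2 * config.conv_padding - config.conv_kernel + 1
            layers.append(nn.Dropout(rate, rng(1010 + bi)))
            blocks.append(nn.Sequential(*layers))
        self.cnn = nn.Sequential(*blocks, nn.GlobalAvgPool1d())
        self.final_t = t_in

        seq_layers: list[nn.Layer] = [nn.LayerNorm((c,))]
        for li in range(config.lstm_layers):
            seq_layers.append(nn.LSTM(c, None, rng(20 + li)))
            seq_layers.append(nn.Dropout(config.lstm_dropout, rng(1020 + li)))
        self.seq = nn.Sequential(*seq_layers)

        self.class_head = nn.Sequential(
            nn.LayerNorm((c,)), nn.Linear(c, config.n_classes, rng(30), init="zero")
        )
        if config.with_domain_head:
            self.domain_head = nn.Sequential(
                nn.GradReversal(config.grl_lambda),
                nn.LayerNorm((c,)),
                nn.Linear(c, c, rng(40)),
                nn.ReLU(),
                nn.LayerNorm((c,)),
                nn.Linear(c, config.n_domains, rng(41), init="zero"),
            )
        else:
            self.domain_head = None

    # -- parameter access -------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = self.cnn.params() + self.seq.params() + self.class_head.params()
        if self.domain_head is not None:
            out += self.domain_head.params()
        return out

    def cnn_params(self) -> list[nn.Param]:
        return self.cnn.params()

    def non_cnn_params(self) -> list[nn.Param]:
        out = self.seq.params() + self.class_head.params()
        if self.domain_head is not None:
            out += self.domain_head.params()
        return out

    def set_train(self, train: bool):
        for s in (self.cnn, self.seq, self.class_head, self.domain_head):
            if s is not None:
                s.set_train(train)

    # -- forward / backward ------------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, with_domain: bool = False
    ) -> tuple[np.ndarray, np.ndarray | None]:
        if x.ndim != 4:
            raise ValueError("input must be (batch, frames, channels, samples)")
        b, f, c, t = x.shape
        if c != self.config.n_input_channels:
            raise ValueError(
                f"expected {self.config.n_input_channels} stacked channels, got {c}"
            )
        self.set_train(train)
        self._bf = (b, f)
        x = np.ascontiguousarray(x, dtype=self.dtype)
        feats = self.cnn.forward(x.reshape(b * f, c, t))  # (B*F, C)
        feats = self.seq.forward(feats.reshape(b, f, c))  # (B, F, C)
        logits = self.class_head.forward(feats)
        dom = None
        if with_domain:
            if self.domain_head is None:
                raise ValueError("model was built without a domain head")
            dom = self.domain_head.forward(feats)
        self._with_domain = dom is not None
        return logits, dom

    def backward(self, d_logits: np.ndarray, d_domain: np.ndarray | None = None):
        gy = self.class_head.backward(d_logits)
        if d_domain is not None:
            if not self._with_domain:
                raise ValueError("no domain forward pass cached")
            gy = gy + self.domain_head.backward(d_domain)
        gy = self.seq.backward(gy)
        b, f = self._bf
        c = self.config.n_input_channels
        self.cnn.backward(gy.reshape(b * f, c))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, train=False)
        return softmax(logits)

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.v.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for i, p in enumerate(params):
            p.v[...] = state[f"p{i}"]

    def save(self, path):
        import json
        from dataclasses import asdict

        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.state_dict())

    @classmethod
    def load(cls, path) -> "CnnLstmClassifier":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            cfg["dropout_rates"] = tuple(cfg["dropout_rates"])
            model = cls(ModelConfig(**cfg))
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


def build_model(config: ModelConfig) -> CnnLstmClassifier:
    """Construct the classifier from its configuration."""
    return CnnLstmClassifier(config)
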