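"""The two attention-based neural classifiers.

* :class:`FusionNet` — the multimodal early-fusion network: each processed
  128-dim feature block passes through its own fully connected projection,
  the projections are stacked vertically into a short sequence, a
  self-attention layer mixes them, and a fully connected head produces one
  activity logit. Four fully connected layers in total (projections plus
  head; with fewer than three blocks the spare layers form a shared
  pre-head stack).

* :class:`SmilesNet` — the sequence network: token embedding (dimension
  100), four stacked LSTM layers, self-attention over time steps with a
  padding mask, masked mean pooling and a fully connected head.

Both train with Adam on binary cross-entropy, early-stopping on validation
AUC, with fully seeded initialization and batching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor, bce_with_logits, embedding_lookup, stack

logger = logging.getLogger(__name__)

EMBEDDING_DIM = 100   # fixed
N_LSTM_LAYERS = 4     # fixed


@dataclass
class AttentionConfig:
    """Hyperparameters shared by the two attention networks."""

    projection_dim: int = 64
    attention_dim: int = 32
    hidden_dim: int = 64
    lstm_hidden: int = 32
    dropout: float = 0.0
    learning_rate: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 60
    patience: int = 8
    embedding_dim: int = EMBEDDING_DIM
    lstm_layers: int = N_LSTM_LAYERS

    def __post_init__(self) -> None:
        if self.embedding_dim != EMBEDDING_DIM:
            raise ValueError(f"embedding_dim is fixed at {EMBEDDING_DIM}")
        if self.lstm_layers != N_LSTM_LAYERS:
            raise ValueError(f"lstm_layers is fixed at {N_LSTM_LAYERS}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class SelfAttention:
    """Scaled dot-product self-attention with learned Q/K/V projections."""

    def __init__(self, input_dim: int, attention_dim: int, rng: np.random.Generator):
        self.d = attention_dim
        self.Wq = Tensor(_glorot(rng, input_dim, attention_dim), requires_grad=True)
        self.Wk = Tensor(_glorot(rng, input_dim, attention_dim), requires_grad=True)
        self.Wv = Tensor(_glorot(rng, input_dim, attention_dim), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv]

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        """x: (batch, seq, input_dim); pad_mask: (batch, seq) True = real.

        Attention weights are a row softmax of Q K^T / sqrt(d); padded key
        positions are excluded before normalization.
        """
        q = x @ self.Wq
        k = x @ self.Wk
        v = x @ self.Wv
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d))
        if pad_mask is not None:
            bias = np.where(pad_mask[:, None, :], 0.0, -1e9)
            scores = scores + Tensor(bias)
        weights = scores.softmax()
        return weights @ v


class _Linear:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class _LSTMLayer:
    """Single LSTM layer unrolled over time (gate order i, f, g, o)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.h = hidden
        self.Wx = Tensor(_glorot(rng, input_dim, 4 * hidden), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, hidden, 4 * hidden), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias init
        self.b = Tensor(b, requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]

    def __call__(self, xs: list[Tensor], batch: int) -> list[Tensor]:
        h = Tensor(np.zeros((batch, self.h)))
        c = Tensor(np.zeros((batch, self.h)))
        hh = self.h
        out: list[Tensor] = []
        for x_t in xs:
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = z[:, :hh].sigmoid()
            f = z[:, hh : 2 * hh].sigmoid()
            g = z[:, 2 * hh : 3 * hh].tanh()
            o = z[:, 3 * hh :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out


class FusionNet:
    """Early-fusion attention classifier over 1-3 processed feature blocks."""

    def __init__(self, config: AttentionConfig, n_blocks: int, block_dim: int = 128,
                 seed: int = 0):
        if n_blocks not in (1, 2, 3):
            raise ValueError("n_blocks must be 1, 2 or 3")
        rng = np.random.default_rng(seed)
        p = config.projection_dim
        self.n_blocks = n_blocks
        self.block_dim = block_dim
        self.config = config
        self.projections = [_Linear(block_dim, p, rng) for _ in range(n_blocks)]
        self.attention = SelfAttention(p, config.attention_dim, rng)
        # allocate the remaining fully connected layers: with 3 blocks the
        # projections + head already make four; with fewer, spare layers
        # become a shared pre-head stack
        n_extra = 3 - n_blocks
        dims = [n_blocks * config.attention_dim] + [config.hidden_dim] * n_extra
        self.hidden = [_Linear(dims[i], dims[i + 1], rng) for i in range(n_extra)]
        self.head = _Linear(dims[-1], 1, rng)

    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.projections + self.hidden + [self.head]:
            ps.extend(layer.params())
        ps.extend(self.attention.params())
        return ps

    def forward(self, blocks: list[np.ndarray]) -> Tensor:
        """blocks: list of (batch, block_dim) arrays -> (batch, 1) logits."""
        if len(blocks) != self.n_blocks:
            raise ValueError(f"expected {self.n_blocks} blocks, got {len(blocks)}")
        proj = [pl(Tensor(b)).tanh() for pl, b in zip(self.projections, blocks)]
        seq = stack(proj, axis=1)                   # (batch, n_blocks, p)
        att = self.attention(seq)                   # (batch, n_blocks, da)
        flat = att.reshape(att.shape[0], -1)
        x = flat
        for layer in self.hidden:
            x = layer(x).tanh()
        return self.head(x)

    def scores(self, blocks: list[np.ndarray]) -> np.ndarray:
        z = self.forward(blocks).data.ravel()
        return 1.0 / (1.0 + np.exp(-z))


class SmilesNet:
    """Embedding -> 4 LSTM layers -> masked self-attention -> head."""

    def __init__(self, config: AttentionConfig, vocab_size: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        h = config.lstm_hidden
        emb = rng.normal(0, 0.1, size=(vocab_size + 1, config.embedding_dim))
        emb[0] = 0.0  # pad embeds to the zero vector
        self.embedding = Tensor(emb, requires_grad=True)
        self.lstm = [
            _LSTMLayer(config.embedding_dim if i == 0 else h, h, rng)
            for i in range(config.lstm_layers)
        ]
        self.attention = SelfAttention(h, config.attention_dim, rng)
        self.head = _Linear(config.attention_dim, 1, rng)
        self.vocab_size = vocab_size

    def params(self) -> list[Tensor]:
        ps = [self.embedding]
        for layer in self.lstm:
            ps.extend(layer.params())
        ps.extend(self.attention.params())
        ps.extend(self.head.params())
        return ps

    def forward(self, sequences: np.ndarray) -> Tensor:
        """sequences: (batch, max_len) int token ids -> (batch, 1) logits."""
        if sequences.max(initial=0) > self.vocab_size:
            raise ValueError("token id exceeds vocabulary size")
        mask = sequences > 0
        lengths = mask.sum(axis=1)
        if (lengths == 0).any():
            raise ValueError("all-pad sequence in batch")
        t_max = int(lengths.max())
        seq = sequences[:, :t_max]
        mask = mask[:, :t_max]
        emb = embedding_lookup(self.embedding, seq)   # (B, T, E)
        xs = [emb[:, t, :] for t in range(t_max)]
        batch = seq.shape[0]
        for layer in self.lstm:
            xs = layer(xs, batch)
        hseq = stack(xs, axis=1)                      # (B, T, h)
        att = self.attention(hseq, pad_mask=mask)     # (B, T, da)
        pooled = (att * Tensor(mask[:, :, None].astype(float))).sum(axis=1) * Tensor(
            (1.0 / lengths)[:, None]
        )
        return self.head(pooled)

    def scores(self, sequences: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(sequences), 256):
            z = self.forward(sequences[start : start + 256]).data.ravel()
            out.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(out) if out else np.empty(0)


def build_fusion_net(config: AttentionConfig, n_blocks: int,
                     block_dim: int = 128, seed: int = 0) -> FusionNet:
    return FusionNet(config, n_blocks, block_dim=block_dim, seed=seed)


def build_smiles_net(config: AttentionConfig, vocabulary: dict[str, int],
                     seed: int = 0) -> SmilesNet:
    return SmilesNet(config, vocab_size=len(vocabulary), seed=seed)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = -np.inf


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_network(
    net,
    train_inputs,
    train_labels: np.ndarray,
    val_inputs,
    val_labels: np.ndarray,
    config: AttentionConfig | None = None,
    seed: int = 0,
) -> TrainingLog:
    """Train with Adam on binary cross-entropy; early stop on validation AUC.

    ``train_inputs`` is a list of block matrices for :class:`FusionNet` or
    an integer sequence matrix for :class:`SmilesNet`. The network's best
    parameters (by validation AUC) are restored on return.
    """
    config = config or net.config
    rng = np.random.default_rng(seed)
    params = net.params()
    opt = Adam(params, lr=config.learning_rate)
    y_train = np.asarray(train_labels, dtype=float)
    is_fusion = isinstance(train_inputs, list)
    n = len(y_train)

    def slice_inputs(inputs, idx):
        if is_fusion:
            return [b[idx] for b in inputs]
        return inputs[idx]

    def val_scores():
        if is_fusion:
            return net.scores(val_inputs)
        return net.scores(val_inputs)

    log = TrainingLog()
    best_params = [p.data.copy() for p in params]
    stale = 0
    for epoch in range(config.max_epochs):
        losses = []
        for idx in _batches(n, config.batch_size, rng):
            opt.zero_grad()
            xb = slice_inputs(train_inputs, idx)
            logits = net.forward(xb)
            loss = bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss); "
                    f"log so far: {log.epochs}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        sv = val_scores()
        val_auc = roc_auc_score(val_labels, sv) if len(np.unique(val_labels)) > 1 else 0.5
        log.epochs.append({"epoch": epoch, "loss": float(np.mean(losses)),
                           "val_auc": float(val_auc)})
        if val_auc > log.best_val_auc + 1e-6:
            log.best_val_auc = float(val_auc)
            log.best_epoch = epoch
            best_params = [p.data.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for p, best in zip(params, best_params):
        p.data = best
    return log
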