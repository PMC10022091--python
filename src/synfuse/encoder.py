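"""Contrastive SMILES sequence encoder.

A small bidirectional transformer over SMILES tokens is fine-tuned with the
SimCSE objective: each string is encoded twice under independent dropout
masks, the two views form a positive pair, and the other batch members'
second views are the in-batch negatives,

    l_i = -log  exp(sim(h_i, h_i') / tau) / sum_j exp(sim(h_i, h_j') / tau),

with sim(.,.) the cosine similarity and tau a temperature. Dropout is the
only augmentation. No pretrained weights are involved: the encoder starts
from a seeded random initialization and is trained on the working corpus,
which preserves the mechanism at a scale that runs on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Adam, Tensor, concat
from .chem import DEFAULT_VOCAB, SmilesVocab, pad_batch, tokenize_smiles
from .nn import Embedding, LayerNorm, Linear, Module, dropout


@dataclass
class EncoderConfig:
    """Hyperparameters of the SMILES transformer.

    d_model is the embedding width D carried through to the fusion network;
    tau is the contrastive temperature (smaller sharpens the softmax over
    in-batch negatives); dropout_p is both the architectural dropout and the
    SimCSE augmentation noise.
    """

    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 128
    d_ff: int = 256
    dropout_p: float = 0.1
    tau: float = 0.05
    max_len: int = 128
    pooling: str = "cls"  # "cls" or "mean"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_layers, self.n_heads, self.d_model, self.d_ff, self.max_len) < 1:
            raise ValueError("encoder dimensions must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")
        if self.pooling not in ("cls", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


class _SelfAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        self.h = heads
        self.dk = d // heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        b, length, d = x.shape
        def split(t: Tensor) -> Tensor:
            return t.reshape(b, length, self.h, self.dk).swapaxes(1, 2)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))
        bias = (key_mask[:, None, None, :] - 1.0) * 1e9  # pad keys -> -inf
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(b, length, d)
        return self.wo(ctx)


class _EncoderLayer(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.attn = _SelfAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ff1 = Linear(cfg.d_model, cfg.d_ff, rng)
        self.ff2 = Linear(cfg.d_ff, cfg.d_model, rng)
        self.ln2 = LayerNorm(cfg.d_model)
        self.p = cfg.dropout_p

    def __call__(self, x: Tensor, key_mask: np.ndarray,
                 rng: np.random.Generator | None, train: bool) -> Tensor:
        a = dropout(self.attn(x, key_mask), self.p, rng, train)
        x = self.ln1(x + a)
        f = dropout(self.ff2(self.ff1(x).relu()), self.p, rng, train)
        return self.ln2(x + f)


class SmilesEncoder(Module):
    """BERT-style encoder producing one embedding per SMILES string."""

    def __init__(self, cfg: EncoderConfig, vocab: SmilesVocab = DEFAULT_VOCAB):
        cfg.validate()
        self.cfg = cfg
        self.vocab = vocab
        rng = np.random.default_rng(cfg.seed)
        self.tok = Embedding(len(vocab), cfg.d_model, rng)
        self.pos = Embedding(cfg.max_len, cfg.d_model, rng)
        self.layers = [_EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def forward_tokens(self, ids: np.ndarray, key_mask: np.ndarray,
                       rng: np.random.Generator | None = None,
                       train: bool = False) -> Tensor:
        if ids.ndim != 2 or ids.shape[0] == 0:
            raise ValueError("expected a non-empty (batch, length) index array")
        b, length = ids.shape
        x = self.tok(ids) + self.pos(np.arange(length))
        x = dropout(x, self.cfg.dropout_p, rng, train)
        for layer in self.layers:
            x = layer(x, key_mask, rng, train)
        if self.cfg.pooling == "cls":
            return x[:, 0, :]
        denom = key_mask.sum(axis=1, keepdims=True)
        return (x * Tensor(key_mask[:, :, None])).sum(axis=1) * Tensor(1.0 / denom)

    def encode(self, sequences: list[np.ndarray],
               rng: np.random.Generator | None = None,
               train: bool = False) -> Tensor:
        """Encode tokenized sequences; eval mode is deterministic."""
        if len(sequences) == 0:
            raise ValueError("empty batch")
        ids, mask = pad_batch(sequences, self.vocab)
        return self.forward_tokens(ids, mask, rng=rng, train=train)

    def encode_smiles(self, smiles: list[str]) -> np.ndarray:
        """Deterministic eval-mode embeddings for a list of SMILES strings."""
        seqs = [tokenize_smiles(s, self.vocab, self.cfg.max_len) for s in smiles]
        return self.encode(seqs, train=False).data


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _row_normalize(h: Tensor) -> Tensor:
    norm = ((h * h).sum(axis=1, keepdims=True)) ** 0.5
    return h * norm**-1.0


def simcse_loss(h1: Tensor | np.ndarray, h2: Tensor | np.ndarray,
                tau: float) -> Tensor:
    """Mean in-batch contrastive loss over N positive pairs (rows of h1, h2)."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    if not isinstance(h1, Tensor):
        h1 = Tensor(h1)
    if not isinstance(h2, Tensor):
        h2 = Tensor(h2)
    n = h1.shape[0]
    if n < 1 or h2.shape[0] != n:
        raise ValueError("h1 and h2 must hold the same positive batch size N >= 1")
    sims = (_row_normalize(h1) @ _row_normalize(h2).swapaxes(0, 1)) * (1.0 / tau)
    shift = Tensor(sims.data.max(axis=1, keepdims=True))  # constant shift, exact
    shifted = sims - shift
    log_p = shifted - shifted.exp().sum(axis=1, keepdims=True).log()
    diag = log_p[np.arange(n), np.arange(n)]
    return -diag.mean()


def finetune(corpus: list[str], cfg: EncoderConfig, epochs: int,
             batch_size: int = 16, lr: float = 1e-3,
             encoder: SmilesEncoder | None = None,
             ) -> tuple[SmilesEncoder, list[float]]:
    """SimCSE fine-tuning on a SMILES corpus.

    Returns the trained encoder and the per-step loss trace. All
    stochasticity (shuffling, dropout masks) derives from cfg.seed, so a
    repeated call reproduces the trace exactly. epochs=0 returns the freshly
    initialized encoder untouched.
    """
    cfg.validate()
    if encoder is None:
        encoder = SmilesEncoder(cfg)
    if epochs == 0:
        return encoder, []
    if len(corpus) < min(batch_size, 2):
        raise ValueError("corpus smaller than a single training batch")
    seqs = [tokenize_smiles(s, encoder.vocab, cfg.max_len) for s in corpus]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51CE]))
    opt = Adam(encoder.parameters(), lr=lr)
    trace: list[float] = []
    idx = np.arange(len(seqs))
    for _ in range(epochs):
        rng.shuffle(idx)
        for start in range(0, len(idx), batch_size):
            batch = [seqs[i] for i in idx[start : start + batch_size]]
            if len(batch) < 2:
                continue  # one pair has zero loss by construction
            h1 = encoder.encode(batch, rng=rng, train=True)
            h2 = encoder.encode(batch, rng=rng, train=True)
            loss = simcse_loss(h1, h2, cfg.tau)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite contrastive loss at step {len(trace)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(loss.item())
    return encoder, trace


def mean_positive_pair_cosine(encoder: SmilesEncoder, corpus: list[str],
                              seed: int = 0) -> float:
    """Mean cosine between two dropout views of each corpus string.

    The quantity SimCSE training should increase: alignment of positive
    pairs under the encoder's own dropout noise.
    """
    rng = np.random.default_rng(seed)
    seqs = [tokenize_smiles(s, encoder.vocab, encoder.cfg.max_len) for s in corpus]
    h1 = encoder.encode(seqs, rng=rng, train=True).data
    h2 = encoder.encode(seqs, rng=rng, train=True).data
    return float(np.mean([cosine_sim(a, b) for a, b in zip(h1, h2)]))
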