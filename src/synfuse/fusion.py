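"""Dual feature fusion: dimensional alignment, vector-level multi-head
attention with a projected residual, and a bit-level highway network.

The five inputs per record — fingerprint of drug A, fingerprint of drug B,
cell-line expression, SMILES embedding of drug A, SMILES embedding of
drug B — are each projected to a shared width d (g(x) = Wx + b) and
concatenated in that fixed order into l = (f_A', f_B', z', x_A', x_B').

The two fusion paths read l at different granularities:

* vector level — l as a 5-token sequence (one token per feature vector),
  reweighted by scaled dot-product multi-head attention, plus a projected
  residual l W^R, then ReLU;
* bit level — l as one flat 5d vector passed through highway layers
  m = g (.) t(l) + (1 - g) (.) q(l), a sigmoid-gated blend of a ReLU
  transform and a linear carry.

The prediction head sums the two paths, layer-normalizes, and maps to a
single synergy logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .autograd import Tensor, concat, stack
from .nn import LayerNorm, Linear, Module, dropout


@dataclass
class FusionConfig:
    """Fusion-network hyperparameters.

    d: shared aligned dimension (all five inputs are projected to d).
    n_heads must divide d; highway_layers >= 1. The ablation switches zero
    out a path or an input wholesale, leaving the rest of the graph intact.
    """

    d: int = 256
    n_heads: int = 4
    highway_layers: int = 2
    dropout_p: float = 0.1
    out_proj: bool = False
    no_attention: bool = False
    no_highway: bool = False
    no_smiles: bool = False
    no_fingerprint: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.d < 1 or self.n_heads < 1:
            raise ValueError("d and n_heads must be positive")
        if self.d % self.n_heads:
            raise ValueError(f"n_heads={self.n_heads} must divide d={self.d}")
        if self.highway_layers < 1:
            raise ValueError("highway_layers must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.no_attention and self.no_highway:
            raise ValueError("cannot ablate both fusion paths at once")
        if self.no_smiles and self.no_fingerprint:
            raise ValueError("cannot ablate both drug inputs at once")


class AlignedFeatureSet(NamedTuple):
    """The five aligned d-dimensional feature tensors, batch-first."""

    f_a: Tensor
    f_b: Tensor
    z: Tensor
    x_a: Tensor
    x_b: Tensor


class FusionInput(NamedTuple):
    """Concatenation l in both granularities: (B, 5d) flat and (B, 5, d)."""

    flat: Tensor
    mat: Tensor


class DualFusionOutput(NamedTuple):
    m_vec: Tensor  # (B, 5d) attention path
    m_bit: Tensor  # (B, 5d) highway path
    m_x: Tensor    # (B, 5d) sum of the two
    logit: Tensor  # (B,)
    prob: Tensor   # (B,)


def build_fusion_input(aligned: AlignedFeatureSet) -> FusionInput:
    dims = {t.shape[-1] for t in aligned}
    if len(dims) != 1:
        raise ValueError(f"aligned features have mixed dimensions {sorted(dims)}")
    d = dims.pop()
    mat = stack(list(aligned), axis=-2)          # (..., 5, d)
    flat = concat(list(aligned), axis=-1)        # (..., 5d)
    assert mat.shape[-2:] == (5, d)
    return FusionInput(flat=flat, mat=mat)


class AttentionPath(Module):
    """Eq.-style multi-head attention over the 5 feature tokens.

    Per head, Q = l W^Q, K = l W^K, V = l W^V (no biases), attention
    softmax(Q K^T / sqrt(d_k)) V with d_k = d / h; head outputs are
    concatenated along the feature axis. A projected residual l W^R is
    added and ReLU applied, so every output entry is >= 0.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 out_proj: bool = False):
        if d % n_heads:
            raise ValueError("n_heads must divide d")
        self.h = n_heads
        self.dk = d // n_heads
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wr = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng, bias=False) if out_proj else None

    def __call__(self, mat: Tensor, return_parts: bool = False):
        b, n_tok, d = mat.shape
        def split(t: Tensor) -> Tensor:
            return t.reshape(b, n_tok, self.h, self.dk).swapaxes(1, 2)
        q, k, v = split(self.wq(mat)), split(self.wk(mat)), split(self.wv(mat))
        weights = ((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))).softmax(axis=-1)
        attended = (weights @ v).swapaxes(1, 2).reshape(b, n_tok, d)
        if self.wo is not None:
            attended = self.wo(attended)
        residual = self.wr(mat)
        m_vec = (attended + residual).relu().reshape(b, n_tok * d)
        if return_parts:
            return m_vec, weights, attended
        return m_vec


class _HighwayLayer(Module):
    def __init__(self, width: int, rng: np.random.Generator):
        self.transform = Linear(width, width, rng)
        self.carry = Linear(width, width, rng)
        self.gate = Linear(width, width, rng)

    def __call__(self, x: Tensor, return_parts: bool = False):
        g = self.gate(x).sigmoid()
        t = self.transform(x).relu()
        q = self.carry(x)
        out = g * t + (1.0 - g) * q
        if return_parts:
            return out, g, t, q
        return out


class HighwayPath(Module):
    """Stack of sigmoid-gated highway layers over the flat 5d vector."""

    def __init__(self, width: int, n_layers: int, rng: np.random.Generator):
        if n_layers < 1:
            raise ValueError("highway needs at least one layer")
        self.layers = [_HighwayLayer(width, rng) for _ in range(n_layers)]

    def __call__(self, flat: Tensor) -> Tensor:
        x = flat
        for layer in self.layers:
            x = layer(x)
        return x


class PredictionHead(Module):
    """m_x = m_vec + m_bit -> LayerNorm -> linear -> sigmoid probability."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.norm = LayerNorm(width)
        self.out = Linear(width, 1, rng)

    def __call__(self, m_x: Tensor) -> tuple[Tensor, Tensor]:
        logit = self.out(self.norm(m_x)).reshape(m_x.shape[0])
        return logit, logit.sigmoid()


class DualFusionNetwork(Module):
    """Alignment + both fusion paths + prediction head for one batch.

    Alignment weights are shared between drug A and drug B within each
    modality (one fingerprint projector, one SMILES projector), so the two
    drugs are featurized identically; the concatenation order still makes
    the network order-sensitive, as specified.
    """

    def __init__(self, cfg: FusionConfig, n_bits: int, n_genes: int,
                 d_smiles: int):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF05]))
        d = cfg.d
        self.align_fp = Linear(n_bits, d, rng)
        self.align_expr = Linear(n_genes, d, rng)
        self.align_smiles = Linear(d_smiles, d, rng)
        self.attention = AttentionPath(d, cfg.n_heads, rng, out_proj=cfg.out_proj)
        self.highway = HighwayPath(5 * d, cfg.highway_layers, rng)
        self.head = PredictionHead(5 * d, rng)

    def align(self, fp_a: Tensor, fp_b: Tensor, expr: Tensor,
              emb_a: Tensor, emb_b: Tensor) -> AlignedFeatureSet:
        if self.cfg.no_fingerprint:
            fp_a = Tensor(np.zeros_like(fp_a.data))
            fp_b = Tensor(np.zeros_like(fp_b.data))
        if self.cfg.no_smiles:
            emb_a = Tensor(np.zeros_like(emb_a.data))
            emb_b = Tensor(np.zeros_like(emb_b.data))
        return AlignedFeatureSet(
            f_a=self.align_fp(fp_a),
            f_b=self.align_fp(fp_b),
            z=self.align_expr(expr),
            x_a=self.align_smiles(emb_a),
            x_b=self.align_smiles(emb_b),
        )

    def __call__(self, fp_a, fp_b, expr, emb_a, emb_b,
                 rng: np.random.Generator | None = None,
                 train: bool = False) -> DualFusionOutput:
        as_t = lambda x: x if isinstance(x, Tensor) else Tensor(x)
        aligned = self.align(as_t(fp_a), as_t(fp_b), as_t(expr),
                             as_t(emb_a), as_t(emb_b))
        p = self.cfg.dropout_p
        aligned = AlignedFeatureSet(*(dropout(t, p, rng, train) for t in aligned))
        l = build_fusion_input(aligned)
        b = l.flat.shape[0]
        width = l.flat.shape[-1]
        if self.cfg.no_attention:
            m_vec = Tensor(np.zeros((b, width)))
        else:
            m_vec = dropout(self.attention(l.mat), p, rng, train)
        if self.cfg.no_highway:
            m_bit = Tensor(np.zeros((b, width)))
        else:
            m_bit = dropout(self.highway(l.flat), p, rng, train)
        m_x = m_vec + m_bit
        logit, prob = self.head(m_x)
        return DualFusionOutput(m_vec=m_vec, m_bit=m_bit, m_x=m_x,
                                logit=logit, prob=prob)
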