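"""BiLSTM + multi-head attention prediction head and the full model.

The head runs three stacked bidirectional LSTM layers (standard gate
recursion: input, forget and output gates with sigmoid activation, a tanh
candidate cell, and output h_t = tanh(c_t) * o_t), with dropout between
layers 1-2 and 2-3.  Scaled dot-product self-attention with three heads is
computed over the BiLSTM states; the BiLSTM output and the attention output
are concatenated, fused by a 1x1 convolution, and a dense layer with
softmax produces per-residue class probabilities.

The full model composes: feature projection with dropout -> improved TCN ->
BiLSTM -> multi-head attention -> classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import FeatureMatrix
from .mstcn import BidirSpec, ImprovedTCN
from .nn import autodiff as ad
from .nn import Dropout, Linear, Module, Tensor, init_uniform, no_grad


@dataclass(frozen=True)
class RecurrentSpec:
    """Stacked bidirectional LSTM layers with inter-layer dropout."""

    layers: int = 3
    hidden: int = 64
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("need at least one LSTM layer")


@dataclass(frozen=True)
class AttentionSpec:
    """Multi-head scaled dot-product self-attention."""

    heads: int = 3
    model_width: int = 128
    d_k: int | None = None     # per-head key width; default model_width//heads

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ValueError("need at least one attention head")

    def key_width(self) -> int:
        if self.d_k is not None:
            if self.d_k < 1:
                raise ValueError("d_k must be positive")
            return self.d_k
        return max(self.model_width // self.heads, 1)


@dataclass(frozen=True)
class ClassifierSpec:
    """1x1 fusion of BiLSTM and attention outputs, dense layer, softmax."""

    classes: int = 3
    fused_width: int = 64


class LSTMCellStack(Module):
    """One-direction LSTM over a padded (B, L, D) batch.

    Gate order in the packed weight matrices is (input, forget, output,
    candidate); the input projection for all time steps is computed in a
    single matrix product, the hidden recursion steps position by position.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.w_x = init_uniform(rng, (d_in, 4 * hidden), d_in)
        self.w_h = init_uniform(rng, (hidden, 4 * hidden), hidden)
        self.bias = init_uniform(rng, (4 * hidden,), hidden)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden
        xp = ad.add(ad.matmul(x, self.w_x), self.bias)      # (B, L, 4H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(L):
            gates = ad.add(ad.reshape(ad.narrow(xp, 1, t, 1), (B, 4 * H)),
                           ad.matmul(h, self.w_h))
            i = ad.sigmoid(ad.narrow(gates, -1, 0, H))
            f = ad.sigmoid(ad.narrow(gates, -1, H, H))
            o = ad.sigmoid(ad.narrow(gates, -1, 2 * H, H))
            g = ad.tanh(ad.narrow(gates, -1, 3 * H, H))
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(ad.tanh(c), o)
            outs.append(ad.reshape(h, (B, 1, H)))
        return ad.concat(outs, axis=1)


class BiLSTM(Module):
    """Stacked bidirectional LSTM; output width is 2 * hidden."""

    def __init__(self, d_in: int, spec: RecurrentSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.forward_cells = []
        self.backward_cells = []
        width = d_in
        for _ in range(spec.layers):
            self.forward_cells.append(LSTMCellStack(width, spec.hidden, rng))
            self.backward_cells.append(LSTMCellStack(width, spec.hidden, rng))
            width = 2 * spec.hidden
        # two dropout layers: between layers 1-2 and 2-3
        self.drops = [Dropout(spec.dropout, rng)
                      for _ in range(max(spec.layers - 1, 0))]

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        h = x
        for layer in range(self.spec.layers):
            fwd = self.forward_cells[layer](h)
            rev = ad.reverse_padded(h, lengths)
            bwd = ad.reverse_padded(self.backward_cells[layer](rev), lengths)
            h = ad.concat([fwd, bwd], axis=-1)
            if layer < len(self.drops):
                h = self.drops[layer](h)
        return h

    @property
    def out_width(self) -> int:
        return 2 * self.spec.hidden


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention, heads concatenated then projected.

    Padded key positions are masked out of the softmax so attention weights
    over valid positions sum to one.
    """

    def __init__(self, d_in: int, spec: AttentionSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        d_k = spec.key_width()
        self.d_k = d_k
        self.w_q = [init_uniform(rng, (d_in, d_k), d_in) for _ in range(spec.heads)]
        self.w_k = [init_uniform(rng, (d_in, d_k), d_in) for _ in range(spec.heads)]
        self.w_v = [init_uniform(rng, (d_in, d_k), d_in) for _ in range(spec.heads)]
        self.w_o = init_uniform(rng, (spec.heads * d_k, spec.model_width),
                                spec.heads * d_k)

    def __call__(self, h: Tensor, mask: np.ndarray | None = None,
                 return_weights: bool = False):
        B, L, _ = h.shape
        if mask is None:
            bias = 0.0
        else:
            key_valid = mask[:, :, 0]                        # (B, L)
            bias = np.where(key_valid[:, None, :] > 0, 0.0, -1e9)  # (B, 1->L, L)
        heads = []
        weights = []
        for i in range(self.spec.heads):
            q = ad.matmul(h, self.w_q[i])
            k = ad.matmul(h, self.w_k[i])
            v = ad.matmul(h, self.w_v[i])
            scores = ad.mul(ad.matmul(q, ad.transpose_last(k)),
                            1.0 / np.sqrt(self.d_k))
            attn = ad.softmax(ad.add(scores, bias), axis=-1)
            heads.append(ad.matmul(attn, v))
            if return_weights:
                weights.append(attn.data)
        out = ad.matmul(ad.concat(heads, axis=-1), self.w_o)
        if return_weights:
            return out, weights
        return out


class Classifier(Module):
    """Concat -> 1x1 convolution -> dense -> softmax over classes."""

    def __init__(self, d_bilstm: int, d_attn: int, spec: ClassifierSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.conv1x1 = Linear(d_bilstm + d_attn, spec.fused_width, rng)
        self.dense = Linear(spec.fused_width, spec.classes, rng)

    def logits(self, h_bilstm: Tensor, h_attn: Tensor) -> Tensor:
        z = self.conv1x1(ad.concat([h_bilstm, h_attn], axis=-1))
        return self.dense(z)

    def __call__(self, h_bilstm: Tensor, h_attn: Tensor) -> Tensor:
        return ad.softmax(self.logits(h_bilstm, h_attn), axis=-1)


class SSModel(Module):
    """Full secondary-structure model.

    Pipeline: feature projection (with dropout) -> improved TCN -> BiLSTM
    -> multi-head self-attention over the BiLSTM states -> classifier.
    """

    def __init__(self, d_features: int, tcn: BidirSpec,
                 recurrent: RecurrentSpec, attention: AttentionSpec,
                 classifier: ClassifierSpec, embed_dropout: float = 0.2,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.embed = Linear(d_features, tcn.out_width, rng)
        self.embed_drop = Dropout(embed_dropout, rng)
        self.tcn = ImprovedTCN(tcn.out_width, tcn, rng)
        self.bilstm = BiLSTM(tcn.out_width, recurrent, rng)
        self.attention = MultiHeadAttention(self.bilstm.out_width, attention, rng)
        self.classifier = Classifier(self.bilstm.out_width,
                                     attention.model_width, classifier, rng)

    def forward_batch(self, x: Tensor, lengths: np.ndarray,
                      mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Return (probabilities, logits), both (B, L, K)."""
        h = self.embed_drop(self.embed(x))
        h = self.tcn(h, lengths, mask)
        h = self.bilstm(h, lengths)
        a = self.attention(h, mask)
        logits = self.classifier.logits(h, a)
        return ad.softmax(logits, axis=-1), logits


def forward(features: FeatureMatrix, model: SSModel) -> np.ndarray:
    """Evaluation-mode forward pass for one record: (L, K) probability rows."""
    if features.length == 0:
        raise ValueError("empty sequence")
    was_training = model.training
    model.eval()
    L = features.length
    with no_grad():
        probs, _ = model.forward_batch(Tensor(features.rows[None]),
                                       np.array([L]), np.ones((1, L, 1)))
    if was_training:
        model.train()
    return probs.data[0]
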