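"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the segment-overlap
score is computed from explicit position sets, the micro-averaged AUC from
exhaustive positive/negative pair comparison, and the BiLSTM from plain
nested loops over the gate equations.
"""

from __future__ import annotations

import numpy as np


def sov99_bruteforce(observed: str, predicted: str) -> float:
    """Naive SOV99: enumerate segments as position sets, literally."""

    def runs(s: str) -> list[tuple[str, set[int]]]:
        out: list[tuple[str, set[int]]] = []
        for i, ch in enumerate(s):
            if out and out[-1][0] == ch:
                out[-1][1].add(i)
            else:
                out.append((ch, {i}))
        return out

    obs = runs(observed)
    pred = runs(predicted)
    states = {ch for ch, _ in obs}
    total = 0.0
    norm = 0
    for state in states:
        s1_list = [p for ch, p in obs if ch == state]
        s2_list = [p for ch, p in pred if ch == state]
        for s1 in s1_list:
            overlapping = [s2 for s2 in s2_list if s1 & s2]
            if not overlapping:
                norm += len(s1)
                continue
            for s2 in overlapping:
                minov = len(s1 & s2)
                maxov = max(s1 | s2) - min(s1 | s2) + 1
                delta = min(maxov - minov, minov,
                            int(len(s1) / 2), int(len(s2) / 2))
                total += (minov + delta) / maxov * len(s1)
                norm += len(s1)
    if norm == 0:
        return 0.0
    return 100.0 * total / norm


def auc_pairwise(y: np.ndarray, scores: np.ndarray) -> float:
    """P(score of random positive > random negative), ties counted half."""
    y = np.asarray(y).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def lstm_unrolled(x: np.ndarray, w_x: np.ndarray, w_h: np.ndarray,
                  b: np.ndarray) -> np.ndarray:
    """One-direction LSTM by plain loops; gate order (i, f, o, g).

    i_t = sigm(x_t W_xi + h_{t-1} W_hi + b_i), same for f_t, o_t;
    g_t = tanh(...); c_t = f_t c_{t-1} + i_t g_t; h_t = tanh(c_t) o_t.
    """
    L = x.shape[0]
    H = w_h.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    out = np.zeros((L, H))
    sigm = lambda v: 1.0 / (1.0 + np.exp(-v))
    for t in range(L):
        z = x[t] @ w_x + h @ w_h + b
        i = sigm(z[0:H])
        f = sigm(z[H:2 * H])
        o = sigm(z[2 * H:3 * H])
        g = np.tanh(z[3 * H:4 * H])
        c = f * c + i * g
        h = np.tanh(c) * o
        out[t] = h
    return out


def bilstm_unrolled(x: np.ndarray, fwd_weights: list[tuple],
                    bwd_weights: list[tuple]) -> np.ndarray:
    """Stacked bidirectional LSTM by loops: per layer run the forward cell
    left-to-right and the backward cell on the reversed input, re-reverse,
    concatenate."""
    h = x
    for (wxf, whf, bf), (wxb, whb, bb) in zip(fwd_weights, bwd_weights):
        fwd = lstm_unrolled(h, wxf, whf, bf)
        bwd = lstm_unrolled(h[::-1], wxb, whb, bb)[::-1]
        h = np.concatenate([fwd, bwd], axis=1)
    return h
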