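"""Per-residue featurization: one-hot, physicochemical properties, embeddings.

Each residue is represented by the concatenation of three blocks:

* a 21-column one-hot block over the canonical amino acids plus 'X',
* a physicochemical block (polarity class one-hot, net charge at pH 7,
  min-max-scaled residue mass, min-max-scaled Kyte-Doolittle hydropathy),
* a learned skip-gram embedding of the residue's k-mer token.

The skip-gram embeddings are trained with negative sampling on overlapping
k-mer tokens of the training sequences; k = 1 keeps the embedding exactly
positionwise.  Unknown residues ('X') and out-of-vocabulary tokens map to
the zero vector so unknowns stay uninformative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import CANONICAL_RESIDUES, RESIDUE_ALPHABET, ProteinRecord

POLARITY_CLASSES = ("nonpolar", "polar", "positive", "negative")

_ONE_HOT_INDEX = {ch: i for i, ch in enumerate(RESIDUE_ALPHABET)}


@dataclass(frozen=True)
class PhysChemTable:
    """Per-residue property vectors (P = 7 columns).

    Columns: 4-class polarity one-hot, integer net charge at pH 7, residue
    mass min-max scaled to [0, 1], Kyte-Doolittle hydropathy scaled to
    [0, 1].  'X' gets the all-zero vector.
    """

    vectors: dict[str, np.ndarray]

    @property
    def width(self) -> int:
        return len(next(iter(self.vectors.values())))

    @classmethod
    def default(cls) -> "PhysChemTable":
        """Load the property table shipped with the package."""
        with resources.files("tcnss.data").joinpath("physchem.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhysChemTable":
        missing = set(CANONICAL_RESIDUES) - set(df["residue"])
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        w = df["weight"].to_numpy(float)
        h = df["hydropathy"].to_numpy(float)
        w_scaled = (w - w.min()) / (w.max() - w.min())
        h_scaled = (h - h.min()) / (h.max() - h.min())
        vectors: dict[str, np.ndarray] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            pol = np.zeros(len(POLARITY_CLASSES))
            pol[POLARITY_CLASSES.index(row.polarity)] = 1.0
            vectors[row.residue] = np.concatenate(
                [pol, [float(row.charge)], [w_scaled[i]], [h_scaled[i]]])
        vectors["X"] = np.zeros(len(POLARITY_CLASSES) + 3)
        return cls(vectors)


@dataclass
class FeatureMatrix:
    """L x D per-residue feature rows for one record."""

    record_id: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rows)):
            raise ValueError(f"non-finite features for record {self.record_id!r}")

    @property
    def length(self) -> int:
        return self.rows.shape[0]

    @property
    def width(self) -> int:
        return self.rows.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window segmentation; width must be odd so windows have centers."""

    width: int = 19
    stride: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if self.width % 2 == 0:
            raise ValueError("window width must be odd")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a residue string (L x 21, columns A..Y then X)."""
    out = np.zeros((len(sequence), len(RESIDUE_ALPHABET)))
    for i, ch in enumerate(sequence):
        j = _ONE_HOT_INDEX.get(ch)
        if j is None:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")
        out[i, j] = 1.0
    return out


def physchem(sequence: str, table: PhysChemTable | None = None) -> np.ndarray:
    """Physicochemical property rows for a residue string (L x P)."""
    if table is None:
        table = PhysChemTable.default()
    rows = []
    for i, ch in enumerate(sequence):
        vec = table.vectors.get(ch)
        if vec is None:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")
        rows.append(vec)
    return np.array(rows) if rows else np.zeros((0, table.width))


def _kmer_tokens(sequence: str, k: int) -> list[str]:
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


@dataclass
class EmbeddingModel:
    """Skip-gram-with-negative-sampling embeddings over k-mer tokens."""

    k: int
    dim: int
    window: int
    epochs: int
    negative: int
    seed: int
    vocab: dict[str, int] = field(default_factory=dict)
    vectors: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def vector(self, token: str) -> np.ndarray:
        """Embedding vector of a token; zero for out-of-vocabulary tokens."""
        idx = self.vocab.get(token)
        if idx is None or "X" in token:
            return np.zeros(self.dim)
        return self.vectors[idx]

    def similarity(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))

    def save(self, prefix: str | Path) -> None:
        """Persist as a plain-text vector table plus a JSON sidecar."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".vec"), "w") as fh:
            for token, idx in self.vocab.items():
                vals = " ".join(f"{v:.9e}" for v in self.vectors[idx])
                fh.write(f"{token} {vals}\n")
        meta = {"k": self.k, "dim": self.dim, "window": self.window,
                "epochs": self.epochs, "negative": self.negative,
                "seed": self.seed}
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingModel":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        vocab: dict[str, int] = {}
        rows = []
        with open(prefix.with_suffix(".vec")) as fh:
            for line in fh:
                parts = line.split()
                vocab[parts[0]] = len(rows)
                rows.append([float(v) for v in parts[1:]])
        model = cls(**meta)
        model.vocab = vocab
        model.vectors = np.array(rows) if rows else np.zeros((0, meta["dim"]))
        return model


def train_embeddings(corpus: list[str], k: int = 1, window: int = 5,
                     dim: int = 16, epochs: int = 20, negative: int = 5,
                     seed: int = 0, lr: float = 0.05) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling on k-mer tokens.

    The vocabulary is the set of k-mers observed in `corpus`; sampling and
    initialization are driven by `seed` so identical inputs give bitwise
    identical vectors.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    token_seqs = [_kmer_tokens(s.upper(), k) for s in corpus]
    token_seqs = [t for t in token_seqs if t]
    if not token_seqs:
        raise ValueError(f"no sequence in corpus reaches length k={k}")

    vocab: dict[str, int] = {}
    counts: list[int] = []
    encoded: list[np.ndarray] = []
    for toks in token_seqs:
        ids = []
        for t in toks:
            if t not in vocab:
                vocab[t] = len(vocab)
                counts.append(0)
            idx = vocab[t]
            counts[idx] += 1
            ids.append(idx)
        encoded.append(np.array(ids, dtype=np.int64))
    V = len(vocab)
    freq = np.array(counts, dtype=float)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, dim)) - 0.5) / dim   # target vectors
    w_out = np.zeros((V, dim))                  # context vectors
    # unigram^0.75 negative-sampling distribution
    neg_p = freq ** 0.75
    neg_p /= neg_p.sum()

    for _epoch in range(epochs):
        for ids in encoded:
            n = len(ids)
            for pos in range(n):
                center = ids[pos]
                span = rng.integers(1, window + 1)
                lo, hi = max(0, pos - span), min(n, pos + span + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = ids[cpos]
                    targets = np.empty(negative + 1, dtype=np.int64)
                    targets[0] = ctx
                    targets[1:] = rng.choice(V, size=negative, p=neg_p)
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    v = w_in[center]
                    u = w_out[targets]
                    scores = 1.0 / (1.0 + np.exp(-np.clip(u @ v, -35, 35)))
                    g = (labels - scores) * lr
                    w_in[center] = v + g @ u
                    w_out[targets] = u + np.outer(g, v)

    model = EmbeddingModel(k=k, dim=dim, window=window, epochs=epochs,
                           negative=negative, seed=seed)
    model.vocab = vocab
    model.vectors = w_in
    return model


def featurize_record(record: ProteinRecord,
                     table: PhysChemTable | None = None,
                     emb: EmbeddingModel | None = None) -> FeatureMatrix:
    """Concatenate [one-hot | physchem | embedding] rows for one record.

    k-mer embedding vectors are assigned to the k-mer's first residue; the
    trailing k-1 positions (which start no k-mer) get the zero vector.  With
    the default k = 1 the embedding block is exactly positionwise.
    """
    if table is None:
        table = PhysChemTable.default()
    seq = record.sequence
    blocks = [one_hot(seq), physchem(seq, table)]
    if emb is not None:
        L = len(seq)
        e = np.zeros((L, emb.dim))
        for i, tok in enumerate(_kmer_tokens(seq, emb.k)):
            e[i] = emb.vector(tok)
        blocks.append(e)
    return FeatureMatrix(record_id=record.id, rows=np.hstack(blocks))


def windows(features: FeatureMatrix,
            spec: WindowSpec = WindowSpec()) -> list[tuple[int, np.ndarray]]:
    """Cut a feature matrix into centered sliding windows.

    Out-of-range positions are filled with zero padding rows; with stride 1
    the window centers cover every residue.
    """
    L, D = features.rows.shape
    half = spec.width // 2
    padded = np.zeros((L + 2 * half, D))
    padded[half:half + L] = features.rows
    out = []
    for center in range(0, L, spec.stride):
        out.append((center, padded[center:center + spec.width].copy()))
    return out
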