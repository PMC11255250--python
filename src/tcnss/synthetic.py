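"""Synthetic protein corpora with segmental secondary-structure labels.

Labels are drawn from a semi-Markov chain: a state is held for a
geometrically distributed dwell (so segments have controllable mean
lengths, which exercises the segment-overlap metric's boundary-tolerance
logic), then a transition row picks the next state.  Residues are emitted
per position from a state-dependent distribution over the 20 canonical
amino acids, a mixture of a state-preferred residue set and the uniform
background controlled by a sharpness parameter.  The preferred sets follow
textbook propensities (helix formers A/E/L/M/Q/K/R/H, strand formers
V/I/Y/C/W/F/T, coil/turn formers G/N/P/S/D).

An oracle teacher produces cached logits from the true labels (margin at
the true class plus Gaussian noise), standing in for a large protein
language model at desk scale.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .distill import TeacherLogits
from .seqdata import (CANONICAL_RESIDUES, ProteinRecord, Q3, Q8, StateAlphabet,
                      reduce_to_q3, write_fasta, write_labels)

#: Residues each three-state class prefers to emit.
PREFERRED_RESIDUES = {
    "H": "AELMQKRH",
    "E": "VIYCWFT",
    "C": "GNPSD",
}


def _default_emission(alphabet: StateAlphabet, sharpness: float) -> np.ndarray:
    """Per-state residue distributions: sharpness-weighted preferred set
    mixed with the uniform background."""
    n_res = len(CANONICAL_RESIDUES)
    rows = []
    for state in alphabet.states:
        key = state if state in PREFERRED_RESIDUES else reduce_to_q3(state)
        preferred = PREFERRED_RESIDUES[key]
        p = np.full(n_res, (1.0 - sharpness) / n_res)
        for ch in preferred:
            p[CANONICAL_RESIDUES.index(ch)] += sharpness / len(preferred)
        rows.append(p / p.sum())
    return np.array(rows)


def _uniform_offdiag(k: int) -> np.ndarray:
    t = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(t, 0.0)
    return t


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic corpus."""

    n_records: int = 20
    length_range: tuple[int, int] = (30, 60)
    alphabet: StateAlphabet = Q3
    transition: np.ndarray | None = None       # default: uniform off-diagonal
    mean_segment_length: float | np.ndarray = 5.0
    emission: np.ndarray | None = None         # default: preferred-set mixture
    emission_sharpness: float = 0.7
    teacher_noise: float = 0.5
    seed: int = 0

    def resolve(self) -> "GeneratorConfig":
        k = self.alphabet.size
        transition = (self.transition if self.transition is not None
                      else _uniform_offdiag(k))
        transition = np.asarray(transition, dtype=float)
        if transition.shape != (k, k) or not np.allclose(transition.sum(1), 1.0):
            raise ValueError("transition must be a row-stochastic KxK matrix")
        emission = (self.emission if self.emission is not None
                    else _default_emission(self.alphabet,
                                           self.emission_sharpness))
        emission = np.asarray(emission, dtype=float)
        if (emission.shape != (k, len(CANONICAL_RESIDUES))
                or not np.allclose(emission.sum(1), 1.0)):
            raise ValueError("emission must be a row-stochastic Kx20 matrix")
        means = np.broadcast_to(np.asarray(self.mean_segment_length,
                                           dtype=float), (k,)).copy()
        if np.any(means < 1.0):
            raise ValueError("mean segment lengths must be >= 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        return replace(self, transition=transition, emission=emission,
                       mean_segment_length=means)


def generate(cfg: GeneratorConfig) -> list[ProteinRecord]:
    """Draw a corpus of labeled records from the semi-Markov emission model."""
    cfg = cfg.resolve()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.alphabet.size
    records = []
    for i in range(cfg.n_records):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        states: list[int] = []
        state = int(rng.integers(k))
        while len(states) < L:
            mean = cfg.mean_segment_length[state]
            # numpy's geometric has support >= 1 with mean 1/p
            dwell = int(rng.geometric(1.0 / mean))
            states.extend([state] * dwell)
            state = int(rng.choice(k, p=cfg.transition[state]))
        states = states[:L]
        residues = "".join(
            CANONICAL_RESIDUES[int(rng.choice(len(CANONICAL_RESIDUES),
                                              p=cfg.emission[s]))]
            for s in states)
        labels = "".join(cfg.alphabet.states[s] for s in states)
        if cfg.alphabet.states == Q8.states:
            rec = ProteinRecord(id=f"syn{i:04d}", sequence=residues,
                                labels8=labels, labels3=reduce_to_q3(labels))
        else:
            rec = ProteinRecord(id=f"syn{i:04d}", sequence=residues,
                                labels3=labels)
        records.append(rec)
    return records


def oracle_teacher(records: list[ProteinRecord], noise_sd: float = 0.5,
                   margin: float = 5.0, seed: int = 0,
                   alphabet: StateAlphabet = Q3) -> TeacherLogits:
    """Teacher logits derived from the true labels.

    Each row has `margin` at the true class and 0 elsewhere, plus Gaussian
    noise of standard deviation `noise_sd`.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    logits: dict[str, np.ndarray] = {}
    for rec in records:
        labels = rec.labels(alphabet)
        z = np.zeros((rec.length, alphabet.size))
        z[np.arange(rec.length), alphabet.encode(labels)] = margin
        if noise_sd > 0:
            z += rng.normal(0.0, noise_sd, z.shape)
        logits[rec.id] = z
    return TeacherLogits(logits=logits, classes="".join(alphabet.states),
                         teacher_name="oracle")


def easy_preset(n_records: int = 20, length: int = 40,
                seed: int = 0) -> GeneratorConfig:
    """Deterministic-emission corpus: each state emits one distinct residue,
    so the label string is a function of the residue string (A->H, V->E,
    G->C).  Used for overfit/convergence checks."""
    emission = np.zeros((3, len(CANONICAL_RESIDUES)))
    for row, res in enumerate("AVG"):
        emission[row, CANONICAL_RESIDUES.index(res)] = 1.0
    return GeneratorConfig(n_records=n_records, length_range=(length, length),
                           alphabet=Q3, emission=emission,
                           mean_segment_length=5.0, seed=seed)


def hard_preset(n_records: int = 100, seed: int = 0) -> GeneratorConfig:
    """Overlapping-emission corpus: residues only weakly determine states,
    so models overfit small training sets and regularization (such as
    distillation toward softened teacher targets) has headroom to matter.
    The distillation comparison uses the first 30 records for training,
    the next 10 for validation-checkpoint selection and the rest as test."""
    return GeneratorConfig(n_records=n_records, length_range=(30, 40),
                           alphabet=Q3, emission_sharpness=0.5,
                           mean_segment_length=5.0, teacher_noise=0.5,
                           seed=seed)


def write_corpus(records: list[ProteinRecord], outdir, stem: str = "corpus",
                 teacher: TeacherLogits | None = None) -> None:
    """Write FASTA + label files (+ optional teacher logits) to a directory."""
    from pathlib import Path

    from .distill import write_teacher_logits

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, outdir / f"{stem}.fasta")
    if all(r.labels8 is not None for r in records):
        write_labels({r.id: r.labels8 for r in records},
                     outdir / f"{stem}.ss8")
    if all(r.labels(Q3) is not None for r in records):
        write_labels({r.id: r.labels(Q3) for r in records},
                     outdir / f"{stem}.ss3")
    if teacher is not None:
        write_teacher_logits(teacher, outdir / f"{stem}.teacher.jsonl")
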