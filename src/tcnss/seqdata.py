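"""Sequence and secondary-structure label I/O, state alphabets, dataset splitting.

Secondary structure is handled in the two standard DSSP-derived alphabets:
the eight-state alphabet (H, G, I, E, B, T, S, C) and its three-state
reduction (H, E, C).  The reduction merges the helical states (H, G, I) into
H, the strand states (E, B) into E and the remaining states (C, S, T) into
the coil class C.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in alphabetical one-letter order, plus 'X'
#: for unknown/non-standard residues.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_ALPHABET = CANONICAL_RESIDUES + "X"


@dataclass(frozen=True)
class StateAlphabet:
    """An ordered secondary-structure state alphabet with fixed class indices."""

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("alphabet states must be unique")

    @property
    def index_of(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}

    @property
    def size(self) -> int:
        return len(self.states)

    def validate(self, labels: str, context: str = "") -> None:
        idx = self.index_of
        for pos, ch in enumerate(labels):
            if ch not in idx:
                where = f" in {context}" if context else ""
                raise ValueError(
                    f"invalid state character {ch!r} at position {pos + 1}{where}; "
                    f"expected one of {''.join(self.states)}"
                )

    def encode(self, labels: str) -> list[int]:
        idx = self.index_of
        return [idx[ch] for ch in labels]


#: Eight-state DSSP alphabet in fixed order (class indices are reproducible).
Q8 = StateAlphabet(tuple("HGIEBTSC"))
#: Three-state alphabet: helix, strand, coil.
Q3 = StateAlphabet(tuple("HEC"))

# Positionwise 8-state -> 3-state reduction: helical states to H, strand
# states to E, everything else to coil.
_Q8_TO_Q3 = str.maketrans({"H": "H", "G": "H", "I": "H",
                           "E": "E", "B": "E",
                           "C": "C", "S": "C", "T": "C"})


@dataclass
class ProteinRecord:
    """One protein chain: identifier, residue string and optional labels."""

    id: str
    sequence: str
    labels8: str | None = None
    labels3: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for name, labels, alphabet in (("labels8", self.labels8, Q8),
                                       ("labels3", self.labels3, Q3)):
            if labels is None:
                continue
            if len(labels) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: {name} length {len(labels)} != "
                    f"sequence length {len(self.sequence)}"
                )
            alphabet.validate(labels, context=f"record {self.id!r} {name}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def labels(self, alphabet: StateAlphabet) -> str:
        """Return this record's labels in the requested alphabet.

        Q3 labels are derived on the fly from Q8 labels when only the latter
        are present.
        """
        if alphabet.states == Q3.states:
            if self.labels3 is not None:
                return self.labels3
            if self.labels8 is not None:
                return reduce_to_q3(self.labels8)
        elif alphabet.states == Q8.states:
            if self.labels8 is not None:
                return self.labels8
        raise ValueError(f"record {self.id!r} has no labels for alphabet "
                         f"{''.join(alphabet.states)}")


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic random train/test split of whole chains."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file.

    Sequences are uppercased and wrapped lines joined; any character outside
    the 21-letter residue alphabet is mapped to ``'X'`` and the number of
    substitutions is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    n_subs = 0
    valid = set(RESIDUE_ALPHABET)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in valid:
                cleaned.append(ch)
            else:
                cleaned.append("X")
                n_subs += 1
        records.append(ProteinRecord(id=rec.id, sequence="".join(cleaned)))
    if n_subs:
        logger.warning("read_fasta(%s): mapped %d non-standard residue "
                       "characters to 'X'", path, n_subs)
    if not records:
        logger.warning("read_fasta(%s): no records found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path: str | Path, alphabet: StateAlphabet) -> dict[str, str]:
    """Read per-residue labels from a FASTA-like ``.ss3``/``.ss8`` file.

    Each entry is a ``>id`` header followed by one label string (wrapping
    allowed) over `alphabet`.  Duplicate ids and out-of-alphabet characters
    raise :class:`ValueError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    current_id: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        labels = "".join(parts)
        alphabet.validate(labels, context=f"id {current_id!r}")
        if current_id in out:
            raise ValueError(f"duplicate id {current_id!r} in {path}")
        out[current_id] = labels

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()
                if not header:
                    raise ValueError(f"{path}:{lineno}: malformed header (empty id)")
                current_id = header[0]
                parts = []
            else:
                if current_id is None:
                    raise ValueError(f"{path}:{lineno}: label line before any header")
                parts.append(line.strip().upper())
    flush()
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, lab in labels.items():
            fh.write(f">{rec_id}\n{lab}\n")


def reduce_to_q3(labels8: str) -> str:
    """Reduce an eight-state label string to three states.

    H, G, I -> H (helix);  E, B -> E (strand);  C, S, T -> C (coil).
    """
    Q8.validate(labels8)
    return labels8.translate(_Q8_TO_Q3)


def attach_labels(records: list[ProteinRecord], labels: Mapping[str, str],
                  alphabet: StateAlphabet) -> list[ProteinRecord]:
    """Return new records with labels from `labels` attached."""
    out = []
    for rec in records:
        lab = labels.get(rec.id)
        if lab is None:
            raise KeyError(f"no labels for record {rec.id!r}")
        if alphabet.states == Q8.states:
            out.append(ProteinRecord(rec.id, rec.sequence, labels8=lab,
                                     labels3=reduce_to_q3(lab)))
        else:
            out.append(ProteinRecord(rec.id, rec.sequence, labels3=lab))
    return out


def split_records(records: list[ProteinRecord],
                  spec: SplitSpec = SplitSpec()) -> tuple[list[ProteinRecord],
                                                          list[ProteinRecord]]:
    """Randomly split whole chains into train/test sets.

    The split is deterministic in (records order, seed); the unit is the
    whole chain, never individual residues, so no sequence contributes to
    both sides.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = round(spec.train_fraction * n)
    n_train = min(max(n_train, 1), n - 1)
    order = list(range(n))
    random.Random(spec.seed).shuffle(order)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [records[i] for i in train_idx], [records[i] for i in test_idx]
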