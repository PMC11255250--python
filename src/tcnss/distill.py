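"""Knowledge-distillation objective with a pluggable cached-logits teacher.

The student is trained against a blend of the hard-label cross-entropy and
a soft distillation term: the KL divergence from the teacher's
temperature-softened class distribution to the student's,

    L = (1 - alpha) * CE(student, labels) + alpha * rho^2 * KL(T_rho || S_rho)

where ``T_rho = softmax(Z_T / rho)`` and likewise for the student.  The
rho^2 factor keeps the soft-gradient magnitude comparable across
temperatures (the classic distillation convention); it can be disabled.
The teacher itself is abstracted as cached per-residue logits keyed by
record id, read from a JSON-lines file whose header declares the class
order, so any teacher model (e.g. a large protein language model) can be
plugged in without being loaded here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqdata import ProteinRecord, StateAlphabet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistillConfig:
    """Temperature and blend weight of the distillation objective."""

    temperature: float = 2.0
    alpha: float = 0.2
    scale_by_temperature_sq: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class TeacherLogits:
    """Cached per-residue class scores from an external teacher model."""

    logits: dict[str, np.ndarray]
    classes: str
    teacher_name: str = "unknown"

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.logits

    def __getitem__(self, record_id: str) -> np.ndarray:
        return self.logits[record_id]

    def validate_against(self, records: list[ProteinRecord]) -> None:
        for rec in records:
            z = self.logits.get(rec.id)
            if z is not None and z.shape[0] != rec.length:
                raise ValueError(
                    f"teacher logits for {rec.id!r} have {z.shape[0]} rows "
                    f"but the sequence has {rec.length} residues")


def soften(z: np.ndarray, rho: float) -> np.ndarray:
    """Temperature-softened softmax along the last axis.

    Larger rho flattens the distribution, so more of the teacher's
    between-class structure ("dark knowledge") survives in the targets.
    """
    if rho <= 0:
        raise ValueError("temperature rho must be positive")
    z = np.asarray(z, dtype=float) / rho
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def kd_loss(z_student: np.ndarray, z_teacher: np.ndarray,
            cfg: DistillConfig = DistillConfig()) -> float:
    """Distillation loss: mean positionwise KL(teacher || student), softened.

    Both logit matrices are (L, K); the result is scaled by rho^2 when
    `cfg.scale_by_temperature_sq` is set.  Zero exactly when the softened
    distributions agree.
    """
    z_student = np.asarray(z_student, dtype=float)
    z_teacher = np.asarray(z_teacher, dtype=float)
    if z_student.shape != z_teacher.shape:
        raise ValueError("student and teacher logit shapes differ")
    rho = cfg.temperature
    p_t = soften(z_teacher, rho)
    log_t = _log_softmax(z_teacher / rho)
    log_p_s = _log_softmax(z_student / rho)
    kl = (p_t * (log_t - log_p_s)).sum(axis=-1).mean()
    if cfg.scale_by_temperature_sq:
        kl *= rho ** 2
    return float(max(kl, 0.0))


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def cross_entropy(probs: np.ndarray, labels: str,
                  alphabet: StateAlphabet) -> float:
    """Mean negative log probability of the true class, in nats."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape[0] != len(labels):
        raise ValueError("probability rows and label string differ in length")
    idx = alphabet.encode(labels)
    p = probs[np.arange(len(labels)), idx]
    return float(-np.log(np.clip(p, 1e-300, None)).mean())


def total_loss(probs_student: np.ndarray, labels: str,
               z_student: np.ndarray, z_teacher: np.ndarray | None,
               alphabet: StateAlphabet,
               cfg: DistillConfig = DistillConfig()) -> float:
    """Blend of hard cross-entropy and the soft distillation term.

    With alpha = 0 (or no teacher logits, which logs a notice) this reduces
    to plain hard-label training.
    """
    hard = cross_entropy(probs_student, labels, alphabet)
    if cfg.alpha == 0.0:
        return hard
    if z_teacher is None:
        logger.info("no teacher logits for this record; using hard loss only")
        return hard
    soft = kd_loss(z_student, z_teacher, cfg)
    return (1.0 - cfg.alpha) * hard + cfg.alpha * soft


def read_teacher_logits(path: str | Path,
                        alphabet: StateAlphabet) -> TeacherLogits:
    """Read cached teacher logits from a JSON-lines file.

    The first line is a header object ``{"classes": "HEC", "teacher": ...}``
    whose class order must match `alphabet`; each further line is
    ``{"id": ..., "logits": [[...], ...]}`` with K columns.

    A directory is also accepted: one ``<record id>.tsv`` matrix per
    record, K tab-separated columns in alphabet order.
    """
    path = Path(path)
    if path.is_dir():
        logits = {}
        for tsv in sorted(path.glob("*.tsv")):
            z = np.loadtxt(tsv, ndmin=2)
            if z.shape[1] != alphabet.size:
                raise ValueError(
                    f"logits in {tsv.name} must have {alphabet.size} columns")
            logits[tsv.stem] = z
        return TeacherLogits(logits=logits,
                             classes="".join(alphabet.states))
    logits: dict[str, np.ndarray] = {}
    classes = ""
    teacher_name = "unknown"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if lineno == 1 and "classes" in obj and "id" not in obj:
                classes = obj["classes"]
                teacher_name = obj.get("teacher", teacher_name)
                if tuple(classes) != alphabet.states:
                    raise ValueError(
                        f"teacher class order {classes!r} does not match "
                        f"alphabet {''.join(alphabet.states)!r}")
                continue
            rec_id = obj["id"]
            if rec_id in logits:
                raise ValueError(f"duplicate id {rec_id!r} in {path}")
            z = np.asarray(obj["logits"], dtype=float)
            if z.ndim != 2 or z.shape[1] != alphabet.size:
                raise ValueError(
                    f"logits for {rec_id!r} must have {alphabet.size} columns")
            logits[rec_id] = z
    return TeacherLogits(logits=logits, classes=classes or
                         "".join(alphabet.states), teacher_name=teacher_name)


def write_teacher_logits(teacher: TeacherLogits, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps({"classes": teacher.classes,
                             "teacher": teacher.teacher_name}) + "\n")
        for rec_id, z in teacher.logits.items():
            fh.write(json.dumps({"id": rec_id,
                                 "logits": np.asarray(z).tolist()}) + "\n")
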