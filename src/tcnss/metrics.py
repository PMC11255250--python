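"""Evaluation metrics for secondary-structure prediction.

Three metrics are provided:

* **SOV99** — the segment-overlap score.  Labels are decomposed into maximal
  same-state runs (segments).  For each state i, every overlapping pair
  (s1 observed, s2 predicted) contributes ``(minov + delta) / maxov * len(s1)``
  where minov is the actual overlap, maxov the total extent of the pair, and
  delta a boundary-tolerance allowance capped at half of the shorter segment:
  ``delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2)``.  The score is
  normalized by N = sum over states of segment lengths of all paired observed
  segments (once per pair) plus the lengths of observed segments with no
  overlapping prediction, and scaled to [0, 100].
* **accuracy** — percentage of residues whose predicted state matches the
  observed one (Q3 or Q8 depending on the alphabet in use).
* **miauc** — micro-averaged one-vs-rest ROC AUC: all (position, class)
  score/indicator pairs are pooled and a single ROC curve is integrated by
  the trapezoidal rule (ties therefore count one half).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.metrics import roc_auc_score

from .seqdata import ProteinRecord, StateAlphabet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """A maximal same-state run: half-open residue interval [start, end)."""

    state: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


def segments(labels: str) -> list[Segment]:
    """Decompose a label string into maximal same-state segments, in order."""
    out = []
    pos = 0
    for state, run in groupby(labels):
        n = sum(1 for _ in run)
        out.append(Segment(state, pos, pos + n))
        pos += n
    return out


def _overlap(a: Segment, b: Segment) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def sov99(observed: str, predicted: str,
          alphabet: StateAlphabet | None = None) -> float:
    """Segment-overlap score (SOV99 variant) as a percentage in [0, 100]."""
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted labels differ in length")
    if alphabet is not None:
        alphabet.validate(observed)
        alphabet.validate(predicted)
    obs_segs = segments(observed)
    pred_segs = segments(predicted)

    total = 0.0
    n_norm = 0
    states = {s.state for s in obs_segs}
    for state in states:
        s1_list = [s for s in obs_segs if s.state == state]
        s2_list = [s for s in pred_segs if s.state == state]
        for s1 in s1_list:
            pairs = [s2 for s2 in s2_list if _overlap(s1, s2) > 0]
            if not pairs:
                n_norm += s1.length            # unmatched observed segment
                continue
            for s2 in pairs:
                minov = _overlap(s1, s2)
                maxov = max(s1.end, s2.end) - min(s1.start, s2.start)
                delta = min(maxov - minov, minov,
                            s1.length // 2, s2.length // 2)
                total += (minov + delta) / maxov * s1.length
                n_norm += s1.length
    if n_norm == 0:
        logger.warning("sov99: no observed segments; returning 0")
        return 0.0
    return 100.0 * total / n_norm


def accuracy(observed: str, predicted: str) -> float:
    """Residue-level accuracy (Q3/Q8 depending on the labels) in percent."""
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted labels differ in length")
    if not observed:
        raise ValueError("cannot compute accuracy of empty strings")
    n_correct = sum(o == p for o, p in zip(observed, predicted))
    return 100.0 * n_correct / len(observed)


def state_counts(observed: str, predicted: str) -> dict[str, int]:
    """Correctly predicted residue counts per observed state."""
    counts: dict[str, int] = {}
    for o, p in zip(observed, predicted):
        if o == p:
            counts[o] = counts.get(o, 0) + 1
    return counts


def miauc(observed: str, scores: np.ndarray,
          alphabet: StateAlphabet) -> float:
    """Micro-averaged one-vs-rest ROC AUC over all (position, class) pairs."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != len(observed):
        raise ValueError("scores must be an L x K matrix aligned with labels")
    if scores.shape[1] != alphabet.size:
        raise ValueError("score columns must match the alphabet size")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    y = np.zeros_like(scores)
    idx = alphabet.encode(observed)
    y[np.arange(len(observed)), idx] = 1.0
    return float(roc_auc_score(y.ravel(), scores.ravel()))


@dataclass
class MetricsReport:
    """Per-record and pooled evaluation results."""

    alphabet: str
    per_record: dict[str, dict[str, float]]
    pooled: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"alphabet": self.alphabet,
                   "per_record": self.per_record,
                   "pooled": self.pooled}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path: str | Path) -> None:
        fields = ["id", "length", "accuracy", "sov99", "miauc"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for rec_id, row in self.per_record.items():
                writer.writerow({"id": rec_id, **{k: row[k] for k in fields[1:]}})
            writer.writerow({"id": "POOLED",
                             "length": self.pooled["n_residues"],
                             "accuracy": self.pooled["accuracy"],
                             "sov99": self.pooled["sov99"],
                             "miauc": self.pooled["miauc"]})


def evaluate(records: list[ProteinRecord],
             predictions: Mapping[str, np.ndarray],
             alphabet: StateAlphabet) -> MetricsReport:
    """Evaluate per-residue probability predictions against record labels.

    Accuracy and MiAUC are pooled over all residues; SOV99 is computed per
    chain and averaged weighted by chain length.
    """
    per_record: dict[str, dict[str, float]] = {}
    all_obs: list[str] = []
    all_scores: list[np.ndarray] = []
    sov_weighted = 0.0
    n_total = 0
    n_correct = 0
    for rec in records:
        if rec.id not in predictions:
            raise KeyError(f"missing prediction for record {rec.id!r}")
        probs = np.asarray(predictions[rec.id], dtype=float)
        obs = rec.labels(alphabet)
        pred = "".join(alphabet.states[j] for j in probs.argmax(axis=1))
        acc = accuracy(obs, pred)
        sov = sov99(obs, pred, alphabet)
        mi = miauc(obs, probs, alphabet)
        per_record[rec.id] = {"length": float(rec.length), "accuracy": acc,
                              "sov99": sov, "miauc": mi}
        all_obs.append(obs)
        all_scores.append(probs)
        sov_weighted += sov * rec.length
        n_total += rec.length
        n_correct += sum(o == p for o, p in zip(obs, pred))
    pooled_obs = "".join(all_obs)
    pooled = {
        "n_residues": float(n_total),
        "accuracy": 100.0 * n_correct / n_total,
        "sov99": sov_weighted / n_total,
        "miauc": miauc(pooled_obs, np.vstack(all_scores), alphabet),
    }
    return MetricsReport(alphabet="".join(alphabet.states),
                         per_record=per_record, pooled=pooled)
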