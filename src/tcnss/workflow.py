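"""Training, prediction, evaluation orchestration and parameter sweeps.

The training loop minimizes the blended hard/soft objective (see
:mod:`tcnss.distill`) by mini-batch adaptive-moment gradient descent over
padded variable-length batches; padding positions are excluded from losses,
metrics and batch-norm statistics via masks.  Runs are deterministic given
the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from .distill import DistillConfig, TeacherLogits, soften
from .featurize import (EmbeddingModel, FeatureMatrix, PhysChemTable,
                        featurize_record, train_embeddings)
from .mstcn import BidirSpec, MultiScaleSpec
from .nn import Adam, Tensor, no_grad
from .nn import autodiff as ad
from .predictor import (AttentionSpec, ClassifierSpec, RecurrentSpec, SSModel)
from .seqdata import ProteinRecord, Q3, Q8, StateAlphabet

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """All architecture and training hyperparameters, with spec defaults."""

    alphabet: str = "HEC"                      # "HEC" (Q3) or "HGIEBTSC" (Q8)
    # featurization
    kmer: int = 1
    embedding_dim: int = 16
    embedding_window: int = 5
    embedding_epochs: int = 20
    embedding_negative: int = 5
    window_width: int = 19                     # sliding-window augmentation
    # improved TCN
    scales: tuple[int, ...] = (1, 9, 81, 729, 6561)
    kernel_size: int = 3
    tcn_channels: int = 32
    conv_layers_per_block: int = 3
    tcn_width: int = 64
    # BiLSTM-MHA head
    lstm_layers: int = 3
    lstm_hidden: int = 64
    dropout: float = 0.2
    attention_heads: int = 3
    attention_width: int = 128
    classifier_width: int = 64
    # distillation
    distill: bool = False
    rho: float = 2.0
    alpha: float = 0.2
    scale_kd_by_rho_sq: bool = True
    # optimization
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 100
    patience: int = 10
    target_train_acc: float | None = None      # optional convergence stop
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.scales, list):
            self.scales = tuple(self.scales)
        if self.alphabet not in ("HEC", "HGIEBTSC"):
            raise ValueError("alphabet must be 'HEC' or 'HGIEBTSC'")

    @property
    def state_alphabet(self) -> StateAlphabet:
        return Q3 if self.alphabet == "HEC" else Q8

    @property
    def n_classes(self) -> int:
        return len(self.alphabet)

    def distill_config(self) -> DistillConfig:
        return DistillConfig(temperature=self.rho, alpha=self.alpha,
                             scale_by_temperature_sq=self.scale_kd_by_rho_sq)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)


@dataclass
class TrainReport:
    """Per-epoch history and the information needed to reproduce a run."""

    history: list[dict[str, float]]
    best_epoch: int
    best_val_accuracy: float
    wall_time_s: float
    seed: int
    config: dict
    checkpoint_path: str | None = None

    @property
    def final_train_accuracy(self) -> float:
        return self.history[-1]["train_acc"]


def build_model(cfg: ModelConfig, d_features: int) -> SSModel:
    tcn = BidirSpec(MultiScaleSpec(scales=cfg.scales,
                                   kernel_size=cfg.kernel_size,
                                   channels=cfg.tcn_channels,
                                   out_width=cfg.tcn_width,
                                   conv_layers=cfg.conv_layers_per_block,
                                   dropout=cfg.dropout))
    rec = RecurrentSpec(layers=cfg.lstm_layers, hidden=cfg.lstm_hidden,
                        dropout=cfg.dropout)
    attn = AttentionSpec(heads=cfg.attention_heads,
                         model_width=cfg.attention_width)
    clf = ClassifierSpec(classes=cfg.n_classes,
                         fused_width=cfg.classifier_width)
    return SSModel(d_features, tcn, rec, attn, clf,
                   embed_dropout=cfg.dropout, seed=cfg.seed)


def build_featurizer(train_records: list[ProteinRecord],
                     cfg: ModelConfig) -> tuple[PhysChemTable, EmbeddingModel]:
    table = PhysChemTable.default()
    emb = train_embeddings([r.sequence for r in train_records],
                           k=cfg.kmer, window=cfg.embedding_window,
                           dim=cfg.embedding_dim, epochs=cfg.embedding_epochs,
                           negative=cfg.embedding_negative, seed=cfg.seed)
    return table, emb


def featurize_all(records: list[ProteinRecord], table: PhysChemTable,
                  emb: EmbeddingModel) -> list[FeatureMatrix]:
    return [featurize_record(r, table, emb) for r in records]


def _pad_batch(feats: list[FeatureMatrix]) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray]:
    B = len(feats)
    L = max(f.length for f in feats)
    D = feats[0].width
    x = np.zeros((B, L, D))
    lengths = np.zeros(B, dtype=int)
    for i, f in enumerate(feats):
        x[i, :f.length] = f.rows
        lengths[i] = f.length
    mask = (np.arange(L)[None, :] < lengths[:, None]).astype(float)[:, :, None]
    return x, lengths, mask


def _batch_loss(model: SSModel, cfg: ModelConfig, x: np.ndarray,
                lengths: np.ndarray, mask: np.ndarray,
                label_idx: np.ndarray,
                teacher_z: np.ndarray | None):
    """Masked blended loss for one padded batch.

    Returns (loss tensor, n_correct, n_valid).  label_idx is (B, L) with -1
    at padding.  When distillation is off (or alpha == 0) the soft term is
    not computed at all, so such runs are bit-identical to hard-only runs.
    """
    K = cfg.n_classes
    probs, logits = model.forward_batch(Tensor(x), lengths, mask)
    onehot = np.zeros(logits.shape)
    valid = label_idx >= 0
    b_idx, t_idx = np.nonzero(valid)
    onehot[b_idx, t_idx, label_idx[b_idx, t_idx]] = 1.0
    n_valid = float(valid.sum())
    logp = ad.log_softmax(logits, axis=-1)
    ce = ad.mul(ad.tsum(ad.mul(logp, onehot * mask)), -1.0 / n_valid)
    loss = ce
    if cfg.distill and cfg.alpha > 0.0 and teacher_z is not None:
        rho = cfg.rho
        p_t = soften(teacher_z, rho)
        log_t = np.log(np.clip(p_t, 1e-300, None))
        logp_s = ad.log_softmax(ad.mul(logits, 1.0 / rho), axis=-1)
        # KL(teacher || student) per valid position, averaged
        cross = ad.tsum(ad.mul(logp_s, p_t * mask))
        ent = float((p_t * log_t * mask).sum())
        kd = ad.mul(ad.add(ad.mul(cross, -1.0), ent), 1.0 / n_valid)
        if cfg.scale_kd_by_rho_sq:
            kd = ad.mul(kd, rho ** 2)
        loss = ad.add(ad.mul(ce, 1.0 - cfg.alpha), ad.mul(kd, cfg.alpha))
    pred = probs.data.argmax(axis=-1)
    n_correct = int((pred[valid] == label_idx[valid]).sum())
    return loss, n_correct, n_valid


def _label_matrix(records: list[ProteinRecord], alphabet: StateAlphabet,
                  L: int) -> np.ndarray:
    out = np.full((len(records), L), -1, dtype=int)
    for i, rec in enumerate(records):
        out[i, :rec.length] = alphabet.encode(rec.labels(alphabet))
    return out


def _teacher_matrix(records: list[ProteinRecord], teacher: TeacherLogits,
                    L: int, K: int) -> np.ndarray:
    z = np.zeros((len(records), L, K))
    for i, rec in enumerate(records):
        z[i, :rec.length] = teacher[rec.id]
    return z


def train(train_records: list[ProteinRecord],
          val_records: list[ProteinRecord],
          cfg: ModelConfig,
          teacher: TeacherLogits | None = None,
          table: PhysChemTable | None = None,
          emb: EmbeddingModel | None = None,
          ) -> tuple[SSModel, EmbeddingModel, TrainReport]:
    """Train a model on labeled records; returns (model, embeddings, report).

    The best-validation-accuracy parameters are restored at the end.  The
    report's config snapshot plus the same records reproduce the run
    bit-for-bit.
    """
    t0 = time.time()
    alphabet = cfg.state_alphabet
    if cfg.distill:
        if teacher is None:
            raise ValueError("distillation enabled but no teacher logits given")
        missing = [r.id for r in train_records if r.id not in teacher]
        if missing:
            raise ValueError(f"teacher logits missing for records: {missing}")
        teacher.validate_against(train_records)
    if table is None or emb is None:
        table_b, emb_b = build_featurizer(train_records, cfg)
        table = table or table_b
        emb = emb or emb_b

    feats = featurize_all(train_records, table, emb)
    val_feats = featurize_all(val_records, table, emb)
    model = build_model(cfg, feats[0].width)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)

    history: list[dict[str, float]] = []
    best_val = -1.0
    best_epoch = -1
    best_state: dict[str, np.ndarray] | None = None
    since_best = 0
    n = len(train_records)

    for epoch in range(cfg.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        ep_valid = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_feats = [feats[i] for i in idx]
            batch_recs = [train_records[i] for i in idx]
            x, lengths, mask = _pad_batch(batch_feats)
            label_idx = _label_matrix(batch_recs, alphabet, x.shape[1])
            tz = (_teacher_matrix(batch_recs, teacher, x.shape[1],
                                  cfg.n_classes)
                  if cfg.distill and teacher is not None else None)
            loss, n_correct, n_valid = _batch_loss(model, cfg, x, lengths,
                                                   mask, label_idx, tz)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            ep_loss += float(loss.data) * n_valid
            ep_correct += n_correct
            ep_valid += n_valid
        entry = {"epoch": float(epoch),
                 "train_loss": ep_loss / ep_valid,
                 "train_acc": ep_correct / ep_valid}
        if val_records:
            val_acc = _token_accuracy(model, val_feats, val_records, alphabet)
            entry["val_acc"] = val_acc
        else:
            val_acc = entry["train_acc"]
        history.append(entry)
        if val_acc > best_val:
            best_val = val_acc
            best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
        if (cfg.target_train_acc is not None
                and entry["train_acc"] >= cfg.target_train_acc):
            logger.info("target train accuracy reached at epoch %d", epoch)
            break
        if cfg.patience and since_best >= cfg.patience:
            logger.info("early stop at epoch %d (no improvement for %d)",
                        epoch, cfg.patience)
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    report = TrainReport(history=history, best_epoch=best_epoch,
                         best_val_accuracy=best_val,
                         wall_time_s=time.time() - t0, seed=cfg.seed,
                         config=cfg.to_dict())
    return model, emb, report


def _token_accuracy(model: SSModel, feats: list[FeatureMatrix],
                    records: list[ProteinRecord],
                    alphabet: StateAlphabet) -> float:
    model.eval()
    n_correct = 0
    n_total = 0
    for f, rec in zip(feats, records):
        with no_grad():
            probs, _ = model.forward_batch(
                Tensor(f.rows[None]), np.array([f.length]),
                np.ones((1, f.length, 1)))
        pred = probs.data[0].argmax(axis=1)
        true = np.array(alphabet.encode(rec.labels(alphabet)))
        n_correct += int((pred == true).sum())
        n_total += rec.length
    model.train()
    return n_correct / n_total


def predict(records: list[ProteinRecord], model: SSModel,
            table: PhysChemTable, emb: EmbeddingModel,
            alphabet: StateAlphabet) -> tuple[dict[str, np.ndarray],
                                              dict[str, str]]:
    """Evaluation-mode per-residue probabilities and argmax label strings."""
    from .predictor import forward as forward_one

    model.eval()
    probs: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for rec in records:
        f = featurize_record(rec, table, emb)
        p = forward_one(f, model)
        probs[rec.id] = p
        labels[rec.id] = "".join(alphabet.states[j] for j in p.argmax(axis=1))
    return probs, labels


def evaluate(records: list[ProteinRecord], probs: dict[str, np.ndarray],
             alphabet: StateAlphabet) -> metrics_mod.MetricsReport:
    return metrics_mod.evaluate(records, probs, alphabet)


# -- checkpointing ------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: SSModel, cfg: ModelConfig, emb: EmbeddingModel,
                    outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "params.npz", **model.state_dict())
    snapshot = {"version": CHECKPOINT_VERSION, "config": cfg.to_dict()}
    (outdir / "config.json").write_text(json.dumps(snapshot, indent=1))
    emb.save(outdir / "embedding")
    return outdir


def load_checkpoint(outdir: str | Path) -> tuple[SSModel, ModelConfig,
                                                 EmbeddingModel]:
    outdir = Path(outdir)
    snapshot = json.loads((outdir / "config.json").read_text())
    if snapshot.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: "
                         f"{snapshot.get('version')}")
    cfg = ModelConfig.from_dict(snapshot["config"])
    emb = EmbeddingModel.load(outdir / "embedding")
    table = PhysChemTable.default()
    d_features = 21 + table.width + emb.dim
    model = build_model(cfg, d_features)
    with np.load(outdir / "params.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model, cfg, emb


def desk_scale_config(**overrides) -> ModelConfig:
    """A small CPU-friendly configuration used by tests and examples.

    Keeps the full architecture (all five dilation scales, three conv
    layers per block, three BiLSTM layers, three attention heads) but with
    narrow widths so full training runs finish in seconds to minutes on
    one CPU core.
    """
    base = dict(tcn_channels=12, tcn_width=24, lstm_hidden=16,
                attention_width=24, classifier_width=24,
                embedding_epochs=3, batch_size=30, learning_rate=5e-3,
                patience=0)
    base.update(overrides)
    return ModelConfig(**base)


def distillation_comparison(seed: int, epochs: int = 100,
                            margin: float = 4.0) -> dict[str, float]:
    """Paired comparison: distilled vs non-distilled student, one seed.

    Draws a hard-mode corpus (30 train / 10 validation / 60 test chains),
    builds the oracle teacher for the training records, and trains two
    students from identical initialization — one with the blended
    distillation loss, one with the hard loss only.  Both restore their
    best-validation-accuracy checkpoint.  Returns test Q3 accuracies.
    """
    import dataclasses as _dc

    from .synthetic import generate, hard_preset, oracle_teacher

    gen = hard_preset(seed=seed)
    records = generate(gen)
    train_recs, val_recs, test_recs = records[:30], records[30:40], records[40:]
    teacher = oracle_teacher(train_recs, noise_sd=gen.teacher_noise,
                             margin=margin, seed=seed + 1000, alphabet=Q3)
    base = desk_scale_config(dropout=0.0, epochs=epochs, seed=seed)
    out: dict[str, float] = {}
    for name, distil in (("plain", False), ("distilled", True)):
        cfg = _dc.replace(base, distill=distil)
        model, emb, _ = train(train_recs, val_recs, cfg,
                              teacher=teacher if distil else None)
        table = PhysChemTable.default()
        probs, _labels = predict(test_recs, model, table, emb, Q3)
        out[name] = metrics_mod.evaluate(test_recs, probs, Q3).pooled["accuracy"]
    return out


# -- parameter sweep ----------------------------------------------------

def sweep(scales_grid: list[tuple[int, ...]], alphas: list[float],
          base_cfg: ModelConfig,
          train_records: list[ProteinRecord],
          val_records: list[ProteinRecord],
          teacher: TeacherLogits | None = None) -> pd.DataFrame:
    """Train one model per (scales, alpha) grid cell; return the accuracy surface."""
    if not scales_grid or not alphas:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for scales in scales_grid:
        for alpha in alphas:
            cfg = dataclasses.replace(base_cfg, scales=tuple(scales),
                                      alpha=alpha)
            model, emb, report = train(train_records, val_records, cfg,
                                       teacher=teacher)
            rows.append({"scales": "-".join(str(s) for s in scales),
                         "alpha": alpha,
                         "seed": cfg.seed,
                         "val_accuracy": report.best_val_accuracy,
                         "epochs_run": len(report.history)})
            logger.info("sweep cell scales=%s alpha=%.2f -> val acc %.4f",
                        scales, alpha, report.best_val_accuracy)
    return pd.DataFrame(rows)
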